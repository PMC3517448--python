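import math

import numpy as np
import pytest

from orthopath import (
    SimulationConfig,
    bidirectional_best_hits,
    expand,
    generate_associations,
    generate_expression_list,
    generate_pangenome,
    map_template_pathway,
    plant_pathway,
    simulate_study,
)
from orthopath.types import GeneRecord, Proteome


class TestGeneratePangenome:
    def test_zero_divergence_copies_are_identical(self):
        cfg = SimulationConfig(n_families=6, divergence=0.0, pathway_size=3, seed=1)
        pg = generate_pangenome(cfg)
        for oa, ga, ob, gb in pg.ortholog_pairs:
            assert pg.proteome(oa)[ga].sequence == pg.proteome(ob)[gb].sequence

    def test_fixed_seed_is_byte_deterministic(self):
        cfg = SimulationConfig(n_families=8, divergence=0.2, pathway_size=3, seed=5)
        a, b = generate_pangenome(cfg), generate_pangenome(cfg)
        for pa, pb in zip(a.proteomes, b.proteomes):
            assert [(g.gene_id, g.sequence) for g in pa] == [
                (g.gene_id, g.sequence) for g in pb
            ]
        assert a.ortholog_pairs == b.ortholog_pairs

    def test_planted_ortholog_identity_respects_divergence_bound(self):
        """Each planted pair diverges along two branches, so identity stays
        above 1 - 2*divergence - 3 sigma of the binomial mutation count."""
        cfg = SimulationConfig(n_families=10, divergence=0.15, pathway_size=3, seed=2)
        pg = generate_pangenome(cfg)
        for oa, ga, ob, gb in pg.ortholog_pairs:
            sa = pg.proteome(oa)[ga].sequence
            sb = pg.proteome(ob)[gb].sequence
            assert len(sa) == len(sb)
            ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
            d = 2 * cfg.divergence
            sigma = math.sqrt(d * (1 - d) / len(sa))
            assert ident >= 1 - d - 3 * sigma

    def test_bbh_recovers_planted_orthologs_at_moderate_divergence(self):
        cfg = SimulationConfig(n_families=50, divergence=0.15, pathway_size=5, seed=3)
        pg = generate_pangenome(cfg)
        truth = {(a, b) for _, a, _, b in pg.ortholog_pairs}
        rec = {(p.template_gene, p.target_gene)
               for p in bidirectional_best_hits(*pg.proteomes) if p.reciprocal}
        assert len(rec & truth) / len(truth) >= 0.95

    def test_paralogs_generated_within_family_size_range(self):
        cfg = SimulationConfig(n_families=10, family_size_range=(2, 3),
                               divergence=0.1, pathway_size=3, seed=4)
        pg = generate_pangenome(cfg)
        for org, fams in pg.families.items():
            for fam, ids in fams.items():
                assert 2 <= len(ids) <= 3


class TestPlantPathway:
    def test_all_singleton_operons_give_zero_operon_recruits(self):
        cfg = SimulationConfig(n_families=12, divergence=0.1, pathway_size=4,
                               n_operons_for_pathway=4, padding_per_operon=0, seed=6)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        assert all(len(g) == 1 for _, g in planted.target_operons.operons)
        model = map_template_pathway(
            planted.template, pg.proteomes[0], pg.proteomes[-1],
            planted.target_operons,
        )
        expanded = expand(model, operons=planted.target_operons)
        assert len(expanded) == len(model)

    def test_true_padding_genes_recovered_by_operon_expansion(self):
        """An 8-gene pathway in 2 operons with 2 designated-true padding
        genes: operon expansion recruits exactly those 2 gold genes."""
        cfg = SimulationConfig(n_families=16, divergence=0.1, pathway_size=8,
                               n_operons_for_pathway=2, padding_per_operon=1,
                               padding_true_fraction=1.0, seed=7)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        extra_gold = planted.gold - {
            pg.families[planted.target_organism][f][0]
            for f in planted.pathway_families
        }
        assert len(extra_gold) == 2
        model = map_template_pathway(
            planted.template, pg.proteomes[0], pg.proteomes[-1],
            planted.target_operons,
        )
        expanded = expand(model, operons=planted.target_operons)
        recruited = expanded.gene_ids("recruited")
        assert recruited == extra_gold

    def test_deleted_template_families_become_holes(self):
        cfg = SimulationConfig(n_families=12, divergence=0.1, pathway_size=5, seed=8)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        target = pg.proteomes[-1]
        drop_fams = planted.pathway_families[:2]
        dropped = {pg.families[target.organism_id][f][0] for f in drop_fams}
        reduced = Proteome(
            target.organism_id,
            [GeneRecord(g.gene_id, g.organism_id, g.sequence)
             for g in target if g.gene_id not in dropped],
        )
        model = map_template_pathway(
            planted.template, pg.proteomes[0], reduced, None
        )
        assert len(model.holes) == 2
        assert len(model) == 3


class TestGenerateAssociations:
    def test_full_sensitivity_no_decoys_only_links_gold_pairs(self):
        cfg = SimulationConfig(n_families=15, divergence=0.1, pathway_size=5,
                               edge_sensitivity=1.0, decoy_rate=0.0, seed=9)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        universe = set(pg.proteome(planted.target_organism).gene_ids)
        edges = generate_associations(planted.gold, universe, cfg, types=("ppi",))
        n_gold = len(planted.gold)
        assert len(edges) == n_gold * (n_gold - 1) // 2
        for e in edges:
            assert e.gene_a in planted.gold and e.gene_b in planted.gold

    def test_zero_sensitivity_zero_decoys_gives_no_edges(self):
        cfg = SimulationConfig(n_families=15, divergence=0.1, pathway_size=5,
                               edge_sensitivity=0.0, decoy_rate=0.0, seed=9)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        universe = set(pg.proteome(planted.target_organism).gene_ids)
        assert len(generate_associations(planted.gold, universe, cfg)) == 0

    def test_decoy_edges_touch_exactly_one_gold_gene(self):
        cfg = SimulationConfig(n_families=15, divergence=0.1, pathway_size=5,
                               edge_sensitivity=0.0, decoy_rate=1.0, seed=9)
        pg = generate_pangenome(cfg)
        planted = plant_pathway(cfg, pg)
        universe = set(pg.proteome(planted.target_organism).gene_ids)
        edges = generate_associations(planted.gold, universe, cfg)
        assert len(edges) > 0
        for e in edges:
            assert (e.gene_a in planted.gold) != (e.gene_b in planted.gold)


class TestGenerateExpressionList:
    UNIVERSE = {f"g{i:02d}" for i in range(40)}
    GOLD = {f"g{i:02d}" for i in range(12)}

    def test_full_sensitivity_no_fpr_returns_gold(self):
        out = generate_expression_list(self.GOLD, 1.0, 0.0, self.UNIVERSE, seed=1)
        assert out == self.GOLD

    def test_zero_sensitivity_no_fpr_is_empty(self):
        assert generate_expression_list(self.GOLD, 0.0, 0.0, self.UNIVERSE, 1) == set()

    def test_fixed_seed_draw_is_reproducible(self):
        a = generate_expression_list(self.GOLD, 0.5, 0.1, self.UNIVERSE, seed=123)
        b = generate_expression_list(self.GOLD, 0.5, 0.1, self.UNIVERSE, seed=123)
        assert a == b
        assert 0 < len(a & self.GOLD) < len(self.GOLD)


class TestStudyDeterminism:
    def test_same_config_same_study(self):
        cfg = SimulationConfig(n_families=12, divergence=0.15, pathway_size=4,
                               seed=10)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.planted.gold == s2.planted.gold
        assert s1.expression == s2.expression
        assert {(e.gene_a, e.gene_b, e.type) for e in s1.associations} == {
            (e.gene_a, e.gene_b, e.type) for e in s2.associations
        }
        assert s1.planted.target_operons.operons == s2.planted.target_operons.operons
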