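import random

import pytest

from orthopath import (
    GeneRecord,
    MappingConfig,
    ModelEntry,
    OperonMap,
    PathwayModel,
    Proteome,
    SimulationConfig,
    TemplatePathway,
    best_hits,
    bidirectional_best_hits,
    generate_pangenome,
    map_template_pathway,
    merge_models,
    transfer_interactions,
)
from orthopath.mapping import (
    build_candidates,
    selection_objective,
    solve_assignment_exact,
    solve_assignment_greedy,
)

from .conftest import make_proteome, random_protein
from .oracles import enumerate_assignment_optimum


def _clone_proteome(prot: Proteome, organism_id: str, rename=None) -> Proteome:
    out = Proteome(organism_id)
    for g in prot:
        gid = rename(g.gene_id) if rename else g.gene_id
        out.add(GeneRecord(gid, organism_id, g.sequence))
    return out


class TestBestHits:
    def test_identical_proteomes_hit_themselves(self):
        p = make_proteome("a", 8, seed=5)
        q = _clone_proteome(p, "a")
        hits = best_hits(p, q)
        assert set(hits) == set(p.gene_ids)
        assert all(h.subject_id == qid for qid, h in hits.items())

    def test_zero_e_cutoff_gives_no_hits(self):
        p = make_proteome("a", 4, seed=5)
        assert best_hits(p, p, MappingConfig(e_cutoff=0.0)) == {}

    def test_tie_breaks_to_smallest_subject_id(self):
        seq = random_protein(random.Random(0), 100)
        query = Proteome("q", [GeneRecord("q1", "q", seq)])
        subject = Proteome(
            "s",
            [GeneRecord("s_b", "s", seq), GeneRecord("s_a", "s", seq)],
        )
        hits = best_hits(query, subject)
        assert hits["q1"].subject_id == "s_a"


class TestBidirectionalBestHits:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_symmetry_under_argument_swap(self, seed):
        cfg = SimulationConfig(n_families=12, divergence=0.15, pathway_size=4,
                               seed=seed)
        pg = generate_pangenome(cfg)
        p1, p2 = pg.proteomes
        fwd = {(p.template_gene, p.target_gene)
               for p in bidirectional_best_hits(p1, p2) if p.reciprocal}
        rev = {(p.target_gene, p.template_gene)
               for p in bidirectional_best_hits(p2, p1) if p.reciprocal}
        assert fwd == rev

    def test_identical_proteomes_give_identity_pairing(self):
        p = make_proteome("a", 10, seed=9)
        q = _clone_proteome(p, "b", rename=lambda g: g.replace("a_", "b_"))
        pairs = {(x.template_gene, x.target_gene)
                 for x in bidirectional_best_hits(p, q) if x.reciprocal}
        assert pairs == {(g, g.replace("a_", "b_")) for g in p.gene_ids}

    def test_planted_orthologs_recovered_at_80pct_identity(self):
        cfg = SimulationConfig(n_families=20, divergence=0.2, pathway_size=4, seed=4)
        pg = generate_pangenome(cfg)
        truth = {(a, b) for _, a, _, b in pg.ortholog_pairs}
        rec = {(p.template_gene, p.target_gene)
               for p in bidirectional_best_hits(*pg.proteomes) if p.reciprocal}
        assert truth <= rec

    def test_duplicated_family_never_yields_two_reciprocal_pairs(self):
        cfg = SimulationConfig(n_families=8, family_size_range=(2, 2),
                               divergence=0.1, pathway_size=3, seed=6)
        pg = generate_pangenome(cfg)
        pairs = bidirectional_best_hits(*pg.proteomes)
        per_gene = {}
        for p in pairs:
            if p.reciprocal:
                per_gene[p.template_gene] = per_gene.get(p.template_gene, 0) + 1
        assert all(v <= 1 for v in per_gene.values())


def _random_instance(rng, n_members, max_candidates, n_operons):
    targets = [f"t{i:02d}" for i in range(n_members * max_candidates)]
    operon_of = {
        t: (f"op{rng.randrange(n_operons)}" if rng.random() < 0.8 else None)
        for t in targets
    }
    candidates = {}
    pool = list(targets)
    rng.shuffle(pool)
    k = 0
    for m in range(n_members):
        n_c = rng.randint(0, max_candidates)
        cands = []
        for _ in range(n_c):
            cands.append((pool[k], round(rng.uniform(5, 100), 2)))
            k += 1
        candidates[f"m{m:02d}"] = cands
    omap = OperonMap("x")
    by_op = {}
    for t, op in operon_of.items():
        if op is not None:
            by_op.setdefault(op, []).append(t)
    for op, genes in sorted(by_op.items()):
        omap.add_operon(op, sorted(genes))
    return candidates, operon_of, omap


class TestAssignmentSolver:
    @pytest.mark.parametrize("seed", range(30))
    def test_exact_solver_matches_enumeration(self, seed):
        rng = random.Random(seed)
        candidates, operon_of, omap = _random_instance(rng, rng.randint(2, 8), 4, 4)
        lam = rng.choice([0.0, 1.0, 5.0, 25.0])
        assign = solve_assignment_exact(candidates, omap, lam)
        got = selection_objective(assign, omap, lam)
        want = enumerate_assignment_optimum(candidates, operon_of, lam)
        assert got == pytest.approx(want)

    def test_zero_penalty_reduces_to_independent_best_hits(self):
        candidates = {
            "m1": [("t1", 50.0), ("t2", 49.0)],
            "m2": [("t3", 20.0), ("t4", 20.0)],  # tie -> lexicographic
            "m3": [],
        }
        assign = solve_assignment_exact(candidates, None, 0.0)
        assert assign["m1"] == ("t1", 50.0)
        assert assign["m2"] == ("t3", 20.0)
        assert assign["m3"] is None

    def test_large_penalty_prefers_co_operonic_solution(self):
        """True genes clustered in 2 operons beat slightly better decoys
        scattered across 6 operons when the operon penalty is large."""
        omap = OperonMap("x")
        omap.add_operon("opA", ["a1", "a2", "a3"])
        omap.add_operon("opB", ["b1", "b2", "b3"])
        for i in range(6):
            omap.add_operon(f"decoy{i}", [f"d{i}"])
        candidates = {}
        clustered = ["a1", "a2", "a3", "b1", "b2", "b3"]
        for i, t in enumerate(clustered):
            candidates[f"m{i}"] = sorted(
                [(t, 100.0), (f"d{i}", 101.0)], key=lambda c: (-c[1], c[0])
            )
        assign = solve_assignment_exact(candidates, omap, 10.0)
        chosen = {g for g, _ in assign.values()}
        assert chosen == set(clustered)
        # sanity: with no penalty the decoys win on raw bits
        free = solve_assignment_exact(candidates, omap, 0.0)
        assert {g for g, _ in free.values()} == {f"d{i}" for i in range(6)}

    def test_greedy_matches_exact_on_small_instances(self):
        for seed in range(10):
            rng = random.Random(100 + seed)
            candidates, _, omap = _random_instance(rng, rng.randint(2, 6), 3, 3)
            lam = rng.choice([0.0, 1.0, 5.0])
            exact = selection_objective(
                solve_assignment_exact(candidates, omap, lam), omap, lam
            )
            greedy = selection_objective(
                solve_assignment_greedy(candidates, omap, lam), omap, lam
            )
            assert greedy <= exact + 1e-9
            assert greedy >= 0.8 * exact - 1e-9


def _ortholog_fixture(n_template, n_shared, seed=0):
    """Template proteome of n_template genes; target carries identical
    orthologs for the first n_shared of them."""
    rng = random.Random(seed)
    tpl = Proteome(
        "tpl",
        [GeneRecord(f"tg{i:02d}", "tpl", random_protein(rng, 90))
         for i in range(n_template)],
    )
    tgt = Proteome(
        "tgt",
        [GeneRecord(f"xg{i:02d}", "tgt", tpl[f"tg{i:02d}"].sequence)
         for i in range(n_shared)],
    )
    pathway = TemplatePathway("demo", "tpl", members=set(tpl.gene_ids))
    return tpl, tgt, pathway


class TestMapTemplatePathway:
    def test_six_of_eleven_mappable_gives_six_entries_five_holes(self):
        tpl, tgt, pathway = _ortholog_fixture(11, 6)
        model = map_template_pathway(pathway, tpl, tgt, None)
        assert len(model) == 6
        assert len(model.holes) == 5
        assert all(e.status == "initial" for e in model.entries.values())
        assert {h["template_gene"] for h in model.holes} == {
            f"tg{i:02d}" for i in range(6, 11)
        }

    def test_entries_carry_mapped_from_provenance(self):
        tpl, tgt, pathway = _ortholog_fixture(4, 4)
        model = map_template_pathway(pathway, tpl, tgt, None)
        for gid, entry in model.entries.items():
            assert entry.mapped_from == [("tpl", gid.replace("xg", "tg"))]

    def test_candidate_sets_shrink_with_stricter_thresholds(self):
        cfg = SimulationConfig(n_families=12, divergence=0.1, pathway_size=5, seed=3)
        pg = generate_pangenome(cfg)
        from orthopath import plant_pathway

        planted = plant_pathway(cfg, pg)
        p1, p2 = pg.proteomes
        loose, _, _ = build_candidates(
            planted.template, p1, p2, MappingConfig(e_cutoff=1e-3,
                                                    candidate_fraction=0.5)
        )
        tight, _, _ = build_candidates(
            planted.template, p1, p2, MappingConfig(e_cutoff=1e-9,
                                                    candidate_fraction=0.95)
        )
        for m in loose:
            assert {g for g, _ in tight[m]} <= {g for g, _ in loose[m]}


class TestMergeModels:
    def _fragment(self, genes, template="eco"):
        frag = PathwayModel("tgt")
        for tgene, tgt_gene in genes:
            frag.add_entry(
                ModelEntry(tgt_gene, "initial",
                           sources=[f"template:{template}:p"],
                           mapped_from=[(template, tgene)])
            )
        return frag

    def test_single_fragment_merge_is_identity(self):
        frag = self._fragment([("g1", "t1"), ("g2", "t2")])
        merged = merge_models([frag])
        assert set(merged.entries) == {"t1", "t2"}
        assert not any(e.conflict for e in merged.entries.values())

    def test_disjoint_fragments_sum_their_entries(self):
        a = self._fragment([("g1", "t1")], template="eco")
        b = self._fragment([("g2", "t2")], template="bsu")
        merged = merge_models([a, b])
        assert len(merged) == 2

    def test_shared_target_gene_keeps_all_provenances_and_flags_conflict(self):
        a = self._fragment([("g1", "t1")], template="eco")
        b = self._fragment([("g9", "t1")], template="bsu")
        merged = merge_models([a, b])
        assert len(merged) == 1
        entry = merged.entries["t1"]
        assert set(entry.mapped_from) == {("eco", "g1"), ("bsu", "g9")}
        assert entry.conflict

    def test_mixed_target_organisms_rejected(self):
        a = PathwayModel("tgt1")
        b = PathwayModel("tgt2")
        with pytest.raises(ValueError, match="mixed"):
            merge_models([a, b])


class TestTransferInteractions:
    def _mapped_model(self, pairs):
        model = PathwayModel("tgt")
        for tgene, tgt_gene in pairs:
            model.add_entry(
                ModelEntry(tgt_gene, "initial", sources=["template:tpl:demo"],
                           mapped_from=[("tpl", tgene)])
            )
        return model

    def test_no_interactions_changes_nothing(self):
        pathway = TemplatePathway("demo", "tpl", members={"a", "b"})
        model = self._mapped_model([("a", "x"), ("b", "y")])
        transfer_interactions(pathway, model)
        assert model.edges == set()

    def test_half_mapped_interaction_not_transferred(self):
        pathway = TemplatePathway("demo", "tpl", members={"a", "b"})
        pathway.add_interaction("a", "b", "pathway")
        model = self._mapped_model([("a", "x")])
        transfer_interactions(pathway, model)
        assert model.edges == set()

    def test_linear_chain_transfers_with_labels_and_is_idempotent(self):
        pathway = TemplatePathway("demo", "tpl", members={"a", "b", "c"})
        pathway.add_interaction("a", "b", "pathway")
        pathway.add_interaction("b", "c", "regulates")
        model = self._mapped_model([("a", "x"), ("b", "y"), ("c", "z")])
        transfer_interactions(pathway, model)
        assert model.edges == {("x", "y", "pathway"), ("y", "z", "regulates")}
        transfer_interactions(pathway, model)
        assert len(model.edges) == 2
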