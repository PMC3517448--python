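"""Synthetic pan-genomes with planted pathways and known ground truth.

The generator emulates the material a template-to-target mapping study
needs: a set of related prokaryotic proteomes descended from shared gene
families, a planted pathway whose target-organism copies sit in a few
operons padded with extra genes, association edges (ppi / co-expression /
co-evolution) over the true members with controllable sensitivity and decoy
rate, and a differential-expression gene list.  Every stage is driven by a
single integer seed and is byte-deterministic.

The mutation model is point substitution only by default (an optional indel
rate exists); proposals are drawn proportional to BLOSUM62 exchangeabilities
so that diverged orthologs keep realistic bit scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .types import (
    AMINO_ACIDS,
    AssociationEdge,
    AssociationEdgeSet,
    GeneRecord,
    OperonMap,
    Proteome,
    TemplatePathway,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth study conditions for one synthetic dataset."""

    n_organisms: int = 2
    n_families: int = 30
    family_size_range: tuple[int, int] = (1, 1)  # paralog copies per organism
    divergence: float = 0.15  # expected substituted fraction per ortholog copy
    pathway_size: int = 8
    n_operons_for_pathway: int = 2
    padding_per_operon: int = 1  # non-pathway genes padded into each operon
    padding_true_fraction: float = 0.5  # fraction of padding genes that are gold
    decoy_rate: float = 0.1
    edge_sensitivity: float = 0.8
    seq_len_range: tuple[int, int] = (80, 300)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 2:
            raise ValueError("need at least 2 organisms")
        if not (0 <= self.divergence <= 0.6):
            raise ValueError("divergence must be in [0, 0.6]")
        for frac in (
            self.padding_true_fraction,
            self.decoy_rate,
            self.edge_sensitivity,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.pathway_size > self.n_families:
            raise ValueError("pathway_size cannot exceed n_families")
        if self.family_size_range[0] < 1:
            raise ValueError("family_size_range minimum is 1")


# substitution proposal weights: P(b | a) proportional to 2**S(a, b), b != a
_B62 = substitution_matrices.load("BLOSUM62")
_AA = np.array(list(AMINO_ACIDS))
_PROPOSAL = np.zeros((20, 20))
for _i, _a in enumerate(AMINO_ACIDS):
    w = np.array(
        [0.0 if _b == _a else 2.0 ** _B62[_a, _b] for _b in AMINO_ACIDS]
    )
    _PROPOSAL[_i] = w / w.sum()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _mutate(seq: str, divergence: float, indel_rate: float, rng: np.random.Generator) -> str:
    if divergence > 0:
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < divergence
        for pos in np.nonzero(hit)[0]:
            i = _AA_INDEX[arr[pos]]
            arr[pos] = rng.choice(_AA, p=_PROPOSAL[i])
        seq = "".join(arr)
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:  # deletion
                continue
            out.append(ch)
            if r > 1 - indel_rate / 2:  # short insertion
                out.append(str(rng.choice(_AA)))
        seq = "".join(out) or seq[:1]
    return seq


@dataclass
class Pangenome:
    """Generated proteomes plus the planted ortholog truth table."""

    config: SimulationConfig
    proteomes: list[Proteome]
    #: true ortholog pairs as (org_a, gene_a, org_b, gene_b), org_a < org_b
    ortholog_pairs: set[tuple[str, str, str, str]]
    #: organism -> family index -> gene ids (primary copy first)
    families: dict[str, dict[int, list[str]]]

    def proteome(self, organism_id: str) -> Proteome:
        for p in self.proteomes:
            if p.organism_id == organism_id:
                return p
        raise KeyError(organism_id)

    @property
    def organism_ids(self) -> list[str]:
        return [p.organism_id for p in self.proteomes]


def generate_pangenome(config: SimulationConfig) -> Pangenome:
    """Simulate ``n_organisms`` proteomes from shared ancestral families.

    Each family gets one root sequence; every organism receives a primary
    (orthologous) copy mutated at the divergence rate, plus paralogous
    duplicates (further mutated from the primary copy) when
    family_size_range allows.  The truth table contains the primary-copy
    pairs across all organism pairs.
    """
    rng = np.random.default_rng([config.seed, 0])
    orgs = [f"org{i + 1}" for i in range(config.n_organisms)]
    lo, hi = config.seq_len_range
    roots = [
        "".join(rng.choice(_AA, size=int(rng.integers(lo, hi + 1))))
        for _ in range(config.n_families)
    ]
    proteomes = []
    families: dict[str, dict[int, list[str]]] = {o: {} for o in orgs}
    for org in orgs:
        prot = Proteome(org)
        for fam, root in enumerate(roots):
            size = int(
                rng.integers(config.family_size_range[0], config.family_size_range[1] + 1)
            )
            primary = _mutate(root, config.divergence, config.indel_rate, rng)
            ids = [f"{org}_f{fam:03d}"]
            prot.add(GeneRecord(ids[0], org, primary))
            for k in range(1, size):
                dup = _mutate(primary, config.divergence, config.indel_rate, rng)
                pid = f"{org}_f{fam:03d}p{k}"
                ids.append(pid)
                prot.add(GeneRecord(pid, org, dup))
            families[org][fam] = ids
        proteomes.append(prot)
    truth = set()
    for i, oa in enumerate(orgs):
        for ob in orgs[i + 1 :]:
            for fam in range(config.n_families):
                truth.add((oa, families[oa][fam][0], ob, families[ob][fam][0]))
    return Pangenome(config, proteomes, truth, families)


@dataclass
class PlantedPathway:
    """A pathway planted into a pangenome, with gold-standard labels."""

    template: TemplatePathway
    gold: set[str]  # true member gene ids in the target organism
    target_operons: OperonMap
    template_organism: str
    target_organism: str
    pathway_families: list[int]
    #: operon padding genes that are NOT gold (negatives)
    negative_padding: set[str]


def plant_pathway(
    config: SimulationConfig,
    pangenome: Pangenome,
    pathway_families: Optional[list[int]] = None,
) -> PlantedPathway:
    """Designate a pathway and arrange its target copies into operons.

    The template uses the first organism's primary copies, linked in a
    chain of ``pathway`` interactions.  The target organism's copies are
    split into ``n_operons_for_pathway`` operons, each padded with
    ``padding_per_operon`` non-pathway genes of which a
    ``padding_true_fraction`` share are additional true members (gold);
    the remaining padding genes are negatives.
    """
    rng = np.random.default_rng([config.seed, 1])
    template_org = pangenome.organism_ids[0]
    target_org = pangenome.organism_ids[-1]
    if pathway_families is None:
        pathway_families = sorted(
            int(f)
            for f in rng.choice(
                config.n_families, size=config.pathway_size, replace=False
            )
        )
    tpl_genes = [pangenome.families[template_org][f][0] for f in pathway_families]
    template = TemplatePathway(
        name="planted", organism_id=template_org, members=set(tpl_genes)
    )
    for a, b in zip(tpl_genes, tpl_genes[1:]):
        template.add_interaction(a, b, "pathway")

    target_genes = [pangenome.families[target_org][f][0] for f in pathway_families]
    gold = set(target_genes)

    non_pathway = [
        pangenome.families[target_org][f][0]
        for f in range(config.n_families)
        if f not in set(pathway_families)
    ]
    n_ops = min(config.n_operons_for_pathway, len(target_genes))
    blocks = [list(b) for b in np.array_split(np.array(target_genes), n_ops)]
    n_padding = config.padding_per_operon * n_ops
    n_padding = min(n_padding, len(non_pathway))
    padding = list(rng.choice(non_pathway, size=n_padding, replace=False))
    n_true = int(round(config.padding_true_fraction * len(padding)))
    true_padding = set(padding[:n_true])
    negative_padding = set(padding[n_true:])
    gold |= true_padding

    omap = OperonMap(target_org)
    pad_iter = iter(padding)
    for i, block in enumerate(blocks):
        genes = [str(g) for g in block]
        for _ in range(config.padding_per_operon):
            nxt = next(pad_iter, None)
            if nxt is not None:
                genes.append(str(nxt))
        omap.add_operon(f"planted_op{i + 1}", genes)
    return PlantedPathway(
        template=template,
        gold=gold,
        target_operons=omap,
        template_organism=template_org,
        target_organism=target_org,
        pathway_families=list(pathway_families),
        negative_padding=negative_padding,
    )


ASSOC_CHANNELS = ("ppi", "coexpression", "coevolution")


def generate_associations(
    gold: set[str],
    universe: set[str],
    config: SimulationConfig,
    types: tuple[str, ...] = ("ppi",),
) -> AssociationEdgeSet:
    """Association edges over the target universe.

    Every unordered pair of gold genes is emitted per type with probability
    ``edge_sensitivity``; every gold gene additionally draws a decoy edge to
    a random non-gold gene with probability ``decoy_rate`` per type.
    """
    rng = np.random.default_rng([config.seed, 2])
    non_gold = sorted(universe - gold)
    edges = AssociationEdgeSet()
    gold_sorted = sorted(gold)
    for etype in types:
        for i, a in enumerate(gold_sorted):
            for b in gold_sorted[i + 1 :]:
                if rng.random() < config.edge_sensitivity:
                    edges.add(AssociationEdge(a, b, etype))
        if non_gold:
            for a in gold_sorted:
                if rng.random() < config.decoy_rate:
                    b = str(rng.choice(non_gold))
                    edges.add(AssociationEdge(a, b, etype))
    return edges


def generate_expression_list(
    gold: set[str],
    sensitivity: float,
    false_positive_rate: float,
    universe: set[str],
    seed: int,
) -> set[str]:
    """A differential-expression gene list: gold genes detected with the
    given sensitivity, non-gold genes leaking in at the false-positive rate."""
    rng = np.random.default_rng([seed, 3])
    evidence = {g for g in sorted(gold) if rng.random() < sensitivity}
    if false_positive_rate > 0:
        evidence |= {
            g
            for g in sorted(universe - gold)
            if rng.random() < false_positive_rate
        }
    return evidence


@dataclass
class SimulatedStudy:
    """Everything one pipeline run consumes, with truth attached."""

    config: SimulationConfig
    pangenome: Pangenome
    planted: PlantedPathway
    associations: AssociationEdgeSet
    expression: set[str]


def simulate_study(
    config: SimulationConfig,
    association_types: tuple[str, ...] = ("ppi",),
    expression_sensitivity: float = 0.6,
    expression_fpr: float = 0.0,
) -> SimulatedStudy:
    """One-call generation of a complete synthetic study."""
    pangenome = generate_pangenome(config)
    planted = plant_pathway(config, pangenome)
    universe = set(pangenome.proteome(planted.target_organism).gene_ids)
    associations = generate_associations(
        planted.gold, universe, config, types=association_types
    )
    expression = generate_expression_list(
        planted.gold, expression_sensitivity, expression_fpr, universe, config.seed
    )
    return SimulatedStudy(config, pangenome, planted, associations, expression)


def write_study(study: SimulatedStudy, out_dir) -> dict:
    """Write every pipeline input of a study as standard-format files.

    Emits per-organism FASTA proteomes, the template table (+ interactions),
    the target operon map, the association TSV, the expression list, the
    gold-standard list, and ``truth.json`` (ortholog pairs, gold set,
    planted operons).  Returns a path map keyed by artifact name.
    """
    import json
    from pathlib import Path

    from . import io as opio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"proteomes": {}}
    for prot in study.pangenome.proteomes:
        p = out / f"{prot.organism_id}.faa"
        opio.write_fasta(prot, p)
        paths["proteomes"][prot.organism_id] = str(p)
    paths["template"] = str(out / "template.tsv")
    paths["interactions"] = str(out / "interactions.tsv")
    opio.write_template_table(
        [study.planted.template], paths["template"], paths["interactions"]
    )
    paths["operons"] = str(out / "operons.tsv")
    opio.write_operons(study.planted.target_operons, paths["operons"])
    paths["associations"] = str(out / "associations.tsv")
    opio.write_associations(study.associations, paths["associations"])
    paths["expression"] = str(out / "expression.txt")
    opio.write_gene_list(study.expression, paths["expression"])
    paths["gold"] = str(out / "gold.txt")
    opio.write_gene_list(study.planted.gold, paths["gold"])
    paths["template_genes"] = str(out / "template_genes.txt")
    opio.write_gene_list(study.planted.template.members, paths["template_genes"])
    truth = {
        "ortholog_pairs": sorted(list(t) for t in study.pangenome.ortholog_pairs),
        "gold": sorted(study.planted.gold),
        "negative_padding": sorted(study.planted.negative_padding),
        "pathway_families": study.planted.pathway_families,
        "template_organism": study.planted.template_organism,
        "target_organism": study.planted.target_organism,
    }
    paths["truth"] = str(out / "truth.json")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
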