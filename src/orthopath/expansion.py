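"""Guilt-by-association expansion of an initial pathway model.

Recruitment is single-hop and anchored exclusively on *initial* entries:
a gene enters the model when it shares an operon with an initial gene or is
linked to one by a selected association edge (ppi, coexpression,
coevolution, user).  Recruits never recruit further — unrestricted
transitive closure would flood the model with genes that, as is well known
for association evidence, may have nothing to do with the target pathway.
A gene reachable through k (source, anchor) combinations keeps k
provenance records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .types import (
    ASSOCIATION_TYPES,
    AssociationEdgeSet,
    ModelEntry,
    OperonMap,
    PathwayModel,
)

EXPANSION_TYPES = tuple(t for t in ASSOCIATION_TYPES if t != "operon")


@dataclass(frozen=True)
class RecruitmentRecord:
    """One piece of evidence that recruited one gene."""

    gene_id: str
    source: str  # operon | ppi | coexpression | coevolution | user
    anchor_gene: str  # the initial-model gene licensing recruitment
    score: Optional[float] = None


def recruit_by_operon(
    model: PathwayModel, operons: OperonMap
) -> list[RecruitmentRecord]:
    """Operon-mates of initial genes, one record per (recruit, anchor).

    Operons typically encode enzymes of consecutive reactions, so genes
    co-transcribed with known members are strong pathway candidates.
    """
    initial = model.initial_genes()
    records = []
    for gene in sorted(initial):
        op = operons.operon_of(gene)
        if op is None:
            continue
        for mate in operons.members_of(op):
            if mate not in model.entries:
                records.append(RecruitmentRecord(mate, "operon", gene))
    return records


def recruit_by_association(
    model: PathwayModel,
    edges: AssociationEdgeSet,
    types: Iterable[str] = EXPANSION_TYPES,
    min_score: float = 0.0,
) -> list[RecruitmentRecord]:
    """Non-model genes linked to initial genes by selected edge types.

    A scored edge must reach ``min_score``; an unscored edge always passes.
    One record per (source type, anchor).
    """
    types = list(types)
    unknown = set(types) - set(EXPANSION_TYPES)
    if unknown:
        raise ValueError(
            f"unknown association type(s): {sorted(unknown)}; "
            f"expected a subset of {EXPANSION_TYPES}"
        )
    initial = model.initial_genes()
    records = []
    for e in edges.edges_of_types(types):
        if e.score is not None and e.score < min_score:
            continue
        for anchor, other in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            if anchor in initial and other not in model.entries:
                records.append(RecruitmentRecord(other, e.type, anchor, e.score))
    records.sort(key=lambda r: (r.gene_id, r.source, r.anchor_gene))
    return records


def expand(
    model: PathwayModel,
    operons: Optional[OperonMap] = None,
    edges: Optional[AssociationEdgeSet] = None,
    types: Iterable[str] = EXPANSION_TYPES,
    min_score: float = 0.0,
) -> PathwayModel:
    """Apply every recruitment channel to the initial entries of *model*.

    Returns a new model: initial entries untouched, each recruit added with
    ``status=recruited`` and one ``source`` label per piece of evidence
    (``<type>:<anchor>``), plus a typed evidence edge anchor—recruit.
    """
    expanded = model.copy()
    records: list[RecruitmentRecord] = []
    if operons is not None:
        records.extend(recruit_by_operon(model, operons))
    if edges is not None:
        records.extend(recruit_by_association(model, edges, types, min_score))
    for rec in sorted(records, key=lambda r: (r.gene_id, r.source, r.anchor_gene)):
        expanded.add_entry(
            ModelEntry(
                gene_id=rec.gene_id,
                status="recruited",
                sources=[f"{rec.source}:{rec.anchor_gene}"],
            )
        )
        expanded.add_edge(rec.anchor_gene, rec.gene_id, rec.source)
    return expanded


def recruit_counts(model: PathwayModel) -> dict[str, int]:
    """Recruited genes per channel: O (operon), P (ppi), X (coevolution),
    E (coexpression), U (user).  A multi-source recruit counts once per
    channel that found it."""
    counts = {"O": 0, "P": 0, "X": 0, "E": 0, "U": 0}
    letter = {
        "operon": "O",
        "ppi": "P",
        "coevolution": "X",
        "coexpression": "E",
        "user": "U",
    }
    for entry in model.entries.values():
        if entry.status != "recruited":
            continue
        channels = {s.split(":", 1)[0] for s in entry.sources}
        for ch in channels:
            if ch in letter:
                counts[letter[ch]] += 1
    return counts
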