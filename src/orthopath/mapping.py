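"""Operon-constrained projection of template pathways onto a target genome.

Orthology between template and target proteomes is detected with the
bidirectional-best-hit (BBH) criterion over local alignment bit scores.
Each template pathway member then gets a *candidate set* — target hits
passing the E-value cutoff whose bit score is within a fraction ``f`` of
that member's best hit, with reciprocal BBH partners always included — and
the mapper picks at most one candidate per member so as to maximize

    sum of selected bit scores  -  lambda * (number of distinct target
                                             operons covered)

where a gene outside any operon counts as its own singleton operon.  The
operon penalty encodes the prior that a pathway's target genes cluster in a
few transcription units, steering ties and near-ties away from scattered
paralogs.  Instances of up to 20 template genes are solved exactly by
branch-and-bound; larger ones by best-improvement local search seeded with
the per-gene best candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentHit, ScoringParams, local_score
from .types import ModelEntry, OperonMap, PathwayModel, Proteome, TemplatePathway

logger = logging.getLogger(__name__)

EXACT_SOLVER_LIMIT = 20


@dataclass(frozen=True)
class MappingConfig:
    """Knobs of the mapping step.

    e_cutoff: maximum E-value for a hit to count at all (default 1e-6).
    candidate_fraction: f in (0, 1]; hits within f of a member's best bit
        score are mapping candidates (default 0.9).
    operon_penalty: lambda >= 0, bit-score units charged per distinct target
        operon covered by the selected genes (default 1.0).
    """

    e_cutoff: float = 1e-6
    candidate_fraction: float = 0.9
    operon_penalty: float = 1.0
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if not (0 < self.candidate_fraction <= 1):
            raise ValueError("candidate_fraction must be in (0, 1]")
        if self.operon_penalty < 0:
            raise ValueError("operon_penalty must be >= 0")


@dataclass(frozen=True)
class OrthologPair:
    template_gene: str
    target_gene: str
    bit_score: float
    reciprocal: bool


def _hit_table(
    queries: Proteome,
    subjects: Proteome,
    config: MappingConfig,
    query_ids: list[str] | None = None,
) -> dict[str, list[AlignmentHit]]:
    """All query->subject hits passing the E-value cutoff, best first.

    Search space is query length x total subject residues, per query.
    """
    params = config.scoring
    total = subjects.total_residues
    table: dict[str, list[AlignmentHit]] = {}
    ids = query_ids if query_ids is not None else queries.gene_ids
    for qid in ids:
        q = queries[qid]
        space = float(len(q.sequence) * total)
        hits = []
        for s in subjects:
            raw = local_score(q.sequence, s.sequence, params)
            e = params.e_value(raw, space)
            if e <= config.e_cutoff:
                hits.append(
                    AlignmentHit(qid, s.gene_id, raw, params.bit_score(raw), e)
                )
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        table[qid] = hits
    return table


def best_hits(
    query: Proteome, subject: Proteome, config: MappingConfig = MappingConfig()
) -> dict[str, AlignmentHit]:
    """Best subject hit per query gene (highest bit score with E <= cutoff).

    Ties break to the lexicographically smallest subject gene_id; queries
    with no acceptable hit are absent from the result.
    """
    table = _hit_table(query, subject, config)
    return {qid: hits[0] for qid, hits in table.items() if hits}


def bidirectional_best_hits(
    p1: Proteome, p2: Proteome, config: MappingConfig = MappingConfig()
) -> list[OrthologPair]:
    """Ortholog pairs by the reciprocal-best-hit criterion.

    A pair (a, b) is reciprocal iff b is a's best hit in p2 and a is b's
    best hit in p1.  Non-reciprocal best hits of p1 genes are retained with
    ``reciprocal=False`` so downstream candidate generation can see them.
    """
    fwd = best_hits(p1, p2, config)
    rev = best_hits(p2, p1, config)
    pairs = []
    for a in sorted(fwd):
        hit = fwd[a]
        b = hit.subject_id
        reciprocal = rev.get(b) is not None and rev[b].subject_id == a
        pairs.append(OrthologPair(a, b, hit.bit_score, reciprocal))
    return pairs


# ---------------------------------------------------------------------------
# candidate selection under the operon constraint


def _operon_key(gene_id: str, operons: OperonMap | None):
    if operons is not None:
        op = operons.operon_of(gene_id)
        if op is not None:
            return ("op", op)
    return ("single", gene_id)


def selection_objective(
    assignment: dict[str, tuple[str, float] | None],
    operons: OperonMap | None,
    operon_penalty: float,
) -> float:
    """Total bit score minus the operon penalty of one candidate assignment."""
    covered = set()
    total = 0.0
    for choice in assignment.values():
        if choice is None:
            continue
        gene, bits = choice
        total += bits
        covered.add(_operon_key(gene, operons))
    return total - operon_penalty * len(covered)


def solve_assignment_exact(
    candidates: dict[str, list[tuple[str, float]]],
    operons: OperonMap | None,
    operon_penalty: float,
) -> dict[str, tuple[str, float] | None]:
    """Optimal assignment by depth-first branch-and-bound.

    Members are processed in sorted order; for each, candidates are tried
    best-bit-first (then lexicographic), with "unmapped" as the final
    branch.  The bound adds the best remaining bit scores and charges no
    further operon penalty, which never underestimates; the first optimum
    found in this order is kept, making ties deterministic.
    """
    members = sorted(candidates)
    ordered = {
        m: sorted(candidates[m], key=lambda c: (-c[1], c[0])) for m in members
    }
    suffix_max = [0.0] * (len(members) + 1)
    for i in range(len(members) - 1, -1, -1):
        best_bit = ordered[members[i]][0][1] if ordered[members[i]] else 0.0
        suffix_max[i] = suffix_max[i + 1] + best_bit

    best_score = -float("inf")
    best_assign: dict[str, tuple[str, float] | None] = {}
    assign: dict[str, tuple[str, float] | None] = {}

    def recurse(i: int, score: float, covered: frozenset) -> None:
        nonlocal best_score, best_assign
        if score + suffix_max[i] <= best_score + 1e-12:
            return
        if i == len(members):
            if score > best_score:
                best_score = score
                best_assign = dict(assign)
            return
        m = members[i]
        for gene, bits in ordered[m]:
            key = _operon_key(gene, operons)
            penalty = 0.0 if key in covered else operon_penalty
            assign[m] = (gene, bits)
            recurse(i + 1, score + bits - penalty, covered | {key})
        assign[m] = None
        recurse(i + 1, score, covered)
        del assign[m]

    recurse(0, 0.0, frozenset())
    return best_assign


def solve_assignment_greedy(
    candidates: dict[str, list[tuple[str, float]]],
    operons: OperonMap | None,
    operon_penalty: float,
) -> dict[str, tuple[str, float] | None]:
    """Best-improvement local search for large instances.

    Seeds every member with its best-bit candidate, then repeatedly applies
    the single-member change (including unmapping) with the largest
    objective gain until no change helps.
    """
    members = sorted(candidates)
    assign: dict[str, tuple[str, float] | None] = {
        m: (
            min(candidates[m], key=lambda c: (-c[1], c[0]))
            if candidates[m]
            else None
        )
        for m in members
    }
    current = selection_objective(assign, operons, operon_penalty)
    while True:
        best_delta = 0.0
        best_move = None
        for m in members:
            options: list[tuple[str, float] | None] = list(candidates[m]) + [None]
            for opt in options:
                if opt == assign[m]:
                    continue
                trial = dict(assign)
                trial[m] = opt
                delta = (
                    selection_objective(trial, operons, operon_penalty) - current
                )
                if delta > best_delta + 1e-12:
                    best_delta = delta
                    best_move = (m, opt)
        if best_move is None:
            return assign
        m, opt = best_move
        assign[m] = opt
        current += best_delta


def build_candidates(
    template: TemplatePathway,
    template_proteome: Proteome,
    target_proteome: Proteome,
    config: MappingConfig,
) -> tuple[dict[str, list[tuple[str, float]]], dict[str, list[AlignmentHit]], set[str]]:
    """Candidate target genes per template member.

    Returns (candidates, full hit table, reciprocal-BBH member set).
    Candidates are hits with E <= cutoff and bit >= f x member's best bit;
    the member's reciprocal BBH partner is always a candidate.
    """
    member_ids = sorted(m for m in template.members if m in template_proteome)
    missing = template.members - set(member_ids)
    if missing:
        raise ValueError(
            f"template members absent from template proteome: {sorted(missing)}"
        )
    hit_table = _hit_table(
        template_proteome, target_proteome, config, query_ids=member_ids
    )
    bbh = {
        p.template_gene: p
        for p in bidirectional_best_hits(template_proteome, target_proteome, config)
        if p.reciprocal
    }
    candidates: dict[str, list[tuple[str, float]]] = {}
    reciprocal_members = set()
    for m in member_ids:
        hits = hit_table[m]
        cands: dict[str, float] = {}
        if hits:
            best_bit = hits[0].bit_score
            for h in hits:
                if h.bit_score >= config.candidate_fraction * best_bit:
                    cands[h.subject_id] = h.bit_score
        pair = bbh.get(m)
        if pair is not None:
            cands.setdefault(pair.target_gene, pair.bit_score)
            reciprocal_members.add(m)
        candidates[m] = sorted(cands.items(), key=lambda c: (-c[1], c[0]))
    return candidates, hit_table, reciprocal_members


def map_template_pathway(
    template: TemplatePathway,
    template_proteome: Proteome,
    target_proteome: Proteome,
    target_operons: OperonMap | None,
    config: MappingConfig = MappingConfig(),
) -> PathwayModel:
    """Map one template pathway onto the target genome.

    Returns a model fragment whose entries have ``status=initial`` and
    ``mapped_from`` provenance; template members that end up unmapped are
    recorded in ``model.holes`` together with their best sub-threshold hit,
    so borderline cases stay visible to the user.
    """
    candidates, hit_table, _ = build_candidates(
        template, template_proteome, target_proteome, config
    )
    solver = (
        solve_assignment_exact
        if len(candidates) <= EXACT_SOLVER_LIMIT
        else solve_assignment_greedy
    )
    assignment = solver(candidates, target_operons, config.operon_penalty)

    model = PathwayModel(target_proteome.organism_id, name=template.name)
    source = f"template:{template.organism_id}:{template.name}"
    chosen_targets: dict[str, list[str]] = {}
    for m in sorted(candidates):
        choice = assignment.get(m)
        if choice is None:
            hits = hit_table[m]
            model.holes.append(
                {
                    "template_gene": m,
                    "template_organism": template.organism_id,
                    "best_hit": hits[0].subject_id if hits else None,
                    "bit_score": hits[0].bit_score if hits else None,
                }
            )
            continue
        target_gene, _bits = choice
        chosen_targets.setdefault(target_gene, []).append(m)
    for target_gene, claimants in sorted(chosen_targets.items()):
        entry = ModelEntry(
            gene_id=target_gene,
            status="initial",
            sources=[source],
            mapped_from=[(template.organism_id, m) for m in claimants],
            conflict=len(claimants) > 1,
        )
        if len(claimants) > 1:
            logger.warning(
                "target gene %s claimed by %d template genes (%s); flagged",
                target_gene,
                len(claimants),
                ",".join(claimants),
            )
        model.add_entry(entry)
    return model


def merge_models(fragments: list[PathwayModel], name: str = "merged") -> PathwayModel:
    """Union of per-template model fragments.

    A target gene mapped from several templates keeps a single entry with
    every provenance; any gene with more than one mapped_from record is
    flagged as a conflict for the user to resolve — never silently.
    """
    if not fragments:
        raise ValueError("no fragments to merge")
    organisms = {f.target_organism for f in fragments}
    if len(organisms) > 1:
        raise ValueError(f"mixed target organisms: {sorted(organisms)}")
    merged = PathwayModel(fragments[0].target_organism, name=name)
    for frag in fragments:
        for gid in sorted(frag.entries):
            merged.add_entry(
                ModelEntry(
                    gene_id=gid,
                    status=frag.entries[gid].status,
                    sources=list(frag.entries[gid].sources),
                    evidence=frag.entries[gid].evidence,
                    mapped_from=list(frag.entries[gid].mapped_from),
                    conflict=frag.entries[gid].conflict,
                )
            )
        for edge in frag.edges:
            merged.edges.add(edge)
        merged.holes.extend(frag.holes)
    for entry in merged.entries.values():
        if len(entry.mapped_from) > 1:
            entry.conflict = True
    merged.validate()
    return merged


def transfer_interactions(
    template: TemplatePathway, model: PathwayModel
) -> PathwayModel:
    """Copy template interactions onto mapped genes (in place, idempotent).

    For each template link (a, b, rel) with both endpoints mapped into the
    model, the corresponding target genes get an edge with the same relation
    label; links with an unmapped endpoint, or whose endpoints collapsed
    onto one target gene, transfer nothing.
    """
    gene_map: dict[str, str] = {}
    for gid, entry in model.entries.items():
        for org, tgene in entry.mapped_from:
            if org == template.organism_id and tgene in template.members:
                gene_map[tgene] = gid
    for a, b, rel in sorted(template.interactions):
        ta, tb = gene_map.get(a), gene_map.get(b)
        if ta is None or tb is None or ta == tb:
            continue
        model.add_edge(ta, tb, rel)
    return model
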