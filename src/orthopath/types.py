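"""Core domain types shared by every pipeline stage.

Gene identifiers are opaque, case-sensitive strings (locus tags, GI numbers,
symbols); all cross-file joins are exact string matches.  Reconciliation of
identifier namespaces is the caller's job, e.g. via an alias table applied
before files enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: recruitment / association evidence channels
ASSOCIATION_TYPES = ("operon", "ppi", "coexpression", "coevolution", "user")


class OrthopathError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OrthopathError):
    """A file could not be parsed, or violated a format invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: identifier, organism, and amino-acid sequence."""

    gene_id: str
    organism_id: str
    sequence: str = ""
    symbol: Optional[str] = None
    product: Optional[str] = None
    genome_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.genome_index is not None and self.genome_index < 0:
            raise ValueError(f"genome_index must be >= 0 for {self.gene_id}")


class Proteome:
    """The protein complement of one organism, indexed by gene_id."""

    def __init__(self, organism_id: str, genes: Iterable[GeneRecord] = ()):
        self.organism_id = organism_id
        self._genes: dict[str, GeneRecord] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneRecord) -> None:
        if gene.gene_id in self._genes:
            raise ParseError(
                f"duplicate gene_id {gene.gene_id!r} in proteome {self.organism_id!r}"
            )
        if gene.organism_id != self.organism_id:
            raise ValueError(
                f"gene {gene.gene_id!r} belongs to {gene.organism_id!r}, "
                f"not {self.organism_id!r}"
            )
        self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    def __iter__(self) -> Iterator[GeneRecord]:
        # deterministic order for reproducible downstream scans
        return iter(sorted(self._genes.values(), key=lambda g: g.gene_id))

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    @property
    def total_residues(self) -> int:
        return sum(len(g.sequence) for g in self._genes.values())

    def __repr__(self) -> str:
        return f"Proteome({self.organism_id!r}, {len(self)} genes)"


@dataclass
class TemplatePathway:
    """A curated pathway from one template organism: members plus labeled links.

    Interaction endpoints must be members and self-loops are rejected; the
    relation label is free text (e.g. ``pathway``, ``regulates``).
    """

    name: str
    organism_id: str
    members: set[str] = field(default_factory=set)
    evidence: dict[str, list[str]] = field(default_factory=dict)
    interactions: set[tuple[str, str, str]] = field(default_factory=set)

    def add_interaction(self, a: str, b: str, relation: str = "pathway") -> None:
        if a == b:
            raise ValueError(f"self-loop interaction on {a!r}")
        if a not in self.members or b not in self.members:
            raise ValueError(f"interaction endpoints {a!r},{b!r} must be members")
        self.interactions.add((min(a, b), max(a, b), relation))

    def validate(self) -> None:
        for a, b, _ in self.interactions:
            if a == b:
                raise ValueError(f"self-loop interaction on {a!r}")
            if a not in self.members or b not in self.members:
                raise ValueError(
                    f"interaction ({a!r},{b!r}) endpoint outside members"
                )


class OperonMap:
    """Partition of (part of) an organism's genes into ordered operons."""

    def __init__(
        self, organism_id: str, operons: Iterable[tuple[str, list[str]]] = ()
    ):
        self.organism_id = organism_id
        self.operons: list[tuple[str, list[str]]] = []
        self._gene_to_operon: dict[str, str] = {}
        for operon_id, genes in operons:
            self.add_operon(operon_id, genes)

    def add_operon(self, operon_id: str, genes: list[str]) -> None:
        if not genes:
            raise ValueError(f"operon {operon_id!r} has no genes")
        for g in genes:
            if g in self._gene_to_operon:
                raise ParseError(
                    f"gene {g!r} assigned to both operon "
                    f"{self._gene_to_operon[g]!r} and {operon_id!r}"
                )
        for g in genes:
            self._gene_to_operon[g] = operon_id
        self.operons.append((operon_id, list(genes)))

    def operon_of(self, gene_id: str) -> Optional[str]:
        """The operon containing *gene_id*, or None if unassigned.

        Genes outside any operon behave as singleton transcription units.
        """
        return self._gene_to_operon.get(gene_id)

    def members_of(self, operon_id: str) -> list[str]:
        for oid, genes in self.operons:
            if oid == operon_id:
                return list(genes)
        raise KeyError(operon_id)

    def __len__(self) -> int:
        return len(self.operons)

    @property
    def assigned_genes(self) -> set[str]:
        return set(self._gene_to_operon)

    def __repr__(self) -> str:
        return (
            f"OperonMap({self.organism_id!r}, {len(self.operons)} operons, "
            f"{len(self._gene_to_operon)} genes)"
        )


@dataclass(frozen=True)
class AssociationEdge:
    """One undirected functional-association edge.

    Endpoints are stored in sorted order so the unordered pair deduplicates
    naturally; ``score`` is an optional non-negative strength (STRING-style,
    unitless) and an unscored edge passes any threshold of 0.
    """

    gene_a: str
    gene_b: str
    type: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-association on {self.gene_a!r}")
        if self.type not in ASSOCIATION_TYPES:
            raise ValueError(f"unknown association type {self.type!r}")
        if self.score is not None and self.score < 0:
            raise ValueError("association score must be >= 0")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


class AssociationEdgeSet:
    """Typed, optionally scored, undirected gene-pair evidence.

    Unordered pairs are deduplicated per type; re-adding a pair keeps the
    higher score.
    """

    def __init__(self, edges: Iterable[AssociationEdge] = ()):
        self._edges: dict[tuple[str, str, str], AssociationEdge] = {}
        for e in edges:
            self.add(e)

    def add(self, edge: AssociationEdge) -> None:
        key = (edge.gene_a, edge.gene_b, edge.type)
        old = self._edges.get(key)
        if old is None:
            self._edges[key] = edge
        else:
            new_score = max(
                (s for s in (old.score, edge.score) if s is not None),
                default=None,
            )
            self._edges[key] = AssociationEdge(
                edge.gene_a, edge.gene_b, edge.type, new_score
            )

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[AssociationEdge]:
        return iter(sorted(self._edges.values(), key=lambda e: (e.gene_a, e.gene_b, e.type)))

    def edges_of_types(self, types: Iterable[str]) -> list[AssociationEdge]:
        wanted = set(types)
        unknown = wanted - set(ASSOCIATION_TYPES)
        if unknown:
            raise ValueError(f"unknown association type(s): {sorted(unknown)}")
        return [e for e in self if e.type in wanted]

    def touching(self, gene_id: str) -> list[AssociationEdge]:
        return [e for e in self if gene_id in e.pair]


@dataclass
class ModelEntry:
    """One gene of a predicted pathway model with full provenance.

    ``status`` is ``initial`` (mapped from a template) or ``recruited``
    (added by association evidence); ``sources`` lists one provenance label
    per piece of supporting evidence (e.g. ``template:eco``, ``operon:g5``,
    ``ppi:g2``); ``evidence`` flips from ``predicted`` to ``validated`` when
    the gene appears in a differential-expression list.
    """

    gene_id: str
    status: str  # "initial" | "recruited"
    sources: list[str] = field(default_factory=list)
    evidence: str = "predicted"  # "predicted" | "validated"
    mapped_from: list[tuple[str, str]] = field(default_factory=list)
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("initial", "recruited"):
            raise ValueError(f"bad status {self.status!r}")
        if self.evidence not in ("predicted", "validated"):
            raise ValueError(f"bad evidence {self.evidence!r}")


class PathwayModel:
    """A predicted target-organism network: entries plus typed edges."""

    def __init__(self, target_organism: str, name: str = "model"):
        self.target_organism = target_organism
        self.name = name
        self.entries: dict[str, ModelEntry] = {}
        self.edges: set[tuple[str, str, str]] = set()
        #: template members that found no acceptable candidate
        self.holes: list[dict] = []

    def add_entry(self, entry: ModelEntry) -> ModelEntry:
        """Add *entry*, merging provenance if the gene is already present."""
        existing = self.entries.get(entry.gene_id)
        if existing is None:
            self.entries[entry.gene_id] = entry
            return entry
        for s in entry.sources:
            if s not in existing.sources:
                existing.sources.append(s)
        for mf in entry.mapped_from:
            if mf not in existing.mapped_from:
                existing.mapped_from.append(mf)
        # an initial mapping outranks recruitment
        if entry.status == "initial":
            existing.status = "initial"
        existing.conflict = existing.conflict or entry.conflict
        return existing

    def add_edge(self, a: str, b: str, relation: str) -> None:
        if a == b:
            raise ValueError(f"self-loop edge on {a!r}")
        if a not in self.entries or b not in self.entries:
            raise ValueError(f"edge ({a!r},{b!r}) endpoint not in model")
        self.edges.add((min(a, b), max(a, b), relation))

    def gene_ids(self, status: Optional[str] = None) -> set[str]:
        if status is None:
            return set(self.entries)
        return {g for g, e in self.entries.items() if e.status == status}

    def initial_genes(self) -> set[str]:
        return self.gene_ids("initial")

    def validate(self) -> None:
        for a, b, _ in self.edges:
            if a not in self.entries or b not in self.entries:
                raise ValueError(f"dangling edge endpoint ({a!r},{b!r})")

    def copy(self) -> "PathwayModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return (
            f"PathwayModel({self.name!r} on {self.target_organism!r}: "
            f"{len(self.entries)} genes, {len(self.edges)} edges, "
            f"{len(self.holes)} holes)"
        )


@dataclass
class EvaluationResult:
    """Precision/recall of a predicted gene set against a gold standard.

    ``precision`` and ``recall`` are fractions in [0, 1], or None when the
    denominator is zero (undefined, never coerced to 0).
    """

    TP: int
    FP: int
    FN: int
    mode: str = "standard"

    @property
    def precision(self) -> Optional[float]:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) > 0 else None

    @property
    def recall(self) -> Optional[float]:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) > 0 else None
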