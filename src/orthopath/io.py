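"""Readers and writers for the flat-file formats the pipeline touches.

All tabular files are TSV: tab-separated, UTF-8, ``#`` comment lines, no
quoting (the dialect of DOOR- and STRING-style dumps).  FASTA parsing goes
through Biopython; network exports go through networkx (GraphML) and plain
SIF.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import networkx as nx
from Bio import SeqIO

from .types import (
    AssociationEdge,
    AssociationEdgeSet,
    GeneRecord,
    ModelEntry,
    OperonMap,
    ParseError,
    PathwayModel,
    Proteome,
    TemplatePathway,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _read_tsv_rows(path: PathLike) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append([c.strip() for c in line.split("\t")])
    return rows


def _split_header(
    rows: list[list[str]], required: list[str]
) -> tuple[list[str], list[list[str]]]:
    """Use the first row as a header when it names the required columns;
    otherwise assume positional columns in the required order."""
    if rows and all(c in [h.lower() for h in rows[0]] for c in required):
        header = [h.lower() for h in rows[0]]
        return header, rows[1:]
    return list(required), rows


def _col(row: list[str], header: list[str], name: str, path, default=None):
    try:
        i = header.index(name)
    except ValueError:
        return default
    if i >= len(row):
        return default
    return row[i] or default


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike, organism_id: Optional[str] = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The gene_id is the first whitespace-delimited token of each header.
    Duplicate ids and empty sequences are rejected.  ``organism_id``
    defaults to the file stem.
    """
    path = Path(path)
    if organism_id is None:
        organism_id = path.stem
    proteome = Proteome(organism_id)
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        proteome.add(GeneRecord(gene_id=rec.id, organism_id=organism_id, sequence=seq))
    return proteome


def write_fasta(proteome: Proteome, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in proteome:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# operons (DOOR-style)

def read_operons(path: PathLike, organism_id: str) -> OperonMap:
    """Read a DOOR-style operon TSV (operon_id, gene_id, position).

    Genes are ordered by their 1-based position within each operon; a gene
    listed in two operons or a non-integer position is an error.
    """
    rows = _read_tsv_rows(path)
    header, rows = _split_header(rows, ["operon_id", "gene_id", "position"])
    by_operon: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    for row in rows:
        oid = _col(row, header, "operon_id", path)
        gid = _col(row, header, "gene_id", path)
        pos = _col(row, header, "position", path)
        if oid is None or gid is None or pos is None:
            raise ParseError(f"{path}: malformed operon row {row!r}")
        try:
            ipos = int(pos)
        except ValueError:
            raise ParseError(
                f"{path}: non-integer position {pos!r} for gene {gid!r}"
            ) from None
        if oid not in by_operon:
            order.append(oid)
        by_operon.setdefault(oid, []).append((ipos, gid))
    omap = OperonMap(organism_id)
    for oid in order:
        genes = [g for _, g in sorted(by_operon[oid])]
        omap.add_operon(oid, genes)
    return omap


def write_operons(omap: OperonMap, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("operon_id\tgene_id\tposition\n")
        for oid, genes in omap.operons:
            for i, g in enumerate(genes, 1):
                fh.write(f"{oid}\t{g}\t{i}\n")


# ---------------------------------------------------------------------------
# template pathways

def read_template_table(
    path: PathLike, interactions_path: Optional[PathLike] = None
) -> list[TemplatePathway]:
    """Read a template table TSV into one pathway per (pathway, organism).

    Columns: pathway, organism, gene_id[, symbol, product, evidence].  The
    same gene listed under two organisms yields independent template
    memberships.  An optional companion interaction TSV (gene_a, gene_b[,
    relation]) attaches links; an interaction whose endpoint is not a member
    of any template sharing that gene set is dropped with a warning.
    """
    rows = _read_tsv_rows(path)
    header, rows = _split_header(rows, ["pathway", "organism", "gene_id"])
    templates: dict[tuple[str, str], TemplatePathway] = {}
    for row in rows:
        pw = _col(row, header, "pathway", path)
        org = _col(row, header, "organism", path)
        gid = _col(row, header, "gene_id", path)
        if pw is None or org is None or gid is None:
            raise ParseError(f"{path}: malformed template row {row!r}")
        key = (pw, org)
        tpl = templates.setdefault(key, TemplatePathway(name=pw, organism_id=org))
        tpl.members.add(gid)
        ev = _col(row, header, "evidence", path)
        if ev:
            tpl.evidence.setdefault(gid, []).append(ev)
    result = sorted(templates.values(), key=lambda t: (t.name, t.organism_id))
    if interactions_path is not None:
        irows = _read_tsv_rows(interactions_path)
        iheader, irows = _split_header(irows, ["gene_a", "gene_b"])
        for row in irows:
            a = _col(row, iheader, "gene_a", interactions_path)
            b = _col(row, iheader, "gene_b", interactions_path)
            rel = _col(row, iheader, "relation", interactions_path, "pathway")
            if a is None or b is None:
                raise ParseError(
                    f"{interactions_path}: malformed interaction row {row!r}"
                )
            attached = False
            for tpl in result:
                if a in tpl.members and b in tpl.members:
                    tpl.add_interaction(a, b, rel)
                    attached = True
            if not attached:
                logger.warning(
                    "dropping interaction (%s, %s): endpoint absent from "
                    "every template's members",
                    a,
                    b,
                )
    return result


def write_template_table(
    templates: list[TemplatePathway],
    path: PathLike,
    interactions_path: Optional[PathLike] = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\torganism\tgene_id\tsymbol\tproduct\tevidence\n")
        for tpl in templates:
            for gid in sorted(tpl.members):
                evs = tpl.evidence.get(gid) or [""]
                for ev in evs:
                    fh.write(f"{tpl.name}\t{tpl.organism_id}\t{gid}\t\t\t{ev}\n")
    if interactions_path is not None:
        with open(interactions_path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\trelation\n")
            for tpl in templates:
                for a, b, rel in sorted(tpl.interactions):
                    fh.write(f"{a}\t{b}\t{rel}\n")


# ---------------------------------------------------------------------------
# association edges

def read_associations(path: PathLike, default_type: str = "user") -> AssociationEdgeSet:
    """Read a two-column association TSV (gene_a, gene_b[, type[, score]]).

    Rows missing a type get ``default_type``; rows missing a score carry no
    score (they pass any threshold of 0).  Self-pairs are an error; duplicate
    unordered pairs per type collapse to one edge.
    """
    rows = _read_tsv_rows(path)
    header, rows = _split_header(rows, ["gene_a", "gene_b"])
    edges = AssociationEdgeSet()
    for row in rows:
        a = _col(row, header, "gene_a", path)
        b = _col(row, header, "gene_b", path)
        if a is None or b is None:
            raise ParseError(f"{path}: malformed association row {row!r}")
        etype = _col(row, header, "type", path) or (
            row[2] if "type" not in header and len(row) > 2 and row[2] else None
        ) or default_type
        raw_score = _col(row, header, "score", path) or (
            row[3] if "score" not in header and len(row) > 3 and row[3] else None
        )
        score = float(raw_score) if raw_score is not None else None
        if a == b:
            raise ParseError(f"{path}: self-pair {a!r}")
        try:
            edges.add(AssociationEdge(a, b, etype, score))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return edges


def write_associations(edges: AssociationEdgeSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\ttype\tscore\n")
        for e in edges:
            s = "" if e.score is None else repr(e.score)
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.type}\t{s}\n")


# ---------------------------------------------------------------------------
# gene lists

def read_gene_list(path: PathLike) -> set[str]:
    """Read a one-column gene list (e.g. differentially expressed genes)."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split()[0])
    return genes


def write_gene_list(genes, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# pathway models

_MF_SEP = "|"  # between (organism, gene) inside one provenance


def _format_mapped_from(mapped_from: list[tuple[str, str]]) -> str:
    return ",".join(f"{org}{_MF_SEP}{gid}" for org, gid in mapped_from) or "-"


def _parse_mapped_from(text: str) -> list[tuple[str, str]]:
    if not text or text == "-":
        return []
    out = []
    for part in text.split(","):
        org, _, gid = part.partition(_MF_SEP)
        out.append((org, gid))
    return out


def write_model(model: PathwayModel, out_dir: PathLike) -> dict[str, Path]:
    """Persist a model as entries TSV + SIF + GraphML (+ holes TSV).

    The entries TSV mirrors the Source/Evidence bookkeeping of the model
    table: a gene recruited by k sources occupies k rows.  Returns the paths
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries_path = out_dir / "entries.tsv"
    with open(entries_path, "w", encoding="utf-8") as fh:
        fh.write("# target_organism\t%s\n" % model.target_organism)
        fh.write("# model_name\t%s\n" % model.name)
        fh.write("gene_id\tstatus\tsource\tevidence\tmapped_from\tconflict\n")
        for gid in sorted(model.entries):
            e = model.entries[gid]
            sources = e.sources or ["-"]
            for src in sources:
                fh.write(
                    "\t".join(
                        [
                            e.gene_id,
                            e.status,
                            src,
                            e.evidence,
                            _format_mapped_from(e.mapped_from),
                            "1" if e.conflict else "0",
                        ]
                    )
                    + "\n"
                )

    sif_path = out_dir / "network.sif"
    with open(sif_path, "w", encoding="utf-8") as fh:
        for a, b, rel in sorted(model.edges):
            fh.write(f"{a}\t{rel.replace(' ', '_')}\t{b}\n")

    graphml_path = out_dir / "network.graphml"
    g = nx.Graph()
    for gid in sorted(model.entries):
        e = model.entries[gid]
        g.add_node(
            gid,
            status=e.status,
            evidence=e.evidence,
            sources=";".join(e.sources),
        )
    for a, b, rel in sorted(model.edges):
        g.add_edge(a, b, relation=rel)
    nx.write_graphml(g, graphml_path)

    holes_path = out_dir / "holes.tsv"
    with open(holes_path, "w", encoding="utf-8") as fh:
        fh.write("template_gene\ttemplate_organism\tbest_subthreshold_hit\tbit_score\n")
        for h in model.holes:
            fh.write(
                "\t".join(
                    [
                        h.get("template_gene", "-"),
                        h.get("template_organism", "-"),
                        h.get("best_hit", "-") or "-",
                        f"{h['bit_score']:.2f}" if h.get("bit_score") else "-",
                    ]
                )
                + "\n"
            )
    return {
        "entries": entries_path,
        "sif": sif_path,
        "graphml": graphml_path,
        "holes": holes_path,
    }


def read_model(model_dir: PathLike) -> PathwayModel:
    """Re-read a model persisted by :func:`write_model`."""
    model_dir = Path(model_dir)
    entries_path = model_dir / "entries.tsv"
    if not entries_path.exists():
        raise ParseError(
            f"no model found: missing artifact {entries_path} "
            "(run the mapping step first)"
        )
    organism = "unknown"
    name = "model"
    with open(entries_path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# target_organism\t"):
            organism = line.split("\t", 1)[1].strip()
        elif line.startswith("# model_name\t"):
            name = line.split("\t", 1)[1].strip()
    model = PathwayModel(organism, name=name)
    data = [
        ln.rstrip("\n").split("\t")
        for ln in lines
        if ln.strip() and not ln.startswith("#")
    ]
    header = data[0]
    for row in data[1:]:
        rec = dict(zip(header, row))
        entry = ModelEntry(
            gene_id=rec["gene_id"],
            status=rec["status"],
            sources=[rec["source"]] if rec.get("source", "-") != "-" else [],
            evidence=rec.get("evidence", "predicted"),
            mapped_from=_parse_mapped_from(rec.get("mapped_from", "-")),
            conflict=rec.get("conflict", "0") == "1",
        )
        model.add_entry(entry)
    sif_path = model_dir / "network.sif"
    if sif_path.exists():
        with open(sif_path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    a, rel, b = parts
                    model.add_edge(a, b, rel)
    holes_path = model_dir / "holes.tsv"
    if holes_path.exists():
        rows = _read_tsv_rows(holes_path)
        for row in rows[1:]:
            model.holes.append(
                {
                    "template_gene": row[0],
                    "template_organism": row[1],
                    "best_hit": None if row[2] == "-" else row[2],
                    "bit_score": None if row[3] == "-" else float(row[3]),
                }
            )
    return model
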