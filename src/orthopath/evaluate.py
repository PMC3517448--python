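"""Expression-based validation and precision/recall scoring of models.

Two evaluation modes exist.  ``standard`` is plain set arithmetic over
predicted vs. gold gene sets: TP = |predicted ∩ gold|, FP = |predicted \\
gold|, FN = |gold \\ predicted|.  ``paper_literal`` reproduces a published
variant in which FP counts *template* genes that were never mapped or whose
mapped target gene is wrong; that definition cannot always be reconstructed
from gene sets alone (see docs/methods.md), so the literal mode also
accepts explicit TP/FP/FN counts via :func:`evaluation_from_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Optional

from .types import EvaluationResult, PathwayModel

MODES = ("standard", "paper_literal")


def validate_expression(model: PathwayModel, evidence: set[str]) -> PathwayModel:
    """Mark model genes found in a differential-expression list.

    Each entry's ``evidence`` becomes ``validated`` iff its gene_id is in
    the uploaded up-/down-regulated list, else ``predicted``; nothing else
    changes.  Idempotent.
    """
    validated = model.copy()
    for entry in validated.entries.values():
        entry.evidence = "validated" if entry.gene_id in evidence else "predicted"
    return validated


def evaluation_from_counts(
    tp: int, fp: int, fn: int, mode: str = "paper_literal"
) -> EvaluationResult:
    if mode not in MODES:
        raise ValueError(f"unknown evaluation mode {mode!r}; expected one of {MODES}")
    return EvaluationResult(TP=tp, FP=fp, FN=fn, mode=mode)


def evaluate_model(
    predicted: set[str],
    gold: set[str],
    template: Optional[set[str]] = None,
    mode: str = "standard",
) -> EvaluationResult:
    """Score a predicted gene set against a gold-standard gene set.

    In ``paper_literal`` mode the FP term charges template genes left
    unmapped (approximated as |template| - |predicted| when only sets are
    available) plus wrongly mapped genes; ``template`` is then required.
    """
    if mode not in MODES:
        raise ValueError(f"unknown evaluation mode {mode!r}; expected one of {MODES}")
    tp = len(predicted & gold)
    fn = len(gold - predicted)
    if mode == "standard":
        fp = len(predicted - gold)
    else:
        if template is None:
            raise ValueError("paper_literal mode requires the template gene set")
        unmapped = max(len(template) - len(predicted), 0)
        fp = unmapped + len(predicted - gold)
    return EvaluationResult(TP=tp, FP=fp, FN=fn, mode=mode)


# ---------------------------------------------------------------------------
# percentage rendering and benchmark-style summaries


def round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(fraction: Optional[float]) -> str:
    """Render a fraction as a percentage string.

    Integers print bare ("75%"); exact half-percent values keep one decimal
    ("62.5%"); everything else rounds half-up to the nearest integer.
    Undefined values (None) print "NA".
    """
    if fraction is None:
        return "NA"
    pct = fraction * 100.0
    if abs(pct * 10 - round(pct * 10)) < 1e-9:  # exact tenth of a percent
        if abs(pct - round(pct)) < 1e-9:
            return f"{int(round(pct))}%"
        return f"{round_half_up(pct, 1)}%"
    return f"{int(round_half_up(pct, 0))}%"


@dataclass
class SummaryRow:
    """One pathway's line in a benchmark summary table.

    Percentages are stored on the 0-100 scale exactly as reported (so
    62.5 stays 62.5).  recruit_counts is (O, P, X, E): genes recruited via
    operon, protein-protein interaction, co-evolution and co-expression.
    """

    pathway: str
    n_template: int
    n_target_gold: int
    n_initial: int
    recruit_counts: tuple[int, int, int, int]
    n_final: int
    precision_initial: float
    recall_initial: float
    precision_final: float
    recall_final: float


def summarize(rows: Iterable[SummaryRow]) -> dict[str, int]:
    """Column means of the four percentage columns, half-up to integer %."""
    rows = list(rows)
    if not rows:
        raise ValueError("summarize requires at least one row")
    n = len(rows)

    def avg(attr: str) -> int:
        return int(round_half_up(sum(getattr(r, attr) for r in rows) / n))

    return {
        "precision_initial": avg("precision_initial"),
        "recall_initial": avg("recall_initial"),
        "precision_final": avg("precision_final"),
        "recall_final": avg("recall_final"),
    }


def load_benchmark_table() -> list[SummaryRow]:
    """The bundled 17-pathway reference benchmark (E. coli templates mapped
    onto B. subtilis, scored against MetaCyc pathway annotations)."""
    text = (
        resources.files("orthopath.data")
        .joinpath("ecoli_bsubtilis_17pathways.tsv")
        .read_text(encoding="utf-8")
    )
    rows = []
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        rows.append(
            SummaryRow(
                pathway=rec["pathway"],
                n_template=int(rec["n_template"]),
                n_target_gold=int(rec["n_target_gold"]),
                n_initial=int(rec["n_initial"]),
                recruit_counts=(
                    int(rec["O"]),
                    int(rec["P"]),
                    int(rec["X"]),
                    int(rec["E"]),
                ),
                n_final=int(rec["n_final"]),
                precision_initial=float(rec["precision_initial"]),
                recall_initial=float(rec["recall_initial"]),
                precision_final=float(rec["precision_final"]),
                recall_final=float(rec["recall_final"]),
            )
        )
    return rows


def write_summary(rows: list[SummaryRow], path) -> None:
    """Benchmark-style summary TSV (counts, O|P|X|E recruits, percentages)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "pathway\tn_template\tn_target_gold\tn_initial\tprecision_initial\t"
            "recall_initial\tO|P|X|E\tn_final\tprecision_final\trecall_final\n"
        )
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.pathway,
                        str(r.n_template),
                        str(r.n_target_gold),
                        str(r.n_initial),
                        format_percent(r.precision_initial / 100),
                        format_percent(r.recall_initial / 100),
                        "|".join(str(c) for c in r.recruit_counts),
                        str(r.n_final),
                        format_percent(r.precision_final / 100),
                        format_percent(r.recall_final / 100),
                    ]
                )
                + "\n"
            )
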