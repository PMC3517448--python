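"""Four-stage pipeline: map -> expand -> validate -> evaluate.

Each stage persists its model under the output directory
(``step1_initial``, ``step2_expanded``, ``step3_validated``) as plain-text
files a user may inspect or hand-edit between stages — the human-in-the-loop
counterpart of an interactive session.  A machine-readable ``report.json``
records per-stage counts and every effective parameter, enough to reproduce
the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as opio
from .evaluate import evaluate_model, validate_expression
from .expansion import EXPANSION_TYPES, expand, recruit_counts
from .mapping import (
    MappingConfig,
    map_template_pathway,
    merge_models,
    transfer_interactions,
)
from .types import OrthopathError, PathwayModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and knobs of one pipeline run."""

    template_table: str
    template_proteomes: list[str]
    target_proteome: str
    out_dir: str
    template_interactions: Optional[str] = None
    operons: Optional[str] = None
    associations: Optional[str] = None
    association_default_type: str = "user"
    expansion_types: list[str] = field(default_factory=lambda: list(EXPANSION_TYPES))
    min_score: float = 0.0
    expression: Optional[str] = None
    gold: Optional[str] = None
    template_genes: Optional[str] = None
    evaluation_mode: str = "standard"
    e_cutoff: float = 1e-6
    candidate_fraction: float = 0.9
    operon_penalty: float = 1.0
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def mapping_config(self) -> MappingConfig:
        return MappingConfig(
            e_cutoff=self.e_cutoff,
            candidate_fraction=self.candidate_fraction,
            operon_penalty=self.operon_penalty,
        )


def _stage(name: str):
    logger.info("[%s] starting", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written to
    ``<out>/report.json``).  A stage failure raises OrthopathError naming
    the stage; artifacts of completed stages are left in place."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": asdict(config), "stages": {}}

    def fail(stage: str, exc: Exception):
        raise OrthopathError(f"stage {stage!r} failed: {exc}") from exc

    # stage 1: template collection + mapping
    try:
        _stage("map")
        templates = opio.read_template_table(
            config.template_table, config.template_interactions
        )
        proteomes = {}
        for p in config.template_proteomes:
            prot = opio.read_fasta(p)
            proteomes[prot.organism_id] = prot
        target = opio.read_fasta(config.target_proteome)
        operons = (
            opio.read_operons(config.operons, target.organism_id)
            if config.operons
            else None
        )
        mcfg = config.mapping_config()
        fragments = []
        used_templates = []
        for tpl in templates:
            if tpl.organism_id not in proteomes:
                logger.warning(
                    "skipping template %s/%s: no proteome supplied",
                    tpl.name,
                    tpl.organism_id,
                )
                continue
            fragments.append(
                map_template_pathway(
                    tpl, proteomes[tpl.organism_id], target, operons, mcfg
                )
            )
            used_templates.append(tpl)
        if not fragments:
            raise OrthopathError("no template could be mapped (no proteomes matched)")
        initial = merge_models(fragments, name="initial")
        for tpl in used_templates:
            transfer_interactions(tpl, initial)
        opio.write_model(initial, out / "step1_initial")
        report["stages"]["map"] = {
            "n_templates": len(used_templates),
            "n_initial": len(initial),
            "n_holes": len(initial.holes),
            "n_edges": len(initial.edges),
            "n_conflicts": sum(e.conflict for e in initial.entries.values()),
        }
    except OrthopathError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        fail("map", exc)

    # stage 2: expansion
    try:
        _stage("expand")
        edges = (
            opio.read_associations(config.associations, config.association_default_type)
            if config.associations
            else None
        )
        expanded = expand(
            initial,
            operons=operons,
            edges=edges,
            types=config.expansion_types,
            min_score=config.min_score,
        )
        opio.write_model(expanded, out / "step2_expanded")
        report["stages"]["expand"] = {
            "n_final": len(expanded),
            "recruits": recruit_counts(expanded),
        }
    except Exception as exc:
        fail("expand", exc)

    # stage 3: validation against expression evidence
    model = expanded
    if config.expression:
        try:
            _stage("validate")
            evidence = opio.read_gene_list(config.expression)
            model = validate_expression(expanded, evidence)
            opio.write_model(model, out / "step3_validated")
            report["stages"]["validate"] = {
                "n_evidence_genes": len(evidence),
                "n_validated": sum(
                    e.evidence == "validated" for e in model.entries.values()
                ),
            }
        except Exception as exc:
            fail("validate", exc)

    # stage 4: evaluation against a gold standard
    if config.gold:
        try:
            _stage("evaluate")
            gold = opio.read_gene_list(config.gold)
            template_genes = (
                opio.read_gene_list(config.template_genes)
                if config.template_genes
                else None
            )
            res_initial = evaluate_model(
                initial.gene_ids(), gold, template_genes, config.evaluation_mode
            )
            res_final = evaluate_model(
                model.gene_ids(), gold, template_genes, config.evaluation_mode
            )
            report["stages"]["evaluate"] = {
                "mode": config.evaluation_mode,
                "initial": {
                    "TP": res_initial.TP,
                    "FP": res_initial.FP,
                    "FN": res_initial.FN,
                    "precision": res_initial.precision,
                    "recall": res_initial.recall,
                },
                "final": {
                    "TP": res_final.TP,
                    "FP": res_final.FP,
                    "FN": res_final.FN,
                    "precision": res_final.precision,
                    "recall": res_final.recall,
                },
            }
        except Exception as exc:
            fail("evaluate", exc)

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def load_report(out_dir) -> dict:
    with open(Path(out_dir) / "report.json", encoding="utf-8") as fh:
        return json.load(fh)
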