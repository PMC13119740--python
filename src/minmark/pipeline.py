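"""End-to-end orchestration: filter → select → validate → fingerprint →
robustness → report.

The pipeline is a pure composition of the stage functions — running the
stages individually on the same intermediates gives identical results — and
every output records the seed and package version, the provenance a genebank
audit trail needs.  Reports are TSV (curator spreadsheets) plus JSON
(machine use).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError
from .fingerprinting import (
    FingerprintTable,
    discrimination_rate,
    duplicate_report,
    fingerprint_table,
)
from .io import (
    Coding,
    DialectSpec,
    read_genotype_matrix,
    read_panel,
    write_fingerprint_registry,
    write_panel,
)
from .qc import drop_monomorphic, filter_accessions, filter_markers
from .robustness import marker_failure_simulation, robustness_plot_table
from .selection import (
    DiscriminationPolicy,
    SelectionConfig,
    select_minimal_markers,
    validate_panel,
)
from .simulate import SimConfig, simulate_panel
from .stats import rounded_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_by_group"]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Exactly one of ``input_path`` (with ``dialect``) or ``simulate`` must be
    set.  ``panel_path`` switches to validate-only mode: selection is skipped
    and the provided panel is validated and fingerprinted instead.
    """

    output_dir: str = "minmark_run"
    seed: int = 0
    # input
    input_path: str | None = None
    dialect: DialectSpec = field(default_factory=DialectSpec)
    simulate: SimConfig | None = None
    # filtering
    min_marker_call_rate: float = 0.95
    min_maf: float = 0.05
    min_accession_call_rate: float = 0.995
    max_het: float = 0.001
    # selection
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    panel_path: str | None = None
    # robustness
    robustness_reps: int = 200
    robustness_k_values: list[int] | None = None
    group_column: str = "group"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dialect" in raw:
            d = raw["dialect"]
            raw["dialect"] = DialectSpec(
                delimiter=d.get("delimiter", "\t"),
                coding=Coding(d.get("coding", "AB")),
                orientation=d.get("orientation", "accessions"),
                missing_tokens=frozenset(d.get("missing_tokens", DialectSpec().missing_tokens)),
                missing_out=d.get("missing_out", "NA"),
            )
        if "simulate" in raw and raw["simulate"] is not None:
            s = dict(raw["simulate"])
            if "pedigree_groups" in s:
                s["pedigree_groups"] = tuple(tuple(g) for g in s["pedigree_groups"])
            if "ancestral_maf_range" in s:
                s["ancestral_maf_range"] = tuple(s["ancestral_maf_range"])
            raw["simulate"] = SimConfig(**s)
        if "selection" in raw and raw["selection"] is not None:
            sel = dict(raw["selection"])
            if "forced_markers" in sel:
                sel["forced_markers"] = tuple(sel["forced_markers"])
            if "excluded_markers" in sel:
                sel["excluded_markers"] = frozenset(sel["excluded_markers"])
            if "policy" in sel:
                sel["policy"] = DiscriminationPolicy(sel["policy"])
            raw["selection"] = SelectionConfig(**sel)
        return cls(**raw)


def summarize_by_group(
    ft: FingerprintTable,
    accession_meta: pd.DataFrame | None,
    group_column: str = "group",
) -> pd.DataFrame:
    """Per-group discrimination table: group, n, n_unique, discrimination %.

    Uniqueness is recomputed *within* each group (a merged or union row must
    be recomputed over the union, never averaged).  Accessions without a
    group label are collected under ``"ungrouped"``.
    """
    if accession_meta is not None and group_column in accession_meta.columns:
        labels = {
            acc: str(accession_meta.loc[acc, group_column])
            if acc in accession_meta.index and pd.notna(accession_meta.loc[acc, group_column])
            else "ungrouped"
            for acc in ft.accession_ids
        }
    else:
        labels = {acc: "ungrouped" for acc in ft.accession_ids}
    rows = []
    for group in sorted(set(labels.values())):
        members = [a for a in ft.accession_ids if labels[a] == group]
        sub = ft.restrict(members)
        rows.append(
            {
                "group": group,
                "n": sub.n_accessions,
                "n_unique": sub.n_unique,
                "discrimination_pct": discrimination_rate(sub),
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, stage_name):
            self.stage_name = stage_name

        def __enter__(self):
            logger.info("pipeline stage: %s", self.stage_name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(self.stage_name, exc) from exc
            return False

    return _Ctx(name)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write TSV/JSON outputs under ``config.output_dir``.

    Returns the run report (also written as ``report.json``).  Any stage
    error aborts with the stage name and cause.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    with _stage("input"):
        if (config.input_path is None) == (config.simulate is None):
            raise ValueError("exactly one of input_path or simulate must be set")
        if config.simulate is not None:
            gm, _truth = simulate_panel(config.simulate)
        else:
            gm = read_genotype_matrix(config.input_path, config.dialect)
        report["input"] = {"n_accessions": gm.n_accessions, "n_markers": gm.n_markers}

    with _stage("filter"):
        gm_f, marker_rep = filter_markers(gm, config.min_marker_call_rate, config.min_maf)
        gm_f, mono_rep = drop_monomorphic(gm_f)
        gm_f, acc_rep = filter_accessions(gm_f, config.min_accession_call_rate, config.max_het)
        report["filter"] = {
            "thresholds": {
                "min_marker_call_rate": config.min_marker_call_rate,
                "min_maf": config.min_maf,
                "min_accession_call_rate": config.min_accession_call_rate,
                "max_het": config.max_het,
            },
            "markers": marker_rep.to_dict(),
            "monomorphic": mono_rep.to_dict(),
            "accessions": acc_rep.to_dict(),
        }
        removed = []
        for rep in (marker_rep, mono_rep, acc_rep):
            for ident, reason in rep.removed.items():
                removed.append({"axis": rep.axis, "id": ident, "reason": reason.value})
        pd.DataFrame(removed, columns=["axis", "id", "reason"]).to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )

    with _stage("stats"):
        rounded_summary(gm_f).to_csv(out / "marker_stats.tsv", sep="\t")

    policy = config.selection.policy
    with _stage("select"):
        if config.panel_path is not None:
            panel = read_panel(config.panel_path)
            report["selection"] = {"mode": "validate-only", "panel_size": len(panel)}
        else:
            panel = select_minimal_markers(gm_f, config.selection)
            report["selection"] = {
                "mode": "greedy",
                "panel_size": len(panel),
                "unresolved_pairs_remaining": panel.unresolved_pairs_remaining,
                "resolved_fraction": panel.resolved_fraction,
            }
        write_panel(panel, out / "panel.tsv")

    with _stage("validate"):
        val = validate_panel(gm_f, panel, policy)
        report["validation"] = {
            "resolved_fraction": val.resolved_fraction,
            "n_pairs_total": val.n_pairs_total,
            "n_pairs_unresolved": val.n_pairs_unresolved,
        }
        pd.DataFrame(
            list(val.per_marker_contribution.items()), columns=["marker", "newly_resolved"]
        ).to_csv(out / "panel_validation.tsv", sep="\t", index=False)

    with _stage("fingerprint"):
        ft = fingerprint_table(gm_f, panel, policy)
        write_fingerprint_registry(ft, out / "fingerprints.tsv")
        dup = duplicate_report(ft, gm_f.accession_meta)
        dup.to_csv(out / "duplicate_report.tsv", sep="\t", index=False)
        overall = discrimination_rate(ft)
        groups_tbl = summarize_by_group(ft, gm_f.accession_meta, config.group_column)
        groups_tbl.to_csv(out / "group_discrimination.tsv", sep="\t", index=False)
        report["fingerprint"] = {
            "discrimination_pct": overall,
            "n_unique": ft.n_unique,
            "n_accessions": ft.n_accessions,
            "n_duplicate_groups": sum(1 for g in ft.groups if len(g) > 1),
            "by_group": groups_tbl.to_dict(orient="records"),
        }

    with _stage("robustness"):
        rob = marker_failure_simulation(
            gm_f,
            panel,
            reps=config.robustness_reps,
            seed=config.seed,
            k_values=config.robustness_k_values,
            policy=policy,
        )
        tbl = robustness_plot_table(rob)
        tbl.to_csv(out / "robustness.tsv", sep="\t", index=False)
        report["robustness"] = {
            "reps": rob.reps,
            "seed": rob.seed,
            "k": rob.k_values,
            "mean": [float(x) for x in rob.mean],
            "sd": [float(x) for x in rob.sd],
        }

    with _stage("report"):
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
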