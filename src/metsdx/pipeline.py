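"""End-to-end orchestration: filter -> indices -> diagnosis -> per-stratum ROC.

A run evaluates every marker against every diagnostic criterion inside
each of the six sex x age strata and renders one accuracy table per
(criterion, stratum), rows sorted by descending Youden index.  The whole
run is deterministic given the config seed: every bootstrap draws from a
sub-stream keyed by (criterion, stratum, marker), so results do not
depend on evaluation order.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import accuracy, cohort, criteria, markers, synthdata
from .accuracy import AccuracyReport, AucComparison
from .cohort import FilterLog, ParticipantRecord, Stratum, all_strata
from .criteria import CRITERIA
from .markers import MARKER_IDS, ORIENTATIONS

TABLE_COLUMNS = ("Index", "Cut-Off Point", "AUC(95% CI)", "Se (%)", "Sp (%)",
                 "PPV (%)", "NPV (%)", "LRP", "LRN", "Youden Index")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: Optional[str] = None
    cohort_spec: Optional[synthdata.CohortSpec] = None
    criteria: Sequence[str] = CRITERIA
    markers: Sequence[str] = MARKER_IDS
    bootstrap_B: int = 2000
    seed: Optional[int] = None
    out_dir: Optional[str] = None
    vai_women_as_printed: bool = False
    column_map: Optional[dict] = None
    compare_all_pairs: bool = False
    top_k: int = 3

    def __post_init__(self):
        if self.bootstrap_B and self.seed is None:
            raise ValueError("a seed is required whenever the bootstrap is enabled")
        if self.input_path is None and self.cohort_spec is None:
            raise ValueError("either an input path or a cohort spec is required")


@dataclass
class StratumResult:
    """All marker reports for one (criterion, stratum) cell."""

    stratum: Stratum
    criterion: str
    n_pos: int
    n_neg: int
    reports: dict[str, AccuracyReport] = field(default_factory=dict)
    best_marker: Optional[str] = None
    evaluable: bool = True
    scores: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    labels: Optional[np.ndarray] = field(default=None, repr=False)


def _marker_seed(base_seed: int, ci: int, si: int, mi: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(10, ci, si, mi))


def prepare_cohort(config: RunConfig) -> tuple[list[ParticipantRecord], FilterLog]:
    """Load or simulate, filter, and attach derived anthropometrics."""
    if config.input_path is not None:
        records = cohort.load_cohort(config.input_path, column_map=config.column_map)
    else:
        records = synthdata.generate_cohort(config.cohort_spec)
    kept, log = cohort.apply_eligibility(records)
    kept = [cohort.derive_anthropometrics(r) for r in kept]
    return kept, log


def run_pipeline(config: RunConfig) -> list[StratumResult]:
    kept, log = prepare_cohort(config)

    panels = [markers.compute_panel(r, women_as_printed=config.vai_women_as_printed)
              for r in kept]
    strata = [cohort.assign_stratum(r) for r in kept]
    diagnoses = {c: [criteria.diagnose(r, c) for r in kept] for c in config.criteria}

    results: list[StratumResult] = []
    for ci, criterion in enumerate(config.criteria):
        for si, stratum in enumerate(all_strata()):
            idx = [i for i, s in enumerate(strata) if s == stratum]
            labels = np.array([diagnoses[criterion][i].positive for i in idx], dtype=bool)
            n_pos = int(labels.sum())
            n_neg = int(labels.size - n_pos)
            result = StratumResult(stratum=stratum, criterion=criterion,
                                   n_pos=n_pos, n_neg=n_neg, labels=labels)
            if n_pos == 0 or n_neg == 0:
                result.evaluable = False
                results.append(result)
                continue
            for mi, marker in enumerate(MARKER_IDS):
                if marker not in config.markers:
                    continue
                scores = np.array([panels[i][marker] for i in idx])
                result.scores[marker] = scores
                seed = (_marker_seed(config.seed, ci, si, mi)
                        if config.bootstrap_B else None)
                result.reports[marker] = accuracy.evaluate_marker(
                    scores, labels, ORIENTATIONS[marker],
                    B=config.bootstrap_B, seed=seed)
            if result.reports:
                result.best_marker = max(
                    sorted(result.reports), key=lambda m: result.reports[m].yi)
            results.append(result)

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "filter_log.json"), "w") as fh:
            fh.write(log.to_json())
        write_marker_csv(kept, panels, strata, os.path.join(config.out_dir, "markers.csv"))
        write_label_csv(kept, diagnoses, os.path.join(config.out_dir, "labels.csv"))
        with open(os.path.join(config.out_dir, "results.json"), "w") as fh:
            fh.write(results_to_json(results))
        render_tables(results, config.out_dir, fmt="csv")
    return results


# ---------------------------------------------------------------------------
# Reporting

def _fmt(value: float, nd: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return f"{value:.{nd}f}"


def _fmt_ci(value: float, ci, nd: int) -> str:
    if ci is None:
        return _fmt(value, nd)
    return f"{_fmt(value, nd)} ({_fmt(ci[0], nd)}–{_fmt(ci[1], nd)})"


def _fmt_cutoff(report: AccuracyReport) -> str:
    sign = "≥" if report.orientation == markers.HIGHER_IS_POSITIVE else "≤"
    return f"{sign}{report.cutoff:.2f}"


def report_row(marker: str, report: AccuracyReport) -> dict[str, str]:
    """One rendered table row (percentages 1 dp, LRs 2 dp, AUC 3 dp)."""
    return {
        "Index": marker,
        "Cut-Off Point": _fmt_cutoff(report),
        "AUC(95% CI)": _fmt_ci(report.auc, report.auc_ci, 3),
        "Se (%)": _fmt_ci(report.se, report.se_ci, 1),
        "Sp (%)": _fmt_ci(report.sp, report.sp_ci, 1),
        "PPV (%)": _fmt_ci(report.ppv, report.ppv_ci, 1),
        "NPV (%)": _fmt_ci(report.npv, report.npv_ci, 1),
        "LRP": _fmt_ci(report.lrp, report.lrp_ci, 2),
        "LRN": _fmt_ci(report.lrn, report.lrn_ci, 2),
        "Youden Index": _fmt_ci(report.yi, report.yi_ci, 1),
    }


def render_tables(results: Sequence[StratumResult], out_dir: str,
                  fmt: str = "csv") -> list[str]:
    """Write one accuracy table per (criterion, stratum), best marker first."""
    if not results:
        raise ValueError("no results to render")
    if fmt not in ("csv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for result in results:
        if not result.evaluable or not result.reports:
            continue
        order = sorted(result.reports, key=lambda m: -result.reports[m].yi)
        rows = [report_row(m, result.reports[m]) for m in order]
        frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
        tag = f"{result.criterion}_{result.stratum.sex}_{result.stratum.age_group}"
        tag = tag.replace(">=", "ge")
        if fmt == "csv":
            path = os.path.join(out_dir, f"table_{tag}.csv")
            frame.to_csv(path, index=False)
        else:
            path = os.path.join(out_dir, f"table_{tag}.md")
            with open(path, "w") as fh:
                fh.write(frame.to_markdown(index=False))
        paths.append(path)
    return paths


def _report_to_dict(report: AccuracyReport) -> dict:
    d = dataclasses.asdict(report)
    d.pop("counts")
    return d


def results_to_json(results: Sequence[StratumResult]) -> str:
    payload = []
    for r in results:
        payload.append({
            "criterion": r.criterion,
            "sex": r.stratum.sex,
            "age_group": r.stratum.age_group,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "evaluable": r.evaluable,
            "best_marker": r.best_marker,
            "reports": {m: _report_to_dict(rep) for m, rep in sorted(r.reports.items())},
        })
    return json.dumps(payload, indent=2, allow_nan=True)


# ---------------------------------------------------------------------------
# Pairwise AUC comparisons

def compare_best_markers(result: StratumResult,
                         pairs: Optional[Sequence[tuple[str, str]]] = None,
                         B: int = 2000, seed: Optional[int] = None,
                         top_k: int = 3, all_pairs: bool = False) -> list[dict]:
    """Paired-bootstrap AUC comparisons within one stratum.

    Default pairs: all pairings among the ``top_k`` markers by Youden
    index (the usual reporting pattern); ``all_pairs`` compares every
    marker pair instead.  No multiplicity adjustment is applied.
    """
    if not result.evaluable:
        raise ValueError("stratum is not evaluable")
    if B and seed is None:
        raise ValueError("a seed is required for bootstrap comparisons")
    if pairs is None:
        ranked = sorted(result.reports, key=lambda m: -result.reports[m].yi)
        chosen = ranked if all_pairs else ranked[:top_k]
        pairs = [(a, b) for i, a in enumerate(chosen) for b in chosen[i + 1:]]
    rows = []
    for k, (a, b) in enumerate(pairs):
        for name in (a, b):
            if name not in result.scores:
                raise ValueError(f"marker {name!r} not present in this stratum result")
        cmp_seed = np.random.SeedSequence(entropy=seed, spawn_key=(20, k))
        comparison = accuracy.compare_auc_paired_bootstrap(
            result.scores[a], result.scores[b], result.labels,
            orientations=(ORIENTATIONS[a], ORIENTATIONS[b]), B=B, seed=cmp_seed)
        rows.append({
            "criterion": result.criterion,
            "sex": result.stratum.sex,
            "age_group": result.stratum.age_group,
            "marker_a": a, "marker_b": b,
            "auc_a": comparison.auc_a, "auc_b": comparison.auc_b,
            "delta_auc": comparison.delta_auc, "p_value": comparison.p_value,
            "degenerate": comparison.degenerate,
        })
    return rows


# ---------------------------------------------------------------------------
# Per-stage CSV outputs

def write_marker_csv(kept, panels, strata, path) -> None:
    rows = []
    for r, panel, stratum in zip(kept, panels, strata):
        row = {"id": r.id, "sex": stratum.sex, "age_group": stratum.age_group}
        row.update({m: panel[m] for m in MARKER_IDS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_label_csv(kept, diagnoses, path) -> None:
    rows = []
    for i, r in enumerate(kept):
        row = {"id": r.id}
        for crit_name, labels in diagnoses.items():
            prefix = "atp3" if crit_name == criteria.ATP_III else crit_name.lower()
            label = labels[i]
            row[f"{prefix}_positive"] = int(label.positive)
            for comp, flag in label.components.items():
                row[f"{prefix}_{comp}"] = int(flag)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_roc(result: StratumResult, path: str) -> None:
    """Optional convenience: one ROC panel per marker with the diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 5, figsize=(18, 7), sharex=True, sharey=True)
    for ax, marker in zip(axes.ravel(), MARKER_IDS):
        if marker not in result.scores:
            ax.axis("off")
            continue
        roc = accuracy.empirical_roc(result.scores[marker], result.labels,
                                     ORIENTATIONS[marker])
        fpr = 1.0 - roc.sp
        order = np.argsort(fpr)
        ax.plot(fpr[order], roc.se[order], lw=1.2)
        ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
        ax.set_title(f"{marker} (AUC {result.reports[marker].auc:.3f})", fontsize=9)
    fig.suptitle(f"{result.criterion} {result.stratum.label}")
    fig.supxlabel("1 - specificity")
    fig.supylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
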