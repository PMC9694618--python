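"""End-to-end analysis: summaries, rank tests, composite index, ROC table.

``run_analysis`` takes a cohort (read from CSV or simulated) and produces a
single deterministic report object holding everything the downstream tables
and figures are built from: per-group descriptive statistics for the three
biomarkers and the composite index, two-sided Wilcoxon-Mann-Whitney
comparisons, the four-row AUC/cut-off/sensitivity/specificity table, the
full ROC point lists, per-episode composite scores, long-form distribution
exports (raw and mean-normalized values, for density/violin plots), and a
log of the analysis conventions used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cindex import (
    CIndexResult,
    ReferenceMeans,
    compute_cindex,
    compute_reference_means,
    results_frame,
)
from .cohort import BIOMARKERS, Cohort
from .roc import (
    MARKER_ORDER,
    CutoffPerformance,
    ROCCurve,
    analyze_markers,
    marker_curves,
)
from .stats import ALPHA, RankTestResult, SummaryRow, rank_sum_test, summarize

#: Conventions that pin down every number in the report.
DECISIONS_LOG = {
    "quartile_convention": "linear interpolation of order statistics "
    "(quantile p at position 1+(n-1)p)",
    "sd_denominator": "n-1 (sample SD)",
    "decision_rule": "score >= cutoff => predicted infection",
    "cutoff_scale": "observed score values (no midpoint interpolation)",
    "cutoff_selection": "maximize Youden J; ties broken by higher "
    "sensitivity, then lower threshold",
    "rank_test": "two-sided Wilcoxon-Mann-Whitney; exact enumeration when "
    "n1+n2 <= 12, else normal approximation with tie and "
    "continuity corrections",
    "alpha": ALPHA,
    "positive_class": "infection (label 1)",
}


@dataclass(frozen=True)
class AnalysisReport:
    provenance: str
    n_total: int
    n_infection: int
    n_no_infection: int
    reference_means: ReferenceMeans
    summaries: tuple[SummaryRow, ...]
    rank_tests: dict[str, RankTestResult]
    performance: tuple[CutoffPerformance, ...]
    curves: tuple[ROCCurve, ...]
    cindex_results: tuple[CIndexResult, ...]


def run_analysis(
    cohort: Cohort, ref: Optional[ReferenceMeans] = None
) -> AnalysisReport:
    """Run every stage on one cohort.

    Reference means default to the cohort's own pooled means; pass an
    external ``ReferenceMeans`` to score against a reference population.
    Deterministic: the same cohort and reference always give the same report.
    """
    if cohort.n_infection() == 0 or cohort.n_no_infection() == 0:
        raise ValueError(
            "analysis requires both infection and no-infection episodes"
        )
    if ref is None:
        ref = compute_reference_means(cohort)
    cindex_results = compute_cindex(cohort, ref)
    cindex_by_label = {
        label: [
            r.cindex
            for r, ep in zip(cindex_results, cohort)
            if ep.infection == label
        ]
        for label in (0, 1)
    }

    summaries: list[SummaryRow] = []
    rank_tests: dict[str, RankTestResult] = {}
    for marker in MARKER_ORDER:
        if marker == "cindex":
            total = [r.cindex for r in cindex_results]
            pos, neg = cindex_by_label[1], cindex_by_label[0]
        else:
            total = cohort.values(marker)
            pos = cohort.group_values(marker, 1)
            neg = cohort.group_values(marker, 0)
        summaries.append(summarize(total, marker, "total"))
        summaries.append(summarize(pos, marker, "infection"))
        summaries.append(summarize(neg, marker, "no_infection"))
        rank_tests[marker] = rank_sum_test(pos, neg)

    performance = analyze_markers(cohort, cindex_results)
    curves = marker_curves(cohort, cindex_results)

    return AnalysisReport(
        provenance=cohort.provenance,
        n_total=len(cohort),
        n_infection=cohort.n_infection(),
        n_no_infection=cohort.n_no_infection(),
        reference_means=ref,
        summaries=tuple(summaries),
        rank_tests=rank_tests,
        performance=tuple(performance),
        curves=tuple(curves),
        cindex_results=tuple(cindex_results),
    )


def summary_frame(summaries: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": s.name, "group": s.group, "n": s.n, "mean": s.mean,
                "median": s.median, "sd": s.sd, "q1": s.q1, "q3": s.q3,
            }
            for s in summaries
        ]
    )


def performance_frame(rows: Sequence[CutoffPerformance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.marker, "auc": r.auc, "cutoff": r.cutoff,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
            }
            for r in rows
        ]
    )


def roc_points_frame(curves: Sequence[ROCCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "marker": c.marker,
                    "threshold": c.thresholds,
                    "fpr": c.fpr,
                    "tpr": c.tpr,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def distributions_frame(report: AnalysisReport, cohort: Cohort) -> pd.DataFrame:
    """Long-form marker values per group, raw and mean-normalized.

    The normalized column divides each biomarker by its reference mean (and
    the composite index by 3, its value at the per-marker means), putting
    all four densities on one comparable axis.
    """
    rows = []
    for ep, res in zip(cohort, report.cindex_results):
        group = "infection" if ep.infection else "no_infection"
        for marker, raw, norm in (
            ("pct", ep.pct, res.pct_term),
            ("crp", ep.crp, res.crp_term),
            ("il6", ep.il6, res.il6_term),
            ("cindex", res.cindex, res.cindex / 3.0),
        ):
            rows.append(
                {
                    "episode_id": ep.episode_id,
                    "marker": marker,
                    "group": group,
                    "value": raw,
                    "normalized": norm,
                }
            )
    return pd.DataFrame(rows)


def report_to_dict(report: AnalysisReport) -> dict:
    """JSON-serializable view of the full report."""
    return {
        "provenance": report.provenance,
        "n_total": report.n_total,
        "n_infection": report.n_infection,
        "n_no_infection": report.n_no_infection,
        "reference_means": {
            "pct_hat": report.reference_means.pct_hat,
            "crp_hat": report.reference_means.crp_hat,
            "il6_hat": report.reference_means.il6_hat,
            "source": report.reference_means.source,
        },
        "summaries": summary_frame(report.summaries).to_dict("records"),
        "rank_tests": {
            marker: dataclasses.asdict(res)
            for marker, res in report.rank_tests.items()
        },
        "performance": performance_frame(report.performance).to_dict("records"),
        "cindex": results_frame(report.cindex_results).to_dict("records"),
        "decisions": DECISIONS_LOG,
    }


def write_report(report: AnalysisReport, cohort: Cohort, outdir: str | Path) -> Path:
    """Write report.json plus one flat CSV per table; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, allow_nan=False) + "\n",
        encoding="utf-8",
    )
    summary_frame(report.summaries).to_csv(outdir / "summary.csv", index=False)
    performance_frame(report.performance).to_csv(
        outdir / "performance.csv", index=False
    )
    results_frame(report.cindex_results).to_csv(
        outdir / "cindex.csv", index=False
    )
    roc_points_frame(report.curves).to_csv(outdir / "roc_points.csv", index=False)
    distributions_frame(report, cohort).to_csv(
        outdir / "distributions.csv", index=False
    )
    return outdir


def load_reference_means(path: str | Path) -> ReferenceMeans:
    """Read external reference means from a JSON file.

    Expected keys: ``pct_hat``, ``crp_hat``, ``il6_hat``.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return ReferenceMeans(
        pct_hat=float(doc["pct_hat"]),
        crp_hat=float(doc["crp_hat"]),
        il6_hat=float(doc["il6_hat"]),
        source="external",
    )
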