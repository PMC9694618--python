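"""The mean-normalized composite biomarker index (CIndex).

For episode i with biomarker values PCT_i, CRP_i, IL6_i and reference means
(PCT_hat, CRP_hat, IL6_hat):

    CIndex_i = PCT_i / PCT_hat + CRP_i / CRP_hat + IL6_i / IL6_hat

The normalization to the mean makes the score dimensionless and puts the
three markers — whose raw scales differ by orders of magnitude — on equal
footing without fitted coefficients. An episode sitting exactly at the mean
of every marker scores 3; when the reference means are the analyzed
cohort's own pooled means, the cohort-average CIndex is exactly 3.

Reference means default to the analyzed cohort's pooled means but may be
supplied externally (e.g. from a large homogeneous reference population)
for deployment on new episodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS, Cohort


class NormalizationError(ValueError):
    """Reference means unusable as normalization denominators."""


@dataclass(frozen=True)
class ReferenceMeans:
    """The three normalization denominators, all strictly positive."""

    pct_hat: float
    crp_hat: float
    il6_hat: float
    source: Literal["cohort", "external"] = "cohort"

    def __post_init__(self) -> None:
        for name in ("pct_hat", "crp_hat", "il6_hat"):
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise NormalizationError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    def denominator(self, biomarker: str) -> float:
        return {"pct": self.pct_hat, "crp": self.crp_hat, "il6": self.il6_hat}[
            biomarker
        ]


@dataclass(frozen=True)
class CIndexResult:
    """One episode's composite score and its three normalized terms."""

    episode_id: str
    cindex: float
    pct_term: float
    crp_term: float
    il6_term: float


def compute_reference_means(cohort: Cohort) -> ReferenceMeans:
    """Arithmetic means of each biomarker over ALL episodes, groups pooled.

    Raises if any biomarker column is all-zero: a zero mean leaves the
    normalization undefined.
    """
    if len(cohort) == 0:
        raise NormalizationError("cohort is empty")
    means = {b: float(np.mean(cohort.values(b))) for b in BIOMARKERS}
    for b, m in means.items():
        if m <= 0:
            raise NormalizationError(
                f"{b} has mean {m}; normalization by the mean is undefined"
            )
    return ReferenceMeans(
        pct_hat=means["pct"],
        crp_hat=means["crp"],
        il6_hat=means["il6"],
        source="cohort",
    )


def compute_cindex(
    cohort: Cohort, ref: ReferenceMeans
) -> list[CIndexResult]:
    """Composite score per episode, in episode order."""
    results = []
    for ep in cohort:
        pct_term = ep.pct / ref.pct_hat
        crp_term = ep.crp / ref.crp_hat
        il6_term = ep.il6 / ref.il6_hat
        results.append(
            CIndexResult(
                episode_id=ep.episode_id,
                cindex=pct_term + crp_term + il6_term,
                pct_term=pct_term,
                crp_term=crp_term,
                il6_term=il6_term,
            )
        )
    return results


def results_frame(results: Sequence[CIndexResult]) -> pd.DataFrame:
    """Tabular view with columns episode_id,cindex,pct_term,crp_term,il6_term."""
    return pd.DataFrame(
        {
            "episode_id": [r.episode_id for r in results],
            "cindex": [r.cindex for r in results],
            "pct_term": [r.pct_term for r in results],
            "crp_term": [r.crp_term for r in results],
            "il6_term": [r.il6_term for r in results],
        }
    )


def write_results(results: Sequence[CIndexResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, index=False)
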