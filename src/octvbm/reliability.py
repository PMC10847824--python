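"""Test-retest reliability maps: Sw, CV and ICC per voxel.

From a stack of repeated registered scans the module computes, at every
voxel,

* Sw  — the within-subject standard deviation across sessions,
  ``sqrt(mean over subjects of the within-subject variance)``; for two
  sessions this reduces to ``sqrt(sum d_i^2 / (2n))``,
* CV  — Sw relative to the voxel grand mean, in percent,
* ICC — the intraclass correlation from the two-way ANOVA decomposition
  (default ICC(2,1): two-way random effects, absolute agreement, single
  measurement),

plus map-level summaries, a qualitative ICC classification and the
paired-comparison null check between two sessions (which reuses the
same FDR + cluster-extent procedure as the group statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, SessionError
from .voxstats import (
    DEFAULT_ALPHA,
    DEFAULT_CONNECTIVITY,
    DEFAULT_MIN_CLUSTER_VOXELS,
    StatMapSet,
    cluster_filter,
    fdr_correct,
)

#: ICC classification bands (lower bound, label), checked top-down.
ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"),
             (-np.inf, "poor"))


@dataclass
class RetestStack:
    """subject x session x row x col thickness array (um)."""

    data: np.ndarray
    layer: str
    same_day: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise SessionError(
                "retest stack must be 4D (subject, session, row, col)")
        if self.data.shape[1] < 2:
            raise SessionError("retest stack needs >= 2 sessions")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.data.shape[2:]


def _anova_mean_squares(data: np.ndarray):
    """Two-way (subject x session) mean squares per voxel.

    data : (n, k, R, C).  Returns (msr, msc, mse, msw, grand_mean), each
    (R, C).  Voxels with any invalid measurement come back NaN.
    """
    n, k = data.shape[:2]
    valid = np.isfinite(data).all(axis=(0, 1))
    d = np.where(valid[None, None], data, np.nan)
    grand = d.mean(axis=(0, 1))
    row_mean = d.mean(axis=1)                      # per subject (n, R, C)
    col_mean = d.mean(axis=0)                      # per session (k, R, C)
    ssr = k * ((row_mean - grand[None]) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand[None]) ** 2).sum(axis=0)
    sst = ((d - grand[None, None]) ** 2).sum(axis=(0, 1))
    sse = np.maximum(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    ssw = ((d - row_mean[:, None]) ** 2).sum(axis=(0, 1))
    msw = ssw / (n * (k - 1))
    return msr, msc, mse, msw, grand


def voxelwise_sw(stack: RetestStack) -> np.ndarray:
    """Within-subject SD (um) at every voxel."""
    if stack.n_sessions < 2:
        raise SessionError("Sw needs >= 2 sessions")
    *_, msw, _ = _anova_mean_squares(stack.data)
    return np.sqrt(msw)


def voxelwise_cv(stack: RetestStack) -> np.ndarray:
    """Coefficient of variation (%) at every voxel: Sw over the voxel
    grand mean.  Voxels with non-positive mean come back NaN."""
    *_, msw, grand = _anova_mean_squares(stack.data)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.sqrt(msw) / grand * 100.0
    cv[~(grand > 0)] = np.nan
    return cv


def voxelwise_icc(stack: RetestStack,
                  form: str = "two-way-random-absolute-single",
                  ) -> np.ndarray:
    """Intraclass correlation at every voxel.

    ``two-way-random-absolute-single`` is ICC(2,1); the consistency
    alternative (ICC(3,1)) drops the session variance term.  Voxels with
    zero total variance come back NaN.
    """
    if stack.n_subjects < 2 or stack.n_sessions < 2:
        raise SessionError("ICC needs >= 2 subjects and >= 2 sessions")
    n, k = stack.n_subjects, stack.n_sessions
    msr, msc, mse, _, _ = _anova_mean_squares(stack.data)
    if form == "two-way-random-absolute-single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "two-way-mixed-consistency-single":
        denom = msr + (k - 1) * mse
    else:
        raise DegenerateInputError(f"unknown ICC form {form!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    icc[~(denom > 0)] = np.nan
    return np.minimum(icc, 1.0)


def classify_icc(icc: float) -> str:
    """Qualitative reliability class of an ICC value."""
    if not np.isfinite(icc):
        return "undefined"
    for lo, label in ICC_BANDS:
        if icc >= lo:
            return label
    return "poor"


@dataclass
class ReliabilityMaps:
    """Voxel-wise reliability maps plus whole-map summaries."""

    sw: np.ndarray
    cv: np.ndarray
    icc: np.ndarray
    summary: Dict[str, float]
    classification: str


def reliability_maps(stack: RetestStack,
                     icc_form: str = "two-way-random-absolute-single",
                     ) -> ReliabilityMaps:
    """Compute Sw/CV/ICC maps and their valid-voxel averages."""
    sw = voxelwise_sw(stack)
    cv = voxelwise_cv(stack)
    icc = voxelwise_icc(stack, form=icc_form)
    summary = {
        "mean_sw_um": float(np.nanmean(sw)),
        "mean_cv_pct": float(np.nanmean(cv)),
        "mean_icc": float(np.nanmean(icc)),
    }
    return ReliabilityMaps(sw=sw, cv=cv, icc=icc, summary=summary,
                           classification=classify_icc(summary["mean_icc"]))


def retest_paired_test(stack: RetestStack,
                       alpha: float = DEFAULT_ALPHA,
                       min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
                       connectivity: int = DEFAULT_CONNECTIVITY,
                       ) -> StatMapSet:
    """Voxel-wise paired t-test between the two sessions, followed by
    the standard FDR + cluster-extent correction.

    On a well-behaved device nothing should survive: repeated same-day
    scans differ only by measurement noise.
    """
    if stack.n_sessions != 2:
        raise SessionError("paired test needs exactly 2 sessions")
    d = stack.data[:, 1] - stack.data[:, 0]            # (n, R, C)
    valid = np.isfinite(d)
    n_eff = valid.sum(axis=0)
    d0 = np.where(valid, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(n_eff > 0, d0.sum(axis=0) / n_eff, np.nan)
        ss = (np.where(valid, d - mean_d[None], 0.0) ** 2).sum(axis=0)
        sd_d = np.sqrt(np.where(n_eff > 1, ss / np.maximum(n_eff - 1, 1),
                                np.nan))
        t = mean_d / (sd_d / np.sqrt(n_eff))
    df = n_eff - 1
    ok = (n_eff >= 2) & (sd_d > 0)
    # identical sessions: zero difference and zero spread -> t = 0, p = 1
    zero = (n_eff >= 2) & (sd_d == 0) & (mean_d == 0)
    t = np.where(ok, t, np.where(zero, 0.0, np.nan))
    p = np.where(np.isfinite(t),
                 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    reject, cutoff = fdr_correct(p, alpha, mask=np.isfinite(p))
    sig, labels = cluster_filter(reject, min_cluster_voxels, connectivity)
    return StatMapSet(stat=t, p=p, sig=sig, clusters=labels,
                      q_threshold=cutoff, diff=mean_d,
                      n_effective=n_eff.astype(int), stat_kind="paired-t",
                      alpha=alpha, min_cluster_voxels=min_cluster_voxels,
                      connectivity=connectivity)


def scalar_reliability(values: np.ndarray,
                       icc_form: str = "two-way-random-absolute-single",
                       ) -> Dict[str, float]:
    """Reliability of a scalar summary parameter (e.g. a macular layer
    volume): CV (%) and ICC with its qualitative class.

    ``values`` is subject x session; the computation is the voxel-wise
    one applied to a 1x1 grid.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise SessionError("scalar reliability needs subject x session input")
    stack = RetestStack(data=values[:, :, None, None], layer="scalar")
    cv = float(voxelwise_cv(stack)[0, 0])
    icc = float(voxelwise_icc(stack, form=icc_form)[0, 0])
    sw = float(voxelwise_sw(stack)[0, 0])
    return {"sw": sw, "cv_pct": cv, "icc": icc,
            "classification": classify_icc(icc)}
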