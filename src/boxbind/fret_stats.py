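"""Acceptor-photobleaching FRET efficiencies and robust group comparisons.

In acceptor-photobleaching FRET the acceptor fluorophore is destroyed by
intense illumination and the donor dequenches: the efficiency of one
region of interest (ROI) is the relative donor gain

    E = 100 * (donor_post - donor_pre) / donor_post   [%]

ROIs are quality-controlled on the achieved acceptor bleach fraction
(default: at least 85% of the acceptor intensity lost).  Groups (wild type
vs binding-box mutants) are summarized by trimmed means and compared to a
reference group with Yuen's two-sample test on trimmed means (winsorized
variances, Welch-Satterthwaite degrees of freedom), with Holm-Bonferroni
step-down correction across the family of comparisons.

Negative efficiencies are retained in group statistics: they are honest
noise around zero and dropping them would bias group means upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, StatError

DEFAULT_TRIM = 0.2
DEFAULT_MIN_BLEACH = 0.85

#: Significance stars on adjusted p-values.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class FretRoi:
    """Background-subtracted mean intensities of one endocytic patch."""

    roi_id: str
    group: str
    donor_pre: float
    donor_post: float
    acceptor_pre: float
    acceptor_post: float


@dataclass(frozen=True)
class YuenResult:
    """Yuen (1974) two-sample trimmed-means comparison."""

    trimmed_mean_1: float
    trimmed_mean_2: float
    t_statistic: float
    df: float
    p_value: float
    trim_fraction: float


def fret_efficiency(roi: FretRoi) -> float:
    """FRET efficiency in percent from donor dequenching.

    Undefined (StatError) when donor_post <= 0; may be negative.
    """
    if roi.donor_post <= 0:
        raise StatError(f"ROI '{roi.roi_id}': donor_post <= 0, efficiency undefined")
    return 100.0 * (roi.donor_post - roi.donor_pre) / roi.donor_post


def bleach_fraction(roi: FretRoi) -> float:
    if roi.acceptor_pre <= 0:
        raise StatError(f"ROI '{roi.roi_id}': acceptor_pre <= 0")
    return 1.0 - roi.acceptor_post / roi.acceptor_pre


def bleach_qc(roi: FretRoi, min_bleach: float = DEFAULT_MIN_BLEACH) -> bool:
    """Keep the ROI iff the acceptor bleach fraction reached ``min_bleach``.

    The threshold is inclusive ("at least"): a bleach of exactly 85% is kept.
    """
    return bleach_fraction(roi) >= min_bleach


def trimmed_mean(x, gamma: float) -> float:
    """Mean after removing the floor(gamma*n) smallest and largest values."""
    if not 0 <= gamma < 0.5:
        raise StatError(f"trim fraction {gamma} outside [0, 0.5)")
    x = np.sort(np.asarray(x, dtype=float))
    g = int(math.floor(gamma * x.size))
    if x.size - 2 * g < 2:
        raise StatError(f"only {x.size - 2 * g} values left after trimming")
    return float(x[g : x.size - g].mean())


def _winsorized_ss(x: np.ndarray, g: int) -> float:
    """Sum of squared deviations of the g-winsorized sample from its mean."""
    xs = np.sort(x)
    w = xs.copy()
    if g > 0:
        w[:g] = xs[g]
        w[-g:] = xs[-g - 1]
    return float(((w - w.mean()) ** 2).sum())


def yuen_test(x, y, gamma: float = DEFAULT_TRIM) -> YuenResult:
    """Yuen's two-sided test for equality of trimmed means.

    With h_i = n_i - 2*floor(gamma*n_i) effective observations and
    winsorized sum of squares SSW_i, the squared standard errors are
    d_i = SSW_i / (h_i (h_i - 1)), the statistic is
    t = (xbar_t - ybar_t) / sqrt(d_1 + d_2), and the degrees of freedom
    follow Welch-Satterthwaite.  At gamma = 0 this is exactly Welch's
    two-sample t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise StatError(f"each group needs >= 5 values (got {x.size}, {y.size})")
    gx = int(math.floor(gamma * x.size))
    gy = int(math.floor(gamma * y.size))
    hx = x.size - 2 * gx
    hy = y.size - 2 * gy
    mx = trimmed_mean(x, gamma)
    my = trimmed_mean(y, gamma)
    dx = _winsorized_ss(x, gx) / (hx * (hx - 1))
    dy = _winsorized_ss(y, gy) / (hy * (hy - 1))
    if dx + dy <= 0:
        raise StatError("zero pooled winsorized variance")
    t = (mx - my) / math.sqrt(dx + dy)
    df = (dx + dy) ** 2 / (dx**2 / (hx - 1) + dy**2 / (hy - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return YuenResult(
        trimmed_mean_1=mx,
        trimmed_mean_2=my,
        t_statistic=float(t),
        df=float(df),
        p_value=float(min(p, 1.0)),
        trim_fraction=gamma,
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def stars(p_adj: float) -> str:
    for level, mark in STAR_LEVELS:
        if p_adj < level:
            return mark
    return "ns"


@dataclass
class GroupComparison:
    """Per-group trimmed means and Holm-adjusted Yuen tests vs a reference."""

    table: pd.DataFrame
    reference: str
    dropped: pd.DataFrame  # QC-rejected or undefined ROIs with reasons


def compare_groups(
    rois: "list[FretRoi] | pd.DataFrame",
    reference_group: str,
    gamma: float = DEFAULT_TRIM,
    min_bleach: float = DEFAULT_MIN_BLEACH,
) -> GroupComparison:
    """Trimmed-mean summary of each group plus pairwise tests vs reference.

    ROIs failing bleach QC (or with undefined efficiency) are dropped and
    logged with a reason.  Output columns: group, n_kept,
    trimmed_mean_pct, p_raw, p_adj_vs_reference, stars (reference row has
    no test).
    """
    if isinstance(rois, pd.DataFrame):
        rois = [
            FretRoi(
                roi_id=str(r.roi_id),
                group=str(r.group),
                donor_pre=float(r.donor_pre),
                donor_post=float(r.donor_post),
                acceptor_pre=float(r.acceptor_pre),
                acceptor_post=float(r.acceptor_post),
            )
            for r in rois.itertuples(index=False)
        ]

    efficiencies: dict[str, list[float]] = {}
    dropped_rows = []
    for roi in rois:
        try:
            if not bleach_qc(roi, min_bleach):
                dropped_rows.append(
                    (roi.roi_id, roi.group,
                     f"bleach {bleach_fraction(roi):.3f} < {min_bleach:g}")
                )
                continue
            e = fret_efficiency(roi)
        except StatError as exc:
            dropped_rows.append((roi.roi_id, roi.group, exc.message))
            continue
        efficiencies.setdefault(roi.group, []).append(e)

    if reference_group not in efficiencies:
        raise ConfigError(f"reference group '{reference_group}' missing or empty")
    ref = np.asarray(efficiencies[reference_group])

    others = [g for g in efficiencies if g != reference_group]
    results = {g: yuen_test(np.asarray(efficiencies[g]), ref, gamma) for g in others}
    p_adj = holm_bonferroni([results[g].p_value for g in others]) if others else []

    rows = [
        (
            reference_group,
            ref.size,
            trimmed_mean(ref, gamma),
            np.nan,
            np.nan,
            "",
        )
    ]
    for g, pa in zip(others, p_adj):
        rows.append(
            (g, len(efficiencies[g]), results[g].trimmed_mean_1,
             results[g].p_value, pa, stars(pa))
        )
    table = pd.DataFrame(
        rows,
        columns=["group", "n_kept", "trimmed_mean_pct", "p_raw",
                 "p_adj_vs_reference", "stars"],
    )
    dropped = pd.DataFrame(dropped_rows, columns=["roi_id", "group", "reason"])
    return GroupComparison(table=table, reference=reference_group, dropped=dropped)
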