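"""Publication-bias diagnostics for catalogues of study-level effects.

Compares published against unpublished effects (Welch t and Mann-Whitney),
pools study means with a DerSimonian-Laird random-effects model, tests
funnel-plot asymmetry with Egger's regression, and lays out cumulative
effect distributions with confidence bands.  Study-level inputs are
``(mean, se)`` pairs in microvolts, as produced by
:func:`spncat.extraction.spn_summary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import SpnSummary

__all__ = [
    "MetaEstimate",
    "FunnelPoint",
    "GroupComparison",
    "group_compare",
    "random_effects_mean",
    "egger_test",
    "cumulative_distribution",
    "funnel_points",
]

_Z975 = stats.norm.ppf(0.975)
_Z995 = stats.norm.ppf(0.995)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison: Welch t plus Mann-Whitney U."""

    welch_t: float
    satterthwaite_df: float
    p: float
    mann_whitney_u: float
    p_mw: float
    mean_difference: float
    ci95: tuple[float, float]


def group_compare(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Compare two groups of study means without assuming equal variances.

    Welch's t with Satterthwaite degrees of freedom, two-tailed, plus a
    Mann-Whitney U test (exact for small tie-free samples, normal
    approximation otherwise, scipy's automatic policy).  The 95% CI of the
    mean difference uses the Welch standard error and t critical value.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(x, y, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    se = math.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
    diff = float(x.mean() - y.mean())
    half = stats.t.ppf(0.975, df) * se
    mw = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return GroupComparison(
        welch_t=t, satterthwaite_df=df, p=p,
        mann_whitney_u=float(mw.statistic), p_mw=float(mw.pvalue),
        mean_difference=diff, ci95=(diff - half, diff + half),
    )


@dataclass(frozen=True)
class MetaEstimate:
    """Random-effects pooled mean with heterogeneity statistics."""

    k: int
    weighted_mean: float
    ci_low: float
    ci_high: float
    tau_squared: float
    q_statistic: float
    i_squared: float


def random_effects_mean(
    points: Sequence[tuple[float, float]], method: str = "dl"
) -> MetaEstimate:
    """Pool study ``(mean, se)`` pairs with a random-effects model.

    DerSimonian-Laird moment estimator of the between-study variance tau²
    (``method="dl"``, default); ``method="fe"`` forces the fixed-effect
    model (tau² = 0).  Weights are ``1 / (se² + tau²)``; the 95% CI uses
    the normal critical value.  ``k = 1`` degenerates to the single study's
    mean with CI ``mean ± 1.96 se``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("need >= 1 (mean, se) study")
    means, ses = pts[:, 0], pts[:, 1]
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    k = pts.shape[0]
    w_fixed = 1.0 / ses**2
    mu_fixed = float((w_fixed * means).sum() / w_fixed.sum())
    q = float((w_fixed * (means - mu_fixed) ** 2).sum())
    df = k - 1
    if method == "fe" or df == 0:
        tau2 = 0.0
    elif method == "dl":
        c = w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum()
        tau2 = max(0.0, (q - df) / c)
    else:
        raise ValueError(f"unknown method {method!r}")
    w = 1.0 / (ses**2 + tau2)
    mu = float((w * means).sum() / w.sum())
    se_mu = math.sqrt(1.0 / w.sum())
    i2 = 0.0 if q <= 0 or df == 0 else max(0.0, (q - df) / q)
    return MetaEstimate(
        k=k, weighted_mean=mu,
        ci_low=mu - _Z975 * se_mu, ci_high=mu + _Z975 * se_mu,
        tau_squared=float(tau2), q_statistic=q, i_squared=float(i2),
    )


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    p: float
    k: int


def egger_test(points: Sequence[tuple[float, float]]) -> EggerResult:
    """Egger's regression test of funnel-plot asymmetry.

    Classic formulation: regress the standard normal deviate ``mean / se``
    on precision ``1 / se``; a non-zero intercept indicates small-study
    (funnel) asymmetry.  Two-tailed t-test on the intercept with ``k - 2``
    degrees of freedom.  Requires at least 3 studies.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("Egger's test needs >= 3 (mean, se) studies")
    means, ses = pts[:, 0], pts[:, 1]
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    snd = means / ses
    precision = 1.0 / ses
    design = np.column_stack([np.ones_like(precision), precision])
    coef, _, rank, _ = np.linalg.lstsq(design, snd, rcond=None)
    if rank < 2:
        raise ValueError("degenerate Egger design (all standard errors equal?)")
    resid = snd - design @ coef
    k = pts.shape[0]
    sigma2 = float(resid @ resid) / (k - 2)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se_int = math.sqrt(cov[0, 0])
    t = float(coef[0] / se_int)
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=float(coef[0]), intercept_se=se_int, t=t, p=p, k=k)


def cumulative_distribution(summaries: Iterable[SpnSummary]) -> pd.DataFrame:
    """Studies sorted by mean amplitude with 95% confidence bands.

    Per-study CI is ``mean ± t(0.975, df) * se``; a study is significant iff
    its CI excludes zero (``ci_high < 0`` for negative effects, ``ci_low >
    0`` for positive ones) — exactly equivalent to ``p < .05`` from the
    two-tailed one-sample t-test.
    """
    rows = []
    for s in summaries:
        half = stats.t.ppf(0.975, s.df) * s.se
        lo, hi = s.mean - half, s.mean + half
        rows.append(
            dict(experiment_id=s.experiment_id, mean=s.mean, ci_low=lo, ci_high=hi,
                 significant=bool(hi < 0.0 or lo > 0.0))
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values("mean", kind="mergesort").reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class FunnelPoint:
    """One study on the funnel plot: mean vs standard error."""

    mean: float
    se: float
    published: bool
    significant_05: bool
    significant_01: bool


def funnel_points(
    summaries: Iterable[SpnSummary], published: Iterable[bool]
) -> list[FunnelPoint]:
    """Funnel-plot coordinates with significance flags.

    Flags use normal critical values (|mean|/se against 1.96 and 2.576),
    matching the straight funnel-triangle edges of the conventional plot.
    """
    out = []
    for s, pub in zip(summaries, published):
        z = abs(s.mean) / s.se
        out.append(
            FunnelPoint(
                mean=s.mean, se=s.se, published=bool(pub),
                significant_05=bool(z > _Z975), significant_01=bool(z > _Z995),
            )
        )
    return out
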