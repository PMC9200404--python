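"""Effect-size modelling, noncentral-t power analysis and sample-size solving.

The within-subject effect size for a paired ERP difference is Cohen's
``d_z = mean(diffs) / sd(diffs)``.  Power of the two-tailed one-sample
(paired) t-test is computed exactly from the noncentral t distribution with
noncentrality ``|d_z| * sqrt(n)`` and ``n - 1`` degrees of freedom — no
normal approximation.  A quadratic map from grand-average amplitude to d_z
lets one tabulate the sample size required to detect an SPN of a given
amplitude, and an exact sign-test threshold gives the nonparametric analogue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeModel",
    "PowerQuery",
    "AmplitudeRegression",
    "cohens_dz",
    "fit_effect_model",
    "predict_dz",
    "power_one_sample_t",
    "required_n",
    "binomial_critical_count",
    "power_table",
    "amplitude_regression",
]

_MAX_N = 10**6


def cohens_dz(diffs: Iterable[float]) -> float:
    """Within-subject effect size: mean of paired differences over their SD.

    The SD uses the ``n - 1`` denominator.  Raises on fewer than two
    differences or zero SD.
    """
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero SD of differences: d_z undefined")
    return float(arr.mean() / sd)


@dataclass(frozen=True)
class EffectSizeModel:
    """Quadratic amplitude -> d_z map, ``d = a*x**2 + b*x + c`` (x in µV)."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    coef_se: tuple[float, float, float] | None = None
    x_range: tuple[float, float] | None = None

    def predict(self, amplitude: float) -> float:
        x = float(amplitude)
        return self.a * x * x + self.b * x + self.c


def fit_effect_model(points: Sequence[tuple[float, float]]) -> EffectSizeModel:
    """Ordinary least squares quadratic fit of d_z on amplitude.

    Requires at least 3 points with at least 3 distinct amplitudes (the
    design is rank-deficient otherwise).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (amplitude, d_z) points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct amplitudes for a quadratic fit")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    coef, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient quadratic design")
    fitted = design @ coef
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    dof = pts.shape[0] - 3
    if dof > 0:
        sigma2 = sse / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        ses = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:
        ses = None
    return EffectSizeModel(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        r_squared=float(r2), n_points=int(pts.shape[0]), coef_se=ses,
        x_range=(float(x.min()), float(x.max())),
    )


def predict_dz(model: EffectSizeModel, amplitude: float) -> float:
    """Predicted d_z for a grand-average amplitude in microvolts."""
    return model.predict(amplitude)


@dataclass(frozen=True)
class PowerQuery:
    """Parameters of a one-sample (paired) t-test power question.

    Only the magnitude of ``d`` matters; ``tails`` is 1 or 2 (default
    two-tailed); ``target_power`` is used by the sample-size solver.
    """

    d: float
    n: int | None = None
    alpha: float = 0.05
    tails: int = 2
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")
        if self.n is not None and self.n < 2:
            raise ValueError("n must be >= 2")


def _power(d: float, n: int, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = abs(d) * math.sqrt(n)
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def power_one_sample_t(q: PowerQuery) -> float:
    """Exact power of the one-sample t-test via the noncentral t distribution.

    Noncentrality is ``|d| * sqrt(n)`` with ``n - 1`` degrees of freedom;
    the two-tailed version includes both rejection regions.  For ``d = 0``
    the power equals alpha exactly.
    """
    if q.n is None:
        raise ValueError("power_one_sample_t needs q.n")
    return _power(q.d, q.n, q.alpha, q.tails)


def required_n(q: PowerQuery) -> int:
    """Smallest n in [2, 1e6] whose power reaches ``q.target_power``.

    Power is monotone increasing in n for fixed ``d != 0``; the solver
    brackets by doubling and then scans linearly back to the boundary.
    """
    if q.d == 0.0:
        raise ValueError("d = 0: target power is unreachable")
    lo, hi = 2, 2
    while _power(q.d, hi, q.alpha, q.tails) < q.target_power:
        lo = hi
        hi *= 2
        if hi > _MAX_N:
            raise ValueError(f"required n exceeds {_MAX_N}")
    # power(hi) >= target; scan the bracket for the boundary
    for n in range(lo, hi + 1):
        if _power(q.d, n, q.alpha, q.tails) >= q.target_power:
            return n
    raise AssertionError("unreachable: bracket guaranteed to contain the boundary")


def binomial_critical_count(
    n: int, alpha: float = 0.05, method: str = "double"
) -> int | None:
    """Minimal successes out of *n* for a significant two-tailed sign test.

    With ``method="double"`` (default) the two-tailed p-value doubles the
    upper tail: the smallest k with ``2 * P(X >= k) <= alpha`` for
    ``X ~ Binomial(n, 1/2)``.  ``method="exact"`` instead sums the
    probabilities of all outcomes no more likely than k.  Returns ``None``
    if no k <= n qualifies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for k in range(n + 1):
        if method == "double":
            p = 2.0 * stats.binom.sf(k - 1, n, 0.5)
        elif method == "exact":
            pk = stats.binom.pmf(np.arange(n + 1), n, 0.5)
            p = float(pk[pk <= pk[k] * (1 + 1e-12)].sum())
        else:
            raise ValueError(f"unknown method {method!r}")
        if p <= alpha:
            return k
    return None


def power_table(
    amplitudes: Sequence[float],
    model: EffectSizeModel,
    q: PowerQuery | None = None,
) -> pd.DataFrame:
    """Required sample size per amplitude: predict d_z, then solve for n.

    Returns a DataFrame with columns ``amplitude_uV``, ``predicted_dz`` and
    ``required_n`` (nullable integer; missing where the predicted effect is
    exactly zero and the target power is unreachable).  Warns when asked to
    extrapolate outside the model's fitted amplitude range.
    """
    if q is None:
        q = PowerQuery(d=1.0)
    if model.x_range is not None:
        lo, hi = model.x_range
        outside = [a for a in amplitudes if a < lo or a > hi]
        if outside:
            warnings.warn(
                f"amplitudes {outside} outside the fitted range [{lo:g}, {hi:g}]; "
                "extrapolating", stacklevel=2,
            )
    rows = []
    for amp in amplitudes:
        d = model.predict(amp)
        if d == 0.0:
            rows.append((float(amp), d, pd.NA))
        else:
            qq = PowerQuery(d=d, alpha=q.alpha, tails=q.tails, target_power=q.target_power)
            rows.append((float(amp), d, required_n(qq)))
    return pd.DataFrame(rows, columns=["amplitude_uV", "predicted_dz", "required_n"]).astype(
        {"required_n": "Int64"}
    )


@dataclass(frozen=True)
class AmplitudeRegression:
    """OLS of grand-average amplitude on W-load and task relevance."""

    intercept: float
    coef_w: float
    coef_task: float
    se_intercept: float
    se_w: float
    se_task: float
    r_squared: float
    n: int


def amplitude_regression(
    summaries: Sequence[tuple[float, float, float]] | pd.DataFrame,
) -> AmplitudeRegression:
    """Two-predictor linear regression of SPN amplitude on W-load and Task.

    *summaries* is either a DataFrame with columns ``mean``/``w_load``/
    ``task_relevant`` or a sequence of ``(mean_amplitude, w_load,
    task_relevant)`` tuples, one per experiment.  Both predictors are on a
    0-1 scale.  Raises on fewer than 4 experiments or collinear predictors.
    """
    import statsmodels.api as sm

    if isinstance(summaries, pd.DataFrame):
        frame = summaries[["mean", "w_load", "task_relevant"]].astype(float)
    else:
        frame = pd.DataFrame(
            list(summaries), columns=["mean", "w_load", "task_relevant"], dtype=float
        )
    if len(frame) < 4:
        raise ValueError("need >= 4 experiments for the amplitude regression")
    design = sm.add_constant(frame[["w_load", "task_relevant"]], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < 3:
        raise ValueError("collinear predictors: amplitude regression is rank-deficient")
    fit = sm.OLS(frame["mean"], design).fit()
    params = fit.params
    bse = fit.bse
    return AmplitudeRegression(
        intercept=float(params["const"]),
        coef_w=float(params["w_load"]),
        coef_task=float(params["task_relevant"]),
        se_intercept=float(bse["const"]),
        se_w=float(bse["w_load"]),
        se_task=float(bse["task_relevant"]),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
    )
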