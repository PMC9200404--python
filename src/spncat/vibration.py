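"""Vibration-of-effects analysis over alternative electrode clusters.

Recomputes every experiment's SPN with a fixed menu of a priori bilateral
posterior clusters, counts how often each cluster yields a significant
effect, tests homogeneity of those counts with a Pearson chi-square, and
correlates per-experiment amplitudes across clusters.  Also provides the
one-way repeated-measures ANOVA (with post-hoc observed power) used to
assess SPN modulation effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import Catalogue, CatalogueError
from .extraction import SpnSummary, spn_summary

__all__ = [
    "DEFAULT_CLUSTERS",
    "VibrationReport",
    "ChiSquareResult",
    "RmAnovaResult",
    "recompute_clusters",
    "chi_square_independence",
    "cross_cluster_correlation",
    "rm_anova_oneway",
]

#: The three a priori bilateral posterior clusters; "Original" (each
#: experiment's own cluster) is added per catalogue at recompute time.
DEFAULT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "Cluster1": ("PO7", "O1", "O2", "PO8"),
    "Cluster2": ("PO7", "PO8"),
    "Cluster3": ("P1", "P3", "P5", "P7", "P9", "PO7", "PO3", "O1",
                 "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2"),
}


@dataclass(frozen=True)
class VibrationReport:
    """Per-cluster SPN summaries for every experiment, plus counts.

    ``summaries[cluster]`` lists one :class:`SpnSummary` per experiment in
    catalogue order; ``significance_counts`` counts two-tailed p < alpha;
    ``correlation_matrix`` holds Pearson r between the per-experiment mean
    amplitude vectors of each cluster pair.
    """

    clusters: dict[str, tuple[str, ...] | None]  # None marks "Original"
    experiment_ids: tuple[str, ...]
    summaries: dict[str, tuple[SpnSummary, ...]]
    alpha: float
    window: tuple[float, float]

    @property
    def significance_counts(self) -> dict[str, int]:
        return {
            name: sum(s.p_two_tailed < self.alpha for s in rows)
            for name, rows in self.summaries.items()
        }

    def amplitudes(self) -> pd.DataFrame:
        """Per-experiment mean amplitude, one column per cluster."""
        return pd.DataFrame(
            {name: [s.mean for s in rows] for name, rows in self.summaries.items()},
            index=list(self.experiment_ids),
        )

    @property
    def correlation_matrix(self) -> pd.DataFrame:
        return cross_cluster_correlation(self)


def recompute_clusters(
    catalogue: Catalogue,
    clusters: Mapping[str, Sequence[str]] | None = None,
    window: tuple[float, float] = (300.0, 1000.0),
    alpha: float = 0.05,
    include_original: bool = True,
) -> VibrationReport:
    """Recompute every experiment's SPN under each named electrode cluster.

    All clusters share *window*; the "Original" pseudo-cluster uses each
    experiment's own recorded cluster and window.  Raises on any cluster
    electrode absent from the montage, naming cluster and label.
    """
    if clusters is None:
        clusters = DEFAULT_CLUSTERS
    montage = catalogue.montage
    for name, labels in clusters.items():
        unknown = set(labels) - set(montage.labels)
        if unknown:
            raise CatalogueError(
                f"cluster {name!r}: electrode(s) {sorted(unknown)} not in montage"
            )
    named: dict[str, tuple[str, ...] | None] = {}
    if include_original:
        named["Original"] = None
    named.update({name: tuple(labels) for name, labels in clusters.items()})
    summaries: dict[str, tuple[SpnSummary, ...]] = {}
    for name, labels in named.items():
        rows = []
        for exp in catalogue.experiments:
            if labels is None:
                rows.append(spn_summary(exp, exp.original_cluster, exp.original_window, montage))
            else:
                rows.append(spn_summary(exp, labels, window, montage))
        summaries[name] = tuple(rows)
    return VibrationReport(
        clusters=named,
        experiment_ids=tuple(exp.id for exp in catalogue.experiments),
        summaries=summaries,
        alpha=alpha,
        window=window,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chi_square_independence(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; ``df = (r - 1)(c - 1)``.  Degenerate tables
    (fewer than 2 rows/columns, negative counts, or an all-zero row or
    column) are rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError("table has an all-zero row or column")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def cross_cluster_correlation(report: VibrationReport) -> pd.DataFrame:
    """Pairwise Pearson r between per-experiment amplitudes of each cluster."""
    amp = report.amplitudes()
    if len(amp) < 3:
        raise ValueError("need >= 3 experiments for cross-cluster correlations")
    if np.any(amp.std(ddof=1) == 0):
        zero = list(amp.columns[amp.std(ddof=1) == 0])
        raise ValueError(f"zero-variance amplitude vector(s): {zero}")
    names = list(amp.columns)
    mat = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = stats.pearsonr(amp[names[i]], amp[names[j]]).statistic
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA with post-hoc observed power."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    observed_power: float


def rm_anova_oneway(amplitudes: Sequence[Sequence[float]], alpha: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions matrix.

    Classic sums-of-squares decomposition with participant blocking and no
    sphericity correction.  Observed (post-hoc) power follows the
    noncentral-F convention ``ncp = F * df1`` at the given alpha — a
    descriptive quantity, reported because it is what common statistical
    packages print, not an inferential one.

    With two conditions, F equals the squared paired t statistic.
    """
    mat = np.asarray(amplitudes, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need a complete participants x conditions matrix, >= 2 each")
    if not np.all(np.isfinite(mat)):
        raise ValueError("incomplete matrix: non-finite entries")
    n, c = mat.shape
    grand = mat.mean()
    ss_subj = c * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df1 = c - 1
    df2 = (n - 1) * (c - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0.0:
        if np.isclose(ss_cond, 0.0):
            # no condition effect and no residual variation: F degenerates to 0
            return RmAnovaResult(F=0.0, df1=int(df1), df2=int(df2), p=1.0,
                                 partial_eta_sq=0.0, observed_power=alpha)
        raise ValueError("zero error variance: ANOVA undefined")
    f = float(ms_cond / ms_err)
    p = float(stats.f.sf(f, df1, df2))
    peta = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    power = float(stats.ncf.sf(fcrit, df1, df2, f * df1))
    return RmAnovaResult(
        F=f, df1=int(df1), df2=int(df2), p=p,
        partial_eta_sq=peta, observed_power=power,
    )
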