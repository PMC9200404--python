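"""Spatio-temporal cluster-based permutation test over electrode x time.

A from-scratch implementation of the mass-univariate cluster permutation
test for paired (one-sample) ERP difference data: pointwise one-sample t
statistics at every (electrode, sample); supra-threshold points grouped
into connected components under the combined relation

    (e1, s1) ~ (e2, s2)  iff  (e1 == e2 and |s1 - s2| == 1)
                          or  (s1 == s2 and e1 adjacent e2 in the montage);

cluster statistic = sum of member t values ("cluster mass"); the null
distribution of the maximum |mass| is built from random per-participant
sign flips, separately for negative and positive clusters, and each
observed cluster receives ``p = (1 + #{null >= |mass|}) / (n_perm + 1)``.

The SPN analysis uses the negative side (regular more negative than
random); the positive side is computed from the same permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .catalogue import CatalogueError, ErpEpoch, Experiment
from .extraction import SpnSummary, spn_summary
from .montage import Montage

__all__ = [
    "SpatioTemporalCluster",
    "ClusterTestResult",
    "cluster_permutation_test",
    "most_significant_negative_cluster",
    "electrode_occurrence",
    "cluster_window_spn",
]


@dataclass(frozen=True)
class SpatioTemporalCluster:
    """A connected set of (electrode label, sample index) points.

    ``mass`` is the sum of pointwise t statistics over the members (all of
    one sign); ``p`` the permutation p-value of |mass| against the null
    maximum of the matching sign.
    """

    members: frozenset[tuple[str, int]]
    mass: float
    sign: str  # "negative" | "positive"
    p: float

    @property
    def electrodes(self) -> frozenset[str]:
        return frozenset(e for e, _ in self.members)

    @property
    def sample_range(self) -> tuple[int, int]:
        """Half-open [min member sample, max member sample + 1)."""
        samples = [s for _, s in self.members]
        return min(samples), max(samples) + 1

    @property
    def onset_sample(self) -> int:
        return min(s for _, s in self.members)


@dataclass(frozen=True)
class ClusterTestResult:
    clusters: tuple[SpatioTemporalCluster, ...]
    cluster_alpha: float
    n_permutations: int
    seed: int | None
    null_distribution_summary: dict[str, dict[str, float]]

    def negative_clusters(self) -> list[SpatioTemporalCluster]:
        return [c for c in self.clusters if c.sign == "negative"]

    def positive_clusters(self) -> list[SpatioTemporalCluster]:
        return [c for c in self.clusters if c.sign == "positive"]


def _grid_edges(adjacency: np.ndarray, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Edge list over flattened (electrode, sample) nodes ``e * S + s``."""
    n_elec = adjacency.shape[0]
    s = n_samples
    # temporal edges: (e, t) -- (e, t+1)
    base = np.arange(n_elec)[:, None] * s + np.arange(s - 1)[None, :]
    u_t = base.ravel()
    v_t = u_t + 1
    # spatial edges at each sample
    ai, aj = np.nonzero(np.triu(adjacency, k=1))
    u_s = (ai[:, None] * s + np.arange(s)[None, :]).ravel()
    v_s = (aj[:, None] * s + np.arange(s)[None, :]).ravel()
    return np.concatenate([u_t, u_s]), np.concatenate([v_t, v_s])


class _ClusterFinder:
    """Reusable connected-component machinery for one grid geometry."""

    def __init__(self, adjacency: np.ndarray, n_samples: int):
        self.n_elec = adjacency.shape[0]
        self.n_samples = n_samples
        self.n_nodes = self.n_elec * n_samples
        self.u, self.v = _grid_edges(adjacency, n_samples)

    def component_masses(self, mask: np.ndarray, t_flat: np.ndarray) -> np.ndarray:
        """Masses of the connected components of the masked subgraph."""
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return np.empty(0)
        keep = mask[self.u] & mask[self.v]
        # relabel nodes to the compact masked index space
        pos = np.full(self.n_nodes, -1, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        m = idx.size
        graph = sparse.csr_matrix(
            (np.ones(keep.sum(), dtype=np.int8), (pos[self.u[keep]], pos[self.v[keep]])),
            shape=(m, m),
        )
        _, labels = connected_components(graph, directed=False)
        return np.bincount(labels, weights=t_flat[idx])

    def components(self, mask: np.ndarray, t_flat: np.ndarray) -> list[tuple[np.ndarray, float]]:
        """(member node ids, mass) per connected component of the mask."""
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return []
        keep = mask[self.u] & mask[self.v]
        pos = np.full(self.n_nodes, -1, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        m = idx.size
        graph = sparse.csr_matrix(
            (np.ones(keep.sum(), dtype=np.int8), (pos[self.u[keep]], pos[self.v[keep]])),
            shape=(m, m),
        )
        n_comp, labels = connected_components(graph, directed=False)
        masses = np.bincount(labels, weights=t_flat[idx], minlength=n_comp)
        order = np.argsort(labels, kind="stable")
        bounds = np.searchsorted(labels[order], np.arange(n_comp))
        out = []
        for c in range(n_comp):
            lo = bounds[c]
            hi = bounds[c + 1] if c + 1 < n_comp else idx.size
            out.append((idx[order[lo:hi]], float(masses[c])))
        return out


def _t_field(signed: np.ndarray, sum_sq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t at every node from sign-flipped sums.

    ``signed`` is the per-node sum of (sign * value) over participants;
    ``sum_sq`` the per-node sum of squares (invariant under sign flips).
    """
    mean = signed / n
    var = (sum_sq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def cluster_permutation_test(
    diff_epochs: Sequence[ErpEpoch],
    montage: Montage,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
    sides: str = "both",
) -> ClusterTestResult:
    """Cluster-based permutation test on per-participant difference epochs.

    Parameters
    ----------
    diff_epochs
        One regular-minus-random difference :class:`ErpEpoch` per
        participant; all must share sampling rate, epoch start and shape,
        with electrode rows in montage order.
    montage
        Supplies the spatial adjacency half of cluster connectivity.
    cluster_alpha
        Forming threshold: points with ``|t| >= t_crit(two-tailed
        cluster_alpha, df = n - 1)`` enter clusters.
    n_permutations
        Random per-participant sign-flip permutations for the max-|mass|
        null distributions.
    seed
        Seeds the permutation generator; identical seeds give identical
        clusters, masses and p-values.
    sides
        ``"both"`` (default) tests negative and positive clusters;
        ``"negative"`` skips the positive null (the SPN analysis only uses
        the negative side).
    """
    n = len(diff_epochs)
    if n < 2:
        raise CatalogueError("cluster permutation test needs >= 2 participants")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if sides not in ("both", "negative"):
        raise ValueError("sides must be 'both' or 'negative'")
    first = diff_epochs[0]
    for ep in diff_epochs:
        if (ep.data.shape != first.data.shape
                or ep.sampling_rate != first.sampling_rate
                or ep.epoch_start != first.epoch_start):
            raise CatalogueError("misaligned epochs: shapes/rates/starts differ")
    if first.n_electrodes != len(montage):
        raise CatalogueError(
            f"epochs have {first.n_electrodes} electrodes, montage has {len(montage)}"
        )
    n_elec, n_samp = first.data.shape
    data = np.stack([ep.data for ep in diff_epochs]).reshape(n, -1)  # (n, nodes)
    sum_sq = (data**2).sum(axis=0)
    tcrit = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    finder = _ClusterFinder(montage.adjacency_matrix(), n_samp)

    t_obs = _t_field(data.sum(axis=0), sum_sq, n)
    obs_neg = finder.components(t_obs <= -tcrit, t_obs)
    obs_pos = finder.components(t_obs >= tcrit, t_obs) if sides == "both" else []

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_permutations, n))
    null_neg = np.zeros(n_permutations)
    null_pos = np.zeros(n_permutations)
    for k in range(n_permutations):
        t_p = _t_field(signs[k] @ data, sum_sq, n)
        masses = finder.component_masses(t_p <= -tcrit, t_p)
        if masses.size:
            null_neg[k] = -masses.min()
        if sides == "both":
            masses = finder.component_masses(t_p >= tcrit, t_p)
            if masses.size:
                null_pos[k] = masses.max()

    def _p(null: np.ndarray, mass: float) -> float:
        return float((1 + int((null >= abs(mass) - 1e-12).sum())) / (n_permutations + 1))

    labels = montage.labels
    clusters = []
    for nodes, mass in obs_neg:
        members = frozenset((labels[i // n_samp], int(i % n_samp)) for i in nodes)
        clusters.append(
            SpatioTemporalCluster(members, mass, "negative", _p(null_neg, mass))
        )
    for nodes, mass in obs_pos:
        members = frozenset((labels[i // n_samp], int(i % n_samp)) for i in nodes)
        clusters.append(
            SpatioTemporalCluster(members, mass, "positive", _p(null_pos, mass))
        )

    def _summary(null: np.ndarray) -> dict[str, float]:
        qs = np.quantile(null, [0.5, 0.9, 0.95, 0.99]) if null.size else [0.0] * 4
        return {"q50": float(qs[0]), "q90": float(qs[1]),
                "q95": float(qs[2]), "q99": float(qs[3]),
                "max": float(null.max()) if null.size else 0.0}

    summary = {"negative": _summary(null_neg)}
    if sides == "both":
        summary["positive"] = _summary(null_pos)
    return ClusterTestResult(
        clusters=tuple(clusters),
        cluster_alpha=cluster_alpha,
        n_permutations=n_permutations,
        seed=seed,
        null_distribution_summary=summary,
    )


def most_significant_negative_cluster(
    result: ClusterTestResult, alpha: float = 0.05
) -> SpatioTemporalCluster | None:
    """The significant negative cluster with the largest |mass|, if any.

    Ties on |mass| break by earliest onset sample, then by lexicographic
    order of the sorted electrode labels.
    """
    candidates = [c for c in result.negative_clusters() if c.p < alpha]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (-abs(c.mass), c.onset_sample, tuple(sorted(c.electrodes))),
    )


def electrode_occurrence(
    clusters: Iterable[SpatioTemporalCluster | None],
    montage: Montage,
) -> dict[str, float]:
    """Per-electrode proportion of clusters the electrode appears in.

    ``None`` entries (experiments without a significant negative cluster)
    are excluded from the denominator.  Raises if every entry is ``None``.
    Display-level masking of rare electrodes (< 10%) is left to callers.
    """
    present = [c for c in clusters if c is not None]
    if not present:
        raise ValueError("no clusters to summarise (all entries are None)")
    counts = {lab: 0 for lab in montage.labels}
    for c in present:
        for lab in c.electrodes:
            counts[lab] += 1
    return {lab: counts[lab] / len(present) for lab in montage.labels}


def cluster_window_spn(
    exp: Experiment, cluster: SpatioTemporalCluster, montage: Montage
) -> SpnSummary:
    """Recompute an experiment's SPN from a data-driven cluster.

    Electrodes are the cluster's member electrodes; the window is the
    half-open sample span [min member sample, max member sample + 1)
    converted to ms at the experiment's sampling rate.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    lo, hi = cluster.sample_range
    step = 1000.0 / exp.sampling_rate
    window = (exp.epoch_start + lo * step, exp.epoch_start + hi * step)
    electrodes = tuple(sorted(cluster.electrodes))
    return spn_summary(exp, electrodes, window, montage)
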