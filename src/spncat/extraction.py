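"""Windowed amplitude extraction and per-experiment SPN summary statistics.

The SPN (sustained posterior negativity) is a difference wave: amplitude in
the regular (symmetric) condition minus amplitude in the random condition,
averaged over a posterior electrode cluster and a time window (typically
PO7/O1/O2/PO8 and 300-1000 ms).  A negative value is an SPN.

Time windows are half-open ``[start_ms, end_ms)`` and map to sample indices
as ``ceil((t - epoch_start) * rate / 1000)`` at both ends, which makes the
mapping idempotent under window concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .catalogue import CatalogueError, ErpEpoch, Experiment
from .montage import Montage

__all__ = [
    "SpnSummary",
    "sample_range",
    "window_mean",
    "spn_summary",
    "grand_average",
    "component_amplitude",
]


def sample_range(
    window: tuple[float, float], epoch_start: float, sampling_rate: float,
    n_samples: int,
) -> tuple[int, int]:
    """Half-open sample index range for a half-open ms window.

    Both endpoints map through ``ceil((t - epoch_start) * rate / 1000)``;
    a tiny tolerance absorbs float fuzz for windows that land exactly on a
    sample.  Raises :class:`CatalogueError` if the window leaves the epoch.
    """
    lo, hi = window
    if not lo < hi:
        raise CatalogueError(f"window start must precede end, got {window}")
    start = math.ceil((lo - epoch_start) * sampling_rate / 1000.0 - 1e-9)
    end = math.ceil((hi - epoch_start) * sampling_rate / 1000.0 - 1e-9)
    if start < 0 or end > n_samples:
        raise CatalogueError(
            f"window {window} ms outside epoch starting {epoch_start} ms "
            f"with {n_samples} samples at {sampling_rate} Hz"
        )
    if start >= end:
        raise CatalogueError(f"window {window} ms contains no samples")
    return start, end


def _cluster_rows(montage: Montage, electrodes: Sequence[str]) -> np.ndarray:
    if len(electrodes) == 0:
        raise CatalogueError("electrode cluster must be non-empty")
    return montage.indices(electrodes)


def window_mean(
    erp: ErpEpoch, electrodes: Sequence[str], window: tuple[float, float],
    montage: Montage,
) -> float:
    """Mean amplitude (microvolts) over an electrode cluster and time window.

    Plain arithmetic mean over the electrode subset and the half-open sample
    range; the cluster is averaged with equal electrode weights.
    """
    rows = _cluster_rows(montage, electrodes)
    start, end = sample_range(window, erp.epoch_start, erp.sampling_rate, erp.n_samples)
    return float(erp.data[np.ix_(rows, np.arange(start, end))].mean())


@dataclass(frozen=True)
class SpnSummary:
    """Per-experiment paired difference statistics for one cluster/window.

    ``diffs`` holds per-participant regular-minus-random amplitudes (µV);
    ``d_z`` is the within-subject effect size mean/SD; ``prop_directional``
    is the fraction of participants with a negative difference (ties count
    as non-directional).
    """

    experiment_id: str
    cluster: tuple[str, ...]
    window: tuple[float, float]
    n: int
    diffs: tuple[float, ...]
    mean: float
    sd: float
    se: float
    d_z: float
    t: float
    df: int
    p_two_tailed: float
    prop_directional: float

    @classmethod
    def from_diffs(
        cls,
        diffs: Iterable[float],
        *,
        experiment_id: str = "",
        cluster: Sequence[str] = (),
        window: tuple[float, float] = (float("nan"), float("nan")),
    ) -> "SpnSummary":
        arr = np.asarray(list(diffs), dtype=float)
        n = arr.size
        if n < 2:
            raise CatalogueError("need n >= 2 paired differences")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        if sd == 0.0:
            raise CatalogueError("degenerate sample: zero SD of differences")
        se = sd / math.sqrt(n)
        t = mean / se
        df = n - 1
        p = float(2.0 * stats.t.sf(abs(t), df))
        prop = float(np.mean(arr < 0.0))
        return cls(
            experiment_id=experiment_id,
            cluster=tuple(cluster),
            window=(float(window[0]), float(window[1])),
            n=n,
            diffs=tuple(float(x) for x in arr),
            mean=mean,
            sd=sd,
            se=se,
            d_z=mean / sd,
            t=t,
            df=df,
            p_two_tailed=p,
            prop_directional=prop,
        )

    @property
    def significant(self) -> bool:
        """Two-tailed significance at the conventional 0.05 level."""
        return self.p_two_tailed < 0.05


def spn_summary(
    exp: Experiment,
    cluster: Sequence[str],
    window: tuple[float, float],
    montage: Montage,
) -> SpnSummary:
    """Paired SPN statistics for *exp* at a given cluster and window.

    ``diffs[i] = window_mean(regular_i) - window_mean(random_i)`` with the
    experiment's designated contrast pair; one-sample two-tailed t-test of
    the differences against zero.
    """
    regular, random_ = exp.contrast
    diffs = [
        window_mean(exp.participants[pid][regular], cluster, window, montage)
        - window_mean(exp.participants[pid][random_], cluster, window, montage)
        for pid in exp.participants
    ]
    return SpnSummary.from_diffs(
        diffs, experiment_id=exp.id, cluster=cluster, window=window
    )


def grand_average(exp: Experiment, condition: str) -> ErpEpoch:
    """Pointwise mean epoch across participants for one condition."""
    epochs = exp.epochs(condition)
    first = epochs[0]
    for ep in epochs[1:]:
        if ep.data.shape != first.data.shape:
            raise CatalogueError(
                f"experiment {exp.id!r}: inconsistent epoch shapes in {condition!r}"
            )
    data = np.mean([ep.data for ep in epochs], axis=0)
    return ErpEpoch(
        participant_id="grand_average",
        condition=condition,
        data=data,
        sampling_rate=first.sampling_rate,
        epoch_start=first.epoch_start,
    )


def component_amplitude(
    erp: ErpEpoch,
    electrodes: Sequence[str],
    window: tuple[float, float],
    montage: Montage,
    mode: Literal["peak", "trough"] = "peak",
) -> float:
    """Peak (max) or trough (min) of the cluster-averaged wave in a window.

    Used for the transient P1 / N1 components; the extremum is taken on the
    cluster-averaged waveform, the standard ERP convention.
    """
    rows = _cluster_rows(montage, electrodes)
    start, end = sample_range(window, erp.epoch_start, erp.sampling_rate, erp.n_samples)
    wave = erp.data[rows, start:end].mean(axis=0)
    if mode == "peak":
        return float(wave.max())
    if mode == "trough":
        return float(wave.min())
    raise ValueError(f"mode must be 'peak' or 'trough', got {mode!r}")
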