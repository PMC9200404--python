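"""Seeded synthetic ERP catalogue generator.

Emulates stage-v data (trial-averaged condition epochs per participant) with
the statistical structure the downstream analyses assume:

* 64-channel posterior-weighted topography peaking at PO7/O1/O2/PO8;
* P1 / N1 transients (Gaussian bumps) shared by both conditions;
* a sustained regular-minus-random negativity: a raised-cosine-edged plateau
  whose cluster/window mean equals the requested true amplitude exactly in
  the noise-free limit;
* between-participant amplitude variability and condition-average
  measurement noise scaling as ``noise_sd / sqrt(n_trials)``;
* experiment-level true amplitudes following the two-predictor regression
  ``amp = intercept + coef_w * W + coef_task * Task`` plus a residual, with
  a publication rule that favours stronger (more negative) responses.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
children, so per-experiment streams are stable under subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .catalogue import Catalogue, CatalogueError, ErpEpoch, Experiment
from .extraction import sample_range
from .montage import Montage, build_montage

__all__ = ["SynthConfig", "synthesize_pair", "generate_experiment", "generate_catalogue"]

_SPN_SEED_ELECTRODES = ("PO7", "O1", "O2", "PO8")


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the catalogue-like conditions.

    ``amplitude_model`` is (intercept, coef_w, coef_task) in microvolts;
    ``amplitude_resid_sd`` is the experiment-level residual SD around that
    regression (0.75 µV puts the explained variance near the one-third level
    typical of grand-average SPN amplitude).  ``between_sd`` is the
    between-participant SD of true amplitudes; ``noise_sd`` the per-sample
    trial-level noise SD, reduced by ``sqrt(n_trials)`` at the condition
    average.  ``heteroscedasticity`` scales ``between_sd`` by
    ``1 + h * |true amplitude|``; off by default.
    """

    seed: int
    n_experiments: int = 40
    n_range: tuple[int, int] = (12, 48)
    amplitude_model: tuple[float, float, float] = (0.071, -1.669, -0.416)
    amplitude_resid_sd: float = 0.75
    between_sd: float = 1.6
    noise_sd: float = 1.0
    n_trials: int = 60
    ar1: float = 0.0
    heteroscedasticity: float = 0.0
    # waveform: (latency_ms, width_ms, amplitude_uV)
    p1: tuple[float, float, float] = (110.0, 25.0, 5.0)
    n1: tuple[float, float, float] = (170.0, 25.0, -8.0)
    spn_onset_ms: float = 250.0
    spn_offset_ms: float = 1000.0
    spn_edge_ms: float = 50.0
    # the cluster/window against which injected amplitudes are calibrated
    calib_cluster: tuple[str, ...] = _SPN_SEED_ELECTRODES
    calib_window: tuple[float, float] = (300.0, 1000.0)
    topo_sigma: float = 0.5  # radians of great-circle falloff
    topography: Mapping[str, float] | None = None  # explicit per-electrode weights
    task_relevance_p: float = 0.5
    published_rule: tuple = ("logistic", -0.95, 2.0)
    epoch_start: float = -200.0
    epoch_end: float = 2000.0
    sampling_rate: float = 128.0

    def __post_init__(self) -> None:
        lo, hi = self.n_range
        if not (2 <= lo <= hi <= 10000):
            raise ValueError("n_range must satisfy 2 <= min <= max <= 10000")
        for name in ("amplitude_resid_sd", "between_sd", "noise_sd", "topo_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.spn_onset_ms < self.spn_offset_ms:
            raise ValueError("spn_onset_ms must precede spn_offset_ms")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.task_relevance_p <= 1:
            raise ValueError("task_relevance_p must be in [0, 1]")
        if self.topography is not None:
            bad = [l for l, w in self.topography.items() if not 0 <= w <= 1]
            if bad:
                raise ValueError(f"topography weights outside [0, 1]: {bad}")
        if self.seed is None:
            raise ValueError("seed is required")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_end - self.epoch_start)
                         * self.sampling_rate / 1000.0))

    def times(self) -> np.ndarray:
        return self.epoch_start + np.arange(self.n_samples) * 1000.0 / self.sampling_rate


def _topography(config: SynthConfig, montage: Montage) -> np.ndarray:
    """Per-electrode weight in [0, 1], maximal (=1) at the SPN seed cluster."""
    if config.topography is not None:
        missing = set(montage.labels) - set(config.topography)
        if missing:
            raise ValueError(f"explicit topography missing labels {sorted(missing)}")
        return np.array([config.topography[lab] for lab in montage.labels], float)
    seeds = [s for s in _SPN_SEED_ELECTRODES if s in montage]
    if not seeds:
        raise ValueError("montage lacks all SPN seed electrodes (PO7/O1/O2/PO8)")
    seed_pos = montage.positions[montage.indices(seeds)]
    cos = np.clip(montage.positions @ seed_pos.T, -1.0, 1.0)
    dist = np.arccos(cos)  # (n_elec, n_seeds) great-circle distances
    w = np.exp(-0.5 * (dist / config.topo_sigma) ** 2).max(axis=1)
    return w


def _gaussian_bump(times: np.ndarray, latency: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((times - latency) / width) ** 2)


def _plateau(times: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Raised-cosine-edged unit plateau over [onset, offset] ms.

    Rises over ``spn_edge_ms`` before the onset and falls over the same span
    after the offset, so the plateau is exactly 1 inside [onset, offset] and
    exactly 0 outside the edges (compact support; zero in the baseline).
    """
    on, off, edge = config.spn_onset_ms, config.spn_offset_ms, config.spn_edge_ms
    y = np.zeros_like(times)
    if edge > 0:
        rise = (times >= on - edge) & (times < on)
        y[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - (on - edge)) / edge))
        fall = (times > off) & (times <= off + edge)
        y[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - off) / edge))
    y[(times >= on) & (times <= off)] = 1.0
    return y


def _signal_fields(config: SynthConfig, montage: Montage) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared transients, unit SPN field, and its calibrated window gain."""
    times = config.times()
    topo = _topography(config, montage)
    transients = _gaussian_bump(times, *config.p1) + _gaussian_bump(times, *config.n1)
    base = topo[:, None] * transients[None, :]
    spn_field = topo[:, None] * _plateau(times, config)[None, :]
    if not (config.epoch_start <= config.spn_onset_ms - config.spn_edge_ms
            and config.spn_offset_ms + config.spn_edge_ms <= config.epoch_end):
        raise CatalogueError("SPN plateau (with edges) extends outside the epoch")
    rows = montage.indices(config.calib_cluster)
    start, end = sample_range(
        config.calib_window, config.epoch_start, config.sampling_rate, config.n_samples
    )
    gain = float(spn_field[np.ix_(rows, np.arange(start, end))].mean())
    if gain <= 0:
        raise CatalogueError("SPN plateau does not overlap the calibration window")
    return base, spn_field, gain


def _noise(config: SynthConfig, rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    sd = config.noise_sd / np.sqrt(config.n_trials)
    eps = rng.normal(0.0, 1.0, size=shape)
    if config.ar1:
        phi = config.ar1
        out = np.empty_like(eps)
        out[:, 0] = eps[:, 0]
        for s in range(1, shape[1]):
            out[:, s] = phi * out[:, s - 1] + np.sqrt(1 - phi**2) * eps[:, s]
        eps = out
    return sd * eps


def _baseline_correct(data: np.ndarray, config: SynthConfig) -> np.ndarray:
    n0 = sample_range(
        (config.epoch_start, 0.0), config.epoch_start, config.sampling_rate,
        config.n_samples,
    )
    base = data[:, n0[0]:n0[1]].mean(axis=1, keepdims=True)
    return data - base


def synthesize_pair(
    true_spn: float,
    config: SynthConfig,
    rng: np.random.Generator,
    montage: Montage,
    participant_id: str = "p0",
    conditions: tuple[str, str] = ("regular", "random"),
    _fields: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> tuple[ErpEpoch, ErpEpoch]:
    """One participant's (regular, random) condition-average pair.

    With ``noise_sd = 0`` the cluster/window mean of regular minus random at
    the calibration cluster and window equals *true_spn* exactly: the unit
    SPN field is rescaled by the reciprocal of its own windowed mean.  Both
    epochs are baseline corrected over [epoch_start, 0) ms, mirroring the
    stage-v convention.
    """
    if not np.isfinite(true_spn):
        raise ValueError("true_spn must be finite")
    base, spn_field, gain = _fields if _fields is not None else _signal_fields(config, montage)
    shape = base.shape
    regular = base + (true_spn / gain) * spn_field + _noise(config, rng, shape)
    random_ = base + _noise(config, rng, shape)
    regular = _baseline_correct(regular, config)
    random_ = _baseline_correct(random_, config)
    mk = lambda cond, data: ErpEpoch(
        participant_id, cond, data,
        sampling_rate=config.sampling_rate, epoch_start=config.epoch_start,
    )
    return mk(conditions[0], regular), mk(conditions[1], random_)


def generate_experiment(
    truth: Mapping,
    config: SynthConfig,
    seed: int | np.random.SeedSequence,
    montage: Montage | None = None,
) -> Experiment:
    """Generate one experiment from a truth record.

    *truth* carries ``n``, ``w_load``, ``task_relevant`` and optionally
    ``true_amp`` (otherwise derived from ``config.amplitude_model``); other
    recognised keys: ``id``, ``project``, ``published``.  Per-participant
    true amplitudes are drawn
    ``Normal(true_amp, between_sd * (1 + heteroscedasticity * |true_amp|))``.
    """
    if montage is None:
        montage = build_montage("biosemi64")
    n = int(truth["n"])
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    w = float(truth["w_load"])
    task = int(truth["task_relevant"])
    if "true_amp" in truth and truth["true_amp"] is not None:
        true_amp = float(truth["true_amp"])
    else:
        a0, aw, at = config.amplitude_model
        true_amp = a0 + aw * w + at * task
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    sd_i = config.between_sd * (1.0 + config.heteroscedasticity * abs(true_amp))
    participant_amps = rng.normal(true_amp, sd_i, size=n)
    fields = _signal_fields(config, montage)
    participants: dict[str, dict[str, ErpEpoch]] = {}
    for i, amp in enumerate(participant_amps):
        pid = f"p{i:03d}"
        reg, rnd = synthesize_pair(
            float(amp), config, rng, montage, participant_id=pid, _fields=fields
        )
        participants[pid] = {"regular": reg, "random": rnd}
    return Experiment(
        id=str(truth.get("id", "exp000")),
        project=str(truth.get("project", "synthetic")),
        conditions=("regular", "random"),
        contrast=("regular", "random"),
        participants=participants,
        w_load=w,
        task_relevant=task,
        published=bool(truth.get("published", False)),
        original_cluster=config.calib_cluster,
        original_window=config.calib_window,
        sampling_rate=config.sampling_rate,
        epoch_start=config.epoch_start,
    )


def _published_probability(rule: tuple, true_amp: float) -> float:
    kind = rule[0]
    if kind == "constant":
        return float(rule[1])
    if kind == "logistic":
        _, center, slope = rule
        return float(1.0 / (1.0 + np.exp(slope * (true_amp - center))))
    raise ValueError(f"unknown published_rule {rule!r}")


def generate_catalogue(config: SynthConfig, montage: Montage | None = None) -> Catalogue:
    """Generate a full synthetic catalogue from *config*.

    Experiment truths (W-load, task relevance, n, true amplitude, published
    flag) are drawn from the root seed; each experiment then gets its own
    deterministic child seed, so regenerating a subset reproduces the same
    experiments.  The truth record for every experiment is stored in the
    catalogue provenance so tests can recover it.
    """
    if montage is None:
        montage = build_montage("biosemi64")
    root = np.random.SeedSequence(config.seed)
    truth_ss, *children = root.spawn(config.n_experiments + 1)
    rng = np.random.default_rng(truth_ss)
    a0, aw, at = config.amplitude_model
    lo, hi = config.n_range
    truths = []
    for k in range(config.n_experiments):
        w = float(rng.uniform(0.0, 1.0))
        task = int(rng.random() < config.task_relevance_p)
        n = int(rng.integers(lo, hi + 1))
        true_amp = a0 + aw * w + at * task
        if config.amplitude_resid_sd > 0:
            true_amp += float(rng.normal(0.0, config.amplitude_resid_sd))
        published = bool(rng.random() < _published_probability(config.published_rule, true_amp))
        truths.append(
            dict(id=f"exp{k:03d}", project=f"proj{k // 5:02d}", n=n, w_load=w,
                 task_relevant=task, true_amp=true_amp, published=published)
        )
    experiments = [
        generate_experiment(truth, config, child, montage)
        for truth, child in zip(truths, children)
    ]
    import json

    provenance = json.dumps(
        {"generator": "spncat.simulate", "seed": config.seed, "truths": truths}
    )
    return Catalogue(montage, experiments, provenance=provenance)
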