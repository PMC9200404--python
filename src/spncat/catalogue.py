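"""Hierarchical data model for an ERP condition-average catalogue.

The catalogue operates at the stage of per-participant, per-condition
trial-averaged epochs (microvolts), the common starting point for ERP
meta-analysis.  On disk a catalogue is a plain directory of JSON metadata
and per-condition TSV waveform tables, so fixtures are diffable and the
format is language-agnostic:

.. code-block:: text

    catalogue.json                  montage file name, ordered experiment ids
    montage.json                    labels, positions, neighbour pairs
    experiments/<id>/meta.json      n, conditions, contrast, w_load, ...
    experiments/<id>/participants/<pid>/<condition>.tsv

Waveform TSVs carry a ``time_ms`` column followed by one column per
electrode in montage order, one row per sample, values in microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import Montage, build_montage

__all__ = [
    "ErpEpoch",
    "Experiment",
    "Catalogue",
    "CatalogueError",
    "load_catalogue",
    "save_catalogue",
]

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


class CatalogueError(ValueError):
    """Structured catalogue validation / IO error."""


@dataclass
class ErpEpoch:
    """One participant x condition trial-averaged epoch.

    ``data`` has shape ``(n_electrodes, n_samples)`` in microvolts, electrode
    rows in montage order.  ``epoch_start`` is in ms relative to stimulus
    onset (the conventional baseline-corrected epoch starts at -200 ms).
    """

    participant_id: str
    condition: str
    data: np.ndarray
    sampling_rate: float = 128.0
    epoch_start: float = -200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise CatalogueError(
                f"epoch data must be (n_electrodes, n_samples>=2), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise CatalogueError(
                f"non-finite values in epoch {self.participant_id}/{self.condition}"
            )
        if not self.sampling_rate > 0:
            raise CatalogueError("sampling_rate must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.epoch_start + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    @property
    def epoch_end(self) -> float:
        """End of the epoch in ms (one sample step past the last sample)."""
        return self.epoch_start + self.n_samples * 1000.0 / self.sampling_rate


@dataclass
class Experiment:
    """A within-subject ERP experiment with one designated contrast pair.

    ``participants`` maps participant id to a ``condition -> ErpEpoch``
    mapping; every participant must have every condition.  ``w_load`` is the
    regularity-salience weight in [0, 1] and ``task_relevant`` a 0/1 flag;
    both are metadata predictors of SPN amplitude, not computed here.
    """

    id: str
    project: str
    conditions: tuple[str, ...]
    contrast: tuple[str, str]  # (regular, random)
    participants: dict[str, dict[str, ErpEpoch]]
    w_load: float
    task_relevant: int
    published: bool
    original_cluster: tuple[str, ...]
    original_window: tuple[float, float]
    sampling_rate: float = 128.0
    epoch_start: float = -200.0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.contrast = tuple(self.contrast)  # type: ignore[assignment]
        self.original_cluster = tuple(self.original_cluster)
        self.original_window = tuple(self.original_window)  # type: ignore[assignment]
        if len(self.conditions) < 2:
            raise CatalogueError(f"experiment {self.id!r}: needs >= 2 conditions")
        if not set(self.contrast) <= set(self.conditions):
            raise CatalogueError(
                f"experiment {self.id!r}: contrast pair {self.contrast} not in conditions"
            )
        if len(self.participants) < 2:
            raise CatalogueError(f"experiment {self.id!r}: needs n >= 2 participants")
        for pid, epochs in self.participants.items():
            missing = set(self.conditions) - set(epochs)
            if missing:
                raise CatalogueError(
                    f"experiment {self.id!r}: participant {pid!r} missing "
                    f"condition(s) {sorted(missing)}"
                )
        if not 0.0 <= self.w_load <= 1.0:
            raise CatalogueError(f"experiment {self.id!r}: w_load must be in [0, 1]")
        if self.task_relevant not in (0, 1):
            raise CatalogueError(f"experiment {self.id!r}: task_relevant must be 0 or 1")
        lo, hi = self.original_window
        if not lo < hi:
            raise CatalogueError(f"experiment {self.id!r}: window start must precede end")

    @property
    def n(self) -> int:
        return len(self.participants)

    def epochs(self, condition: str) -> list[ErpEpoch]:
        """Per-participant epochs for *condition*, in participant order."""
        if condition not in self.conditions:
            raise CatalogueError(f"experiment {self.id!r}: unknown condition {condition!r}")
        return [self.participants[pid][condition] for pid in self.participants]


@dataclass
class Catalogue:
    """A montage plus a list of experiments sharing it."""

    montage: Montage
    experiments: list[Experiment] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [exp.id for exp in self.experiments]
        if len(set(ids)) != len(ids):
            raise CatalogueError("duplicate experiment ids in catalogue")
        for exp in self.experiments:
            unknown = set(exp.original_cluster) - set(self.montage.labels)
            if unknown:
                raise CatalogueError(
                    f"experiment {exp.id!r}: cluster electrodes {sorted(unknown)} "
                    "not in montage"
                )
            for pid, epochs in exp.participants.items():
                for cond, ep in epochs.items():
                    if ep.n_electrodes != len(self.montage):
                        raise CatalogueError(
                            f"experiment {exp.id!r}/{pid}/{cond}: "
                            f"{ep.n_electrodes} electrodes, montage has {len(self.montage)}"
                        )
                    lo, hi = exp.original_window
                    if lo < ep.epoch_start or hi > ep.epoch_end:
                        raise CatalogueError(
                            f"experiment {exp.id!r}: original window {exp.original_window} "
                            f"outside epoch [{ep.epoch_start}, {ep.epoch_end}] ms"
                        )

    def __len__(self) -> int:
        return len(self.experiments)

    def experiment(self, exp_id: str) -> Experiment:
        for exp in self.experiments:
            if exp.id == exp_id:
                return exp
        raise KeyError(f"no experiment {exp_id!r} in catalogue")


# ---------------------------------------------------------------------------
# on-disk interchange


def _montage_to_json(montage: Montage) -> dict:
    return {
        "labels": list(montage.labels),
        "positions": [
            {"label": lab, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for lab, p in zip(montage.labels, montage.positions)
        ],
        "neighbour_pairs": [list(pair) for pair in montage.adjacency_pairs()],
    }


def _montage_from_json(obj: dict) -> Montage:
    labels = tuple(obj["labels"])
    pos = np.array(
        [[row["x"], row["y"], row["z"]] for row in obj["positions"]], dtype=float
    )
    neigh: dict[str, set[str]] = {lab: set() for lab in labels}
    for a, b in obj["neighbour_pairs"]:
        neigh[a].add(b)
        neigh[b].add(a)
    return Montage(labels, pos, {k: frozenset(v) for k, v in neigh.items()})


def save_catalogue(catalogue: Catalogue, path: str | Path) -> Path:
    """Write *catalogue* to directory *path* in the interchange layout.

    Values are serialised with 17 significant digits so a load/save
    round-trip is numerically lossless.  Refuses to write a catalogue that
    violates its invariants (revalidated on entry).
    """
    # revalidate: the dataclasses check on construction but may have been
    # mutated since
    Catalogue(catalogue.montage, catalogue.experiments, catalogue.provenance)
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "montage.json").write_text(
        json.dumps(_montage_to_json(catalogue.montage), indent=1)
    )
    manifest = {
        "format_version": FORMAT_VERSION,
        "montage": "montage.json",
        "experiments": [exp.id for exp in catalogue.experiments],
        "provenance": catalogue.provenance,
    }
    (root / "catalogue.json").write_text(json.dumps(manifest, indent=1))
    for exp in catalogue.experiments:
        exp_dir = root / "experiments" / exp.id
        exp_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "id": exp.id,
            "project": exp.project,
            "n": exp.n,
            "conditions": list(exp.conditions),
            "contrast": list(exp.contrast),
            "participants": list(exp.participants),
            "w_load": exp.w_load,
            "task_relevant": exp.task_relevant,
            "published": exp.published,
            "original_cluster": list(exp.original_cluster),
            "original_window": list(exp.original_window),
            "sampling_rate": exp.sampling_rate,
            "epoch_start": exp.epoch_start,
        }
        (exp_dir / "meta.json").write_text(json.dumps(meta, indent=1))
        for pid, epochs in exp.participants.items():
            pdir = exp_dir / "participants" / pid
            pdir.mkdir(parents=True, exist_ok=True)
            for cond, ep in epochs.items():
                frame = pd.DataFrame(
                    ep.data.T, columns=list(catalogue.montage.labels)
                )
                frame.insert(0, "time_ms", ep.times)
                frame.to_csv(
                    pdir / f"{cond}.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT,
                )
    return root


def _read_epoch_tsv(
    path: Path, montage: Montage, pid: str, cond: str,
    sampling_rate: float, epoch_start: float,
) -> ErpEpoch:
    if not path.is_file():
        raise CatalogueError(
            f"missing condition file for participant {pid!r}, condition {cond!r}: {path}"
        )
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in frame.columns if c != "time_ms"]
    unknown = set(cols) - set(montage.labels)
    if unknown:
        raise CatalogueError(
            f"{path}: electrode label(s) {sorted(unknown)} not in montage"
        )
    missing = set(montage.labels) - set(cols)
    if missing:
        raise CatalogueError(f"{path}: missing electrode column(s) {sorted(missing)}")
    # normalise column order to montage order regardless of file order
    sub = frame[list(montage.labels)]
    bad = sub.columns[[not np.issubdtype(dt, np.number) for dt in sub.dtypes]]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(sub[col], errors="coerce")
            line = int(coerced.index[coerced.isna()][0]) + 2  # 1-based + header
            raise CatalogueError(f"{path}: non-numeric value in column {col!r}, line {line}")
    data = sub.to_numpy(dtype=float).T
    return ErpEpoch(pid, cond, data, sampling_rate=sampling_rate, epoch_start=epoch_start)


def load_catalogue(path: str | Path) -> Catalogue:
    """Load a catalogue directory written by :func:`save_catalogue`.

    Electrode columns are normalised to montage order; participant and
    experiment iteration order equals manifest order.  Raises
    :class:`CatalogueError` naming the experiment / participant / condition
    on any structural defect.
    """
    root = Path(path)
    manifest_path = root / "catalogue.json"
    if not manifest_path.is_file():
        raise CatalogueError(f"not a catalogue directory (no catalogue.json): {root}")
    manifest = json.loads(manifest_path.read_text())
    montage = _montage_from_json(
        json.loads((root / manifest.get("montage", "montage.json")).read_text())
    )
    experiments = []
    for exp_id in manifest["experiments"]:
        exp_dir = root / "experiments" / exp_id
        meta_path = exp_dir / "meta.json"
        if not meta_path.is_file():
            raise CatalogueError(f"experiment {exp_id!r}: missing {meta_path}")
        meta = json.loads(meta_path.read_text())
        participants: dict[str, dict[str, ErpEpoch]] = {}
        for pid in meta["participants"]:
            epochs: dict[str, ErpEpoch] = {}
            for cond in meta["conditions"]:
                tsv = exp_dir / "participants" / pid / f"{cond}.tsv"
                try:
                    epochs[cond] = _read_epoch_tsv(
                        tsv, montage, pid, cond,
                        meta["sampling_rate"], meta["epoch_start"],
                    )
                except CatalogueError as err:
                    raise CatalogueError(f"experiment {exp_id!r}: {err}") from None
            participants[pid] = epochs
        experiments.append(
            Experiment(
                id=meta["id"],
                project=meta["project"],
                conditions=tuple(meta["conditions"]),
                contrast=tuple(meta["contrast"]),
                participants=participants,
                w_load=meta["w_load"],
                task_relevant=meta["task_relevant"],
                published=meta["published"],
                original_cluster=tuple(meta["original_cluster"]),
                original_window=tuple(meta["original_window"]),
                sampling_rate=meta["sampling_rate"],
                epoch_start=meta["epoch_start"],
            )
        )
    return Catalogue(montage, experiments, provenance=manifest.get("provenance", ""))
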