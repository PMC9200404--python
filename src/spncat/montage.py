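"""Electrode montages: labels, unit-sphere positions and adjacency.

A :class:`Montage` is the spatial backbone of every cluster definition in the
package: windowed amplitude extraction averages over subsets of its labels,
and the spatio-temporal permutation test uses its neighbour relation as the
spatial half of the cluster connectivity.

Positions live on the unit sphere (dimensionless); adjacency is defined by a
great-circle distance threshold, chosen so that a 64-channel scalp layout has
a median neighbour count of 6-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Montage", "build_montage", "DEFAULT_ADJACENCY_THRESHOLD"]

#: Default great-circle adjacency threshold in radians.  On the bundled
#: 64-channel layout this yields a median neighbour count of 7.
DEFAULT_ADJACENCY_THRESHOLD = 0.55

_POSITION_TOL = 1e-6


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with unit-sphere positions and adjacency.

    Parameters
    ----------
    labels
        Ordered, unique electrode names (10-05 / Biosemi-64 convention).
    positions
        Array of shape ``(n_electrodes, 3)``; every row must have unit norm
        within ``1e-6``.
    neighbours
        Mapping from each label to the frozenset of its neighbours.  The
        relation must be symmetric and irreflexive, and every endpoint must
        be a known label.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    neighbours: Mapping[str, frozenset[str]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate electrode labels in montage")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 3):
            raise ValueError(
                f"positions must have shape ({len(labels)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.all(np.abs(norms - 1.0) <= _POSITION_TOL):
            raise ValueError("electrode positions must lie on the unit sphere")
        known = set(labels)
        neigh = {lab: frozenset(self.neighbours.get(lab, ())) for lab in labels}
        for lab, nbrs in neigh.items():
            unknown = nbrs - known
            if unknown:
                raise ValueError(f"adjacency of {lab!r} references unknown {sorted(unknown)}")
            if lab in nbrs:
                raise ValueError(f"adjacency must be irreflexive ({lab!r} ~ itself)")
            for other in nbrs:
                if lab not in neigh[other]:
                    raise ValueError(f"adjacency not symmetric: {lab!r} ~ {other!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "neighbours", neigh)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        """Row index of *label* in the montage (and in every epoch matrix)."""
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.array([self.index(lab) for lab in labels], dtype=int)

    def adjacency_pairs(self) -> list[tuple[str, str]]:
        """Unordered neighbour pairs, each listed once, deterministically."""
        pairs = []
        for lab in self.labels:
            for other in sorted(self.neighbours[lab]):
                if self._index[lab] < self._index[other]:
                    pairs.append((lab, other))
        return pairs

    def adjacency_matrix(self) -> np.ndarray:
        """Dense boolean adjacency matrix in label order."""
        n = len(self.labels)
        mat = np.zeros((n, n), dtype=bool)
        for a, b in self.adjacency_pairs():
            i, j = self._index[a], self._index[b]
            mat[i, j] = mat[j, i] = True
        return mat

    def restrict(self, labels: Sequence[str]) -> "Montage":
        """Sub-montage over *labels*, adjacency restricted accordingly."""
        keep = set(labels)
        missing = keep - set(self.labels)
        if missing:
            raise KeyError(f"electrodes not in montage: {sorted(missing)}")
        labs = tuple(lab for lab in labels)
        pos = self.positions[self.indices(labs)]
        neigh = {lab: frozenset(self.neighbours[lab] & keep) for lab in labs}
        return Montage(labs, pos, neigh)


def _great_circle_adjacency(
    labels: Sequence[str], positions: np.ndarray, threshold: float
) -> dict[str, frozenset[str]]:
    unit = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    cosines = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = np.arccos(cosines)
    close = (dist <= threshold) & ~np.eye(len(labels), dtype=bool)
    return {
        lab: frozenset(labels[j] for j in np.flatnonzero(close[i]))
        for i, lab in enumerate(labels)
    }


def _biosemi64_positions() -> tuple[tuple[str, ...], np.ndarray]:
    # mne ships idealised spherical coordinates for the standard Biosemi
    # 64-channel cap; we normalise its (head-radius) positions onto the
    # unit sphere.  Imported lazily so the rest of the package has no hard
    # mne dependency.
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    ch_pos = std.get_positions()["ch_pos"]
    labels = tuple(ch_pos)
    pos = np.array([ch_pos[lab] for lab in labels], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return labels, pos


_REQUIRED_POSTERIOR = (
    "P1 P3 P5 P7 P9 PO7 PO3 O1 P2 P4 P6 P8 P10 PO8 PO4 O2".split()
)


def build_montage(
    source: str | Mapping[str, Sequence[float]] = "biosemi64",
    *,
    threshold: float = DEFAULT_ADJACENCY_THRESHOLD,
) -> Montage:
    """Build a :class:`Montage` from a standard layout name or position table.

    Parameters
    ----------
    source
        Either the name of a bundled standard layout (currently
        ``"biosemi64"``) or a mapping ``label -> (x, y, z)``.  Positions are
        normalised onto the unit sphere.
    threshold
        Great-circle adjacency threshold in radians: two electrodes are
        neighbours iff their angular distance is at most this value.

    Raises
    ------
    ValueError
        On unknown layout names, duplicate labels, fewer than two
        electrodes, or a position with zero norm.
    """
    if isinstance(source, str):
        name = source.lower()
        if name != "biosemi64":
            raise ValueError(f"unknown montage layout {source!r}")
        labels, pos = _biosemi64_positions()
        missing = set(_REQUIRED_POSTERIOR) - set(labels)
        if missing:  # pragma: no cover - guards against upstream layout drift
            raise RuntimeError(f"bundled layout lacks posterior electrodes {missing}")
    else:
        labels = tuple(source)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate electrode labels in position table")
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        pos = np.array([source[lab] for lab in labels], dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be 3D coordinates")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0) or not np.all(np.isfinite(norms)):
            raise ValueError("positions must be finite and non-zero")
        pos = pos / norms[:, None]
    if not (0 < threshold < math.pi):
        raise ValueError("adjacency threshold must be in (0, pi) radians")
    neighbours = _great_circle_adjacency(labels, pos, threshold)
    return Montage(labels, pos, neighbours)
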