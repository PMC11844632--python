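"""Electrode-grid geometry, amplitude ladder, and threshold-map data model.

The data model targets epiretinal implants of the Argus II type: a small
rectangular grid of stimulating electrodes (6 rows x 10 columns by default),
each of which has a perceptual threshold -- the minimum stimulus current (in
microamps) at which the user reliably reports a percept.  Thresholds are
measured on a logarithmically spaced amplitude ladder and are censored at the
device safety limit: an electrode that needs more current than the maximum
tested amplitude is recorded *at* the maximum and flagged as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LADDER_MIN_UA",
    "LADDER_MAX_UA",
    "LADDER_STEPS",
    "ElectrodeGrid",
    "AmplitudeLadder",
    "ThresholdMap",
    "build_grid",
    "build_ladder",
]

#: Default amplitude ladder: 60 log-spaced currents from 40 to 677 microamps.
LADDER_MIN_UA: float = 40.0
LADDER_MAX_UA: float = 677.0
LADDER_STEPS: int = 60


class InvalidGridError(ValueError):
    """Raised when a grid specification cannot form a usable electrode array."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular electrode array with row-major integer ids.

    Electrode ``(r, c)`` has id ``r * n_cols + c`` and sits at position
    ``(c * pitch, r * pitch)``; distances are therefore expressed in units of
    the inter-electrode pitch (1.0 by default).

    Attributes
    ----------
    n_rows, n_cols : int
        Grid shape; the Argus II array is 6 x 10.
    pitch : float
        Center-to-center electrode spacing, in arbitrary grid units.
    active_mask : np.ndarray of bool, shape (n_rows * n_cols,)
        False marks electrodes that are inactive (broken or disabled) and
        hence cannot be measured.
    """

    n_rows: int
    n_cols: int
    pitch: float = 1.0
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidGridError("grid must have at least one row and column")
        if not self.pitch > 0:
            raise InvalidGridError(f"pitch must be positive, got {self.pitch}")
        if self.active_mask is None:
            object.__setattr__(
                self, "active_mask", np.ones(self.n_electrodes, dtype=bool)
            )
        else:
            mask = np.asarray(self.active_mask, dtype=bool)
            if mask.shape != (self.n_electrodes,):
                raise InvalidGridError(
                    f"active_mask has shape {mask.shape}, "
                    f"expected ({self.n_electrodes},)"
                )
            object.__setattr__(self, "active_mask", mask)
        if self.active_mask.sum() < 2:
            raise InvalidGridError("grid must retain at least 2 active electrodes")
        self.active_mask.setflags(write=False)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def electrode_ids(self) -> np.ndarray:
        return np.arange(self.n_electrodes)

    @property
    def active_ids(self) -> np.ndarray:
        """Ids of active electrodes, ascending."""
        return np.flatnonzero(self.active_mask)

    @property
    def positions(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) = (col * pitch, row * pitch)."""
        ids = self.electrode_ids
        rows, cols = np.divmod(ids, self.n_cols)
        return np.column_stack([cols * self.pitch, rows * self.pitch]).astype(float)

    def positions_of(self, ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(ids, dtype=int)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_electrodes):
            raise IndexError(f"electrode ids out of range 0..{self.n_electrodes - 1}")
        return self.positions[ids]

    def distance(self, i: int, j: int) -> float:
        """Euclidean distance between two electrodes, in pitch units."""
        p = self.positions_of([i, j])
        return float(np.hypot(*(p[0] - p[1])))


def build_grid(
    n_rows: int = 6,
    n_cols: int = 10,
    pitch: float = 1.0,
    inactive_ids: Iterable[int] = (),
) -> ElectrodeGrid:
    """Construct a rectangular electrode grid with some electrodes disabled.

    Raises
    ------
    InvalidGridError
        If ids are out of range or fewer than 2 active electrodes remain.
    """
    n = n_rows * n_cols
    mask = np.ones(n, dtype=bool)
    for eid in inactive_ids:
        if not 0 <= int(eid) < n:
            raise InvalidGridError(f"inactive id {eid} outside 0..{n - 1}")
        mask[int(eid)] = False
    return ElectrodeGrid(n_rows=n_rows, n_cols=n_cols, pitch=pitch, active_mask=mask)


@dataclass(frozen=True)
class AmplitudeLadder:
    """Logarithmically spaced stimulus-amplitude ladder.

    The consecutive ratio ``(maximum / minimum) ** (1 / (n_steps - 1))`` is
    constant, so the ladder is a geometric sequence from ``minimum`` to
    ``maximum`` inclusive.
    """

    minimum: float = LADDER_MIN_UA
    maximum: float = LADDER_MAX_UA
    n_steps: int = LADDER_STEPS

    @property
    def values(self) -> np.ndarray:
        return np.geomspace(self.minimum, self.maximum, self.n_steps)

    def snap(self, amplitudes: np.ndarray) -> np.ndarray:
        """Snap amplitudes to the nearest ladder value (nearest in log space).

        Values outside [minimum, maximum] map to the respective endpoint.
        """
        log_vals = np.log(self.values)
        amp = np.clip(np.asarray(amplitudes, dtype=float), self.minimum, self.maximum)
        idx = np.argmin(np.abs(np.log(amp)[..., None] - log_vals), axis=-1)
        return self.values[idx]


def build_ladder(
    minimum: float = LADDER_MIN_UA,
    maximum: float = LADDER_MAX_UA,
    n_steps: int = LADDER_STEPS,
) -> AmplitudeLadder:
    """Build a geometric amplitude ladder; log spacing requires minimum > 0."""
    if not minimum > 0:
        raise ValueError(f"ladder minimum must be positive, got {minimum}")
    if not maximum > minimum:
        raise ValueError("ladder maximum must exceed minimum")
    if n_steps < 2:
        raise ValueError("ladder needs at least 2 steps")
    return AmplitudeLadder(minimum=minimum, maximum=maximum, n_steps=n_steps)


@dataclass(frozen=True)
class ThresholdMap:
    """Per-electrode perceptual thresholds on an electrode grid.

    Attributes
    ----------
    grid : ElectrodeGrid
    thresholds_uA : np.ndarray, shape (n_electrodes,)
        Threshold current in microamps; NaN on inactive electrodes.
    censored : np.ndarray of bool
        True where the threshold equals the safety-limit maximum, meaning the
        true threshold is only lower-bounded by it.
    pulse_width_ms, frequency_hz, label
        Stimulus metadata carried through to serialized files.
    """

    grid: ElectrodeGrid
    thresholds_uA: np.ndarray
    censored: np.ndarray
    pulse_width_ms: float = 0.45
    frequency_hz: float = 20.0
    label: str = ""
    ladder: AmplitudeLadder = field(default_factory=AmplitudeLadder)

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds_uA, dtype=float)
        cen = np.asarray(self.censored, dtype=bool)
        n = self.grid.n_electrodes
        if thr.shape != (n,) or cen.shape != (n,):
            raise ValueError(f"thresholds and censored must have shape ({n},)")
        active = self.grid.active_mask
        if np.isnan(thr[active]).any():
            raise ValueError("active electrodes must all carry a threshold")
        if not np.isnan(thr[~active]).all():
            raise ValueError("inactive electrodes must have NaN thresholds")
        lo, hi = self.ladder.minimum, self.ladder.maximum
        vals = thr[active]
        if (vals < lo - 1e-9).any() or (vals > hi + 1e-9).any():
            raise ValueError(f"thresholds must lie within [{lo}, {hi}] microamps")
        at_max = np.isclose(thr, hi) & active
        if not np.array_equal(cen & active, at_max):
            raise ValueError(
                "censored flag must be set exactly where the threshold "
                "equals the ladder maximum"
            )
        object.__setattr__(self, "thresholds_uA", thr)
        object.__setattr__(self, "censored", cen)
        thr.setflags(write=False)
        cen.setflags(write=False)

    @property
    def measured_ids(self) -> np.ndarray:
        """Active electrode ids (every active electrode carries a threshold)."""
        return self.grid.active_ids

    def trainable_ids(self, include_censored: bool = False) -> np.ndarray:
        """Active ids usable as GP training data.

        Censored electrodes are excluded by default: their recorded value is
        only a lower bound on the true threshold.
        """
        mask = self.grid.active_mask.copy()
        if not include_censored:
            mask &= ~self.censored
        return np.flatnonzero(mask)

    def with_label(self, label: str) -> "ThresholdMap":
        return replace(self, label=label)
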