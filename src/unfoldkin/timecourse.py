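"""The :class:`TimeCourse` container for stopped-flow fluorescence traces.

A trace is a strictly increasing time grid (seconds) with one signal value
per time point, plus the metadata needed to interpret it: which substrate it
was collected on, the substrate's total length ``L`` in amino acids, the
ATPgammaS pre-incubation delay ``dt1``, a replicate identifier, and an
explicit normalization state -- ``"raw"`` for instrument-units fluorescence,
``"relative"`` for relative fluorescence enhancement.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import DataError

#: Allowed normalization states.
STATES = ("raw", "relative")


@dataclass
class TimeCourse:
    """One fluorescence time-course.

    Parameters
    ----------
    t : array
        Time grid in seconds; strictly increasing, nonnegative.
    y : array
        Signal at each time point (raw fluorescence or relative
        enhancement, see ``state``).
    substrate : str
        Substrate name, e.g. ``"RepA-Titin_3"``.
    length : float
        Total substrate length L in amino acids.
    dt1 : float
        Pre-incubation delay time in seconds (0 for standard mixing).
    replicate : int
        Replicate index.
    state : str
        ``"raw"`` or ``"relative"``.
    extras : dict
        Free-form metadata (per-point standard deviations under ``"sd"``,
        replicate counts under ``"n_averaged"``, generating truth, ...).
    """

    t: np.ndarray
    y: np.ndarray
    substrate: str = ""
    length: float = 0.0
    dt1: float = 0.0
    replicate: int = 0
    state: str = "raw"
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.shape != self.t.shape:
            raise DataError("t and y must be 1-D arrays of equal length")
        if self.t.size and (np.any(~np.isfinite(self.t)) or self.t[0] < 0):
            raise DataError("time grid must be finite and nonnegative")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise DataError(f"time grid not strictly increasing at row {bad}")
        if np.any(~np.isfinite(self.y)):
            raise DataError("signal contains non-finite values")
        if self.state not in STATES:
            raise DataError(f"unknown normalization state {self.state!r}")

    def __len__(self) -> int:
        return self.t.size

    @property
    def is_raw(self) -> bool:
        return self.state == "raw"

    def with_signal(self, y: np.ndarray, state: str | None = None) -> "TimeCourse":
        """Copy of this trace with a new signal array (same grid/metadata)."""
        return replace(self, y=np.asarray(y, float),
                       state=self.state if state is None else state,
                       extras=dict(self.extras))


def same_grid(a: TimeCourse, b: TimeCourse) -> bool:
    """True if two traces share an identical time grid."""
    return a.t.shape == b.t.shape and bool(np.array_equal(a.t, b.t))


def default_time_grid(t_min: float = 1e-2, t_max: float = 5000.0,
                      n_points: int = 2000) -> np.ndarray:
    """Log-spaced acquisition grid mimicking stopped-flow sampling.

    The defaults span 10 ms to 5000 s, covering the lag, peak (up to the
    ~3000 s peak times seen with slow ATPgammaS-only unfolding) and decay.
    """
    if not (0 < t_min < t_max) or n_points < 2:
        raise DataError("need 0 < t_min < t_max and n_points >= 2")
    return np.geomspace(t_min, t_max, n_points)
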