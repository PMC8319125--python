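"""Shared containers for time-domain FLIM data.

Conventions used throughout the package:

* images are 0-based, row-major, indexed ``(row=y, col=x)``;
* decay cubes are ``(y, x, t)`` photon-count histograms;
* all lifetimes are in picoseconds end to end;
* time bins are referenced by their centers, ``t_i = (i + 1/2) * bin_width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Default laser repetition period, ps (80 MHz Ti:sapphire convention).
DEFAULT_PERIOD_PS = 12500.0
#: Default number of TCSPC time bins.
DEFAULT_N_BINS = 256

NADPH = "NADPH"
FAD = "FAD"


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC time axis over one laser period."""

    n_bins: int
    bin_width_ps: float

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.bin_width_ps <= 0:
            raise ValueError("bin_width_ps must be positive")

    @classmethod
    def from_period(cls, period_ps: float = DEFAULT_PERIOD_PS,
                    n_bins: int = DEFAULT_N_BINS) -> "TimeAxis":
        return cls(n_bins=n_bins, bin_width_ps=period_ps / n_bins)

    @property
    def period_ps(self) -> float:
        return self.n_bins * self.bin_width_ps

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ps


@dataclass
class IRFCurve:
    """Normalized instrument response histogram on a :class:`TimeAxis`."""

    values: np.ndarray
    axis: TimeAxis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.axis.n_bins:
            raise ValueError("IRF length must match the time axis")
        if np.any(self.values < 0):
            raise ValueError("IRF values must be non-negative")
        total = float(self.values.sum())
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"IRF must sum to 1 (got {total:.6g}); "
                             "normalize before constructing IRFCurve")

    @classmethod
    def delta(cls, axis: TimeAxis, bin_index: int = 0) -> "IRFCurve":
        """Single-bin (delta) response, useful for tests and ideal decays."""
        v = np.zeros(axis.n_bins)
        v[bin_index] = 1.0
        return cls(v, axis)


@dataclass
class DecayCube:
    """Per-pixel TCSPC photon-count histograms for one channel.

    ``counts`` has shape ``(y, x, t)`` and holds non-negative integers
    (stored as int64; sliding-window binning keeps integrality).
    """

    counts: np.ndarray
    axis: TimeAxis
    channel: str = NADPH
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (y, x, t)")
        if self.counts.shape[2] != self.axis.n_bins:
            raise ValueError("time dimension must match the time axis")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-6):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def intensity(self) -> np.ndarray:
        """Per-pixel intensity: photon counts integrated over the decay."""
        return self.counts.sum(axis=2)


@dataclass
class LifetimeMaps:
    """Per-pixel fitted two-component lifetime maps for one channel.

    Invalid pixels (below the photon threshold, or failed fits) are flagged
    in ``valid`` and carry NaN in the parameter maps — never a silent zero.
    ``intensity`` always comes from the unbinned cube.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    offset: np.ndarray
    intensity: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray
    channel: str = NADPH
    bin_level: int = 0

    def __post_init__(self) -> None:
        shape = self.alpha1.shape
        for name in ("alpha2", "tau1", "tau2", "tau_m", "offset",
                     "intensity", "chi2", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"map {name!r} has mismatched shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha1.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "alpha1": self.alpha1, "alpha2": self.alpha2,
            "tau1": self.tau1, "tau2": self.tau2, "tau_m": self.tau_m,
            "offset": self.offset, "intensity": self.intensity,
            "chi2": self.chi2,
        }
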