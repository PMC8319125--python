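"""Frequency-domain (phasor) representation of fluorescence decays.

The phasor of a decay histogram {cᵢ} sampled at bin centers tᵢ is

    G = Σᵢ cᵢ cos(ω tᵢ) / Σᵢ cᵢ,    S = Σᵢ cᵢ sin(ω tᵢ) / Σᵢ cᵢ,

with ω = 2π · harmonic / period. Noiseless mono-exponential decays fall on
the universal semicircle (G − ½)² + S² = ¼; mixtures lie on the chord
between their components at the intensity-weighted position, which makes
the plot useful for discriminating fluorophores (e.g. EGFP from NAD(P)H)
without fitting. Supplying an IRF calibrates the instrument response out
by complex division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DecayCube, IRFCurve, TimeAxis

__all__ = ["PhasorPoint", "phasor_transform", "phasor_map",
           "mono_exponential_phasor"]


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float
    harmonic: int = 1
    frequency_hz: float = 0.0

    @property
    def modulation(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.s, self.g))


def mono_exponential_phasor(tau_ps: float, omega_per_ps: float
                            ) -> tuple[float, float]:
    """Closed-form phasor of an ideal mono-exponential decay."""
    wt = omega_per_ps * tau_ps
    return 1.0 / (1.0 + wt * wt), wt / (1.0 + wt * wt)


def _omega(axis: TimeAxis, harmonic: int) -> float:
    return 2.0 * np.pi * harmonic / axis.period_ps


def phasor_transform(decay: np.ndarray, axis: TimeAxis, harmonic: int = 1,
                     irf: IRFCurve | None = None) -> PhasorPoint:
    """Phasor of a single decay histogram, optionally IRF-calibrated."""
    c = np.asarray(decay, dtype=float)
    if c.ndim != 1 or c.size != axis.n_bins:
        raise ValueError("decay length must match the time axis")
    total = c.sum()
    if total <= 0:
        raise ValueError("decay has no photons; phasor undefined")
    w = _omega(axis, harmonic)
    t = axis.centers
    z = complex((c * np.cos(w * t)).sum() / total,
                (c * np.sin(w * t)).sum() / total)
    if irf is not None:
        zi = complex((irf.values * np.cos(w * t)).sum(),
                     (irf.values * np.sin(w * t)).sum())
        z = z / zi
    freq = harmonic / (axis.period_ps * 1e-12)
    return PhasorPoint(g=z.real, s=z.imag, harmonic=harmonic,
                       frequency_hz=freq)


def phasor_map(cube: DecayCube, harmonic: int = 1,
               irf: IRFCurve | None = None, min_photons: float = 100.0
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel phasor images ``(G, S, valid)`` for a decay cube.

    Pixels below ``min_photons`` total counts are flagged invalid and
    carry NaN coordinates.
    """
    axis = cube.axis
    w = _omega(axis, harmonic)
    t = axis.centers
    counts = cube.counts.astype(float)
    total = counts.sum(axis=2)
    valid = total >= max(min_photons, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ np.cos(w * t) / total
        s = counts @ np.sin(w * t) / total
    if irf is not None:
        zi = complex((irf.values * np.cos(w * t)).sum(),
                     (irf.values * np.sin(w * t)).sum())
        z = (g + 1j * s) / zi
        g, s = z.real, z.imag
    g = np.where(valid, g, np.nan)
    s = np.where(valid, s, np.nan)
    return g, s, valid
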