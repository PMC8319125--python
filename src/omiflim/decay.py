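"""Two-component fluorescence-lifetime fitting with IRF convolution.

The per-pixel model for TCSPC photon-count histograms is

    I(t) = A * (IRF ⊛ [α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂)]) + C,   α₁ + α₂ = 1,

with the convolution taken circularly over the laser period when the
incomplete-decay (wrap-around) correction is enabled, which is the default:
at an 80 MHz repetition rate the long NAD(P)H/FAD component (τ₂ ≈ 2.5 ns)
has not fully decayed within one 12.5 ns period.

Counts in TCSPC are Poisson, so the default objective is the Poisson
negative log-likelihood; a Neyman weighted-least-squares objective
(weights ``max(count, 1)``) is available for comparability with
commercial least-squares fitters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, optimize

from .core import DecayCube, IRFCurve, LifetimeMaps, TimeAxis

__all__ = [
    "FitOptions", "FitParams", "mean_lifetime", "decay_kernel",
    "model_decay", "bin_pixels", "fit_pixel", "fit_image",
    "poisson_nll", "neyman_chi2",
]

# Component bounds, ps. Overlap between the τ₁ and τ₂ ranges is resolved by
# the ordering convention τ₁ < τ₂ (swap + relabel after optimization).
TAU1_BOUNDS = (50.0, 1500.0)
TAU2_BOUNDS = (800.0, 8000.0)


def mean_lifetime(alpha1, tau1, alpha2, tau2):
    """Amplitude-weighted mean lifetime τ_m = α₁τ₁ + α₂τ₂ (picoseconds)."""
    return alpha1 * tau1 + alpha2 * tau2


@dataclass
class FitParams:
    """Result of a single-pixel two-component decay fit."""

    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    offset: float
    amplitude: float
    tau_m: float
    chi2_reduced: float
    converged: bool
    valid: bool
    shift_ps: float = 0.0

    @classmethod
    def invalid(cls) -> "FitParams":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, nan,
                   converged=False, valid=False)

    def check(self, atol: float = 1e-9) -> None:
        if not self.valid:
            return
        if abs(self.alpha1 + self.alpha2 - 1.0) > atol:
            raise ValueError("alpha1 + alpha2 must equal 1")
        if not (0.0 <= self.alpha1 <= 1.0):
            raise ValueError("alpha1 outside [0, 1]")
        if not (0.0 < self.tau1 <= self.tau2):
            raise ValueError("component ordering tau1 <= tau2 violated")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass
class FitOptions:
    """Fitting configuration shared by :func:`fit_pixel` and :func:`fit_image`."""

    objective: Literal["mle", "wlsq"] = "mle"
    min_photons: float = 100.0
    periodic: bool = True
    tau1_bounds: tuple[float, float] = TAU1_BOUNDS
    tau2_bounds: tuple[float, float] = TAU2_BOUNDS
    fit_offset: bool = True
    max_iter: int = 200


def decay_kernel(alpha1: float, tau1: float, tau2: float, axis: TimeAxis,
                 periodic: bool = True) -> np.ndarray:
    """Bi-exponential decay sampled at bin centers.

    With ``periodic`` the incomplete decay from preceding excitation pulses
    is folded in: each component becomes e^(−t/τ) / (1 − e^(−T/τ)) over the
    laser period T.
    """
    t = axis.centers
    T = axis.period_ps
    k = np.zeros(axis.n_bins)
    for a, tau in ((alpha1, tau1), (1.0 - alpha1, tau2)):
        if a == 0.0:
            continue
        comp = np.exp(-t / tau)
        if periodic:
            comp = comp / (1.0 - np.exp(-T / tau))
        k += a * comp
    return k


def _convolve_irf(kernel: np.ndarray, irf_values: np.ndarray,
                  periodic: bool) -> np.ndarray:
    if periodic:
        return np.fft.irfft(np.fft.rfft(kernel) * np.fft.rfft(irf_values),
                            n=kernel.size)
    return np.convolve(kernel, irf_values)[: kernel.size]


def model_decay(params: FitParams, axis: TimeAxis, irf: IRFCurve,
                periodic: bool = True) -> np.ndarray:
    """Expected counts per bin for the two-component model."""
    if not periodic:
        T = axis.period_ps
        for tau in (params.tau1, params.tau2):
            if tau > T:
                raise ValueError(
                    f"lifetime {tau:.0f} ps exceeds the laser period "
                    f"{T:.0f} ps; enable periodic wrap-around to model "
                    "incomplete decays")
    kernel = decay_kernel(params.alpha1, params.tau1, params.tau2, axis,
                          periodic=periodic)
    return params.amplitude * _convolve_irf(kernel, irf.values, periodic) \
        + params.offset


def bin_pixels(cube: DecayCube, level: int) -> DecayCube:
    """Sliding-window spatial binning of decay histograms.

    Each output pixel's histogram is the sum over its (2·level+1)² square
    neighborhood; image dimensions are unchanged and edge pixels sum only
    the in-image subset (truncated neighborhoods — no photons fabricated).
    Level 1 corresponds to 3 × 3 binning, level 2 to 5 × 5.
    """
    if level < 0:
        raise ValueError("binning level must be >= 0")
    if level == 0:
        return cube
    size = 2 * level + 1
    kernel = np.ones((size, size, 1))
    summed = ndimage.convolve(cube.counts.astype(np.int64), kernel.astype(np.int64),
                              mode="constant", cval=0)
    return DecayCube(summed, cube.axis, cube.channel,
                     {**cube.meta, "bin_level": level})


def poisson_nll(model: np.ndarray, counts: np.ndarray) -> float:
    """Poisson negative log-likelihood (up to the data-only constant)."""
    m = np.clip(model, 1e-12, None)
    return float(np.sum(m - counts * np.log(m)))


def neyman_chi2(model: np.ndarray, counts: np.ndarray) -> float:
    """Neyman weighted least squares: Σ (c − m)² / max(c, 1)."""
    w = np.maximum(counts, 1.0)
    return float(np.sum((counts - model) ** 2 / w))


def _objective_fn(name: str):
    if name == "mle":
        return poisson_nll
    if name == "wlsq":
        return neyman_chi2
    raise ValueError(f"unknown objective {name!r}")


class _ConvBasis:
    """IRF-convolved single-exponential basis curves on a coarse τ grid.

    Bi-exponential objectives are ill-conditioned, so the optimizer is
    started from the best point of a deterministic (τ₁, τ₂) grid where,
    for each lifetime pair, the amplitudes and offset are solved as a
    non-negative linear problem (Neyman-weighted). The basis depends only
    on the IRF and the grids, so it is computed once per image.
    """

    def __init__(self, irf: IRFCurve, opts: "FitOptions",
                 n_grid: int = 7):
        self.axis = irf.axis
        lo1 = max(opts.tau1_bounds[0], 80.0)
        hi1 = min(opts.tau1_bounds[1], 1400.0)
        lo2 = max(opts.tau2_bounds[0], 900.0)
        hi2 = min(opts.tau2_bounds[1], 6000.0)
        self.tau1_grid = np.geomspace(lo1, hi1, n_grid)
        self.tau2_grid = np.geomspace(lo2, hi2, n_grid)
        taus = np.unique(np.concatenate([self.tau1_grid, self.tau2_grid]))
        self.curves = {}
        for tau in taus:
            k = decay_kernel(1.0, tau, tau, irf.axis,
                             periodic=opts.periodic)
            if opts.periodic:
                f = np.fft.irfft(np.fft.rfft(k) * np.fft.rfft(irf.values),
                                 n=irf.axis.n_bins)
            else:
                f = np.convolve(k, irf.values)[: irf.axis.n_bins]
            self.curves[float(tau)] = np.clip(f, 0.0, None)

    def best_start(self, counts: np.ndarray, objective,
                   fit_offset: bool) -> tuple[float, float, float, float, float]:
        """Grid-search (τ₁, τ₂) with an inner NNLS amplitude solve."""
        w = np.sqrt(1.0 / np.maximum(counts, 1.0))
        cw = counts * w
        ones = np.ones_like(counts)
        best = None
        for t1 in self.tau1_grid:
            f1 = self.curves[float(t1)]
            for t2 in self.tau2_grid:
                if t2 <= 1.5 * t1:
                    continue
                f2 = self.curves[float(t2)]
                cols = [f1, f2] + ([ones] if fit_offset else [])
                a = np.stack([c * w for c in cols], axis=1)
                coef, _ = optimize.nnls(a, cw)
                b1, b2 = coef[0], coef[1]
                off = coef[2] if fit_offset else 0.0
                model = b1 * f1 + b2 * f2 + off
                val = objective(model, counts)
                if best is None or val < best[0]:
                    amp = b1 + b2
                    a1 = b1 / amp if amp > 0 else 0.5
                    best = (val, a1, float(t1), float(t2), amp, off)
        _, a1, t1, t2, amp, off = best
        return a1, t1, t2, max(amp, 1e-9), off


def fit_pixel(counts: np.ndarray, irf: IRFCurve,
              options: FitOptions | None = None,
              _basis: _ConvBasis | None = None) -> FitParams:
    """Fit one pixel's decay histogram; flags instead of raising on bad data.

    Pixels whose total counts fall below ``options.min_photons`` are
    returned invalid without fitting. Component ordering τ₁ < τ₂ is
    enforced by swap-and-relabel, so the initializer's labeling never
    affects the result.
    """
    opts = options or FitOptions()
    counts = np.asarray(counts, dtype=float)
    axis = irf.axis
    if counts.ndim != 1 or counts.size != axis.n_bins:
        raise ValueError("decay length must match the IRF time axis")
    total = counts.sum()
    if not np.isfinite(total) or total < opts.min_photons:
        return FitParams.invalid()

    objective = _objective_fn(opts.objective)
    irf_fft = np.fft.rfft(irf.values)
    t = axis.centers
    T = axis.period_ps
    n = axis.n_bins

    def conv_with_irf(v):
        if opts.periodic:
            return np.fft.irfft(np.fft.rfft(v) * irf_fft, n=n)
        return np.convolve(v, irf.values)[:n]

    def single_kernel_and_dtau(tau):
        e = np.exp(-t / tau)
        if opts.periodic:
            d = 1.0 - np.exp(-T / tau)
            k = e / d
            dk = k * (t / tau ** 2 - (T / tau ** 2) * np.exp(-T / tau) / d)
        else:
            k = e
            dk = k * (t / tau ** 2)
        return k, dk

    def forward(alpha1, tau1, tau2, amplitude, offset):
        k = decay_kernel(alpha1, tau1, tau2, axis, periodic=opts.periodic)
        return amplitude * conv_with_irf(k) + offset

    # Optimize in a scaled space: lifetimes in ns, amplitude in log units.
    def unpack(x):
        alpha1 = x[0]
        tau1 = x[1] * 1000.0
        tau2 = x[2] * 1000.0
        amplitude = np.exp(x[3])
        offset = x[4] if opts.fit_offset else 0.0
        return alpha1, tau1, tau2, amplitude, offset

    def fun(x):
        model = forward(*unpack(x))
        val = objective(model, counts)
        return val if np.isfinite(val) else 1e300

    def fun_and_grad(x):
        alpha1, tau1, tau2, amplitude, offset = unpack(x)
        k1, dk1 = single_kernel_and_dtau(tau1)
        k2, dk2 = single_kernel_and_dtau(tau2)
        c1, c2 = conv_with_irf(k1), conv_with_irf(k2)
        m = amplitude * (alpha1 * c1 + (1.0 - alpha1) * c2) + offset
        m = np.clip(m, 1e-12, None)
        if opts.objective == "mle":
            f = float(np.sum(m - counts * np.log(m)))
            r = 1.0 - counts / m          # dL/dm
        else:
            w = np.maximum(counts, 1.0)
            f = float(np.sum((counts - m) ** 2 / w))
            r = -2.0 * (counts - m) / w
        if not np.isfinite(f):
            return 1e300, np.zeros(5)
        g = np.empty(5)
        g[0] = amplitude * float(r @ (c1 - c2))
        g[1] = amplitude * alpha1 * float(r @ conv_with_irf(dk1)) * 1000.0
        g[2] = amplitude * (1 - alpha1) * float(r @ conv_with_irf(dk2)) * 1000.0
        g[3] = float(r @ (m - offset))    # d/d ln A
        g[4] = float(r.sum()) if opts.fit_offset else 0.0
        return f, g

    basis = _basis or _ConvBasis(irf, opts)
    a1_0, tau1_0, tau2_0, amp_0, offset_0 = basis.best_start(
        counts, objective, opts.fit_offset)
    tau1_0 = float(np.clip(tau1_0, *opts.tau1_bounds))
    tau2_0 = float(np.clip(tau2_0, *opts.tau2_bounds))

    x0 = np.array([a1_0, tau1_0 / 1000.0, tau2_0 / 1000.0,
                   np.log(amp_0), offset_0])
    bounds = [
        (0.0, 1.0),
        (opts.tau1_bounds[0] / 1000.0, opts.tau1_bounds[1] / 1000.0),
        (opts.tau2_bounds[0] / 1000.0, opts.tau2_bounds[1] / 1000.0),
        (np.log(amp_0) - 10.0, np.log(amp_0) + 10.0),
        (0.0, max(1.0, float(counts.max()))),
    ]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(fun_and_grad, x0, jac=True,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": opts.max_iter})
    # keep whichever of {grid start, polished point} scores better
    if np.isfinite(res.fun) and res.fun <= fun(x0):
        alpha1, tau1, tau2, amplitude, offset = unpack(res.x)
        converged = bool(res.success)
    else:
        alpha1, tau1, tau2, amplitude, offset = (a1_0, tau1_0, tau2_0,
                                                 amp_0, offset_0)
        converged = False
    if tau1 > tau2:  # enforce the ordering convention
        tau1, tau2 = tau2, tau1
        alpha1 = 1.0 - alpha1
    alpha2 = 1.0 - alpha1
    model = forward(alpha1, tau1, tau2, amplitude, offset)
    n_free = 5 if opts.fit_offset else 4
    dof = max(n - n_free, 1)
    chi2 = neyman_chi2(model, counts) / dof
    return FitParams(alpha1=alpha1, alpha2=alpha2, tau1=tau1, tau2=tau2,
                     offset=offset, amplitude=amplitude,
                     tau_m=mean_lifetime(alpha1, tau1, alpha2, tau2),
                     chi2_reduced=chi2, converged=converged, valid=True)


def fit_image(cube: DecayCube, irf: IRFCurve, bin_level: int = 1,
              options: FitOptions | None = None) -> LifetimeMaps:
    """Fit every pixel of a decay cube after spatial binning.

    Binning (``bin_level`` 1 → 3×3) pools neighboring histograms to reach
    usable photon statistics before fitting; the intensity map is always
    integrated from the *unbinned* cube. Pixels below the photon threshold
    after binning are flagged invalid.
    """
    opts = options or FitOptions()
    binned = bin_pixels(cube, bin_level)
    ny, nx = cube.shape
    maps = {name: np.full((ny, nx), np.nan)
            for name in ("alpha1", "alpha2", "tau1", "tau2", "tau_m",
                         "offset", "chi2")}
    valid = np.zeros((ny, nx), dtype=bool)
    totals = binned.counts.sum(axis=2)
    for y, x in zip(*np.nonzero(totals >= opts.min_photons)):
        p = fit_pixel(binned.counts[y, x], irf, opts)
        if not p.valid:
            continue
        valid[y, x] = True
        maps["alpha1"][y, x] = p.alpha1
        maps["alpha2"][y, x] = p.alpha2
        maps["tau1"][y, x] = p.tau1
        maps["tau2"][y, x] = p.tau2
        maps["tau_m"][y, x] = p.tau_m
        maps["offset"][y, x] = p.offset
        maps["chi2"][y, x] = p.chi2_reduced
    return LifetimeMaps(alpha1=maps["alpha1"], alpha2=maps["alpha2"],
                        tau1=maps["tau1"], tau2=maps["tau2"],
                        tau_m=maps["tau_m"], offset=maps["offset"],
                        intensity=cube.intensity().astype(float),
                        chi2=maps["chi2"], valid=valid,
                        channel=cube.channel, bin_level=bin_level)
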