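"""Synthetic two-channel FLIM data with known ground truth.

This module stands in for both the microscope and the biological
experiment: it renders fields of disk-shaped cells whose NAD(P)H and FAD
decay parameters are drawn from condition-dependent metabolic profiles,
produces Poisson-noise TCSPC decay cubes through the same forward model the
fitter inverts, and generates single-cell feature tables with a controlled
low/high differentiation-efficiency class structure.

Everything is deterministic given the master seed: child generators are
spawned per cell and per channel through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cells import OMI_VARIABLES, binarize_condition
from .core import (DEFAULT_N_BINS, DEFAULT_PERIOD_PS, FAD, NADPH, DecayCube,
                   IRFCurve, TimeAxis)
from .decay import decay_kernel, mean_lifetime

__all__ = [
    "MetabolicProfile", "SceneSpec", "GroundTruth", "ConditionSpec",
    "synth_irf", "generate_decay_cube", "generate_feature_table",
    "default_profiles", "profiles_for_efficiency",
    "baseline_omi_mean", "baseline_omi_cov", "make_condition_spec",
]


@dataclass(frozen=True)
class MetabolicProfile:
    """Generative ground truth for one channel's two-component decay.

    ``alpha1`` is the fractional contribution of the short component
    (free NAD(P)H; protein-bound FAD), lifetimes are in picoseconds,
    ``offset_rate`` is the background count rate per time bin, and
    ``photons_per_pixel`` the mean total signal photons in a foreground
    pixel. ``intensity_cv`` sets the per-cell brightness spread.
    """

    channel: str
    alpha1_mean: float
    alpha1_sd: float
    tau1_mean: float
    tau1_sd: float
    tau2_mean: float
    tau2_sd: float
    offset_rate: float = 0.01
    photons_per_pixel: float = 5000.0
    intensity_cv: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha1_mean < 1.0:
            raise ValueError("alpha1 mean must lie in (0, 1)")
        if not self.tau1_mean < self.tau2_mean:
            raise ValueError("tau1 must be strictly less than tau2")
        for name in ("alpha1_sd", "tau1_sd", "tau2_sd", "offset_rate",
                     "intensity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")


def default_profiles() -> dict[str, MetabolicProfile]:
    """Baseline hPSC-like metabolic profiles for the two channels.

    Values are typical of cultured-cell autofluorescence: free NAD(P)H
    dominates (α₁ ≈ 0.75, τ₁ ≈ 400 ps, τ₂ ≈ 2500 ps) and FAD shows the
    reversed convention with its short, protein-bound component first.
    """
    return {
        NADPH: MetabolicProfile(NADPH, alpha1_mean=0.75, alpha1_sd=0.02,
                                tau1_mean=400.0, tau1_sd=20.0,
                                tau2_mean=2500.0, tau2_sd=100.0,
                                photons_per_pixel=5000.0),
        FAD: MetabolicProfile(FAD, alpha1_mean=0.65, alpha1_sd=0.02,
                              tau1_mean=300.0, tau1_sd=15.0,
                              tau2_mean=2300.0, tau2_sd=100.0,
                              photons_per_pixel=2500.0),
    }


def profiles_for_efficiency(efficiency: float) -> dict[str, MetabolicProfile]:
    """Condition-dependent profile shift along the efficiency axis.

    High-efficiency conditions are modeled as shifted toward a more
    glycolytic day-1 state: larger free-NAD(P)H fraction (lower NAD(P)H
    τ_m) and brighter NAD(P)H relative to FAD (higher redox ratio). The
    shift interpolates linearly in efficiency between the low (0%) and
    high (100%) archetypes.
    """
    f = float(np.clip(efficiency, 0.0, 100.0)) / 100.0
    base = default_profiles()
    nadph = replace(base[NADPH],
                    alpha1_mean=base[NADPH].alpha1_mean + 0.08 * f,
                    photons_per_pixel=base[NADPH].photons_per_pixel
                    * (1.0 + 0.3 * f))
    fad = replace(base[FAD],
                  alpha1_mean=base[FAD].alpha1_mean + 0.04 * f)
    return {NADPH: nadph, FAD: fad}


@dataclass
class SceneSpec:
    """Layout and biology of one synthetic two-channel field of view."""

    shape: tuple[int, int] = (128, 128)
    n_cells: int = 12
    radius_range: tuple[float, float] = (7.0, 11.0)
    nucleus_radius_fraction: float = 0.0
    nucleus_dimming: float = 0.3
    profiles: dict[str, MetabolicProfile] = field(default_factory=default_profiles)
    efficiency: float = 50.0
    seed: int = 0
    overlap_tolerance: float = 0.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("image shape must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must lie in [0, 1)")

    @property
    def condition_class(self) -> str:
        return binarize_condition(self.efficiency)


@dataclass
class GroundTruth:
    """True label mask and per-cell parameter table for one scene."""

    mask: np.ndarray          # integer cell id per pixel, 0 = background
    table: pd.DataFrame       # one row per cell id, per-channel truth

    def __post_init__(self) -> None:
        ids = set(np.unique(self.mask)) - {0}
        if ids != set(self.table["cell_id"]):
            raise ValueError("mask ids and truth table rows must match 1:1")


def synth_irf(fwhm_ps: float, center_ps: float,
              n_bins: int = DEFAULT_N_BINS,
              bin_width_ps: float = DEFAULT_PERIOD_PS / DEFAULT_N_BINS) -> IRFCurve:
    """Discretized Gaussian instrument response, normalized to unit sum.

    Emulates the measured response of a TCSPC system (in practice acquired
    from second-harmonic generation, which is temporally instantaneous).
    """
    if fwhm_ps <= 0:
        raise ValueError("fwhm must be positive")
    axis = TimeAxis(n_bins=n_bins, bin_width_ps=bin_width_ps)
    if not 0 <= center_ps <= axis.period_ps:
        raise ValueError("center must lie within the time window")
    if fwhm_ps < bin_width_ps:
        warnings.warn("IRF FWHM below one bin width: effectively a delta",
                      stacklevel=2)
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = axis.centers
    v = np.exp(-0.5 * ((t - center_ps) / sigma) ** 2)
    total = v.sum()
    if total <= 0:  # center so far out every sample underflowed
        idx = int(np.argmin(np.abs(t - center_ps)))
        v = np.zeros(n_bins)
        v[idx] = 1.0
        return IRFCurve(v, axis)
    return IRFCurve(v / total, axis)


def _place_cells(scene: SceneSpec, rng: np.random.Generator,
                 max_tries: int = 20000) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk centers and radii."""
    ny, nx = scene.shape
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < scene.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {scene.n_cells} non-overlapping cells in a "
                f"{ny}x{nx} image; reduce n_cells or radii")
        r = rng.uniform(*scene.radius_range)
        cy = rng.uniform(r, ny - r)
        cx = rng.uniform(r, nx - r)
        ok = all((cy - py) ** 2 + (cx - px) ** 2
                 >= (r + pr - scene.overlap_tolerance) ** 2
                 for py, px, pr in placed)
        if ok:
            placed.append((cy, cx, r))
    return placed


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_decay_cube(scene: SceneSpec, irf: IRFCurve
                        ) -> tuple[dict[str, DecayCube], GroundTruth]:
    """Render a scene into per-channel TCSPC decay cubes plus ground truth.

    Per pixel the expected histogram is
    ``amplitude × (IRF ⊛ [α₁e^(−t/τ₁) + α₂e^(−t/τ₂)]) + offset`` scaled so
    a foreground pixel's expected signal photons equal the cell's drawn
    brightness; counts are independent Poisson draws. Background pixels
    carry offset-only noise. Parameters are constant within a cell — the
    cell is the biological unit of the downstream analysis.
    """
    axis = irf.axis
    if not np.isclose(irf.values.sum(), 1.0, atol=1e-9):
        raise ValueError("IRF must be normalized to unit sum")
    if axis.n_bins < 16:
        raise ValueError("need at least 16 time bins")
    if not scene.periodic:
        for prof in scene.profiles.values():
            if prof.tau2_mean > axis.period_ps:
                raise ValueError(
                    "tau2 exceeds the laser period; enable periodic "
                    "wrap-around (scene.periodic=True) to model the "
                    "incomplete decay")

    ss = np.random.SeedSequence(scene.seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    disks = _place_cells(scene, layout_rng)

    ny, nx = scene.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros((ny, nx), dtype=np.int32)
    nucleus = np.zeros((ny, nx), dtype=bool)
    for cid, (cy, cx, r) in enumerate(disks, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask[d2 <= r ** 2] = cid
        if scene.nucleus_radius_fraction > 0:
            nucleus |= d2 <= (scene.nucleus_radius_fraction * r) ** 2

    channels = sorted(scene.profiles)
    cell_seeds = ss.spawn(scene.n_cells * len(channels) + len(channels))
    cubes: dict[str, DecayCube] = {}
    rows = []
    irf_fft = np.fft.rfft(irf.values)

    for ci, channel in enumerate(channels):
        prof = scene.profiles[channel]
        expected = np.full((ny, nx, axis.n_bins), prof.offset_rate)
        truth: dict[int, dict[str, float]] = {}
        for cid in range(1, scene.n_cells + 1):
            rng = np.random.default_rng(
                cell_seeds[(cid - 1) * len(channels) + ci])
            a1 = _truncnorm(rng, prof.alpha1_mean, prof.alpha1_sd, 0.0, 1.0)
            t1 = _truncnorm(rng, prof.tau1_mean, prof.tau1_sd,
                            1.0, prof.tau2_mean)
            t2 = _truncnorm(rng, prof.tau2_mean, prof.tau2_sd,
                            t1, 50.0 * prof.tau2_mean)
            photons = prof.photons_per_pixel * _truncnorm(
                rng, 1.0, prof.intensity_cv, 0.05, 5.0)
            kernel = decay_kernel(a1, t1, t2, axis, periodic=scene.periodic)
            if scene.periodic:
                shape = np.fft.irfft(np.fft.rfft(kernel) * irf_fft,
                                     n=axis.n_bins)
            else:
                shape = np.convolve(kernel, irf.values)[: axis.n_bins]
            shape = np.clip(shape, 0.0, None)
            curve = photons * shape / shape.sum()
            in_cell = mask == cid
            dim = in_cell & nucleus
            expected[in_cell & ~nucleus] += curve
            if dim.any():
                expected[dim] += scene.nucleus_dimming * curve
            truth[cid] = {"alpha1": a1, "tau1": t1, "tau2": t2,
                          "intensity": photons,
                          "tau_m": mean_lifetime(a1, t1, 1.0 - a1, t2)}
        noise_rng = np.random.default_rng(
            cell_seeds[scene.n_cells * len(channels) + ci])
        counts = noise_rng.poisson(expected).astype(np.int64)
        cubes[channel] = DecayCube(counts, axis, channel,
                                   meta={"efficiency": scene.efficiency,
                                         "seed": scene.seed})
        for cid, tr in truth.items():
            rows.append({"cell_id": cid, "channel": channel, **tr})

    table = pd.DataFrame(rows)
    if not table.empty:
        wide = table.pivot(index="cell_id", columns="channel")
        flat = pd.DataFrame(index=wide.index)
        for (var, channel) in wide.columns:
            prefix = "nadph" if channel == NADPH else channel.lower()
            flat[f"{prefix}_{var}"] = wide[(var, channel)]
        for col in list(flat.columns):
            if col.endswith("_alpha1"):
                flat[col.replace("_alpha1", "_alpha2")] = 1.0 - flat[col]
        if {"nadph_intensity", "fad_intensity"} <= set(flat.columns):
            flat["redox_ratio"] = flat["nadph_intensity"] / flat["fad_intensity"]
        flat = flat.reset_index()
    else:
        flat = pd.DataFrame({"cell_id": []})
    return cubes, GroundTruth(mask=mask, table=flat)


# ---------------------------------------------------------------------------
# Cell-level feature-table generation (stands in for the full imaging
# pipeline when only the multivariate stage is under study).

#: Baseline means for the 13 single-cell OMI variables, matching the
#: channel profiles above (lifetimes ps, intensities in photons/pixel).
_BASELINE_MEAN = {
    "redox_ratio": 2.0,
    "nadph_intensity": 5000.0, "nadph_tau1": 400.0, "nadph_tau2": 2500.0,
    "nadph_alpha1": 0.75, "nadph_alpha2": 0.25, "nadph_tau_m": 925.0,
    "fad_intensity": 2500.0, "fad_tau1": 300.0, "fad_tau2": 2300.0,
    "fad_alpha1": 0.65, "fad_alpha2": 0.35, "fad_tau_m": 1000.0,
}

#: Cell-to-cell standard deviations (same units as the means).
_BASELINE_SD = {
    "redox_ratio": 0.3,
    "nadph_intensity": 800.0, "nadph_tau1": 40.0, "nadph_tau2": 200.0,
    "nadph_alpha1": 0.03, "nadph_alpha2": 0.03, "nadph_tau_m": 80.0,
    "fad_intensity": 500.0, "fad_tau1": 30.0, "fad_tau2": 180.0,
    "fad_alpha1": 0.03, "fad_alpha2": 0.03, "fad_tau_m": 70.0,
}


def baseline_omi_mean() -> np.ndarray:
    """Baseline 13-variable mean vector in :data:`OMI_VARIABLES` order."""
    return np.array([_BASELINE_MEAN[v] for v in OMI_VARIABLES])


def baseline_omi_cov() -> np.ndarray:
    """Diagonal covariance with realistic per-variable spreads."""
    return np.diag(np.array([_BASELINE_SD[v] for v in OMI_VARIABLES]) ** 2)


@dataclass
class ConditionSpec:
    """One differentiation condition's feature distribution."""

    efficiency: float
    mean: np.ndarray
    cov: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(OMI_VARIABLES)
        if self.mean.shape != (k,):
            raise ValueError(f"mean must have length {k}")
        if self.cov.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("covariance must be positive semidefinite")
        if self.name is None:
            self.name = f"eff_{self.efficiency:g}"


def make_condition_spec(efficiency: float,
                        shift: dict[str, float] | None = None,
                        name: str | None = None) -> ConditionSpec:
    """Baseline condition with optional per-variable mean shifts.

    ``shift`` maps variable names to offsets in units of that variable's
    baseline SD (so ``{"nadph_tau_m": 5.0}`` moves NAD(P)H τ_m by five
    standard deviations).
    """
    mean = baseline_omi_mean().copy()
    if shift:
        for var, n_sd in shift.items():
            i = OMI_VARIABLES.index(var)
            mean[i] += n_sd * _BASELINE_SD[var]
    return ConditionSpec(efficiency=efficiency, mean=mean,
                         cov=baseline_omi_cov(), name=name)


def generate_feature_table(n_cells_per_condition: int,
                           conditions: list[ConditionSpec],
                           seed: int = 0,
                           n_datasets: int = 2) -> pd.DataFrame:
    """Draw single-cell OMI feature tables with class structure.

    Cells are multivariate-normal draws per condition, clipped to physical
    ranges (fractions to [0, 1], lifetimes and intensities positive); the
    α₂ columns are then set to 1 − α₁ so every record satisfies the
    unit-sum constraint. Each condition's cells are split evenly across
    ``n_datasets`` replicate ids (independent biological replicates in the
    study design), and the binary class follows the ≥ 50 % efficiency rule.
    """
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    ss = np.random.SeedSequence(seed)
    frames = []
    for spec, child in zip(conditions, ss.spawn(len(conditions))):
        rng = np.random.default_rng(child)
        x = rng.multivariate_normal(spec.mean, spec.cov,
                                    size=n_cells_per_condition,
                                    method="svd")
        df = pd.DataFrame(x, columns=OMI_VARIABLES)
        for var in OMI_VARIABLES:
            if var.endswith(("alpha1", "alpha2")):
                df[var] = df[var].clip(0.0, 1.0)
            else:
                df[var] = df[var].clip(lower=1e-6)
        for ch in ("nadph", "fad"):
            df[f"{ch}_alpha2"] = 1.0 - df[f"{ch}_alpha1"]
        df["condition"] = spec.name
        df["efficiency"] = spec.efficiency
        df["efficiency_class"] = binarize_condition(spec.efficiency)
        df["day"] = 1
        df["cell_line"] = "synthetic"
        df["dataset"] = (np.arange(n_cells_per_condition)
                         % n_datasets) + 1
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "cell_id", np.arange(len(out)))
    return out
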