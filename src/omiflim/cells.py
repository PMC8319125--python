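"""Cytoplasm segmentation and single-cell OMI feature extraction.

Cells are segmented on the NAD(P)H intensity image (global threshold →
connected components → distance-transform watershed to split touching
cells) and each labeled cytoplasm is summarized into the 13 optical
metabolic imaging variables: the optical redox ratio plus, per channel
(NAD(P)H and FAD), intensity, τ₁, τ₂, α₁, α₂ and the mean lifetime
τ_m = α₁τ₁ + α₂τ₂.

Lifetime-component semantics differ per channel — for NAD(P)H the short
component τ₁ is the free co-enzyme, for FAD the convention is reversed
(τ₁ protein-bound, τ₂ free) — but both are stored under the same ordered
column names; interpretation is the reader's concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .core import LifetimeMaps

logger = logging.getLogger(__name__)

#: The 13 OMI variables, fixed order and names, one row per cell cytoplasm.
OMI_VARIABLES = [
    "redox_ratio",
    "nadph_intensity", "nadph_tau1", "nadph_tau2",
    "nadph_alpha1", "nadph_alpha2", "nadph_tau_m",
    "fad_intensity", "fad_tau1", "fad_tau2",
    "fad_alpha1", "fad_alpha2", "fad_tau_m",
]

#: Named variable subsets used in classifier comparisons.
VARIABLE_SUBSETS: dict[str, list[str]] = {
    "all": list(OMI_VARIABLES),
    "nadph_lifetime": ["nadph_tau_m", "nadph_tau2", "nadph_alpha2",
                       "nadph_alpha1", "nadph_tau1"],
    "fad_lifetime": ["fad_tau_m", "fad_tau2", "fad_alpha2",
                     "fad_alpha1", "fad_tau1"],
    "both_tau_m": ["nadph_tau_m", "fad_tau_m"],
    "nadph_tau_m": ["nadph_tau_m"],
}


def binarize_condition(efficiency: float) -> str:
    """Binary efficiency class: ``"high"`` iff cTnT+ efficiency ≥ 50 %."""
    if not 0.0 <= efficiency <= 100.0:
        raise ValueError(f"efficiency must be in [0, 100], got {efficiency}")
    return "high" if efficiency >= 50.0 else "low"


@dataclass(frozen=True)
class ConditionLabel:
    """Condition metadata attached to every cell record."""

    efficiency: float
    name: str = ""
    day: int = 1
    cell_line: str = ""
    dataset: int = 1

    @property
    def condition_class(self) -> str:
        return binarize_condition(self.efficiency)


@dataclass
class CellMask:
    """Labeled cytoplasm image: integer cell id per pixel, 0 = background."""

    labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D image")
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("cell ids must be contiguous from 1")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


@dataclass
class SegmentationParams:
    threshold: float | None = None     # None → Otsu on nonzero histogram
    min_area: int = 20                 # pixels
    max_area: int | None = None
    split_touching: bool = True
    min_peak_distance: int = 5
    exclude_nucleus: bool = False
    nucleus_dip_fraction: float = 0.5  # interior pixels dimmer than this
                                       # fraction of the cell median → nucleus


def segment_cytoplasm(intensity: np.ndarray,
                      params: SegmentationParams | None = None) -> CellMask:
    """Segment cell cytoplasms on an NAD(P)H intensity image.

    Global threshold (Otsu by default), connected components, then a
    distance-transform watershed to split touching cells; components
    outside the configured area limits are dropped and ids relabeled
    contiguously. A blank image yields an empty mask, not an error.
    """
    p = params or SegmentationParams()
    img = np.asarray(intensity, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity must be a 2D image")
    if np.any(img < 0):
        raise ValueError("intensity must be non-negative")

    if p.threshold is not None:
        thr = p.threshold
    else:
        finite = img[np.isfinite(img)]
        if finite.size == 0 or finite.max() == finite.min():
            return CellMask(np.zeros(img.shape, dtype=np.int32),
                            {"threshold": None, "params": vars(p)})
        thr = float(threshold_otsu(finite))
    fg = img > thr
    if not fg.any():
        return CellMask(np.zeros(img.shape, dtype=np.int32),
                        {"threshold": thr, "params": vars(p)})

    if p.min_area > 1:  # drop specks before seeding the watershed
        cc = cc_label(fg, connectivity=1)
        areas = np.bincount(cc.ravel())
        fg &= ~(areas < p.min_area)[cc]

    if p.split_touching:
        dist = ndimage.distance_transform_edt(fg)
        # seed the watershed from smoothed distance maxima
        smooth = ndimage.gaussian_filter(dist, sigma=1.0)
        maxi = (smooth == ndimage.maximum_filter(
            smooth, size=2 * p.min_peak_distance + 1)) & fg & (dist > 1)
        markers, _ = ndimage.label(maxi)
        if markers.max() == 0:
            labels = cc_label(fg, connectivity=1)
        else:
            labels = watershed(-dist, markers, mask=fg)
    else:
        labels = cc_label(fg, connectivity=1)

    if p.exclude_nucleus:
        for cid in range(1, labels.max() + 1):
            cell = labels == cid
            med = np.median(img[cell])
            interior = cell & ndimage.binary_erosion(cell, iterations=2)
            dip = interior & (img < p.nucleus_dip_fraction * med)
            labels[dip] = 0

    # area filter + contiguous relabeling
    areas = np.bincount(labels.ravel())
    drop = np.zeros(areas.size, dtype=bool)
    drop[1:] = areas[1:] < p.min_area
    if p.max_area is not None:
        drop[1:] |= areas[1:] > p.max_area
    labels[drop[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    return CellMask(labels.astype(np.int32),
                    {"threshold": thr, "params": vars(p)})


def redox_ratio_map(nadph_intensity: np.ndarray,
                    fad_intensity: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel optical redox ratio NAD(P)H / FAD with a validity mask.

    Pixels where FAD intensity is zero are flagged invalid (NaN in the
    ratio image) rather than producing infinities; they are excluded from
    cell-level aggregation.
    """
    n = np.asarray(nadph_intensity, dtype=float)
    f = np.asarray(fad_intensity, dtype=float)
    if n.shape != f.shape:
        raise ValueError("channel images must share the same shape")
    valid = f > 0
    ratio = np.full(n.shape, np.nan)
    np.divide(n, f, out=ratio, where=valid)
    return ratio, valid


def _masked_mean(values: np.ndarray, where: np.ndarray,
                 statistic: str) -> float:
    v = values[where]
    if v.size == 0:
        return float("nan")
    return float(np.median(v) if statistic == "median" else np.mean(v))


def extract_features(mask: CellMask,
                     nadph_maps: LifetimeMaps,
                     fad_maps: LifetimeMaps,
                     label: ConditionLabel,
                     min_valid_pixels: int = 25,
                     statistic: str = "mean") -> pd.DataFrame:
    """Aggregate per-pixel maps into 13-variable single-cell records.

    Each variable is the mean (or median) over the cell's valid cytoplasm
    pixels; the redox ratio is averaged per pixel (ratio first, then
    aggregate — a ratio-of-means column ``redox_ratio_of_means`` is kept
    for sensitivity checks). Cells with fewer than ``min_valid_pixels``
    jointly-valid pixels are dropped with a log entry. The QC column
    ``tau_m_qc`` reports |τ_m − (α₁τ₁ + α₂τ₂)| evaluated on the aggregated
    NAD(P)H values; it is nonzero only because aggregation and the τ_m
    product do not commute, and should stay small for homogeneous cells.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if nadph_maps.shape != mask.labels.shape or fad_maps.shape != mask.labels.shape:
        raise ValueError("maps and mask must share geometry")

    ratio, ratio_valid = redox_ratio_map(nadph_maps.intensity,
                                         fad_maps.intensity)
    joint_valid = nadph_maps.valid & fad_maps.valid & ratio_valid
    records = []
    for cid in range(1, mask.n_cells + 1):
        cell = mask.labels == cid
        ok = cell & joint_valid
        n_valid = int(ok.sum())
        if n_valid < min_valid_pixels:
            logger.info("cell %d dropped: %d valid pixels (< %d)",
                        cid, n_valid, min_valid_pixels)
            continue
        rec: dict[str, Any] = {"cell_id": cid, "n_pixels": int(cell.sum()),
                               "n_valid_pixels": n_valid}
        rec["redox_ratio"] = _masked_mean(ratio, ok, statistic)
        rec["redox_ratio_of_means"] = (
            _masked_mean(nadph_maps.intensity, ok, statistic)
            / _masked_mean(fad_maps.intensity, ok, statistic))
        for prefix, maps in (("nadph", nadph_maps), ("fad", fad_maps)):
            rec[f"{prefix}_intensity"] = _masked_mean(maps.intensity, ok,
                                                      statistic)
            for var in ("tau1", "tau2", "alpha1", "alpha2", "tau_m"):
                rec[f"{prefix}_{var}"] = _masked_mean(
                    getattr(maps, var), ok, statistic)
        rec["tau_m_qc"] = abs(
            rec["nadph_tau_m"] - (rec["nadph_alpha1"] * rec["nadph_tau1"]
                                  + rec["nadph_alpha2"] * rec["nadph_tau2"]))
        rec.update(condition=label.name, efficiency=label.efficiency,
                   efficiency_class=label.condition_class, day=label.day,
                   cell_line=label.cell_line, dataset=label.dataset)
        records.append(rec)
    columns = (["cell_id", "n_pixels", "n_valid_pixels"] + OMI_VARIABLES
               + ["redox_ratio_of_means", "tau_m_qc", "condition",
                  "efficiency", "efficiency_class", "day", "cell_line",
                  "dataset"])
    return pd.DataFrame(records, columns=columns)


def validate_records(records: pd.DataFrame, atol: float = 1e-6) -> None:
    """Full-table invariant scan; raises on the first violation."""
    missing = [v for v in OMI_VARIABLES if v not in records.columns]
    if missing:
        raise ValueError(f"missing OMI variables: {missing}")
    for ch in ("nadph", "fad"):
        a1, a2 = records[f"{ch}_alpha1"], records[f"{ch}_alpha2"]
        if ((a1 < -atol) | (a1 > 1 + atol)).any():
            raise ValueError(f"{ch}_alpha1 outside [0, 1]")
        if (np.abs(a1 + a2 - 1.0) > atol).any():
            raise ValueError(f"{ch} fractional contributions do not sum to 1")
        for var in ("tau1", "tau2", "tau_m"):
            if (records[f"{ch}_{var}"] <= 0).any():
                raise ValueError(f"{ch}_{var} must be positive")
    if (records["redox_ratio"] < 0).any():
        raise ValueError("redox ratio must be non-negative")
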