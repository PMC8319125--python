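"""Readers and writers for the formats the pipeline exchanges.

* ASC — whitespace-delimited plain-text matrices, one value per pixel
  (the export dialect of commercial FLIM fitting software); lossless
  float round trip.
* HDF5 decay cubes — datasets ``counts`` (y, x, t) with time-axis and
  channel metadata as attributes; optional multi-page TIFF of time bins
  with a JSON sidecar.
* TIFF — 16-bit label masks and 32-bit float variable maps.

Images are row-major with the origin at the top-left pixel, (row=y, col=x).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import DecayCube, LifetimeMaps, TimeAxis

__all__ = [
    "read_asc_matrix", "write_asc_matrix",
    "read_cube_h5", "write_cube_h5",
    "read_cube_tiff", "write_cube_tiff",
    "read_label_tiff", "write_label_tiff", "write_map_tiff",
    "write_maps_asc",
]


def write_asc_matrix(image: np.ndarray, path: str | Path) -> None:
    """Write a 2D matrix as whitespace-delimited text at full precision."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("ASC export expects a 2D matrix")
    # %.17g preserves float64 exactly through a text round trip
    np.savetxt(path, image, fmt="%.17g", delimiter=" ")


def read_asc_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited numeric matrix; reject ragged rows."""
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value on row {lineno}") from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path}: ragged row {lineno} has {len(values)} values, "
                    f"expected {width}")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty ASC file")
    return np.array(rows, dtype=float)


def write_cube_h5(cube: DecayCube, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=cube.counts, compression="gzip")
        d.attrs["bin_width_ps"] = cube.axis.bin_width_ps
        d.attrs["n_bins"] = cube.axis.n_bins
        d.attrs["channel"] = cube.channel
        f.create_dataset("time_ps", data=cube.axis.centers)
        if cube.meta:
            f.attrs["meta"] = json.dumps(cube.meta, default=str)


def read_cube_h5(path: str | Path) -> DecayCube:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        axis = TimeAxis(n_bins=int(d.attrs["n_bins"]),
                        bin_width_ps=float(d.attrs["bin_width_ps"]))
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
        return DecayCube(d[()], axis, str(d.attrs["channel"]), meta)


def write_cube_tiff(cube: DecayCube, path: str | Path) -> None:
    """Multi-page TIFF, one page per time bin, with a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.counts, 2, 0).astype(np.uint32)
    tifffile.imwrite(path, pages)
    sidecar = {"bin_width_ps": cube.axis.bin_width_ps,
               "n_bins": cube.axis.n_bins, "channel": cube.channel,
               "meta": cube.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, default=str))


def read_cube_tiff(path: str | Path) -> DecayCube:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    axis = TimeAxis(n_bins=int(sidecar["n_bins"]),
                    bin_width_ps=float(sidecar["bin_width_ps"]))
    return DecayCube(np.moveaxis(pages, 0, 2).astype(np.int64), axis,
                     str(sidecar["channel"]), sidecar.get("meta", {}))


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_map_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_maps_asc(maps: LifetimeMaps, directory: str | Path,
                   prefix: str = "") -> list[Path]:
    """One ASC matrix per fitted variable, plus float TIFF copies.

    The validity mask is exported alongside (``*_valid.asc``, 0/1) so the
    maps can be reloaded without treating the NaN→0 fill as data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    exports = dict(maps.as_dict())
    exports["valid"] = maps.valid.astype(float)
    for name, image in exports.items():
        stem = f"{prefix}{maps.channel.lower()}_{name}"
        asc = directory / f"{stem}.asc"
        write_asc_matrix(np.nan_to_num(image, nan=0.0), asc)
        write_map_tiff(image, directory / f"{stem}.tif")
        written.append(asc)
    return written


def read_maps_asc(directory: str | Path, channel: str,
                  bin_level: int = 0) -> LifetimeMaps:
    """Reload a :class:`LifetimeMaps` from a `write_maps_asc` directory."""
    directory = Path(directory)
    prefix = channel.lower()
    def load(name):
        return read_asc_matrix(directory / f"{prefix}_{name}.asc")
    valid = load("valid") > 0.5
    fields = {name: load(name) for name in
              ("alpha1", "alpha2", "tau1", "tau2", "tau_m", "offset",
               "intensity", "chi2")}
    for name, image in fields.items():
        if name != "intensity":
            image[~valid] = np.nan
    return LifetimeMaps(**fields, valid=valid, channel=channel,
                        bin_level=bin_level)
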