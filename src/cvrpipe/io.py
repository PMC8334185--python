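"""Readers and writers for the formats the pipeline touches.

Physiological traces travel as comma-separated text with a header row and
a ``time`` column in seconds plus ``pco2``, ``po2`` (mmHg) and ``flow``
(L/s) columns.  Volumes are NIfTI-1 (via nibabel); the BOLD TR is read
from the header time zoom (milliseconds are detected and converted).
Parcellation lookups are two-column TSV (label, name).
"""

from __future__ import annotations

import logging

import nibabel as nib
import numpy as np
import pandas as pd

from .config import ParcellationVolume, PipelineConfig
from .exceptions import DataError, FormatError
from .physio import FlowTrace, GasTrace
from .preprocess import BoldSeries

log = logging.getLogger(__name__)

PHYSIO_COLUMNS = ("time", "pco2", "po2", "flow")


# ---------------------------------------------------------------------------
# physiological traces
# ---------------------------------------------------------------------------

def read_physio_csv(path, config: PipelineConfig
                    ) -> tuple[GasTrace, GasTrace, FlowTrace]:
    """Read (PCO2, PO2, flow) traces from a physio CSV.

    Requires the documented columns; the time axis must be strictly
    increasing and uniform (gaps larger than twice the nominal sample
    interval are a data error).  Traces are interpolated onto a uniform
    grid at the configured sampling rate.
    """
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in PHYSIO_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    t = frame["time"].to_numpy(dtype=float)
    if t.size < 2 or not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: time column must strictly increase")
    dt = np.diff(t)
    nominal = np.median(dt)
    if np.any(dt > 2 * nominal):
        raise DataError(f"{path}: time gaps exceed 2 sample intervals")
    rate = config.sampling_rate_physio
    grid = np.arange(t[0], t[-1] + 0.5 / rate, 1.0 / rate)

    def onto_grid(col):
        return np.interp(grid, t, frame[col].to_numpy(dtype=float))

    pco2 = GasTrace(onto_grid("pco2"), rate, grid[0], "CO2")
    po2 = GasTrace(onto_grid("po2"), rate, grid[0], "O2")
    flow = FlowTrace(onto_grid("flow"), rate, grid[0])
    return pco2, po2, flow


def write_physio_csv(path, pco2: GasTrace, po2: GasTrace,
                     flow: FlowTrace) -> None:
    pd.DataFrame({
        "time": pco2.times, "pco2": pco2.values,
        "po2": po2.values, "flow": flow.values,
    }).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_bold_nifti(path) -> BoldSeries:
    """Load a 4-D BOLD NIfTI; TR from the header (ms auto-converted)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    units = img.header.get_xyzt_units()[1] if hasattr(img.header,
                                                     "get_xyzt_units") else ""
    if units == "msec" or tr > 100:
        tr /= 1000.0
    if tr <= 0:
        raise FormatError(f"{path}: header lacks a usable TR")
    return BoldSeries(data, tr, tuple(float(z) for z in zooms[:3]))


def write_bold_nifti(series: BoldSeries, path) -> None:
    affine = np.diag(list(series.voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_dims) + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map_nifti(map3d: np.ndarray,
                    voxel_dims: tuple[float, float, float], path) -> None:
    """Write a 3-D map as float32 NIfTI (bit-exact round trip)."""
    map3d = np.asarray(map3d)
    if map3d.ndim != 3:
        raise FormatError("write_map_nifti expects a 3-D map")
    affine = np.diag(list(voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(map3d.astype(np.float32), affine), str(path))


def read_map_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D map")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def write_parcellation(parcellation: ParcellationVolume, nifti_path,
                       lookup_path) -> None:
    affine = np.diag(list(parcellation.voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(parcellation.labels.astype(np.int32), affine),
             str(nifti_path))
    pd.DataFrame(
        sorted(parcellation.lookup.items()),
        columns=["label", "name"],
    ).to_csv(lookup_path, sep="\t", index=False)


def read_parcellation(nifti_path, lookup_path) -> ParcellationVolume:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    if labels.ndim != 3:
        raise FormatError(f"{nifti_path}: parcellation must be 3-D")
    table = pd.read_csv(lookup_path, sep="\t")
    lookup = {int(r["label"]): str(r["name"]) for _, r in table.iterrows()}
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ParcellationVolume(labels, lookup, dims)


# ---------------------------------------------------------------------------
# motion regressors
# ---------------------------------------------------------------------------

def read_motion_regressors(path) -> np.ndarray:
    """Whitespace- or comma-delimited t x k regressor matrix."""
    try:
        arr = np.loadtxt(str(path))
    except ValueError:
        arr = np.loadtxt(str(path), delimiter=",")
    arr = np.asarray(arr, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr
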