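"""BOLD preprocessing: volume discard, polynomial detrend, nuisance
projection, percent-signal-change normalization and masking.

Slice-timing and rigid-body motion *correction* are upstream of this
module (the synthetic generator emits pre-aligned data); only the removal
of supplied motion regressors by orthogonal projection is implemented
here.  The processing order is fixed: discard -> detrend -> nuisance
projection -> percent change, with the percent-change denominator taken
from the raw (pre-detrend) voxel mean for scale stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import legendre

from .config import ParcellationVolume, PipelineConfig
from .exceptions import ConfigError, DataError

log = logging.getLogger(__name__)


@dataclass
class BoldSeries:
    """4-D BOLD array with acquisition metadata.

    Axis order is (x, y, z, t); ``t0`` is the acquisition time of the first
    retained volume.
    """

    data: np.ndarray
    tr: float
    voxel_dims: tuple[float, float, float]
    mask: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError("BOLD data must be 4-D (x, y, z, t)")
        if self.tr <= 0:
            raise DataError("tr must be positive")
        if any(d <= 0 for d in self.voxel_dims):
            raise DataError("voxel_dims must be strictly positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise DataError("mask shape must equal the spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_volumes) * self.tr


@dataclass
class NuisanceSet:
    """Motion (or other nuisance) regressors: a t x k matrix."""

    motion_regressors: np.ndarray
    polynomial_order: int = 5

    def __post_init__(self) -> None:
        self.motion_regressors = np.atleast_2d(
            np.asarray(self.motion_regressors, dtype=float))
        if self.motion_regressors.ndim != 2:
            raise DataError("regressors must form a t x k matrix")


@dataclass
class DeltaBoldSeries:
    """Percent-signal-change BOLD (mean-referenced); NaN outside the mask."""

    data: np.ndarray
    tr: float
    voxel_dims: tuple[float, float, float]
    mask: np.ndarray
    t0: float = 0.0

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def discard_initial_volumes(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (pre-equilibrium magnetization)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.n_volumes:
        raise ValueError(f"cannot discard {n} of {series.n_volumes} volumes")
    if n == 0:
        return series
    return replace(series, data=series.data[..., n:],
                   t0=series.t0 + n * series.tr)


def legendre_basis(t_len: int, order: int) -> np.ndarray:
    """Legendre polynomial design matrix (t_len x (order+1)) on [-1, 1].

    An orthogonal basis keeps the fit well conditioned at several hundred
    time points, unlike raw monomials.
    """
    x = np.linspace(-1.0, 1.0, t_len)
    return legendre.legvander(x, order)


def detrend_polynomial(data: np.ndarray, order: int) -> np.ndarray:
    """Remove a least-squares Legendre polynomial fit along the last axis.

    Works on any array whose last axis is time.  The residual is orthogonal
    to the polynomial basis.
    """
    data = np.asarray(data, dtype=float)
    t_len = data.shape[-1]
    if t_len <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} time points")
    X = legendre_basis(t_len, order)
    flat = data.reshape(-1, t_len).T  # t x v
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return resid.T.reshape(data.shape)


def remove_nuisance(data: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Project nuisance regressors out of time series (last axis = time).

    Regressors are demeaned; linearly dependent columns are dropped with a
    warning.  The operation is an orthogonal projection: idempotent, with
    residuals orthogonal to the regressor column space.
    """
    data = np.asarray(data, dtype=float)
    R = nuisance.motion_regressors
    if R.shape[1] == 0:
        return data.copy()
    t_len = data.shape[-1]
    if R.shape[0] != t_len:
        raise DataError(f"regressors have {R.shape[0]} rows, data has "
                        f"{t_len} time points")
    R = R - R.mean(axis=0)
    q, r, _ = _qr_drop_dependent(R)
    flat = data.reshape(-1, t_len).T
    resid = flat - q @ (q.T @ flat)
    return resid.T.reshape(data.shape)


def _qr_drop_dependent(R: np.ndarray, tol: float = 1e-10):
    """QR with column pivoting; drops near-dependent columns with a warning."""
    q, r, piv = _pivoted_qr(R)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return q[:, :0], r, piv
    keep = diag > tol * max(diag[0], 1.0)
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropped %d linearly dependent nuisance column(s)", n_drop)
    return q[:, keep], r, piv


def _pivoted_qr(R: np.ndarray):
    from scipy.linalg import qr
    q, r, piv = qr(R, mode="economic", pivoting=True)
    return q, r, piv


def to_percent_change(data: np.ndarray, raw_mean: np.ndarray | None = None,
                      mask: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray | None]:
    """Map voxel series to percent change about the raw temporal mean.

    ``100 * (value - mean) / mean`` per voxel.  ``raw_mean`` should be the
    voxel mean of the *raw* (pre-detrend) data; if omitted, the temporal
    mean of ``data`` itself is used.  When ``data`` is already
    mean-removed (detrended), the mapping reduces to ``100 * value / mean``
    about zero; both cases are handled by subtracting the temporal mean of
    ``data`` explicitly.

    Voxels inside the mask with a nonpositive raw mean are excluded from
    the returned mask (count logged) and set NaN; out-of-mask voxels are
    NaN.  Returns (percent-change array, updated mask or None).
    """
    data = np.asarray(data, dtype=float)
    mean_now = data.mean(axis=-1)
    denom = mean_now if raw_mean is None else np.asarray(raw_mean, dtype=float)
    out_mask = None
    bad = ~(denom > 0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        n_bad = int((bad & mask).sum())
        if n_bad:
            log.warning("excluding %d in-mask voxel(s) with nonpositive mean",
                        n_bad)
        out_mask = mask & ~bad
    safe = np.where(bad, 1.0, denom)
    pct = 100.0 * (data - mean_now[..., None]) / safe[..., None]
    if out_mask is not None:
        pct[~out_mask] = np.nan
    elif np.any(bad):
        pct[bad] = np.nan
    return pct, out_mask


def build_mask(parcellation: ParcellationVolume,
               exclude_labels) -> np.ndarray:
    """Boolean brain mask: True wherever the label is not excluded.

    ``exclude_labels`` should contain at least the background label (0) and
    any ventricle labels.
    """
    exclude = np.asarray(sorted(set(int(v) for v in exclude_labels)))
    mask = ~np.isin(parcellation.labels, exclude)
    if not mask.any():
        raise ConfigError("mask is empty after exclusions")
    return mask


def preprocess_bold(series: BoldSeries, nuisance: NuisanceSet | None,
                    config: PipelineConfig,
                    mask: np.ndarray | None = None) -> DeltaBoldSeries:
    """Full preprocessing chain: discard, detrend, project, percent change.

    ``nuisance`` regressors, if given, must cover all input volumes; the
    rows matching discarded volumes are dropped alongside.
    """
    mask = series.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None:
        mask = np.ones(series.data.shape[:3], dtype=bool)
    n = config.n_discard_volumes
    kept = discard_initial_volumes(series, n)
    raw_mean = kept.data.mean(axis=-1)
    clean = detrend_polynomial(kept.data, config.detrend_order)
    if nuisance is not None and nuisance.motion_regressors.shape[1] > 0:
        R = nuisance.motion_regressors
        if R.shape[0] == series.n_volumes:
            R = R[n:]
        clean = remove_nuisance(clean, NuisanceSet(R, config.detrend_order))
    pct, out_mask = to_percent_change(clean, raw_mean=raw_mean, mask=mask)
    return DeltaBoldSeries(pct, kept.tr, kept.voxel_dims, out_mask, kept.t0)
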