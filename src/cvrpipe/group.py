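"""Region-level group inference.

Voxelwise coupling coefficients are Fisher-transformed
(``z = ln[(1+r)/(1-r)]/2``), averaged within each parcellation region per
subject, and modelled per region with ordinary least squares

    z ~ intercept + group + age

Group estimates are reported as linear combinations of the coefficients at
a fixed reference age (50 years), with 95% confidence intervals from the t
distribution; the HD-minus-control difference is the group coefficient
itself.  Unadjusted p-values are corrected across regions with
Benjamini-Hochberg FDR.  The monotone association between regional z and
clinical severity (TFC) is summarized by a partial Spearman correlation
adjusting for age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import ParcellationVolume
from .exceptions import DataError

log = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Variance-stabilizing Fisher transform z = ln[(1+r)/(1-r)]/2.

    Values with 1 - 1e-7 < |r| < 1 are clipped with a warning; |r| >= 1
    raises.  Accepts scalars or arrays (NaN passes through).
    """
    arr = np.asarray(r, dtype=float)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) >= 1.0):
        raise ValueError("|r| >= 1 is outside the Fisher transform domain")
    clipped = np.abs(arr) > _CLIP
    if np.any(clipped & finite):
        warnings.warn(f"clipping {int(np.sum(clipped & finite))} correlation"
                      f" value(s) to |r| = {_CLIP}", stacklevel=2)
        arr = np.clip(arr, -_CLIP, _CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z):
    """Back-transform: r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


# ---------------------------------------------------------------------------
# regional averaging
# ---------------------------------------------------------------------------

def regional_average(zmap: np.ndarray,
                     parcellation: ParcellationVolume) -> pd.Series:
    """Mean of a voxel map within every named region.

    NaN voxels (undefined coupling) are ignored; a region with no defined
    voxel yields NaN with a warning.  Returns a Series indexed by region
    name.
    """
    zmap = np.asarray(zmap, dtype=float)
    if zmap.shape != parcellation.labels.shape:
        raise DataError("map and parcellation grids differ")
    out = {}
    for label in parcellation.region_labels:
        sel = parcellation.labels == label
        vals = zmap[sel]
        vals = vals[np.isfinite(vals)]
        name = parcellation.lookup[label]
        if vals.size == 0:
            log.warning("region %s has no defined voxels", name)
            out[name] = np.nan
        else:
            out[name] = float(vals.mean())
    return pd.Series(out)


def build_region_table(rows: dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-subject regional averages into a subject x region table."""
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# group models
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    """Per-region group statistics (Table-2-shaped)."""

    table: pd.DataFrame  # region-indexed

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True, index_label="region")


def fit_region_models(table: pd.DataFrame, meta: pd.DataFrame,
                      reference_age: float = 50.0,
                      adjust_sex: bool = False) -> GroupResult:
    """Age-adjusted group contrast per region.

    ``table`` is subject x region Fisher z; ``meta`` must carry columns
    ``subject_id``, ``group`` (HD/control) and ``age`` (and ``sex`` when
    ``adjust_sex``), indexed or keyed consistently with the table rows.
    Per region an OLS fit of z on group and age yields control and HD
    estimates at ``reference_age`` with 95% CIs, their difference
    (HD - control), the unadjusted p and the BH-FDR adjusted p across all
    regions.
    """
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns \
        else meta
    if "age" not in meta.columns:
        raise DataError("metadata is missing the 'age' column")
    meta = meta.loc[table.index]
    groups = meta["group"].astype(str).str.lower()
    if not set(groups) <= {"hd", "control"}:
        raise DataError("group labels must be 'HD' or 'control'")
    hd = (groups == "hd").astype(float).to_numpy()
    if hd.sum() < 3 or (1 - hd).sum() < 3:
        raise DataError("need at least 3 subjects per group")
    age = meta["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise DataError("age must not be constant")

    cols = [np.ones_like(age), hd, age]
    names = ["const", "hd", "age"]
    if adjust_sex:
        sex = (meta["sex"].astype(str).str.upper() == "M").astype(float)
        cols.append(sex.to_numpy())
        names.append("sex_male")
    X = np.column_stack(cols)

    l_ctrl = np.zeros(X.shape[1])
    l_ctrl[[0, 2]] = 1.0, reference_age
    l_hd = l_ctrl.copy()
    l_hd[1] = 1.0
    l_diff = np.zeros(X.shape[1])
    l_diff[1] = 1.0

    rows = {}
    for region in table.columns:
        y = table[region].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if keep.sum() < X.shape[1] + 1:
            log.warning("region %s: too few defined subjects, skipped", region)
            continue
        try:
            fit = sm.OLS(y[keep], X[keep]).fit()
        except np.linalg.LinAlgError:  # pragma: no cover
            log.warning("region %s: singular design, skipped", region)
            continue
        if fit.df_resid <= 0 or np.linalg.matrix_rank(X[keep]) < X.shape[1]:
            log.warning("region %s: singular design, skipped", region)
            continue
        row = {}
        for tag, L in (("control", l_ctrl), ("hd", l_hd), ("diff", l_diff)):
            tt = fit.t_test(L)
            lo, hi = np.ravel(tt.conf_int(alpha=0.05))
            row[f"{tag}_est"] = float(np.ravel(tt.effect)[0])
            row[f"{tag}_lo"] = float(lo)
            row[f"{tag}_hi"] = float(hi)
            if tag == "diff":
                row["p"] = float(np.ravel(tt.pvalue)[0])
        rows[region] = row
    out = pd.DataFrame(rows).T
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return GroupResult(out)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# partial Spearman
# ---------------------------------------------------------------------------

def partial_spearman(z, tfc, age) -> tuple[float, float]:
    """Partial Spearman correlation of z with TFC adjusting for age.

    All three variables are rank-transformed (average ranks for ties); the
    age ranks are projected out of the z and TFC ranks (with intercept) and
    the Pearson correlation of the residuals is returned with a p-value
    from the t approximation at n - 3 degrees of freedom.

    Rows with any missing value are dropped; at least 5 complete triples
    are required.  A constant TFC yields (nan, nan) with a warning — the
    operation still runs.
    """
    z = np.asarray(z, dtype=float)
    tfc = np.asarray(tfc, dtype=float)
    age = np.asarray(age, dtype=float)
    keep = np.isfinite(z) & np.isfinite(tfc) & np.isfinite(age)
    z, tfc, age = z[keep], tfc[keep], age[keep]
    n = z.size
    if n < 5:
        raise DataError("need at least 5 complete (z, tfc, age) triples")
    if np.ptp(tfc) == 0:
        warnings.warn("TFC is constant; partial Spearman undefined",
                      stacklevel=2)
        return np.nan, np.nan
    rz = stats.rankdata(z)
    rt = stats.rankdata(tfc)
    ra = stats.rankdata(age)
    X = np.column_stack([np.ones(n), ra])
    res_z = rz - X @ np.linalg.lstsq(X, rz, rcond=None)[0]
    res_t = rt - X @ np.linalg.lstsq(X, rt, rcond=None)[0]
    denom = np.linalg.norm(res_z) * np.linalg.norm(res_t)
    if denom == 0:
        return np.nan, np.nan
    rho = float(np.dot(res_z, res_t) / denom)
    df = n - 3
    rho_c = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    tstat = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(tstat), df))
    return rho, p
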