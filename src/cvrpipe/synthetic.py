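"""Synthetic study generator with known ground truth.

Emulates the full data inventory of a hypercapnic-challenge CVR study —
breath-resolved gas and flow traces, 4-D BOLD with region-specific coupling
and response delay, a toy blocky parcellation, and a two-group cohort with
an HD-like age imbalance — so that every pipeline stage is testable without
any acquisition.

The forward BOLD model is a delayed first-order low-pass response of the
voxel signal to the end-tidal CO2 deviation (a full balloon model is not
needed: the analysis identifies only coupling strength and delay).  The
disease effect is a reduction of the true region-level Fisher z in a
configurable affected-region set (default true HD-minus-control z
difference -0.25, between-subject residual SD 0.12), realized physically
by calibrating each region's BOLD amplitude against the in-band noise so
that the band-limited correlation equals tanh(z); HD subjects additionally
receive a delayed and more variable response in affected regions.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParcellationVolume
from .cvr import bandlimit, finite_noise_gain
from .paradigm import Paradigm, first_order_response
from .physio import FlowTrace, GasTrace
from .preprocess import BoldSeries


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class EffectProfile:
    """Disease effect injected into affected regions of HD subjects."""

    delta_z: float = -0.25          # true HD-control Fisher-z difference
    z_sd: float = 0.12              # between-subject residual SD of z
    n_affected: int = 12            # regions carrying the effect
    delay_shift: float = 2.0        # extra response delay in HD (s)
    delay_jitter_sd: float = 1.0    # HD delay variability in affected regions
    age_slope: float = -0.003       # z change per year, both groups


@dataclass
class GroundTruth:
    """Per-subject generative parameters (one entry of a cohort)."""

    subject_id: str
    group: str                      # "HD" or "control"
    age: float
    sex: str
    tfc: float | None
    resting_petco2: float
    technical_delay: float          # gas analyzer delay (s)
    z_true: np.ndarray              # per-region target Fisher z
    delays: np.ndarray              # per-region response delay (s)
    amplitudes: np.ndarray | None   # %BOLD per mmHg, set by make_bold
    noise_sd_percent: float = 0.5   # BOLD thermal noise SD (% of baseline)
    analyzer_noise_sd: float = 0.5  # gas analyzer noise SD (mmHg)
    flow_noise_sd: float = 0.02     # flow noise SD (L/s)
    breath_rate: float = 12.0       # breaths per minute
    breath_jitter_sd: float = 0.3   # per-breath period jitter (s)
    drift_sd_percent: float = 0.3   # drift polynomial coefficient scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.resting_petco2 <= 50.0):
            raise ValueError("resting_petco2 must lie in [30, 50] mmHg")
        self.z_true = np.asarray(self.z_true, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def _factor3(n: int, shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Split n into three factors roughly proportional to the grid shape."""
    best, score = (n, 1, 1), np.inf
    for a in range(1, n + 1):
        if n % a:
            continue
        for b in range(1, n // a + 1):
            if (n // a) % b:
                continue
            c = n // (a * b)
            dims = np.array([a, b, c], dtype=float)
            tgt = np.array(shape, dtype=float)
            s = np.sum((dims / dims.sum() - tgt / tgt.sum()) ** 2)
            if s < score:
                best, score = (a, b, c), s
    return best


def make_parcellation(grid_shape: tuple[int, int, int] = (24, 24, 12),
                      n_regions: int = 48, seed: int = 0,
                      voxel_dims: tuple[float, float, float] =
                      (3.4375, 3.4375, 6.0),
                      with_ventricle: bool = True) -> ParcellationVolume:
    """Blocky toy parcellation: contiguous regions tiling the interior.

    A one-voxel background shell (label 0) surrounds the tiled interior;
    a small central block is relabelled "ventricle" when requested.  Every
    region keeps at least 8 voxels.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    n_vox = int(np.prod(grid_shape))
    if n_regions > n_vox // 8:
        raise ValueError("n_regions may not exceed voxel count / 8")
    if any(g < 4 for g in grid_shape):
        raise ValueError("grid must be at least 4 voxels per axis")
    labels = np.zeros(grid_shape, dtype=np.int32)
    interior = tuple(slice(1, g - 1) for g in grid_shape)
    inner_shape = tuple(g - 2 for g in grid_shape)
    nx, ny, nz = _factor3(n_regions, inner_shape)
    if any(t > s for t, s in zip((nx, ny, nz), inner_shape)):
        raise ValueError(f"cannot tile {n_regions} regions on grid "
                         f"{grid_shape}")
    xb = np.array_split(np.arange(inner_shape[0]), nx)
    yb = np.array_split(np.arange(inner_shape[1]), ny)
    zb = np.array_split(np.arange(inner_shape[2]), nz)
    inner = np.zeros(inner_shape, dtype=np.int32)
    label = 1
    for xs in xb:
        for ys in yb:
            for zs in zb:
                inner[np.ix_(xs, ys, zs)] = label
                label += 1
    labels[interior] = inner
    lookup = {i: f"region_{i:03d}" for i in range(1, n_regions + 1)}

    if with_ventricle:
        cx, cy, cz = (g // 2 for g in grid_shape)
        vent = (slice(cx - 1, cx + 1), slice(cy - 1, cy + 1),
                slice(cz - 1, cz + 1))
        host = np.unique(labels[vent])
        labels[vent] = n_regions + 1
        lookup[n_regions + 1] = "ventricle"
        for h in host:
            if h > 0 and np.sum(labels == h) < 8:
                raise ValueError("ventricle carve-out left a region with "
                                 "fewer than 8 voxels; enlarge the grid")
    counts = np.bincount(labels.ravel())
    if np.any(counts[1:n_regions + 1] < 8):
        raise ValueError("tiling produced a region with fewer than 8 voxels")
    return ParcellationVolume(labels, lookup, voxel_dims)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(n_hd: int = 12, n_control: int = 11,
                effect: EffectProfile | None = None,
                n_regions: int = 48, seed: int = 0
                ) -> tuple[list[GroundTruth], np.ndarray]:
    """Draw a two-group cohort with HD-like demographics.

    Control ages center on a median near 32 y and HD ages near 51.5 y,
    mirroring the age imbalance of the modelled study; TFC scores for HD
    subjects are drawn in [9, 13] skewed toward 13.  Returns the cohort and
    the (sorted) array of affected region indices (0-based).
    """
    if n_hd < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    effect = EffectProfile() if effect is None else effect
    rng = np.random.default_rng(seed)

    mu_region = rng.uniform(0.55, 0.80, n_regions)
    base_delay = rng.uniform(2.0, 8.0, n_regions)
    n_aff = min(effect.n_affected, n_regions)
    affected = np.sort(rng.choice(n_regions, size=n_aff, replace=False))
    aff_mask = np.zeros(n_regions, dtype=bool)
    aff_mask[affected] = True

    cohort: list[GroundTruth] = []
    # ages taken at stratified quantiles of piecewise-linear quantile
    # functions matching the modelled cohort's demographics: controls
    # median 32 y (IQR 27.5-46, right-skewed, range 22-62), HD median
    # 51.5 y (IQR 47.25-57.25).  The cohort's age structure is a fixed
    # feature of the emulated study, so it is reproduced deterministically
    # (not resampled per seed); the overlap of the two age ranges is what
    # keeps the age-adjusted group contrast identifiable.
    age_quantiles = {
        "control": ([0.0, 0.25, 0.5, 0.75, 1.0],
                    [22.0, 27.5, 32.0, 46.0, 62.0]),
        "HD": ([0.0, 0.25, 0.5, 0.75, 1.0],
               [40.0, 47.25, 51.5, 57.25, 62.0]),
    }
    specs = [("control", n_control, 9 / 11),
             ("HD", n_hd, 5 / 12)]
    idx = 0
    for grp, count, p_male in specs:
        qs, vals = age_quantiles[grp]
        group_ages = np.interp((np.arange(count) + 0.5) / count, qs, vals)
        for j in range(count):
            idx += 1
            age = float(group_ages[j])
            sex = "M" if rng.random() < p_male else "F"
            tfc = None
            if grp == "HD":
                tfc = float(rng.choice([9, 10, 11, 12, 13],
                                       p=[0.05, 0.10, 0.15, 0.25, 0.45]))
            z = (mu_region
                 + effect.age_slope * (age - 40.0)
                 + rng.normal(0.0, effect.z_sd, n_regions))
            delays = base_delay + rng.normal(0.0, 0.3, n_regions)
            if grp == "HD":
                z = z + effect.delta_z * aff_mask
                delays = delays + aff_mask * (
                    effect.delay_shift
                    + rng.normal(0.0, effect.delay_jitter_sd, n_regions))
            delays = np.clip(delays, 0.0, 15.0)
            cohort.append(GroundTruth(
                subject_id=f"sub-{idx:02d}",
                group=grp, age=age, sex=sex, tfc=tfc,
                resting_petco2=float(rng.uniform(35.0, 45.0)),
                technical_delay=float(rng.uniform(1.0, 3.0)),
                z_true=np.clip(z, 0.02, 2.5),
                delays=delays,
                amplitudes=None,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            ))
    return cohort, affected


def cohort_metadata(cohort: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": t.subject_id, "group": t.group, "age": t.age,
        "sex": t.sex, "tfc": np.nan if t.tfc is None else t.tfc,
    } for t in cohort])


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def make_physio(truth: GroundTruth, paradigm: Paradigm,
                rate: float = 100.0
                ) -> tuple[GasTrace, GasTrace, FlowTrace]:
    """Breath-resolved gas and flow traces tracking the challenge target.

    Breath cycles (default 12/min with seeded period jitter) modulate the
    PCO2 trace so that each expiratory plateau equals the subject's resting
    end-tidal CO2 plus the paradigm target deviation at that breath; PO2 is
    anticorrelated with PCO2 within the breath.  Both gas traces are then
    delayed by the subject's analyzer technical delay relative to flow, and
    analyzer/flow noise is added.
    """
    rng = np.random.default_rng(truth.seed)
    duration = paradigm.duration
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    flow = np.zeros(n)
    pco2 = np.full(n, truth.resting_petco2 - 25.0)

    period_mean = 60.0 / truth.breath_rate
    t_b = 0.0
    prev_plateau = truth.resting_petco2
    while t_b < duration:
        period = max(2.0, period_mean
                     + rng.normal(0.0, truth.breath_jitter_sd))
        insp_dur = 0.4 * period
        exp_dur = period - insp_dur
        a = int(round(t_b * rate))
        m = int(round((t_b + insp_dur) * rate))
        b = int(round((t_b + period) * rate))
        m, b = min(m, n), min(b, n)
        plateau = truth.resting_petco2 + float(
            paradigm.deviation_at(np.array([min(t_b + period, duration - 1 / rate)]),
                                  smoothed=False)[0])
        insp_min = plateau - 25.0
        # Half-sine flow with a raised-cosine gas curve: the gas derivative
        # is then proportional to the flow within each phase, so the
        # technical-delay cross-correlation peaks at the true lag, and the
        # noise-free expiratory maximum equals the plateau exactly.
        if m > a:
            ph = np.pi * np.arange(1, m - a + 1) / (m - a)
            flow[a:m] = -0.5 * np.sin(ph)
            pco2[a:m] = prev_plateau + (insp_min - prev_plateau) \
                * 0.5 * (1.0 - np.cos(ph))
        if b > m:
            ph = np.pi * np.arange(1, b - m + 1) / (b - m)
            flow[m:b] = 0.6 * np.sin(ph)
            pco2[m:b] = insp_min + (plateau - insp_min) \
                * 0.5 * (1.0 - np.cos(ph))
        prev_plateau = plateau
        t_b += period

    po2 = 150.0 - 1.8 * (pco2 - (truth.resting_petco2 - 25.0))

    k = int(round(truth.technical_delay * rate))
    pco2_d = _delay(pco2, k)
    po2_d = _delay(po2, k)
    if truth.analyzer_noise_sd > 0:
        pco2_d = pco2_d + rng.normal(0, truth.analyzer_noise_sd, n)
        po2_d = po2_d + rng.normal(0, truth.analyzer_noise_sd, n)
    if truth.flow_noise_sd > 0:
        flow = flow + rng.normal(0, truth.flow_noise_sd, n)

    return (GasTrace(np.clip(pco2_d, 0.0, 100.0), rate, 0.0, "CO2"),
            GasTrace(po2_d, rate, 0.0, "O2"),
            FlowTrace(flow, rate, 0.0))


def _delay(values: np.ndarray, k: int) -> np.ndarray:
    if k <= 0:
        return values.copy()
    out = np.empty_like(values)
    out[:k] = values[0]
    out[k:] = values[:-k]
    return out


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def region_regressor(paradigm: Paradigm, times: np.ndarray, delay: float,
                     tau: float = 8.0) -> np.ndarray:
    """End-tidal CO2 deviation convolved with a first-order response and
    shifted by the regional delay, sampled at volume times (mmHg)."""
    dev = first_order_response(paradigm.target - paradigm.spec.baseline_petco2,
                               paradigm.rate, tau, initial=0.0)
    return np.interp(times - delay, paradigm.times, dev)


def calibrate_amplitudes(truth: GroundTruth, paradigm: Paradigm,
                         times: np.ndarray, tr: float,
                         band: tuple[float, float] = (0.004, 0.02),
                         response_tau: float = 8.0) -> np.ndarray:
    """Region amplitudes (%BOLD per mmHg) realizing the target Fisher z.

    For white voxel noise of SD ``noise_sd_percent``, the in-band noise SD
    after the zero-phase band-pass is ``noise_sd * sqrt(g)`` with ``g`` the
    filter's white-noise variance gain.  Setting the band-limited signal SD
    to ``sigma_n_band * r / sqrt(1 - r^2)`` with ``r = tanh(z_true)`` makes
    the band-limited correlation equal r in expectation.
    """
    fs = 1.0 / tr
    g = finite_noise_gain(band, fs, times.size)
    sigma_n_band = truth.noise_sd_percent * np.sqrt(g)
    r = np.tanh(truth.z_true)
    amps = np.empty_like(r)
    for j, d in enumerate(truth.delays):
        reg = region_regressor(paradigm, times, d, response_tau)
        sig_sd = bandlimit(reg - reg.mean(), band, fs).std()
        target_sd = sigma_n_band * r[j] / np.sqrt(1.0 - r[j] ** 2)
        amps[j] = 0.0 if sig_sd == 0 else target_sd / sig_sd
    return amps


def make_bold(truth: GroundTruth, paradigm: Paradigm,
              parcellation: ParcellationVolume, tr: float = 1.25,
              n_volumes: int = 480, n_dummy: int = 12,
              band: tuple[float, float] = (0.004, 0.02),
              response_tau: float = 8.0, baseline_intensity: float = 1000.0,
              n_motion: int = 6) -> tuple[BoldSeries, np.ndarray]:
    """Forward-model a 4-D BOLD series plus motion regressors.

    Voxel signal (retained volumes):

        baseline * (1 + amp_j * dPETCO2(t - delay_j)/100 + drift/100
                    + motion@beta/100 + noise/100)

    where j indexes the voxel's region.  ``n_dummy`` high-intensity
    pre-equilibrium volumes are prepended so the discard stage is
    exercised.  Motion regressors are returned for all ``n_volumes``
    volumes (t x n_motion).  Region amplitudes are calibrated so the
    band-limited coupling equals tanh(z_true); the calibrated values are
    stored on ``truth.amplitudes``.
    """
    rng = np.random.default_rng(truth.seed + 1)
    grid = parcellation.labels.shape
    n_ret = n_volumes - n_dummy
    if n_ret <= 0:
        raise ValueError("n_volumes must exceed n_dummy")
    times = n_dummy * tr + np.arange(n_ret) * tr

    amps = calibrate_amplitudes(truth, paradigm, times, tr, band,
                                response_tau)
    truth.amplitudes = amps

    labels = parcellation.labels
    region_ids = parcellation.region_labels
    signal_pct = np.zeros(grid + (n_ret,), dtype=float)
    for k, lab in enumerate(region_ids):
        name = parcellation.lookup[lab]
        if name == "ventricle":
            continue
        j = k if k < truth.z_true.size else truth.z_true.size - 1
        reg = region_regressor(paradigm, times, truth.delays[j], response_tau)
        sel = labels == lab
        scale = rng.uniform(0.9, 1.1, int(sel.sum()))
        signal_pct[sel] = scale[:, None] * amps[j] * (reg - reg.mean())

    # nuisance structure
    tnorm = np.linspace(-1.0, 1.0, n_ret)
    drift_coeffs = rng.normal(0.0, truth.drift_sd_percent, 3)
    drift = (drift_coeffs[0] * tnorm + drift_coeffs[1] * tnorm ** 2
             + drift_coeffs[2] * tnorm ** 3)
    # slow head motion + respiration-locked jitter, band-limited to
    # 0.03-0.2 Hz: keeps the regressors' energy above the CVR analysis
    # band so their projection does not excise the coupling signal (a
    # random-walk motion model concentrates power inside the narrow band
    # and destroys a realization-dependent share of it)
    fs_vol = 1.0 / tr
    motion_full = bandlimit(rng.normal(0.0, 1.0, (n_motion, n_volumes)),
                            (0.03, min(0.2, 0.49 * fs_vol)), fs_vol).T
    motion_full /= motion_full.std(axis=0)
    motion_ret = motion_full[n_dummy:]

    mask = labels > 0
    n_vox = int(mask.sum())
    betas = rng.normal(0.0, 0.2, (n_vox, n_motion))
    motion_pct = betas @ motion_ret.T  # (n_vox, t)
    noise = rng.normal(0.0, truth.noise_sd_percent, (n_vox, n_ret))

    data = np.full(grid + (n_volumes,), 100.0, dtype=float)
    body = np.empty((n_vox, n_ret))
    body[:] = signal_pct[mask]
    body += drift[None, :] + motion_pct + noise
    data[..., n_dummy:][mask] = baseline_intensity * (1.0 + body / 100.0)
    # pre-equilibrium volumes: elevated intensity decaying toward baseline
    decay = 1.0 + 0.5 * np.exp(-np.arange(n_dummy) / 3.0)
    data[..., :n_dummy][mask] = baseline_intensity * decay[None, :]
    out_noise = rng.normal(0.0, 2.0, (int((~mask).sum()), n_volumes))
    data[~mask] = 100.0 + out_noise

    series = BoldSeries(data.astype(np.float32), tr,
                        parcellation.voxel_dims, mask=mask, t0=0.0)
    return series, motion_full
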