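"""Breath-by-breath end-tidal gas extraction from capnography and flow.

The gas analyzer sits downstream of a sampling line, so the recorded PCO2 /
PO2 traces lag the respiratory flow by a technical delay (gas transit plus
analyzer response).  The pipeline first recovers that delay by
cross-correlating the time-derivative of the gas trace with the flow, then
segments the recording into breaths using flow zero-crossings with
hysteresis, and reads the end-tidal value of each breath as the gas maximum
within the expiratory phase (robust to phase-boundary jitter).  Breath-
resolved end-tidal series are finally interpolated onto the BOLD volume
acquisition grid to serve as the reference regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .exceptions import DataError, DegenerateInputError

log = logging.getLogger(__name__)

CO2_BOUNDS = (0.0, 100.0)  # mmHg, physiological sanity window


@dataclass
class GasTrace:
    """Uniformly sampled partial-pressure trace in mmHg."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    gas: str = "CO2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("gas trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("gas trace contains non-finite samples")
        if self.rate <= 0:
            raise DataError("sampling rate must be positive")
        if self.gas == "CO2":
            lo, hi = CO2_BOUNDS
            frac = np.mean((self.values < lo) | (self.values > hi))
            if frac > 0:
                log.warning("%.1f%% of CO2 samples outside [%g, %g] mmHg",
                            100 * frac, lo, hi)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass
class FlowTrace:
    """Respiratory flow in L/s; inspiration negative by convention."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    apneic: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("flow trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("flow trace contains non-finite samples")
        if self.rate <= 0:
            raise DataError("sampling rate must be positive")
        # breathing present iff the signed flow crosses zero
        v = self.values
        self.apneic = not (np.any(v > 0) and np.any(v < 0))
        if self.apneic:
            log.warning("flow trace has no zero crossings; flagged apneic")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate


class BreathTable:
    """Per-breath timing table.

    Wraps a :class:`pandas.DataFrame` with one row per breath and columns

    ``insp_start, end_inspiration_time, exp_start, end_expiration_time,
    exp_end, petco2, peto2``

    (times in seconds; gas values in mmHg; ``peto2`` is NaN until
    :func:`extract_end_tidal` fills it).
    """

    COLUMNS = ["insp_start", "end_inspiration_time", "exp_start",
               "end_expiration_time", "exp_end", "petco2", "peto2"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise DataError(f"breath table missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        t = self.frame["end_expiration_time"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise DataError("breath end-expiration times must strictly increase")
        within = (self.frame["end_inspiration_time"]
                  < self.frame["end_expiration_time"])
        if not within.all():
            raise DataError("end inspiration must precede end expiration")
        if (self.frame["petco2"] <= 0).any():
            raise DataError("petco2 values must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BreathTable":
        return cls(pd.read_csv(path))


@dataclass
class EndTidalSeries:
    """Breath-resolved or volume-gridded end-tidal series in mmHg."""

    times: np.ndarray
    values: np.ndarray
    grid: str = "breath"  # "breath" or "tr"
    gas: str = "CO2"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataError("times and values must have equal length")
        if self.grid not in ("breath", "tr"):
            raise DataError("grid must be 'breath' or 'tr'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


# ---------------------------------------------------------------------------
# technical delay
# ---------------------------------------------------------------------------

def correct_technical_delay(gas: GasTrace, flow: FlowTrace,
                            max_lag: float) -> tuple[GasTrace, float]:
    """Recover and remove the gas-analyzer technical delay.

    The first time-derivative of the gas trace is cross-correlated with the
    flow trace; the lag (within ``+-max_lag`` seconds) maximizing the
    magnitude of the normalized cross-correlation is taken as the technical
    delay, and the gas trace is advanced by that amount (edge samples are
    held).  A positive lag means the gas trace lags the flow.

    Returns the shifted trace and the lag in seconds.
    """
    if gas.rate != flow.rate or gas.values.size != flow.values.size:
        raise DataError("gas and flow traces must share one uniform grid")
    if max_lag >= gas.duration / 4:
        raise DataError("max_lag must be below a quarter of the trace duration")
    # breathing is well below 1 Hz: a symmetric 0.1 s Gaussian smooth keeps
    # the derivative clean without introducing any lag
    sigma = max(0.1 * gas.rate, 1.0)
    g = np.gradient(gaussian_filter1d(gas.values, sigma))
    f = gaussian_filter1d(flow.values, sigma)
    f = f - f.mean()
    g = g - g.mean()
    if np.allclose(g, 0) or np.allclose(f, 0):
        raise DegenerateInputError("flat gas or flow trace: cannot align")
    n = g.size
    corr = signal.correlate(g, f, mode="full", method="fft")
    lags = np.arange(-n + 1, n)
    max_k = int(round(max_lag * gas.rate))
    keep = np.abs(lags) <= max_k
    corr, lags = corr[keep], lags[keep]
    denom = np.linalg.norm(g) * np.linalg.norm(f)
    k = int(lags[np.argmax(np.abs(corr / denom))])
    lag_s = k / gas.rate
    shifted = _shift_samples(gas.values, -k)
    out = replace(gas, values=shifted)
    log.info("technical delay of %s trace: %.3f s", gas.gas, lag_s)
    return out, lag_s


def _shift_samples(values: np.ndarray, k: int) -> np.ndarray:
    """Shift a series by k samples (positive = later), holding edge values."""
    if k == 0:
        return values.copy()
    out = np.empty_like(values)
    if k > 0:
        out[:k] = values[0]
        out[k:] = values[:-k]
    else:
        out[k:] = values[-1]
        out[:k] = values[-k:]
    return out


# ---------------------------------------------------------------------------
# breath segmentation
# ---------------------------------------------------------------------------

def _flow_phases(flow: np.ndarray, deadband_frac: float = 0.05,
                 smooth_samples: float = 0.0) -> np.ndarray:
    """Per-sample respiratory phase: +1 expiration, -1 inspiration.

    Zero-crossings are taken with hysteresis: a sample switches phase only
    when the flow leaves a deadband of ``deadband_frac`` times the flow SD;
    samples inside the deadband inherit the previous phase.  ``smooth_samples``
    optionally applies a symmetric Gaussian smooth before detection to
    suppress sensor noise around the crossings.
    """
    if smooth_samples > 0:
        flow = gaussian_filter1d(flow, smooth_samples)
    thr = deadband_frac * flow.std()
    raw = np.where(flow > thr, 1, np.where(flow < -thr, -1, 0))
    # forward-fill zeros with the last decided phase
    idx = np.arange(raw.size)
    decided = np.where(raw != 0, idx, -1)
    last = np.maximum.accumulate(decided)
    phase = np.where(last >= 0, raw[np.clip(last, 0, None)], 0)
    # leading undecided samples take the first decided phase
    first_decided = np.argmax(raw != 0) if np.any(raw != 0) else 0
    phase[:first_decided] = raw[first_decided] if np.any(raw != 0) else 0
    return phase


def detect_breaths(pco2: GasTrace, flow: FlowTrace,
                   min_breath_duration: float = 1.5,
                   deadband_frac: float = 0.05,
                   edge_guard: float = 5.0) -> BreathTable:
    """Segment the recording into breaths and locate end-tidal points.

    Respiratory phases come from flow zero-crossings with hysteresis; the
    end-inspiration point of a breath is the PCO2 minimum within its
    inspiratory phase and the end-expiration point the PCO2 maximum within
    the following expiratory phase.  Breath cycles shorter than
    ``min_breath_duration`` seconds are merged with the next cycle.
    """
    if flow.apneic:
        raise DataError("apneic flow trace: no breaths to segment")
    if pco2.rate != flow.rate or pco2.values.size != flow.values.size:
        raise DataError("pco2 and flow must be co-sampled and delay-corrected")
    phase = _flow_phases(flow.values, deadband_frac,
                         smooth_samples=0.1 * flow.rate)
    # segment boundaries where phase switches
    change = np.flatnonzero(np.diff(phase) != 0) + 1
    bounds = np.concatenate(([0], change, [phase.size]))
    segments = [(phase[a], a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    segments = [s for s in segments if s[0] != 0]

    # pair inspiratory segment with the following expiratory segment
    cycles: list[tuple[int, int, int, int]] = []  # (ia, ib, ea, eb)
    i = 0
    while i < len(segments) - 1:
        ph, a, b = segments[i]
        ph2, a2, b2 = segments[i + 1]
        if ph == -1 and ph2 == 1:
            cycles.append((a, b, a2, b2))
            i += 2
        else:
            i += 1

    # merge cycles shorter than the minimum breath duration into the next
    min_n = int(round(min_breath_duration * pco2.rate))
    merged: list[tuple[int, int, int, int]] = []
    pending: tuple[int, int, int, int] | None = None
    for cyc in cycles:
        if pending is not None:
            cyc = (pending[0], cyc[1], cyc[2], cyc[3])
            pending = None
        if cyc[3] - cyc[0] < min_n:
            pending = cyc
        else:
            merged.append(cyc)
    if pending is not None and merged:
        ia, ib, ea, eb = merged[-1]
        merged[-1] = (ia, ib, pending[2], pending[3])

    # a breath whose expiration runs into the end of the recording is
    # truncated, and the delay-corrected gas trace holds edge values over
    # roughly the technical delay there: drop trailing breaths inside the
    # guard window
    guard = phase.size - int(edge_guard * pco2.rate)
    while merged and merged[-1][3] > guard:
        merged.pop()

    if len(merged) < 3:
        raise DataError(f"only {len(merged)} breaths detected; need >= 3")

    rows = []
    t = pco2.times
    v = pco2.values
    for ia, ib, ea, eb in merged:
        i_min = ia + int(np.argmin(v[ia:ib]))
        e_max = ea + int(np.argmax(v[ea:eb]))
        rows.append({
            "insp_start": t[ia],
            "end_inspiration_time": t[i_min],
            "exp_start": t[ea],
            "end_expiration_time": t[e_max],
            "exp_end": t[eb - 1],
            "petco2": v[e_max],
            "peto2": np.nan,
        })
    frame = pd.DataFrame(rows)
    # guard against duplicated end-expiration times from merges
    frame = frame[frame["end_expiration_time"].diff().fillna(1.0) > 0]
    return BreathTable(frame)


# ---------------------------------------------------------------------------
# end-tidal extraction and resampling
# ---------------------------------------------------------------------------

def extract_end_tidal(pco2: GasTrace, po2: GasTrace,
                      breaths: BreathTable) -> tuple[EndTidalSeries,
                                                     EndTidalSeries]:
    """Read breath-to-breath end-tidal CO2 and O2 values.

    The CO2 end-tidal value of a breath is the PCO2 maximum within its
    expiratory phase; the O2 value is read off the PO2 trace at the same
    end-expiration time (where PO2, anticorrelated with PCO2 within the
    breath, attains its expiratory minimum).
    """
    f = breaths.frame
    t_co2, v_co2, v_o2 = [], [], []
    for _, row in f.iterrows():
        a = int(round((row["exp_start"] - pco2.start_time) * pco2.rate))
        b = int(round((row["exp_end"] - pco2.start_time) * pco2.rate)) + 1
        seg = pco2.values[a:b]
        if seg.size == 0:
            continue
        k = a + int(np.argmax(seg))
        t_co2.append(pco2.times[k])
        v_co2.append(pco2.values[k])
        v_o2.append(po2.values[k])
    co2 = EndTidalSeries(np.array(t_co2), np.array(v_co2), "breath", "CO2")
    o2 = EndTidalSeries(np.array(t_co2), np.array(v_o2), "breath", "O2")
    return co2, o2


def plot_breaths(pco2: GasTrace, flow: FlowTrace, breaths: BreathTable,
                 path, t_max: float | None = 120.0) -> None:
    """QC figure: gas and flow traces with breath marks, written as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_end = pco2.duration if t_max is None else min(t_max, pco2.duration)
    sel = pco2.times <= t_end
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    ax1.plot(pco2.times[sel], pco2.values[sel], lw=0.8, color="tab:blue")
    f = breaths.frame
    marks = f[f["end_expiration_time"] <= t_end]
    ax1.plot(marks["end_expiration_time"], marks["petco2"], "v",
             color="tab:red", ms=4, label="end expiration")
    ax1.plot(marks["end_inspiration_time"],
             np.interp(marks["end_inspiration_time"], pco2.times,
                       pco2.values), "^", color="tab:green", ms=4,
             label="end inspiration")
    ax1.set_ylabel("PCO2 (mmHg)")
    ax1.legend(loc="upper right", fontsize=8)
    ax2.plot(flow.times[sel], flow.values[sel], lw=0.6, color="tab:gray")
    ax2.axhline(0.0, color="k", lw=0.5)
    ax2.set_ylabel("flow (L/s)")
    ax2.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def resample_to_tr_grid(series: EndTidalSeries, tr: float, n_volumes: int,
                        t0: float) -> EndTidalSeries:
    """Linearly interpolate a breath-resolved series onto volume times.

    Volume acquisition times are ``t0 + k*tr`` for k = 0..n_volumes-1.
    Values outside the breath span are extrapolated with the nearest breath
    value.  Linear interpolation is used because the breath interval (~4-5 s)
    exceeds the TR; higher-order splines risk overshoot at the step
    transitions of the challenge.
    """
    if n_volumes <= 0:
        raise ValueError("n_volumes must be positive")
    grid = t0 + np.arange(n_volumes) * tr
    vals = np.interp(grid, series.times, series.values)
    return EndTidalSeries(grid, vals, "tr", series.gas)
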