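"""Block design of the CO2 challenge.

The challenge alternates normocapnia with epochs of mild hypercapnia in
which the target end-tidal CO2 is raised 4 or 8 mmHg above the subject's
resting level.  The default protocol runs six cycles — three +4 mmHg and
three +8 mmHg epochs of 30 s each, alternating — separated by normocapnic
phases, for a total of 10 minutes.  The physical gas circuit cannot switch
levels instantaneously, so the ideal piecewise-constant target is also
provided convolved with a first-order exponential wash-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass(frozen=True)
class ParadigmSpec:
    baseline_petco2: float = 40.0
    n_cycles: int = 6
    hypercapnia_duration: float = 30.0
    normocapnia_duration_range: tuple[float, float] = (70.0, 70.0)
    step_sizes: tuple[float, ...] = (4.0, 8.0, 4.0, 8.0, 4.0, 8.0)
    transition_time_constant: float = 8.0

    def __post_init__(self) -> None:
        if len(self.step_sizes) != self.n_cycles:
            raise ValueError("need one step size per cycle")
        lo, hi = self.normocapnia_duration_range
        if lo <= 0 or hi < lo or self.hypercapnia_duration <= 0:
            raise ValueError("durations must be positive and range ordered")
        if any(not (0.0 <= s <= 10.0) for s in self.step_sizes):
            raise ValueError("step sizes must lie in [0, 10] mmHg "
                             "(mild hypercapnia)")

    @property
    def mean_cycle_duration(self) -> float:
        lo, hi = self.normocapnia_duration_range
        return (lo + hi) / 2 + self.hypercapnia_duration

    @property
    def fundamental_frequency(self) -> float:
        """Paradigm fundamental in Hz: one over the mean cycle duration."""
        return 1.0 / self.mean_cycle_duration


@dataclass
class Paradigm:
    """Realized challenge time course.

    ``target`` is the ideal piecewise-constant end-tidal CO2 target;
    ``trace`` is the same target passed through a first-order exponential
    transition mimicking circuit wash-in.  ``epochs`` annotates every phase
    with onset, offset and step size (0 for normocapnia).
    """

    spec: ParadigmSpec
    rate: float
    times: np.ndarray
    target: np.ndarray
    trace: np.ndarray
    epochs: pd.DataFrame

    @property
    def duration(self) -> float:
        return self.times.size / self.rate

    @property
    def n_hypercapnic_epochs(self) -> int:
        return int((self.epochs["step_mmhg"] > 0).sum())

    def target_at(self, t: np.ndarray) -> np.ndarray:
        """Ideal target interpolated (piecewise-constant) at times ``t``."""
        idx = np.clip((np.asarray(t) * self.rate).astype(int), 0,
                      self.target.size - 1)
        return self.target[idx]

    def deviation_at(self, t: np.ndarray, smoothed: bool = True) -> np.ndarray:
        """Target deviation from baseline at times ``t`` (mmHg)."""
        src = self.trace if smoothed else self.target
        idx = np.clip((np.asarray(t) * self.rate).astype(int), 0, src.size - 1)
        return src[idx] - self.spec.baseline_petco2


def build_paradigm(spec: ParadigmSpec, rate: float,
                   seed: int | None = None) -> Paradigm:
    """Construct the challenge time course.

    Normocapnia durations are drawn uniformly from the configured range
    (per cycle) with the given seed, or are fixed when the range collapses
    to a point.  Each cycle is a normocapnic phase followed by a
    hypercapnic epoch of the cycle's step size.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = spec.normocapnia_duration_range
    if lo == hi:
        normo = np.full(spec.n_cycles, lo)
    else:
        normo = rng.uniform(lo, hi, spec.n_cycles)

    rows = []
    t = 0.0
    for i, (nd, step) in enumerate(zip(normo, spec.step_sizes)):
        rows.append({"cycle": i, "phase": "normocapnia", "onset": t,
                     "offset": t + nd, "step_mmhg": 0.0})
        t += nd
        rows.append({"cycle": i, "phase": "hypercapnia", "onset": t,
                     "offset": t + spec.hypercapnia_duration,
                     "step_mmhg": float(step)})
        t += spec.hypercapnia_duration
    epochs = pd.DataFrame(rows)
    total = t

    n = int(round(total * rate))
    times = np.arange(n) / rate
    target = np.full(n, spec.baseline_petco2)
    for _, row in epochs.iterrows():
        if row["step_mmhg"] > 0:
            a = int(round(row["onset"] * rate))
            b = int(round(row["offset"] * rate))
            target[a:b] = spec.baseline_petco2 + row["step_mmhg"]

    trace = first_order_response(target, rate, spec.transition_time_constant,
                                 initial=spec.baseline_petco2)
    return Paradigm(spec, rate, times, target, trace, epochs)


def epoch_plateau_means(times: np.ndarray, values: np.ndarray,
                        paradigm: Paradigm,
                        margin: float = 6.0) -> dict[float, float]:
    """Mean end-tidal value per step level, plateau breaths only.

    A breath counts toward an epoch when its end-expiration time falls at
    least ``margin`` seconds (about one breath period) inside the epoch at
    both ends, so transition breaths straddling either step edge are
    excluded.  Returns ``{step_mmhg: mean value}`` including the
    normocapnic baseline under key 0.0.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sums: dict[float, list[float]] = {}
    for _, row in paradigm.epochs.iterrows():
        sel = (times >= row["onset"] + margin) \
            & (times < row["offset"] - margin)
        if sel.any():
            sums.setdefault(float(row["step_mmhg"]), []).extend(values[sel])
    return {step: float(np.mean(v)) for step, v in sums.items()}


def first_order_response(u: np.ndarray, rate: float, tau: float,
                         initial: float | None = None) -> np.ndarray:
    """Pass a series through a first-order low-pass (exponential wash-in).

    Exact zero-order-hold discretization of ``tau * y' = u - y``; with
    ``tau <= 0`` the input is returned unchanged.
    """
    if tau <= 0:
        return np.asarray(u, dtype=float).copy()
    u = np.asarray(u, dtype=float)
    a = np.exp(-1.0 / (rate * tau))
    y0 = u[0] if initial is None else initial
    # y[k] = a*y[k-1] + (1-a)*u[k]
    y = signal.lfilter([1 - a], [1, -a], u, zi=[a * y0])[0]
    return y
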