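"""End-tidal extraction: delay correction, breath detection, resampling."""

import numpy as np
import pytest

from cvrpipe.exceptions import DataError, DegenerateInputError
from cvrpipe.physio import (BreathTable, EndTidalSeries, FlowTrace, GasTrace,
                            correct_technical_delay, detect_breaths,
                            extract_end_tidal, resample_to_tr_grid)


RATE = 100.0


def _breathing(duration=60.0, bpm=12.0, plateau=40.0, rate=RATE):
    """Clean co-sampled (pco2, flow) traces with exact expiratory plateaus.

    Half-sine flow with a raised-cosine gas curve, so the gas derivative is
    proportional to the flow and the expiratory maximum equals ``plateau``.
    """
    period = 60.0 / bpm
    n = int(duration * rate)
    flow = np.zeros(n)
    pco2 = np.full(n, plateau)
    insp_min = plateau - 25.0
    t_b = 0.0
    while t_b < duration - 1e-9:
        a = int(round(t_b * rate))
        # asymmetric inspiration/expiration (40/60) as in real breathing;
        # a symmetric split makes the delay ambiguous by half a period
        m = min(int(round((t_b + 0.4 * period) * rate)), n)
        b = min(int(round((t_b + period) * rate)), n)
        if m > a:
            ph = np.pi * np.arange(1, m - a + 1) / (m - a)
            flow[a:m] = -0.5 * np.sin(ph)
            pco2[a:m] = plateau + (insp_min - plateau) * 0.5 * (1 - np.cos(ph))
        if b > m:
            ph = np.pi * np.arange(1, b - m + 1) / (b - m)
            flow[m:b] = 0.6 * np.sin(ph)
            pco2[m:b] = insp_min + (plateau - insp_min) * 0.5 * (1 - np.cos(ph))
        t_b += period
    return GasTrace(pco2, rate), FlowTrace(flow, rate)


class TestTechnicalDelay:
    @pytest.mark.parametrize("true_delay", [0.0, 0.5, 2.0])
    def test_known_delay_recovered_exactly(self, true_delay):
        gas, flow = _breathing(duration=120.0)
        k = int(true_delay * RATE)
        delayed = np.concatenate([np.full(k, gas.values[0]),
                                  gas.values[:gas.values.size - k]]) \
            if k else gas.values
        shifted, lag = correct_technical_delay(
            GasTrace(delayed, RATE), flow, max_lag=5.0)
        assert lag == pytest.approx(true_delay, abs=1.5 / RATE)

    def test_idempotent(self):
        gas, flow = _breathing(duration=120.0)
        k = 150
        delayed = np.concatenate([np.full(k, gas.values[0]),
                                  gas.values[:-k]])
        once, lag1 = correct_technical_delay(GasTrace(delayed, RATE), flow,
                                             5.0)
        _, lag2 = correct_technical_delay(once, flow, 5.0)
        assert lag1 == pytest.approx(1.5, abs=1.5 / RATE)
        assert abs(lag2) <= 2 / RATE

    def test_constant_gas_raises(self):
        _, flow = _breathing()
        with pytest.raises(DegenerateInputError):
            correct_technical_delay(GasTrace(np.full(6000, 40.0), RATE),
                                    flow, 5.0)

    def test_excessive_max_lag_rejected(self):
        gas, flow = _breathing(duration=60.0)
        with pytest.raises(DataError):
            correct_technical_delay(gas, flow, max_lag=20.0)


class TestBreathDetection:
    def test_breath_count_12_per_minute(self):
        gas, flow = _breathing(duration=60.0, bpm=12.0)
        breaths = detect_breaths(gas, flow, edge_guard=0.0)
        assert abs(len(breaths) - 12) <= 1

    def test_times_strictly_increasing(self):
        gas, flow = _breathing(duration=90.0)
        frame = detect_breaths(gas, flow).frame
        assert (frame["end_expiration_time"].diff().dropna() > 0).all()
        assert (frame["end_inspiration_time"]
                < frame["end_expiration_time"]).all()

    def test_apneic_flow_raises(self):
        gas, _ = _breathing()
        with pytest.raises(DataError):
            detect_breaths(gas, FlowTrace(np.zeros(6000), RATE))

    def test_too_few_breaths_raises(self):
        gas, flow = _breathing(duration=6.0)
        with pytest.raises(DataError):
            detect_breaths(gas, flow, edge_guard=0.0)


class TestEndTidalExtraction:
    def test_flat_plateau_read_exactly(self):
        gas, flow = _breathing(duration=60.0, plateau=40.0)
        po2 = GasTrace(150.0 - 1.8 * (gas.values - 15.0), RATE, gas="O2")
        breaths = detect_breaths(gas, flow, edge_guard=0.0)
        co2, o2 = extract_end_tidal(gas, po2, breaths)
        assert np.allclose(co2.values, 40.0, atol=1e-3)
        # O2 anticorrelated: end-tidal O2 at the CO2 maximum
        assert np.allclose(o2.values, 150.0 - 1.8 * 25.0, atol=1e-2)

    def test_shift_equivariance(self):
        gas, flow = _breathing(duration=60.0)
        po2 = GasTrace(np.full_like(gas.values, 105.0), RATE, gas="O2")
        breaths = detect_breaths(gas, flow, edge_guard=0.0)
        co2, _ = extract_end_tidal(gas, po2, breaths)
        shifted = GasTrace(gas.values + 5.0, RATE)
        co2s, _ = extract_end_tidal(shifted, po2,
                                    detect_breaths(shifted, flow,
                                                   edge_guard=0.0))
        assert np.allclose(co2s.values, co2.values + 5.0, atol=1e-9)

    def test_three_breath_hand_example(self):
        # three triangular breaths with distinct expiratory maxima
        rate = 10.0
        flow = np.tile(np.concatenate([-np.ones(20), np.ones(20)]), 3)
        peaks = [38.0, 42.0, 46.0]
        pco2 = np.concatenate([
            np.concatenate([np.linspace(p, 15.0, 20),
                            np.linspace(15.0, p, 20)])
            for p in peaks
        ])
        gas = GasTrace(pco2, rate)
        po2 = GasTrace(200.0 - 2 * pco2, rate, gas="O2")
        breaths = detect_breaths(gas, FlowTrace(flow, rate),
                                 edge_guard=0.0)
        co2, o2 = extract_end_tidal(gas, po2, breaths)
        assert list(co2.values) == pytest.approx(peaks)
        assert list(o2.values) == pytest.approx([200 - 2 * p for p in peaks])


class TestResampling:
    def test_linear_interpolation_closed_form(self):
        series = EndTidalSeries(np.array([0.0, 5.0]),
                                np.array([40.0, 48.0]))
        out = resample_to_tr_grid(series, tr=1.25, n_volumes=4, t0=0.0)
        assert np.allclose(out.values, [40.0, 42.0, 44.0, 46.0])

    def test_constant_series_stays_constant(self):
        series = EndTidalSeries(np.array([0.0, 10.0, 20.0]),
                                np.full(3, 40.0))
        out = resample_to_tr_grid(series, 1.25, 32, 0.0)
        assert np.allclose(out.values, 40.0)

    def test_output_length_and_edge_extrapolation(self):
        series = EndTidalSeries(np.array([5.0, 10.0]),
                                np.array([40.0, 44.0]))
        out = resample_to_tr_grid(series, 1.25, 16, 0.0)
        assert out.values.size == 16
        assert out.values[0] == 40.0  # nearest-value extrapolation
        assert out.values[-1] == 44.0

    def test_nonpositive_n_volumes_rejected(self):
        series = EndTidalSeries(np.array([0.0, 1.0]), np.array([40.0, 41.0]))
        with pytest.raises(ValueError):
            resample_to_tr_grid(series, 1.25, 0, 0.0)


class TestBreathTableValidation:
    def test_nonmonotone_times_rejected(self):
        import pandas as pd
        frame = pd.DataFrame({
            "insp_start": [0.0, 4.0], "end_inspiration_time": [1.0, 5.0],
            "exp_start": [1.5, 5.5], "end_expiration_time": [3.0, 3.0],
            "exp_end": [3.5, 7.5], "petco2": [40.0, 41.0],
            "peto2": [np.nan, np.nan]})
        with pytest.raises(DataError):
            BreathTable(frame)
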