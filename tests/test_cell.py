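"""Single-cell ionic model: variants, pacing, APD measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bzsim._kernels import INITIAL_STATE, N_STATES, pace_cells
from bzsim.cell import (APTrace, CaptureFailureError,
                        IncompleteRepolarizationError, UnknownVariantError,
                        CellParams, initial_state, load_state, make_variant,
                        measure_apd, pace_to_steady_state, save_state,
                        step_cell)

GATES = slice(1, 14)  # m..rbar in the state layout


@pytest.mark.parametrize("kind,scale", [("control", 1.0),
                                        ("longer_apd", 0.5),
                                        ("shorter_apd", 2.0)])
def test_variant_gks_scaling(kind, scale):
    params = make_variant(kind)
    assert params.gKs_scale == scale
    assert params.Cm == 1.0


def test_unknown_variant_rejected():
    with pytest.raises(UnknownVariantError):
        make_variant("reduced_ina")


def _relaxed_state(ms=2000.0, dt=0.02):
    S = initial_state().reshape(1, -1)
    pace_cells(S, np.ones(1), ms, 1, dt, 0.0, 0.0, ms, 1)
    return S[0]


def test_rest_is_fixed_point():
    """Without stimulation the relaxed state is (numerically) stationary."""
    rest = _relaxed_state()
    for dt in (0.005, 0.02):
        nxt = step_cell(rest, dt, CellParams())
        rel = np.abs(nxt - rest) / np.maximum(np.abs(rest), 1e-12)
        assert rel.max() < 1e-6
    assert -90.0 < rest[0] < -80.0


def test_threshold_stimulus_elicits_upstroke():
    params = CellParams()
    state, trace = pace_to_steady_state(params, 500.0, 1, record_last=1)
    assert trace.V.max() > 10.0
    assert np.all(state[GATES] >= 0.0) and np.all(state[GATES] <= 1.0)
    assert np.all(state[14:] > 0.0)  # concentrations


def test_step_convergence_in_dt():
    """Halving dt changes the paced-cycle voltage trace by < 1 mV away from
    the upstroke; at the ~370 mV/ms upstroke itself pointwise agreement is
    limited by timing jitter, so the upstroke instant is bounded instead."""
    traces = {}
    for dt in (0.02, 0.01):
        S = initial_state().reshape(1, -1)
        t, v, _ = pace_cells(S, np.ones(1), 500.0, 1, dt, 52.0, 1.0, 0.5, 0)
        traces[dt] = v[:, 0]
    after = t >= 5.0
    assert np.abs(traces[0.02][after] - traces[0.01][after]).max() < 1.0
    up1 = t[np.argmax(np.diff(traces[0.02]))]
    up2 = t[np.argmax(np.diff(traces[0.01]))]
    assert abs(up1 - up2) <= 0.5  # within one output sample
    a1 = measure_apd(APTrace(t, traces[0.02], 500.0))
    a2 = measure_apd(APTrace(t, traces[0.01], 500.0))
    assert abs(a1 - a2) < 0.5


def test_nonfinite_state_aborts_with_variable_name():
    bad = initial_state()
    bad[17] = np.nan  # Nai
    with pytest.raises(FloatingPointError, match="Nai"):
        step_cell(bad, 0.02, CellParams())


def test_zero_beats_returns_published_initial_conditions():
    state = pace_to_steady_state(CellParams(), 500.0, 0)
    np.testing.assert_array_equal(state, INITIAL_STATE)


def test_subthreshold_pacing_raises_capture_failure():
    params = CellParams(stimulus_amplitude=0.5)
    with pytest.raises(CaptureFailureError, match="beat 1"):
        pace_to_steady_state(params, 500.0, 3)


def test_steady_state_periodicity(variant_traces):
    """After 100 beats, consecutive cycles are nearly identical."""
    params = make_variant("control")
    state, trace2 = pace_to_steady_state(params, 500.0, 100, record_last=2)
    n = len(trace2.time) // 2
    v_prev, v_last = trace2.V[:n], trace2.V[n:2 * n]
    assert np.abs(v_prev - v_last).max() < 1.0
    apd_prev = measure_apd(APTrace(trace2.time[:n], v_prev, 500.0))
    apd_last = measure_apd(APTrace(trace2.time[:n], v_last, 500.0))
    assert abs(apd_prev - apd_last) < 1.0
    assert np.all(state[GATES] >= 0.0) and np.all(state[GATES] <= 1.0)


def test_apd_monotone_in_gks(variant_traces):
    """APD strictly decreases as g_Ks is scaled up (0.5 -> 1.0 -> 2.0)."""
    apds = {k: v["apd"] for k, v in variant_traces.items()}
    assert apds["longer_apd"] > apds["control"] > apds["shorter_apd"]


def test_apd_at_minus70_close_to_apd90(variant_traces):
    """The -70 mV convention used in tissue is close to APD90."""
    tr = variant_traces["control"]["trace"]
    apd90 = measure_apd(tr, 0.9)
    apd70 = measure_apd(tr, 0.9, v_threshold=-70.0)
    assert abs(apd90 - apd70) < 15.0


def test_square_pulse_apd_exact():
    t = np.arange(0.0, 400.0, 0.5)
    v = np.where(t < 200.0, 20.0, -85.0)
    assert measure_apd(APTrace(t, v, 500.0), 0.9) == pytest.approx(200.0,
                                                                   abs=0.5)


def test_apd50_less_than_apd90(variant_traces):
    tr = variant_traces["control"]["trace"]
    assert measure_apd(tr, 0.5) < measure_apd(tr, 0.9)


def test_incomplete_repolarization_raises():
    t = np.arange(0.0, 100.0, 0.5)
    v = np.full_like(t, 20.0)
    v[0] = -85.0
    with pytest.raises(IncompleteRepolarizationError):
        measure_apd(APTrace(t, v, 500.0))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(duration=st.floats(20.0, 300.0), peak=st.floats(10.0, 45.0),
       rest=st.floats(-95.0, -75.0))
def test_measure_apd_recovers_constructed_plateau(duration, peak, rest):
    """For a trapezoidal AP the measured APD tracks the plateau length."""
    t = np.arange(0.0, 400.0, 0.1)
    v = np.full_like(t, rest)
    up = 5.0
    v[(t >= up) & (t < up + duration)] = peak
    down = t >= up + duration
    v[down] = rest
    apd = measure_apd(APTrace(t, v, 500.0), 0.9)
    assert apd == pytest.approx(duration, abs=0.5)


def test_state_roundtrip(tmp_path, variant_traces):
    state = variant_traces["control"]["state"]
    p = tmp_path / "state.txt"
    save_state(p, state, "control", 1.0)
    np.testing.assert_allclose(load_state(p), state, rtol=0, atol=0)


def test_published_model_characteristics():
    """Paced at CL 1000 ms the model reproduces the published epicardial
    characteristics: resting potential near -86 mV, APD90 near 300 ms,
    overshoot of a few tens of mV."""
    S = initial_state().reshape(1, -1)
    t, v, _ = pace_cells(S, np.ones(1), 1000.0, 30, 0.02, 52.0, 1.0, 0.5, 29)
    trace = APTrace(t, v[:, 0], 1000.0)
    assert -90.0 < v[0, 0] < -80.0
    assert 10.0 < v.max() < 50.0
    assert measure_apd(trace) == pytest.approx(301.0, abs=20.0)
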