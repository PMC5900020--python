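"""Single-cell layer: ionic-model variants, pacing to steady state, APD.

The action-potential model is the 2006 ten Tusscher-Panfilov human
ventricular formulation (epicardial parameter set); see ``_kernels`` for the
equations.  Border-zone electrophysiology is represented purely through a
multiplicative scaling of the slow delayed-rectifier conductance g_Ks:
halving g_Ks prolongs the action potential by roughly 40 ms at a 500 ms
cycle length and doubling it shortens it by a similar amount.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from ._kernels import INITIAL_STATE, N_STATES

STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "rbar", "Cai", "CaSS", "CaSR", "Nai", "Ki",
)

GKS_SCALE = {"control": 1.0, "longer_apd": 0.5, "shorter_apd": 2.0}


class UnknownVariantError(ValueError):
    pass


class CaptureFailureError(RuntimeError):
    """Raised when a paced cycle fails to elicit an action potential."""


class IncompleteRepolarizationError(ValueError):
    pass


@dataclass(frozen=True)
class CellParams:
    """Tunable parameters of the cell model.

    gKs_scale multiplies the published slow delayed-rectifier conductance;
    Cm is the membrane capacitance per unit area (uF/cm^2); the stimulus is
    a rectangular transmembrane current (A/F) of the given duration (ms).
    A stimulus_amplitude of None means "2x diastolic threshold, found by
    bisection" at pacing time.
    """

    gKs_scale: float = 1.0
    Cm: float = 1.0
    stimulus_amplitude: float | None = None
    stimulus_duration: float = 2.0
    dt: float = 0.02
    variant: str = "control"

    def __post_init__(self):
        if self.gKs_scale <= 0:
            raise ValueError("gKs_scale must be positive")
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class APTrace:
    """Sampled membrane potential of one or more paced cycles."""

    time: np.ndarray          # ms, strictly increasing
    V: np.ndarray             # mV
    cycle_length: float       # ms

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time samples must be strictly increasing")


def make_variant(kind: str) -> CellParams:
    """Cell parameter sets of the study: control, longer_apd (g_Ks x0.5),
    shorter_apd (g_Ks x2.0)."""
    if kind not in GKS_SCALE:
        raise UnknownVariantError(
            f"unknown variant {kind!r}; expected one of {sorted(GKS_SCALE)}")
    return CellParams(gKs_scale=GKS_SCALE[kind], variant=kind)


def initial_state() -> np.ndarray:
    """Published resting initial conditions of the ionic model."""
    return INITIAL_STATE.copy()


def step_cell(state: np.ndarray, dt: float, params: CellParams,
              i_stim: float = 0.0) -> np.ndarray:
    """Advance a single cell one step of ``dt`` ms; returns the new state.

    Gates use the exponential (Rush-Larsen) update, so steps up to ~0.05 ms
    remain stable; accuracy is validated at dt <= 0.02 ms.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(s)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(s))[0])]
        raise FloatingPointError(f"non-finite state variable: {bad}")
    S = s.reshape(1, N_STATES).copy()
    K.ionic_step(S, np.array([params.gKs_scale]), np.array([float(i_stim)]),
                 dt, 1)
    out = S[0]
    if not np.all(np.isfinite(out)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(out))[0])]
        raise FloatingPointError(f"non-finite state variable: {bad}")
    return out


def find_stimulus_threshold(params: CellParams, state: np.ndarray | None = None,
                            lo: float = 0.5, hi: float = 200.0,
                            rel_tol: float = 0.05) -> float:
    """Diastolic threshold amplitude (A/F) of the rectangular stimulus,
    found by bisection on a single trial beat."""
    if state is None:
        state = initial_state()

    def captures(amp: float) -> bool:
        S = state.reshape(1, N_STATES).copy()
        gks = np.array([params.gKs_scale])
        t, v, vmax = K.pace_cells(S, gks, 60.0, 1, params.dt, amp,
                                  params.stimulus_duration, 1.0, 0)
        return vmax[0] > 0.0

    if captures(lo):
        return lo
    if not captures(hi):
        raise CaptureFailureError(
            f"no capture even at {hi} A/F; cell not excitable")
    while hi / lo > 1.0 + rel_tol:
        mid = np.sqrt(lo * hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _resolve_amplitude(params: CellParams, state: np.ndarray) -> float:
    if params.stimulus_amplitude is not None:
        return params.stimulus_amplitude
    return 2.0 * find_stimulus_threshold(params, state)


def pace_to_steady_state(params: CellParams, cycle_length: float = 500.0,
                         n_beats: int = 100, record_last: int = 0,
                         out_dt: float = 0.1):
    """Pace the cell ``n_beats`` times at constant cycle length.

    Returns the end-diastolic state after the last cycle; with
    ``record_last > 0`` returns ``(state, APTrace)`` covering the last
    ``record_last`` cycles.  Every cycle must capture 1:1 (an upstroke above
    0 mV), otherwise the failing beat is reported.
    """
    state = initial_state()
    if n_beats == 0:
        return (state, None) if record_last else state
    amp = _resolve_amplitude(params, state)
    S = state.reshape(1, N_STATES)
    gks = np.array([params.gKs_scale])
    t, v, vmax = K.pace_cells(S, gks, float(cycle_length), int(n_beats),
                              params.dt, amp, params.stimulus_duration,
                              out_dt, max(0, n_beats - record_last))
    failed = np.flatnonzero(vmax < 0.0)
    if failed.size:
        raise CaptureFailureError(
            f"loss of 1:1 capture: no upstroke on beat {failed[0] + 1} "
            f"of {n_beats}")
    state = S[0].copy()
    if record_last:
        trace = APTrace(time=t, V=v[:, 0], cycle_length=float(cycle_length))
        return state, trace
    return state


def measure_apd(trace: APTrace, repolarization_fraction: float = 0.9,
                v_threshold: float | None = None) -> float:
    """Action-potential duration of the *last* complete AP in the trace.

    Measured from the maximum-upstroke instant to the downward crossing of
    V_peak - fraction*(V_peak - V_rest) (linear interpolation between
    samples).  With ``v_threshold`` given, the crossing level is that fixed
    voltage instead (e.g. -70 mV, the tissue repolarization convention).
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization_fraction must be in (0, 1)")
    t, v = trace.time, trace.V
    dvdt = np.diff(v) / np.diff(t)
    # maximum-upstroke instant of the *last* AP: last run of near-maximal dV/dt
    if dvdt.max() <= 1e-12:  # no rising segment (e.g. a square pulse)
        up = 0
    else:
        thr = 0.5 * float(dvdt.max())
        cand = np.flatnonzero(dvdt >= thr)
        breaks = np.flatnonzero(np.diff(cand) > 1)
        last_run = cand[breaks[-1] + 1:] if breaks.size else cand
        up = int(last_run[np.argmax(dvdt[last_run])])
    v_rest = float(v.min())
    seg_v = v[up:]
    seg_t = t[up:]
    v_peak = float(seg_v.max())
    if v_threshold is not None:
        level = float(v_threshold)
    else:
        level = v_peak - repolarization_fraction * (v_peak - v_rest)
    ipk = int(np.argmax(seg_v))
    below = np.flatnonzero((seg_v[ipk:-1] >= level) & (seg_v[ipk + 1:] < level))
    if below.size == 0:
        raise IncompleteRepolarizationError(
            "incomplete repolarization: no downward crossing of "
            f"{level:.1f} mV before trace end")
    k = ipk + below[0]
    tc = seg_t[k] + (seg_v[k] - level) / (seg_v[k] - seg_v[k + 1]) \
        * (seg_t[k + 1] - seg_t[k])
    return float(tc - seg_t[0])


def apd_of_variant(params: CellParams, cycle_length: float = 500.0,
                   n_beats: int = 100, fraction: float = 0.9) -> float:
    """Convenience: steady-state APD of a parameter set (last paced beat)."""
    _, trace = pace_to_steady_state(params, cycle_length, n_beats,
                                    record_last=1)
    return measure_apd(trace, fraction)


def save_state(path, state: np.ndarray, variant: str = "control",
               gks_scale: float = 1.0) -> None:
    """Write a steady-state snapshot as a flat named-value text table."""
    with open(path, "w") as fh:
        fh.write(f"# model tt2006_epi variant {variant} "
                 f"gKs_scale {gks_scale}\n")
        for name, val in zip(STATE_NAMES, state):
            fh.write(f"{name} {float(val)!r}\n")


def load_state(path) -> np.ndarray:
    names = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            k, v = line.split()
            names[k] = float(v)
    missing = set(STATE_NAMES) - set(names)
    if missing:
        raise ValueError(f"state file missing variables: {sorted(missing)}")
    return np.array([names[n] for n in STATE_NAMES])
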