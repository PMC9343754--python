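"""Single-cell CRN electrophysiology: stepping, pacing, APD90 measurement.

The single cell is integrated with the same kernel as tissue (one node, no
neighbours).  Default numerics: Rush–Larsen gates + forward-Euler membrane
potential and concentrations at ``dt = 0.02 ms``.

APD90 convention: the upstroke time is the instant of maximum dV/dt, the
take-off potential is the diastolic minimum immediately preceding the
upstroke, and APD90 is the time from the upstroke until V first recovers to
``peak - 0.9 (peak - takeoff)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import crn
from .kernels import (BLANK_MS, SIG_TAB, V_THRESH, DivergenceError, aux_table,
                      make_event_buffers, run_segment)
from .presets import ScalingPreset

#: default stimulus: 2 ms rectangular pulse, ~2x diastolic threshold
STIM_AMP = 20.0   # pA/pF
STIM_DUR = 2.0    # ms
DEFAULT_DT = 0.02  # ms

_GATE_SLICE = slice(1, 16)
_CONC_SLICE = slice(16, 21)


@dataclass
class CellState:
    """Full state of one atrial myocyte (thin wrapper over the 21-vector)."""

    vec: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.vec = np.asarray(self.vec, dtype=float)
        if self.vec.shape != (crn.N_STATE,):
            raise ValueError(f"state vector must have shape ({crn.N_STATE},)")

    @property
    def V(self) -> float:
        return float(self.vec[0])

    @property
    def gates(self) -> np.ndarray:
        return self.vec[_GATE_SLICE]

    @property
    def concentrations(self) -> np.ndarray:
        return self.vec[_CONC_SLICE]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vec)):
            bad = int(np.flatnonzero(~np.isfinite(self.vec))[0])
            raise DivergenceError(f"non-finite state component index {bad} at t={self.time} ms")
        g = self.gates
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(self.concentrations <= 0):
            raise ValueError("non-positive ionic concentration")

    def copy(self) -> "CellState":
        return CellState(self.vec.copy(), self.time)


@dataclass
class APTrace:
    """Uniformly sampled (time, V) action-potential trace."""

    t: np.ndarray                 # ms
    v: np.ndarray                 # mV
    preset_name: str = ""
    cycle_length: float = np.nan  # ms
    captured: bool = True         # False when 1:1 capture was lost
    apd90_history: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.v]),
                   header="time_ms V_mV", fmt="%.4f")


def _run_single(vec: np.ndarray, preset: ScalingPreset, dt: float,
                n_steps: int, t0: float,
                stim_times: np.ndarray, stim_amp: float = STIM_AMP,
                stim_dur: float = STIM_DUR,
                rec_every: int = 0, vm_out: np.ndarray | None = None,
                ev: dict | None = None) -> tuple[float, dict]:
    state = vec.reshape(1, crn.N_STATE)
    if ev is None:
        ev = make_event_buffers(1, n_steps * dt)
    if vm_out is None:
        vm_out = np.empty((1, 0), dtype=np.float32)
        rec_every = 0
    status, node, t, _ = run_segment(
        state, np.zeros(1, dtype=np.int32),
        preset.as_vector().reshape(1, -1),
        np.ones(1, dtype=np.uint8),
        np.full((1, 8), -1, dtype=np.int32), np.zeros((1, 8)),
        crn.rate_table(dt), crn.TAB_VMIN, crn.TAB_DV, dt, n_steps, t0,
        np.ones(1, dtype=np.uint8), np.asarray(stim_times, dtype=float),
        stim_dur, stim_amp,
        np.zeros(1, dtype=np.int32) if rec_every else np.empty(0, dtype=np.int32),
        rec_every, vm_out, 0,
        ev["act_t"], ev["rep_t"], ev["n_act"], ev["n_rep"],
        ev["in_ap"], ev["peak_v"], ev["takeoff_v"], ev["last_act"],
        V_THRESH, BLANK_MS, SIG_TAB, aux_table(dt), 0.0)
    if status != 0:
        raise DivergenceError(f"membrane potential diverged at t={t:.3f} ms")
    return t, ev


def resting_state(preset: ScalingPreset, dt: float = DEFAULT_DT,
                  tol: float = 1e-4, max_seconds: int = 60) -> CellState:
    """Equilibrated quiescent state for ``preset``.

    Integrates without stimulus from the published CRN resting state until
    the membrane potential drifts by less than ``tol`` mV/ms (measured over
    1-s blocks), so the returned state is a numerical fixed point.
    """
    key = (hash(preset), round(dt, 9), tol)
    if key in _rest_cache:
        return _rest_cache[key].copy()
    vec = crn.INITIAL_STATE.copy()
    none = np.empty(0)
    t = 0.0
    steps_1s = int(round(1000.0 / dt))
    for _ in range(max_seconds):
        v0 = vec[0]
        t, _ev = _run_single(vec, preset, dt, steps_1s, t, none)
        if abs(vec[0] - v0) < tol * 1000.0:
            break
    st = CellState(vec, 0.0)
    st.validate()
    _rest_cache[key] = st.copy()
    return st


_rest_cache: dict = {}


def step_cell(state: CellState, preset: ScalingPreset, stim: float = 0.0,
              dt: float = DEFAULT_DT) -> CellState:
    """Advance one cell a single step of ``dt`` ms with stimulus ``stim``
    (pA/pF, depolarizing positive)."""
    if dt > 0.05:
        raise ValueError("cell-level dt must be <= 0.05 ms")
    out = state.copy()
    if stim != 0.0:
        _run_single(out.vec, preset, dt, 1, state.time,
                    np.array([state.time]), stim_amp=stim, stim_dur=dt + 1e-9)
    else:
        _run_single(out.vec, preset, dt, 1, state.time, np.empty(0))
    out.time = state.time + dt
    out.validate()
    return out


def _trace_beat_apd90(t: np.ndarray, v: np.ndarray) -> float:
    """APD90 of a single-beat trace (nan when no upstroke detected)."""
    vals = apd90_series(t, v)
    return float(vals[0]) if vals.size else np.nan


def apd90_series(t: np.ndarray, v: np.ndarray,
                 dvdt_thresh: float = 5.0, blank_ms: float = 60.0) -> np.ndarray:
    """APD90 per beat of a sampled trace.

    Upstrokes are sample runs where dV/dt exceeds ``dvdt_thresh`` mV/ms
    (separated by ``blank_ms``); for each, the take-off potential is V at
    the maximum-dV/dt sample and APD90 the time to first recovery to
    ``peak - 0.9 (peak - takeoff)``, with linear sub-sample interpolation.
    Returns an empty array (with a warning) when no upstroke is found.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dt = t[1] - t[0]
    dvdt = np.gradient(v, dt)
    above = dvdt > dvdt_thresh
    if not above.any():
        warnings.warn("no upstroke detected in trace")
        return np.array([])
    # segment starts: rising edges separated by the blanking interval
    idx = np.flatnonzero(above)
    starts = [idx[0]]
    for k in idx[1:]:
        if t[k] - t[starts[-1]] > blank_ms:
            if not above[k - 1]:
                starts.append(k)
    starts.append(len(t))
    out = []
    pre = int(round(50.0 / dt))  # diastolic look-back for the take-off potential
    for s, e in zip(starts[:-1], starts[1:]):
        seg = slice(s, e)
        up_rel = np.argmax(dvdt[seg])
        up = s + up_rel
        takeoff = float(np.min(v[max(0, up - pre):up + 1]))
        peak_rel = np.argmax(v[up:e])
        peak_i = up + peak_rel
        peak = v[peak_i]
        v90 = peak - 0.9 * (peak - takeoff)
        below = np.flatnonzero(v[peak_i:e] <= v90)
        if below.size == 0:
            continue  # beat not repolarized within the trace
        k = peak_i + below[0]
        if k == 0 or v[k - 1] == v[k]:
            t90 = t[k]
        else:
            t90 = t[k - 1] + dt * (v[k - 1] - v90) / (v[k - 1] - v[k])
        out.append(t90 - t[up])
    return np.asarray(out)


def apd90(trace: APTrace) -> np.ndarray:
    """APD90 (ms) of each beat in ``trace``; see :func:`apd90_series`."""
    return apd90_series(trace.t, trace.v)


def pace_cell(preset: ScalingPreset, cycle_length: float, n_beats: int = 50,
              dt: float = DEFAULT_DT, sample_ms: float = 0.1,
              steady_tol: float = 1.0,
              stim_amp: float = STIM_AMP, stim_dur: float = STIM_DUR) -> APTrace:
    """Pace a cell at fixed ``cycle_length`` until APD90 is steady.

    Beats are applied until the beat-to-beat APD90 change falls below
    ``steady_tol`` ms (after at least 5 beats) or ``n_beats`` is reached.
    Returns the trace of the final beat; ``apd90_history`` holds the per-beat
    APD90 series and ``captured`` is False if any beat failed to elicit an
    upstroke (loss of 1:1 capture).
    """
    if cycle_length < 100:
        raise ValueError("cycle_length must be >= 100 ms")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    vec = resting_state(preset, dt).vec
    steps_beat = int(round(cycle_length / dt))
    rec_every = max(1, int(round(sample_ms / dt)))
    nsamp = (steps_beat + rec_every - 1) // rec_every
    captured = True
    apds: list[float] = []
    t = 0.0
    beat_v = np.empty((1, nsamp), dtype=np.float32)
    for b in range(n_beats):
        beat_v[:] = 0.0
        _run_single(vec, preset, dt, steps_beat, t, np.array([t]),
                    stim_amp=stim_amp, stim_dur=stim_dur,
                    rec_every=rec_every, vm_out=beat_v)
        t += cycle_length
        tb = np.arange(nsamp) * (rec_every * dt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = _trace_beat_apd90(tb, beat_v[0].astype(float))
        if np.isnan(a):
            captured = False
        apds.append(a)
        if b >= 4 and captured and abs(apds[-1] - apds[-2]) < steady_tol:
            break
    return APTrace(tb, beat_v[0].astype(float), preset.name, cycle_length,
                   captured, np.asarray(apds))


def dynamic_restitution(preset: ScalingPreset,
                        cycle_lengths=(1000, 800, 600, 500, 400, 350, 300,
                                       250, 220, 200, 180, 160, 140),
                        dt: float = DEFAULT_DT,
                        **kw) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic (pacing-down) restitution portrait of a cell preset.

    Paces to steady state at each cycle length and returns the matched
    (DI, APD90) arrays, with DI = CL - preceding APD90.  This is the
    explicit pacing-protocol alternative to collecting restitution pairs
    from fibrillatory activity.
    """
    di, apd = [], []
    for cl in cycle_lengths:
        tr = pace_cell(preset, float(cl), dt=dt, **kw)
        if not tr.captured or tr.apd90_history.size < 2:
            continue
        a = float(tr.apd90_history[-1])
        di.append(float(cl) - a)
        apd.append(a)
    di, apd = np.asarray(di), np.asarray(apd)
    keep = di > 0
    return di[keep], apd[keep]


def steady_apd90(preset: ScalingPreset, cycle_length: float = 600.0,
                 **kw) -> float:
    """Steady-state APD90 (ms) at ``cycle_length``; nan on capture failure."""
    tr = pace_cell(preset, cycle_length, **kw)
    if not tr.captured or tr.apd90_history.size == 0:
        return np.nan
    return float(tr.apd90_history[-1])
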