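"""Anisotropic monodomain reaction-diffusion solver on a 2D lattice.

The tissue is a regular lattice of CRN nodes coupled by an anisotropic
diffusion tensor ``D = D_T I + (D_L - D_T) f f^T`` (``f`` the local fiber
direction).  The divergence-form operator is discretized as a 9-point
stencil with face-averaged coefficients and no-flux boundaries; fibrotic
nodes carry reduced coupling, ablated nodes are clamped at 0 mV and removed
from the coupling graph entirely (permanent conduction block).

Region labels on the grid (pulmonary-vein ostia, high septum = pacing zone,
appendage, body) drive pacing-site selection, conduction-velocity
measurement and ablation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import crn
from .cellmodel import resting_state
from .kernels import (BLANK_MS, SIG_TAB, V_THRESH, DivergenceError, aux_table,
                      make_event_buffers, run_segment)
from .presets import CURRENTS, FIBROTIC_MODIFIER, ScalingPreset, compose

# region label codes
BODY, PV1, PV2, PV3, PV4, SEPTUM, APPENDAGE = 0, 1, 2, 3, 4, 5, 6
LABEL_NAMES = {BODY: "body", PV1: "pv1", PV2: "pv2", PV3: "pv3", PV4: "pv4",
               SEPTUM: "septum", APPENDAGE: "appendage"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}
PV_LABELS = (PV1, PV2, PV3, PV4)

#: coupling multiplier applied to fibrotic nodes
FIBROTIC_COUPLING = 0.5

# default diffusion (mm^2/ms) before CV calibration; anisotropy 5:1
DEFAULT_D_L = 0.10
DEFAULT_D_T = 0.02


class CalibrationError(RuntimeError):
    """Conduction-velocity calibration could not bracket the target."""


@dataclass
class AblationMask:
    """Set of lattice nodes (flat indices) destined for conduction block."""

    nodes: np.ndarray
    descriptor: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.unique(np.asarray(self.nodes, dtype=np.int64))

    @property
    def size(self) -> int:
        return int(self.nodes.size)

    def union(self, other: "AblationMask") -> "AblationMask":
        return AblationMask(np.union1d(self.nodes, other.nodes),
                            f"{self.descriptor}+{other.descriptor}")


@dataclass
class TissueGrid:
    """Discretized 2D atrial sheet.

    Arrays are (ny, nx); flat node index is ``iy * nx + ix``.
    """

    dx: float                       # lattice spacing, mm
    labels: np.ndarray              # int8 region codes
    fibrotic: np.ndarray            # bool
    fiber_angle: np.ndarray         # radians
    interior: np.ndarray            # bool, conducting domain
    D_L: float = DEFAULT_D_L        # longitudinal diffusion, mm^2/ms
    D_T: float = DEFAULT_D_T        # transverse diffusion, mm^2/ms
    ablated: np.ndarray | None = None
    voltage: np.ndarray | None = None   # bipolar-voltage surrogate, mV
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if not (self.D_L >= self.D_T > 0):
            raise ValueError("require D_L >= D_T > 0")
        if self.ablated is None:
            self.ablated = np.zeros_like(self.interior)
        for a in (self.fibrotic, self.fiber_angle, self.interior, self.ablated):
            if a.shape != self.labels.shape:
                raise ValueError("all grid arrays must share one shape")
        if np.any(self.ablated & ~self.interior):
            raise ValueError("ablated nodes must lie inside the interior")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinates (x, y) in mm, shaped like the grid."""
        ny, nx = self.shape
        x = np.arange(nx) * self.dx
        y = np.arange(ny) * self.dx
        return np.meshgrid(x, y)

    def region_nodes(self, label: int | str) -> np.ndarray:
        code = LABEL_CODES[label] if isinstance(label, str) else label
        return np.flatnonzero((self.labels == code).ravel() & self.interior.ravel())

    def region_centroid(self, label: int | str) -> np.ndarray:
        nodes = self.region_nodes(label)
        if nodes.size == 0:
            raise ValueError(f"region {label!r} is empty")
        X, Y = self.coords()
        return np.array([X.ravel()[nodes].mean(), Y.ravel()[nodes].mean()])

    def mean_adjacent_spacing(self) -> float:
        """Mean distance (mm) over 4-neighbor interior node pairs."""
        ny, nx = self.shape
        inter = self.interior
        n_h = np.count_nonzero(inter[:, 1:] & inter[:, :-1])
        n_v = np.count_nonzero(inter[1:, :] & inter[:-1, :])
        if n_h + n_v == 0:
            raise ValueError("no adjacent interior pairs")
        return float((n_h + n_v) * self.dx / (n_h + n_v))

    def copy(self) -> "TissueGrid":
        return replace(
            self, labels=self.labels.copy(), fibrotic=self.fibrotic.copy(),
            fiber_angle=self.fiber_angle.copy(), interior=self.interior.copy(),
            ablated=self.ablated.copy(),
            voltage=None if self.voltage is None else self.voltage.copy(),
            meta=dict(self.meta))


def apply_ablation(grid: TissueGrid, mask: AblationMask) -> TissueGrid:
    """Grid with ``mask`` nodes permanently blocked (idempotent)."""
    if mask.size and (mask.nodes.min() < 0 or mask.nodes.max() >= grid.n_nodes):
        raise ValueError("ablation mask outside the lattice")
    if mask.size and not grid.interior.ravel()[mask.nodes].all():
        raise ValueError("ablation mask outside the interior")
    out = grid.copy()
    flat = out.ablated.ravel()
    flat[mask.nodes] = True
    return out


def _conductance_tensor(grid: TissueGrid, scale: float):
    """Per-node (Dxx, Dxy, Dyy); zero at non-conducting nodes."""
    th = grid.fiber_angle
    c, s = np.cos(th), np.sin(th)
    dl, dt = grid.D_L * scale, grid.D_T * scale
    dxx = dt + (dl - dt) * c * c
    dyy = dt + (dl - dt) * s * s
    dxy = (dl - dt) * c * s
    coup = np.where(grid.fibrotic, FIBROTIC_COUPLING, 1.0)
    cond = grid.interior & ~grid.ablated
    coup = np.where(cond, coup, 0.0)
    return dxx * coup, dxy * coup, dyy * coup


def build_stencil(grid: TissueGrid, scale: float = 1.0):
    """Neighbor indices (n, 8) and weights (n, 8) of the diffusion operator
    ``L(V)_i = sum_q w[i,q] (V[nbr[i,q]] - V_i)`` (zero on constant fields)."""
    ny, nx = grid.shape
    dxx, dxy, dyy = _conductance_tensor(grid, scale)
    inv2 = 1.0 / grid.dx ** 2
    cond = (grid.interior & ~grid.ablated)

    def shifted(a, dy, dx_):
        out = np.zeros_like(a)
        ys = slice(max(dy, 0), ny + min(dy, 0))
        xs = slice(max(dx_, 0), nx + min(dx_, 0))
        yt = slice(max(-dy, 0), ny + min(-dy, 0))
        xt = slice(max(-dx_, 0), nx + min(-dx_, 0))
        out[yt, xt] = a[ys, xs]
        return out

    has = {}
    for q, (dy, dx_) in enumerate(_OFFSETS):
        has[q] = shifted(cond, dy, dx_)

    w = np.zeros((ny, nx, 8))
    # axis faces: arithmetic-mean face coefficient, zero flux at missing faces
    for q, (dy, dx_), comp in ((0, (0, 1), dxx), (1, (0, -1), dxx),
                               (2, (1, 0), dyy), (3, (-1, 0), dyy)):
        face = 0.5 * (comp + shifted(comp, dy, dx_)) * inv2
        w[:, :, q] = np.where(has[q] & cond, face, 0.0)
    # cross-derivative terms on diagonals
    dxy_e, dxy_w = shifted(dxy, 0, 1), shifted(dxy, 0, -1)
    dxy_n, dxy_s = shifted(dxy, 1, 0), shifted(dxy, -1, 0)
    quarter = 0.25 * inv2
    w[:, :, 4] = np.where(has[4] & cond, (dxy_e + dxy_n) * quarter, 0.0)   # NE
    w[:, :, 5] = np.where(has[5] & cond, -(dxy_w + dxy_n) * quarter, 0.0)  # NW
    w[:, :, 6] = np.where(has[6] & cond, -(dxy_e + dxy_s) * quarter, 0.0)  # SE
    w[:, :, 7] = np.where(has[7] & cond, (dxy_w + dxy_s) * quarter, 0.0)   # SW

    idx = np.arange(ny * nx).reshape(ny, nx)
    nbr = np.full((ny, nx, 8), -1, dtype=np.int32)
    for q, (dy, dx_) in enumerate(_OFFSETS):
        sh = shifted(idx + 1, dy, dx_) - 1  # -1 where out of lattice
        nbr[:, :, q] = np.where(has[q] & cond & (sh >= 0), sh, -1)
    w[nbr == -1] = 0.0
    return nbr.reshape(-1, 8), w.reshape(-1, 8)


# neighbor offsets (dy, dx): E, W, N, S, NE, NW, SE, SW
_OFFSETS = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))


def max_stable_dt(grid: TissueGrid, scale: float = 1.0) -> float:
    """Conservative explicit-diffusion stability limit (ms)."""
    return grid.dx ** 2 / (2.0 * (grid.D_L + grid.D_T) * scale * max(FIBROTIC_COUPLING, 1.0))


@dataclass
class SimulationRecord:
    """Sampled membrane potential and per-node event times of one episode."""

    t_samp: np.ndarray            # ms, sample instants
    vm: np.ndarray                # (n_recorded, n_samples) float32, mV
    rec_nodes: np.ndarray         # flat node indices of recorded rows
    act_t: np.ndarray             # (n_nodes, max_ev) activation times, NaN-padded
    rep_t: np.ndarray             # (n_nodes, max_ev) 90%-repolarization times
    n_act: np.ndarray             # per-node activation counts
    n_rep: np.ndarray
    duration: float               # ms
    dt: float
    ablated: np.ndarray           # flat bool, nodes excluded from analysis
    meta: dict = field(default_factory=dict)

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / (self.t_samp[1] - self.t_samp[0])

    def activations(self, node: int) -> np.ndarray:
        return self.act_t[node, : self.n_act[node]]

    def repolarizations(self, node: int) -> np.ndarray:
        return self.rep_t[node, : self.n_rep[node]]


def node_preset_assignment(grid: TissueGrid, base: ScalingPreset,
                           fibrotic_modifier: ScalingPreset = FIBROTIC_MODIFIER):
    """Per-node preset table: ``base`` everywhere, ``base x fibrotic`` at
    fibrotic nodes.  Returns (factors (P,13), pidx (n,), presets list)."""
    fib = compose(base, fibrotic_modifier)
    factors = np.stack([base.as_vector(), fib.as_vector()])
    pidx = grid.fibrotic.ravel().astype(np.int32)
    return factors, pidx, [base, fib]


def simulate(grid: TissueGrid, node_presets, schedule, duration: float,
             dt: float = 0.1, sample_ms: float = 1.0,
             stim_region: int | str = SEPTUM, stim_radius_mm: float = 3.0,
             stim_amp: float = 40.0, max_recorded: int = 4096,
             diffusion_scale: float = 1.0, initial_state: np.ndarray | None = None,
             quiescence_exit_ms: float = 1500.0,
             meta: dict | None = None) -> SimulationRecord:
    """Run one tissue episode.

    ``node_presets`` is either a single :class:`ScalingPreset` (fibrotic
    nodes automatically receive the fibrotic modifier on top) or a
    ``(factors, pidx)`` pair.  ``schedule`` provides ``times`` (ms),
    ``amplitude`` (ignored when None; ``stim_amp`` pA/pF is used) and
    ``duration`` (ms) of the stimulus pulses, delivered in a disc of
    ``stim_radius_mm`` around the centroid of ``stim_region``.

    With no stimulus pending, a sheet that has been free of activations
    for ``quiescence_exit_ms`` can never re-activate (the model has no
    spontaneous activity), so integration stops early; the remaining
    samples stay at the resting value they would have held.  Set 0 to
    disable.
    """
    dt_max = max_stable_dt(grid, diffusion_scale)
    if dt > dt_max:
        raise ValueError(f"dt={dt} ms unstable for this grid; max admissible ~{dt_max:.4f} ms")

    n = grid.n_nodes
    if isinstance(node_presets, ScalingPreset):
        factors, pidx, preset_list = node_preset_assignment(grid, node_presets)
    else:
        factors, pidx = node_presets
        preset_list = None

    cond = (grid.interior & ~grid.ablated).ravel()
    active = cond.astype(np.uint8)

    # initial state: per-preset equilibrated cell, broadcast
    state = np.empty((n, crn.N_STATE))
    if initial_state is not None:
        state[:] = initial_state
    else:
        for p in range(factors.shape[0]):
            ps = ScalingPreset(f"_node{p}", dict(zip(CURRENTS, factors[p])))
            state[pidx == p] = resting_state(ps).vec
    state[~cond, 0] = 0.0  # ablated / exterior clamp

    nbr, wgt = build_stencil(grid, diffusion_scale)

    # stimulus disc
    X, Y = grid.coords()
    cx, cy = grid.region_centroid(stim_region)
    stim_mask = (((X - cx) ** 2 + (Y - cy) ** 2) <= stim_radius_mm ** 2)
    stim_mask = (stim_mask.ravel() & cond).astype(np.uint8)

    stim_times = np.asarray(getattr(schedule, "times", schedule), dtype=float)
    stim_dur = float(getattr(schedule, "duration", 2.0))
    amp = getattr(schedule, "amplitude", None)
    if amp is not None:
        stim_amp = float(amp)

    # recording subset: stride chosen to stay under max_recorded nodes
    cand = np.flatnonzero(cond)
    stride = 1
    ny, nx = grid.shape
    while cand.size > max_recorded:
        stride += 1
        iy, ix = np.divmod(np.flatnonzero(cond), nx)
        keep = (iy % stride == 0) & (ix % stride == 0)
        cand = np.flatnonzero(cond)[keep]
    rec_nodes = cand.astype(np.int32)

    rec_every = max(1, int(round(sample_ms / dt)))
    n_steps = int(round(duration / dt))
    nsamp = (n_steps + rec_every - 1) // rec_every
    vm = np.zeros((rec_nodes.size, nsamp), dtype=np.float32)
    ev = make_event_buffers(n, duration)

    status, node, t_bad, _ = run_segment(
        state, pidx.astype(np.int32), factors, active, nbr, wgt,
        crn.rate_table(dt), crn.TAB_VMIN, crn.TAB_DV, dt, n_steps, 0.0,
        stim_mask, stim_times, stim_dur, stim_amp,
        rec_nodes, rec_every, vm, 0,
        ev["act_t"], ev["rep_t"], ev["n_act"], ev["n_rep"],
        ev["in_ap"], ev["peak_v"], ev["takeoff_v"], ev["last_act"],
        V_THRESH, BLANK_MS, SIG_TAB, aux_table(dt), quiescence_exit_ms)
    if status != 0:
        iy, ix = divmod(int(node), nx)
        raise DivergenceError(f"divergence at node ({iy},{ix}) t={t_bad:.2f} ms")

    md = dict(meta or {})
    md.setdefault("dt", dt)
    if preset_list is not None:
        md.setdefault("presets", [p.name for p in preset_list])
    return SimulationRecord(
        t_samp=np.arange(nsamp) * rec_every * dt, vm=vm, rec_nodes=rec_nodes,
        act_t=ev["act_t"], rep_t=ev["rep_t"], n_act=ev["n_act"], n_rep=ev["n_rep"],
        duration=duration, dt=dt, ablated=grid.ablated.ravel().copy(), meta=md)


def measure_cv(record: SimulationRecord, grid: TissueGrid,
               from_region: int | str = SEPTUM,
               to_region: int | str = APPENDAGE, beat: int = 0) -> float:
    """Conduction velocity (m/s) of a paced beat between two regions:
    centroid distance over the difference of median activation times."""
    if (LABEL_CODES.get(from_region, from_region)
            == LABEL_CODES.get(to_region, to_region)):
        raise ValueError("from_region and to_region must differ")
    t_from = _region_beat_times(record, grid, from_region, beat)
    t_to = _region_beat_times(record, grid, to_region, beat)
    if t_from.size == 0 or t_to.size == 0:
        raise CaptureFailure("target region never activated")
    d = np.linalg.norm(grid.region_centroid(from_region)
                       - grid.region_centroid(to_region))
    dt_ms = float(np.median(t_to) - np.median(t_from))
    if dt_ms <= 0:
        raise CaptureFailure("activation did not propagate from source to target")
    return d / dt_ms  # mm/ms == m/s


class CaptureFailure(RuntimeError):
    """A paced beat failed to capture / propagate to the target region."""


def _region_beat_times(record, grid, region, beat):
    nodes = grid.region_nodes(region)
    times = [record.activations(i)[beat] for i in nodes
             if record.n_act[i] > beat]
    return np.asarray(times)


def _strip_grid(dx: float, D_L: float, D_T: float,
                length_mm: float = 40.0, width_mm: float = 2.0) -> TissueGrid:
    nx = int(round(length_mm / dx)) + 1
    ny = int(round(width_mm / dx)) + 1
    shape = (ny, nx)
    labels = np.zeros(shape, dtype=np.int8)
    return TissueGrid(dx=dx, labels=labels, fibrotic=np.zeros(shape, bool),
                      fiber_angle=np.zeros(shape), interior=np.ones(shape, bool),
                      D_L=D_L, D_T=D_T)


def planar_cv(dx: float, dt: float, D_L: float, D_T: float,
              preset: ScalingPreset, scale: float = 1.0,
              transverse: bool = False, duration: float = 500.0,
              length_mm: float = 40.0) -> float:
    """Longitudinal (or transverse) planar-wave CV (m/s) on a homogeneous
    fiber-aligned reference strip at the given numerics.  Activation times
    are taken at 1/4 and 3/4 of the strip length."""
    grid = _strip_grid(dx, D_L, D_T, length_mm=length_mm)
    if transverse:
        grid.fiber_angle[:] = np.pi / 2
    ny, nx = grid.shape
    dt = min(dt, 0.9 * max_stable_dt(grid, scale))
    factors = preset.as_vector().reshape(1, -1)
    pidx = np.zeros(grid.n_nodes, dtype=np.int32)
    state = np.tile(resting_state(preset).vec, (grid.n_nodes, 1))
    nbr, wgt = build_stencil(grid, scale)
    # stimulate a 1-mm-wide band at the left edge
    stim = np.zeros((ny, nx), dtype=np.uint8)
    stim[:, :max(3, int(round(1.0 / dx)))] = 1
    # default duration is generous so slow waves (~0.05 m/s) still traverse
    ev = make_event_buffers(grid.n_nodes, duration)
    status, *_ = run_segment(
        state, pidx, factors, np.ones(grid.n_nodes, dtype=np.uint8), nbr, wgt,
        crn.rate_table(dt), crn.TAB_VMIN, crn.TAB_DV, dt, int(round(duration / dt)), 0.0,
        stim.ravel(), np.array([1.0]), 2.0, 40.0,
        np.empty(0, dtype=np.int32), 0, np.empty((0, 0), dtype=np.float32), 0,
        ev["act_t"], ev["rep_t"], ev["n_act"], ev["n_rep"],
        ev["in_ap"], ev["peak_v"], ev["takeoff_v"], ev["last_act"],
        V_THRESH, BLANK_MS, SIG_TAB, aux_table(dt), 0.0)
    if status != 0:
        raise DivergenceError("divergence during reference-strip CV measurement")
    mid = ny // 2
    i1 = mid * nx + int(round(0.25 * length_mm / dx))
    i2 = mid * nx + int(round(0.75 * length_mm / dx))
    if ev["n_act"][i1] < 1 or ev["n_act"][i2] < 1:
        raise CaptureFailure("plane wave did not traverse the reference strip")
    return (0.5 * length_mm) / float(ev["act_t"][i2, 0] - ev["act_t"][i1, 0])


def calibrate_diffusion(grid: TissueGrid, preset: ScalingPreset,
                        target_cv: float, dt: float = 0.1,
                        tol: float = 0.05, max_iter: int = 12) -> float:
    """Global diffusion scale such that the longitudinal planar-wave CV at
    this grid's spacing and numerics matches ``target_cv`` within ``tol``
    (relative).  Bisection, at most ``max_iter`` iterations."""
    if not (0.1 < target_cv < 2.0):
        raise ValueError("target_cv must lie in (0.1, 2.0) m/s")

    def cv_at(s):
        try:
            return planar_cv(grid.dx, dt, grid.D_L, grid.D_T, preset, s)
        except CaptureFailure:
            return 0.0  # decremental conduction: below any positive target

    cv1 = cv_at(1.0)
    if abs(cv1 - target_cv) / target_cv <= tol:
        return 1.0
    # bracket the target: CV grows ~ sqrt(scale)
    if cv1 > 0:
        guess = (target_cv / cv1) ** 2
        lo, hi = guess / 4.0, guess * 4.0
    else:
        lo, hi = 1.0, 16.0
    cv_lo, cv_hi = cv_at(lo), cv_at(hi)
    for _ in range(6):
        if cv_lo >= target_cv and lo > 1e-4:
            hi, cv_hi = lo, cv_lo
            lo /= 16.0
            cv_lo = cv_at(lo)
        elif cv_hi <= target_cv and hi < 1e4:
            lo, cv_lo = hi, cv_hi
            hi *= 16.0
            cv_hi = cv_at(hi)
        else:
            break
    if not (cv_lo < target_cv < cv_hi):
        raise CalibrationError(
            f"target {target_cv} m/s outside achievable range "
            f"[{cv_lo:.3f}, {cv_hi:.3f}] m/s")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log space (CV ~ sqrt(D))
        cv_mid = cv_at(mid)
        if abs(cv_mid - target_cv) / target_cv <= tol:
            return float(mid)
        if cv_mid < target_cv:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
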