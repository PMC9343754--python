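"""Stimulation and intervention protocols.

Implements the study protocol: ramp-pacing AF induction (cycle length
stepping 200 -> 120 ms, 8 beats per stage, 11,520 ms), the 32-s episode
layout with its 17-23 s analysis window, fixed-rate pacing for APD90/CV
measurement, circumferential PV isolation (CPVI) contours, and high-DF-site
ablation targeting.  A proportionally scaled episode layout (4 beats per
stage, 16 s total) is provided for desk-scale runs.

Episode plans are pure data: JSON-serializable, no simulation side effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .tissue import AblationMask, PV_LABELS, TissueGrid

GENOTYPES = ("wild_type", "pitx2_deficient")


@dataclass
class PacingSchedule:
    """Ordered stimulus train: pulse onset times, amplitude, pulse width."""

    times: np.ndarray               # ms, strictly increasing
    amplitude: float | None = None  # pA/pF; None -> solver default
    duration: float = 2.0           # pulse width, ms

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")

    @property
    def n_stimuli(self) -> int:
        return int(self.times.size)


def ramp_pacing_protocol(start_cl: float = 200.0, end_cl: float = 120.0,
                         step: float = 10.0, beats_per_stage: int = 8,
                         t0: float = 0.0) -> tuple[PacingSchedule, float]:
    """Burst-induction ramp: stages at CL start, start-step, ..., end with
    ``beats_per_stage`` stimuli each.

    Returns ``(schedule, total_duration_ms)`` where the duration is exactly
    ``beats_per_stage * sum(CLs)`` (11,520 ms at the defaults).
    """
    if start_cl < end_cl:
        raise ValueError("start_cl must be >= end_cl")
    if end_cl <= 0:
        raise ValueError("end_cl must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    n_stages = (start_cl - end_cl) / step
    if abs(n_stages - round(n_stages)) > 1e-9:
        raise ValueError("(start_cl - end_cl) must be divisible by step")
    cls = start_cl - step * np.arange(int(round(n_stages)) + 1)
    times = []
    t = t0
    for cl in cls:
        for _ in range(beats_per_stage):
            times.append(t)
            t += cl
    return PacingSchedule(np.asarray(times)), float(beats_per_stage * cls.sum())


@dataclass
class Intervention:
    """What is done to the substrate before/during an episode."""

    kind: str = "none"           # none | cpvi | cpvi_dfa | drug
    drug: str | None = None
    dose: str | None = None      # "low" | "high"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "cpvi", "cpvi_dfa", "drug"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "drug" and (self.drug is None or self.dose is None):
            raise ValueError("drug intervention requires drug and dose")

    @property
    def label(self) -> str:
        return f"{self.drug}_{self.dose}" if self.kind == "drug" else self.kind


@dataclass
class EpisodePlan:
    """Full layout of one simulated episode (pure data)."""

    genotype: str
    intervention: Intervention
    induction_times: np.ndarray      # ms
    induction_duration: float        # ms
    observation: float               # ms
    analysis_window: tuple[float, float]
    stim_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        lo, hi = self.analysis_window
        if not (0 <= lo < hi <= self.total_duration):
            raise ValueError("analysis window must lie inside the episode")

    @property
    def total_duration(self) -> float:
        return self.induction_duration + self.observation

    @property
    def schedule(self) -> PacingSchedule:
        return PacingSchedule(self.induction_times, duration=self.stim_duration)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["induction_times"] = [float(t) for t in self.induction_times]
        d["analysis_window"] = list(self.analysis_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EpisodePlan":
        d = dict(d)
        d["intervention"] = Intervention(**d["intervention"])
        d["induction_times"] = np.asarray(d["induction_times"])
        d["analysis_window"] = tuple(d["analysis_window"])
        return cls(**d)


def episode_plan(genotype: str, intervention: Intervention | str = "none",
                 scale: str = "full") -> EpisodePlan:
    """Standard episode layout for a genotype and intervention.

    ``scale="full"``: ramp induction 11,520 ms + 20,480 ms observation
    (32 s total), wave dynamics analyzed over 17,000-23,000 ms.
    ``scale="desk"``: proportionally scaled episode — 4 beats per ramp
    stage (5,760 ms) + 10,240 ms observation (16 s), window 8,000-14,000 ms.
    """
    if isinstance(intervention, str):
        intervention = Intervention(kind=intervention)
    if scale == "full":
        sched, dur = ramp_pacing_protocol(beats_per_stage=8)
        return EpisodePlan(genotype, intervention, sched.times, dur,
                           observation=20480.0, analysis_window=(17000.0, 23000.0))
    if scale == "desk":
        sched, dur = ramp_pacing_protocol(beats_per_stage=4)
        return EpisodePlan(genotype, intervention, sched.times, dur,
                           observation=10240.0, analysis_window=(8000.0, 14000.0))
    if scale == "mini":  # smoke-test layout: 1 beat per stage, 4 s episode
        sched, dur = ramp_pacing_protocol(beats_per_stage=1)
        return EpisodePlan(genotype, intervention, sched.times, dur,
                           observation=2560.0, analysis_window=(1500.0, 3900.0))
    raise ValueError("scale must be 'full', 'desk' or 'mini'")


def _pv_pairs(grid: TissueGrid) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ipsilateral PV ostium pairs (by x coordinate of the centroids)."""
    cents = []
    for lab in PV_LABELS:
        if grid.region_nodes(lab).size:
            cents.append((lab, grid.region_centroid(lab)))
    if len(cents) != 4:
        raise ValueError("grid must carry 4 labeled PV ostia")
    cents.sort(key=lambda lc: lc[1][0])
    return [(cents[0][1], cents[1][1]), (cents[2][1], cents[3][1])]


def cpvi_mask(grid: TissueGrid, line_width: int = 2,
              margin_mm: float = 3.0) -> AblationMask:
    """Circumferential PV isolation: two closed stadium-shaped contours,
    each encircling one ipsilateral PV pair, ``line_width`` nodes wide.

    Raises a geometry error when a contour cannot close inside the domain.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    X, Y = grid.coords()
    pv_r = grid.meta.get("pv_radius")
    if pv_r is None:
        # infer from ostium area: r = sqrt(A/pi)
        area = grid.region_nodes(PV_LABELS[0]).size * grid.dx ** 2
        pv_r = float(np.sqrt(area / np.pi))
    ring_r = pv_r + margin_mm
    nodes = []
    for (c1, c2) in _pv_pairs(grid):
        d = _dist_to_segment(X, Y, c1, c2)
        ring = (d >= ring_r) & (d < ring_r + line_width * grid.dx)
        inner = d < ring_r
        if np.any(ring & ~grid.interior) or _touches_boundary(ring):
            raise ValueError("CPVI contour cannot close: PV pair too near the boundary")
        # closure check: flood fill from inside must not escape the ring
        outside = _flood_outside(grid.interior & ~ring)
        if np.any(inner & outside):
            raise ValueError("CPVI contour is not closed")
        nodes.append(np.flatnonzero(ring.ravel()))
    return AblationMask(np.concatenate(nodes), descriptor="cpvi")


def _dist_to_segment(X, Y, a, b):
    ab = b - a
    L2 = float(ab @ ab)
    t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / (L2 if L2 else 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(X - (a[0] + t * ab[0]), Y - (a[1] + t * ab[1]))


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def _flood_outside(open_mask: np.ndarray) -> np.ndarray:
    """Nodes of ``open_mask`` reachable (4-connected) from the lattice rim."""
    lab, _ = ndimage.label(open_mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    rim = np.unique(np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    rim = rim[rim > 0]
    return np.isin(lab, rim)


def high_df_targets(df_map: np.ndarray, grid: TissueGrid,
                    percentile: float = 90.0, site_radius_mm: float = 5.0,
                    max_sites: int = 3) -> AblationMask:
    """Ablation discs at high dominant-frequency sites.

    Candidate regions are the connected components of the map at or above
    the given percentile (undefined nodes excluded); each contributes its
    peak node (ties -> lowest flat index), peaks are non-maximum-suppressed
    at twice the disc radius in descending DF order, and up to
    ``max_sites`` discs of ``site_radius_mm`` are returned.  Deterministic
    for a given map.  An all-undefined map yields an empty mask with a
    warning.
    """
    ny, nx = grid.shape
    df = np.asarray(df_map, dtype=float).reshape(ny, nx)
    defined = np.isfinite(df) & grid.interior & ~grid.ablated
    if not defined.any():
        warnings.warn("DF map has no defined nodes; empty ablation set")
        return AblationMask(np.array([], dtype=np.int64), descriptor="dfa:empty")
    thr = np.percentile(df[defined], percentile)
    cand = defined & (df >= thr)
    lab, n_comp = ndimage.label(cand)
    peaks = []
    for c in range(1, n_comp + 1):
        idx = np.flatnonzero((lab == c).ravel())
        vals = df.ravel()[idx]
        peaks.append((idx[int(np.argmax(vals))], float(vals.max())))
    # NMS: descending DF, ties by lowest node index
    peaks.sort(key=lambda p: (-p[1], p[0]))
    X, Y = grid.coords()
    xf, yf = X.ravel(), Y.ravel()
    chosen: list[int] = []
    for node, _val in peaks:
        if len(chosen) >= max_sites:
            break
        if all(np.hypot(xf[node] - xf[c], yf[node] - yf[c]) > 2 * site_radius_mm
               for c in chosen):
            chosen.append(node)
    discs = np.zeros(ny * nx, dtype=bool)
    for c in chosen:
        discs |= (np.hypot(xf - xf[c], yf - yf[c]) <= site_radius_mm)
    discs &= (grid.interior & ~grid.ablated).ravel()
    return AblationMask(np.flatnonzero(discs),
                        descriptor=f"dfa:{len(chosen)}sites")
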