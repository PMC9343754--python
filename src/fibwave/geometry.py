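"""Seeded synthetic left-atrium-like substrate generator.

Stands in for patient electroanatomical models: a rectangular monolayer
sheet with four labeled pulmonary-vein (PV) ostia, a high-septum pacing
zone and an appendage zone; a spatially correlated bipolar-voltage
surrogate in the clinical 0.05-5 mV envelope (smooth random field sampled
at pseudo-electrode points and inverse-distance-weighted back onto the
lattice, mimicking electroanatomical map interpolation); a voltage-driven
probabilistic fibrosis field; and a smooth fiber-orientation field with
circumferential wrap around each PV ostium.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .tissue import (APPENDAGE, BODY, PV_LABELS, SEPTUM, TissueGrid,
                     DEFAULT_D_L, DEFAULT_D_T)

#: clinical bipolar-voltage envelope (mV)
V_LO, V_HI = 0.05, 5.0


@dataclass
class GeometryConfig:
    """Parameters of the synthetic substrate.

    Defaults give the 60 x 60 mm experiment sheet; use
    :func:`full_resolution_config` for the mesh-statistic-matched spacing
    and :func:`test_scale_config` for coarse, fast grids.
    """

    size_mm: tuple[float, float] = (60.0, 60.0)
    dx: float = 0.25                      # lattice spacing, mm
    pv_radius: float = 4.0                # ostium disc radius, mm
    pv_centers: tuple | None = None       # ((x,y),)*4; default from size
    septum_center: tuple | None = None
    septum_radius: float = 4.0
    appendage_center: tuple | None = None
    appendage_radius: float = 4.0
    fibrosis_burden: float | None = 0.20  # target fibrotic fraction; None -> fixed v0
    corr_length_mm: float = 8.0           # voltage-field correlation length
    n_electrodes: int = 500               # pseudo-electrode sample points
    v0: float = 0.5                       # logistic fibrosis midpoint, mV
    k: float = 0.15                       # logistic slope, mV
    fiber_perturb_deg: float = 25.0       # amplitude of smooth fiber deviation
    fiber_smooth_mm: float = 10.0
    pv_wrap: bool = True                  # circumferential fibers at PV rims
    pv_hole_frac: float = 0.5             # vein-lumen fraction of the ostium disc
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.size_mm
        if self.pv_centers is None:
            self.pv_centers = ((0.2 * w, 0.3 * h), (0.2 * w, 0.7 * h),
                               (0.8 * w, 0.3 * h), (0.8 * w, 0.7 * h))
        if self.septum_center is None:
            self.septum_center = (0.5 * w, 0.87 * h)
        if self.appendage_center is None:
            self.appendage_center = (0.5 * w, 0.13 * h)
        if self.fibrosis_burden is not None and not (0 <= self.fibrosis_burden < 1):
            raise ValueError("fibrosis burden must be in [0, 1)")
        if self.k <= 0:
            raise ValueError("logistic slope k must be > 0")
        # ostia must be disjoint and strictly interior
        cs = np.asarray(self.pv_centers, dtype=float)
        for i in range(len(cs)):
            x, y = cs[i]
            if not (self.pv_radius < x < w - self.pv_radius
                    and self.pv_radius < y < h - self.pv_radius):
                raise ValueError("PV ostium not strictly interior")
            for j in range(i + 1, len(cs)):
                if np.linalg.norm(cs[i] - cs[j]) <= 2 * self.pv_radius:
                    raise ValueError("PV ostia overlap")


def full_resolution_config(**kw) -> GeometryConfig:
    """Config at the mesh-statistic-matched spacing (235.1 um)."""
    kw.setdefault("dx", 0.2351)
    return GeometryConfig(**kw)


def test_scale_config(**kw) -> GeometryConfig:
    """Small, coarse substrate for fast tests (20 x 20 mm, dx 0.5 mm)."""
    kw.setdefault("size_mm", (20.0, 20.0))
    kw.setdefault("dx", 0.5)
    kw.setdefault("pv_radius", 1.5)
    kw.setdefault("septum_radius", 1.5)
    kw.setdefault("appendage_radius", 1.5)
    kw.setdefault("corr_length_mm", 4.0)
    kw.setdefault("n_electrodes", 60)
    return GeometryConfig(**kw)


@dataclass
class VoltageMap:
    """Per-node bipolar-voltage surrogate (mV), shaped like the grid."""

    values: np.ndarray
    electrode_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))
    electrode_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("voltage map must be finite and positive")


def _lattice(config: GeometryConfig) -> tuple[int, int]:
    w, h = config.size_mm
    return int(round(h / config.dx)) + 1, int(round(w / config.dx)) + 1


def make_geometry(config: GeometryConfig) -> TissueGrid:
    """Labeled, fibrosis- and fiber-annotated substrate for ``config``.

    Pipeline: label zones -> correlated voltage surrogate -> logistic
    voltage-to-fibrosis draw (midpoint auto-tuned when a burden target is
    set) -> fiber field.  Bit-reproducible for a given seed.
    """
    ny, nx = _lattice(config)
    labels = np.zeros((ny, nx), dtype=np.int8)
    x = np.arange(nx) * config.dx
    y = np.arange(ny) * config.dx
    X, Y = np.meshgrid(x, y)

    # PV ostia: non-conducting vein lumen surrounded by a labeled sleeve
    interior = np.ones((ny, nx), dtype=bool)
    r_hole = config.pv_hole_frac * config.pv_radius
    for lab, (cx, cy) in zip(PV_LABELS, config.pv_centers):
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        labels[d2 <= config.pv_radius ** 2] = lab
        interior[d2 <= r_hole ** 2] = False
    cx, cy = config.septum_center
    labels[(X - cx) ** 2 + (Y - cy) ** 2 <= config.septum_radius ** 2] = SEPTUM
    cx, cy = config.appendage_center
    labels[(X - cx) ** 2 + (Y - cy) ** 2 <= config.appendage_radius ** 2] = APPENDAGE

    grid = TissueGrid(dx=config.dx, labels=labels,
                      fibrotic=np.zeros((ny, nx), dtype=bool),
                      fiber_angle=np.zeros((ny, nx)), interior=interior,
                      D_L=DEFAULT_D_L, D_T=DEFAULT_D_T,
                      meta={"seed": config.seed, "pv_radius": config.pv_radius,
                            "size_mm": tuple(config.size_mm)})

    vmap = make_voltage_map(grid, config)
    grid.voltage = vmap.values
    grid.fibrotic = voltage_to_fibrosis(
        vmap, v0=config.v0, k=config.k, seed=config.seed + 1,
        target_burden=config.fibrosis_burden)
    grid.fiber_angle = make_fiber_field(grid, config)
    return grid


def make_voltage_map(grid: TissueGrid, config: GeometryConfig) -> VoltageMap:
    """Correlated bipolar-voltage surrogate on the lattice.

    A Gaussian random field with correlation length ``corr_length_mm`` is
    passed through a lognormal transform into the 0.05-5 mV clinical
    envelope, sampled at ``n_electrodes`` pseudo-electrode nodes, and
    interpolated back with inverse distance weighting (power 2), which is
    exact at the electrode locations.
    """
    if config.n_electrodes < 50:
        raise ValueError("need at least 50 pseudo-electrode points")
    rng = np.random.default_rng(config.seed)
    ny, nx = grid.shape
    z = rng.standard_normal((ny, nx))
    sig = config.corr_length_mm / grid.dx / 2.0
    z = gaussian_filter(z, sig, mode="reflect")
    z /= z.std() or 1.0
    # lognormal: median ~0.9 mV, heavy low-voltage tail; clip to envelope
    v_true = np.clip(np.exp(np.log(0.9) + 0.9 * z), V_LO, V_HI)

    el = rng.choice(grid.n_nodes, size=config.n_electrodes, replace=False)
    X, Y = grid.coords()
    pts = np.column_stack([X.ravel()[el], Y.ravel()[el]])
    vals = v_true.ravel()[el]

    tree = cKDTree(pts)
    k = min(8, config.n_electrodes)
    d, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]), k=k)
    w = 1.0 / np.maximum(d, 1e-12) ** 2
    interp = (w * vals[idx]).sum(axis=1) / w.sum(axis=1)
    exact = d[:, 0] < 1e-9
    interp[exact] = vals[idx[exact, 0]]
    return VoltageMap(interp.reshape(ny, nx), el, vals)


def fibrosis_probability(v: np.ndarray, v0: float, k: float) -> np.ndarray:
    """Logistic probability of fibrosis given bipolar voltage:
    ``P(v) = 1 / (1 + exp((v - v0)/k))`` — strictly decreasing in v."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return 1.0 / (1.0 + np.exp(np.clip((np.asarray(v) - v0) / k, -500, 500)))


def voltage_to_fibrosis(vmap: VoltageMap | np.ndarray, v0: float = 0.5,
                        k: float = 0.15, seed: int = 0,
                        target_burden: float | None = None) -> np.ndarray:
    """Seeded Bernoulli fibrosis flags from the voltage map.

    With ``target_burden`` set, the logistic midpoint ``v0`` is tuned by
    bisection so the expected fibrotic fraction equals the target.
    """
    v = vmap.values if isinstance(vmap, VoltageMap) else np.asarray(vmap)
    if np.any(v <= 0):
        raise ValueError("voltage must be positive")
    if target_burden is not None:
        lo, hi = -2.0, 2.0 * V_HI
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if fibrosis_probability(v, mid, k).mean() < target_burden:
                lo = mid
            else:
                hi = mid
        v0 = 0.5 * (lo + hi)
    p = fibrosis_probability(v, v0, k)
    rng = np.random.default_rng(seed)
    return rng.random(v.shape) < p


def make_fiber_field(grid: TissueGrid, config: GeometryConfig) -> np.ndarray:
    """Smooth fiber-orientation field (radians, orientation mod pi).

    Background: horizontally biased orientation plus a smooth random
    deviation of amplitude ``fiber_perturb_deg``.  Around each PV ostium
    the orientation wraps circumferentially (exact within one radius of the
    rim, blended back to background over the next radius), emulating the
    myocardial sleeves around the veins.
    """
    rng = np.random.default_rng(config.seed + 7)
    ny, nx = grid.shape
    amp = np.deg2rad(config.fiber_perturb_deg)
    if amp > 0:
        z = rng.standard_normal((ny, nx))
        z = gaussian_filter(z, config.fiber_smooth_mm / grid.dx / 2.0, mode="reflect")
        z /= z.std() or 1.0
        theta = amp * z
    else:
        theta = np.zeros((ny, nx))

    if config.pv_wrap:
        X, Y = grid.coords()
        # blend orientations through the double-angle representation
        c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
        for cx, cy in config.pv_centers:
            d = np.hypot(X - cx, Y - cy)
            tang = np.arctan2(Y - cy, X - cx) + np.pi / 2.0
            r = config.pv_radius
            wgt = np.clip((3.0 * r - d) / r, 0.0, 1.0)  # 1 inside 2r, 0 beyond 3r
            c2 = (1 - wgt) * c2 + wgt * np.cos(2 * tang)
            s2 = (1 - wgt) * s2 + wgt * np.sin(2 * tang)
        theta = 0.5 * np.arctan2(s2, c2)
    return theta
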