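"""Synthetic substrate generator: labels, voltage surrogate, fibrosis
draw, fiber field, determinism."""

import numpy as np
import pytest

import fibwave as fw
from fibwave import geometry as geo
from fibwave import tissue as ts


@pytest.fixture(scope="module")
def grid():
    return geo.make_geometry(geo.GeometryConfig(dx=1.0, seed=5))


def test_default_geometry_has_all_zones(grid):
    labels = set(np.unique(grid.labels[grid.interior]))
    assert {ts.PV1, ts.PV2, ts.PV3, ts.PV4, ts.SEPTUM, ts.APPENDAGE} <= labels
    assert ts.BODY in labels


def test_same_seed_identical_grids():
    cfg = geo.GeometryConfig(dx=1.0, seed=42)
    a = geo.make_geometry(cfg)
    b = geo.make_geometry(geo.GeometryConfig(dx=1.0, seed=42))
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.fibrotic, b.fibrotic)
    assert np.array_equal(a.fiber_angle, b.fiber_angle)
    assert np.array_equal(a.voltage, b.voltage)
    c = geo.make_geometry(geo.GeometryConfig(dx=1.0, seed=43))
    assert not np.array_equal(a.fibrotic, c.fibrotic)


def test_full_resolution_mean_spacing():
    """Full-resolution lattice reproduces the 235.1 um mesh statistic."""
    g = geo.make_geometry(geo.full_resolution_config(
        size_mm=(20.0, 20.0), pv_radius=1.5, septum_radius=1.5,
        appendage_radius=1.5, n_electrodes=80, seed=1))
    assert g.mean_adjacent_spacing() * 1000 == pytest.approx(235.1, abs=1.0)


def test_voltage_in_clinical_envelope(grid):
    v = grid.voltage[grid.interior]
    assert v.min() >= geo.V_LO - 1e-12
    assert v.max() <= geo.V_HI + 1e-12


def test_idw_exact_at_electrodes_and_constant_preserved(grid):
    cfg = geo.GeometryConfig(dx=1.0, seed=5)
    vm = geo.make_voltage_map(grid, cfg)
    got = vm.values.ravel()[vm.electrode_nodes]
    assert np.allclose(got, vm.electrode_values, rtol=0, atol=1e-9)
    # constant samples -> constant field (IDW is a convex combination)
    vm2 = geo.VoltageMap(np.full(grid.shape, 1.0))
    flags = geo.voltage_to_fibrosis(vm2, v0=1.0, k=0.2, seed=0)
    assert flags.shape == grid.shape


def test_voltage_correlation_length_ordering():
    """Longer configured correlation length -> slower variogram growth."""
    def short_range_gamma(corr):
        acc = []
        for seed in range(6):
            cfg = geo.GeometryConfig(size_mm=(40., 40.), dx=1.0,
                                     corr_length_mm=corr, n_electrodes=200,
                                     seed=seed)
            g = geo.make_geometry(cfg)
            v = g.voltage
            lag = 3  # nodes
            gam = np.mean((v[:, lag:] - v[:, :-lag]) ** 2)
            acc.append(gam / np.var(v))
        return np.mean(acc)
    assert short_range_gamma(12.0) < short_range_gamma(2.0)


def test_fibrosis_probability_is_logistic():
    p = geo.fibrosis_probability(np.array([0.5]), v0=0.5, k=0.15)
    assert p[0] == pytest.approx(0.5)
    assert geo.fibrosis_probability(np.array([50.0]), 0.5, 0.15)[0] < 1e-6
    lo = geo.fibrosis_probability(np.array([1e-9]), 0.5, 0.15)[0]
    assert lo == pytest.approx(1 / (1 + np.exp(-0.5 / 0.15)), rel=1e-6)
    v = np.linspace(0.05, 5, 50)
    pv = geo.fibrosis_probability(v, 0.5, 0.15)
    assert np.all(np.diff(pv) < 0)


def test_fibrosis_draw_matches_binomial_oracle():
    """At fixed voltage the fibrotic fraction is binomial around P(v)."""
    v = np.full(10000, 0.45)
    p = float(geo.fibrosis_probability(np.array([0.45]), 0.5, 0.15)[0])
    frac = geo.voltage_to_fibrosis(v, v0=0.5, k=0.15, seed=7).mean()
    se = np.sqrt(p * (1 - p) / v.size)
    assert abs(frac - p) < 3 * se


def test_fibrosis_burden_autotuned():
    """Burden targeting holds within 2 percentage points across seeds."""
    fracs = []
    for seed in range(10):
        g = geo.make_geometry(geo.GeometryConfig(
            dx=1.0, seed=seed, fibrosis_burden=0.20))
        fracs.append(g.fibrotic.mean())
    assert abs(np.mean(fracs) - 0.20) < 0.02


def test_nonpositive_voltage_rejected():
    with pytest.raises(ValueError):
        geo.voltage_to_fibrosis(np.array([0.0, 1.0]), seed=0)


def test_fiber_field_uniform_config():
    cfg = geo.GeometryConfig(dx=1.0, seed=0, fiber_perturb_deg=0.0,
                             pv_wrap=False)
    g = geo.make_geometry(cfg)
    assert np.allclose(g.fiber_angle, g.fiber_angle.flat[0])


def test_fiber_field_wraps_pv_ostia(grid):
    """Fibers adjacent to an ostium rim align with the rim tangent."""
    cfg = geo.GeometryConfig(dx=1.0, seed=5)
    X, Y = grid.coords()
    cx, cy = cfg.pv_centers[0]
    d = np.hypot(X - cx, Y - cy)
    rim = (d > cfg.pv_radius) & (d < 1.6 * cfg.pv_radius) & grid.interior
    tang = np.arctan2(Y - cy, X - cx) + np.pi / 2
    diff = np.angle(np.exp(2j * (grid.fiber_angle[rim] - tang[rim]))) / 2
    assert np.max(np.abs(np.rad2deg(diff))) < 15.0


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        geo.GeometryConfig(fibrosis_burden=1.2)
    with pytest.raises(ValueError):
        geo.GeometryConfig(k=0.0)
    with pytest.raises(ValueError):  # overlapping ostia
        geo.GeometryConfig(pv_centers=((10, 10), (12, 10), (40, 10), (40, 40)),
                           pv_radius=4.0)
    with pytest.raises(ValueError):  # ostium leaves the sheet
        geo.GeometryConfig(pv_centers=((2, 10), (20, 10), (40, 10), (40, 40)))
    with pytest.raises(ValueError):
        geo.make_voltage_map(
            geo.make_geometry(geo.test_scale_config(seed=0)),
            geo.test_scale_config(n_electrodes=10, seed=0))
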