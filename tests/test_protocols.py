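"""Pacing protocols, episode plans, CPVI geometry, high-DF targeting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import fibwave as fw
from fibwave import protocols as pr
from fibwave import tissue as ts


def test_ramp_defaults_match_protocol_arithmetic():
    """200->120 ms, 8 beats/stage: 72 stimuli lasting 11,520 ms."""
    sched, dur = pr.ramp_pacing_protocol()
    assert dur == 11520.0
    assert sched.n_stimuli == 72
    assert sched.times[0] == 0.0
    # last stimulus starts one CL before the end of the last stage
    assert sched.times[-1] == 11520.0 - 120.0


def test_ramp_single_stage():
    sched, dur = pr.ramp_pacing_protocol(200, 200, 10, 8)
    assert dur == 1600.0
    assert sched.n_stimuli == 8


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(12, 30), st.integers(0, 8), st.integers(1, 4),
       st.integers(1, 10))
def test_ramp_duration_identity(start10, down, step10, beats):
    """duration == beats * sum(CLs), exactly, for all valid configs."""
    from hypothesis import assume
    start = 10.0 * start10
    step = 10.0 * step10
    end = start - step * down
    assume(end > 0)
    sched, dur = pr.ramp_pacing_protocol(start, end, step, beats)
    cls = np.arange(start, end - 1e-9, -step)
    assert dur == beats * cls.sum()
    assert sched.n_stimuli == beats * len(cls)
    assert np.all(np.diff(sched.times) > 0)


def test_ramp_validation():
    with pytest.raises(ValueError):
        pr.ramp_pacing_protocol(200, 120, 7)   # not divisible
    with pytest.raises(ValueError):
        pr.ramp_pacing_protocol(120, 200, 10)  # ascending
    with pytest.raises(ValueError):
        pr.PacingSchedule(np.array([0.0, 0.0]))


def test_episode_plan_layout():
    """32-s episode: 11,520 ms induction + 20,480 ms observation;
    6-s analysis window at 17-23 s."""
    plan = pr.episode_plan("wild_type", "none", scale="full")
    assert plan.total_duration == 32000.0
    assert plan.induction_duration == 11520.0
    assert plan.observation == 20480.0
    lo, hi = plan.analysis_window
    assert (lo, hi) == (17000.0, 23000.0)
    assert hi - lo == 6000.0


def test_episode_plan_drug_and_serialization():
    iv = pr.Intervention("drug", drug="dronedarone", dose="low")
    plan = pr.episode_plan("pitx2_deficient", iv, scale="desk")
    blob = json.dumps(plan.to_dict())
    back = pr.EpisodePlan.from_dict(json.loads(blob))
    assert back.genotype == plan.genotype
    assert back.intervention == plan.intervention
    assert np.array_equal(back.induction_times, plan.induction_times)
    assert back.analysis_window == plan.analysis_window
    # the drug preset composes over the genotype AF baseline
    p = fw.compose(fw.genotype_baseline(back.genotype, "af"),
                   fw.drug_preset("dronedarone", "low"))
    assert p.factor("I_K1") == pytest.approx(1.575 * 0.9)


def test_intervention_validation():
    with pytest.raises(ValueError):
        pr.Intervention("drug")
    with pytest.raises(ValueError):
        pr.Intervention("zap")
    with pytest.raises(ValueError):
        pr.episode_plan("wild_type", "none", scale="huge")


def test_cpvi_two_closed_loops(cpvi_grid):
    """CPVI mask forms two closed contours, each around one PV pair."""
    mask = pr.cpvi_mask(cpvi_grid)
    m = np.zeros(cpvi_grid.n_nodes, bool)
    m[mask.nodes] = True
    m = m.reshape(cpvi_grid.shape)
    lab, n = ndimage.label(m, structure=np.ones((3, 3)))
    assert n == 2
    # flood fill from the rim through non-ring tissue must not reach any PV
    open_mask = cpvi_grid.interior & ~m
    outside = pr._flood_outside(open_mask)
    for pv in ts.PV_LABELS:
        nodes = cpvi_grid.region_nodes(pv)
        assert not outside.ravel()[nodes].any()
    # and each loop interior contains exactly one ipsilateral pair
    inside = open_mask & ~outside
    labs_in = set(np.unique(cpvi_grid.labels[inside]))
    assert set(ts.PV_LABELS) <= labs_in


def test_cpvi_linewidth_validation(cpvi_grid):
    with pytest.raises(ValueError):
        pr.cpvi_mask(cpvi_grid, line_width=0)


def test_cpvi_fails_near_boundary():
    g = ts.TissueGrid(dx=1.0, labels=np.zeros((30, 30), np.int8),
                      fibrotic=np.zeros((30, 30), bool),
                      fiber_angle=np.zeros((30, 30)),
                      interior=np.ones((30, 30), bool))
    for lab, (cy, cx) in zip(ts.PV_LABELS, ((3, 3), (3, 12), (26, 3), (26, 12))):
        g.labels[cy - 1:cy + 2, cx - 1:cx + 2] = lab
    with pytest.raises(ValueError, match="contour"):
        pr.cpvi_mask(g, margin_mm=4.0)


def test_high_df_single_plateau(cpvi_grid):
    """8 Hz plateau on a 5 Hz background -> one disc on the plateau."""
    ny, nx = cpvi_grid.shape
    df = np.full((ny, nx), 5.0)
    df[10:14, 20:24] = 8.0
    mask = pr.high_df_targets(df, cpvi_grid, site_radius_mm=3.0)
    m = np.zeros(cpvi_grid.n_nodes, bool)
    m[mask.nodes] = True
    m = m.reshape(ny, nx)
    lab, n = ndimage.label(m, structure=np.ones((3, 3)))
    assert n == 1
    cy, cx = ndimage.center_of_mass(m)
    assert 10 <= cy <= 14 and 20 <= cx <= 24


def test_high_df_uniform_map_collapses_to_one_site(cpvi_grid):
    df = np.full(cpvi_grid.shape, 6.0)
    mask = pr.high_df_targets(df, cpvi_grid, site_radius_mm=3.0, max_sites=3)
    m = np.zeros(cpvi_grid.n_nodes, bool)
    m[mask.nodes] = True
    lab, n = ndimage.label(m.reshape(cpvi_grid.shape), np.ones((3, 3)))
    assert n == 1


def test_high_df_two_distant_peaks(cpvi_grid):
    """Peaks beyond the suppression radius both get a disc; none else."""
    df = np.full(cpvi_grid.shape, 5.0)
    df[6:10, 6:10] = 9.0
    df[28:32, 18:22] = 9.0   # ~25 mm away at dx=1
    mask = pr.high_df_targets(df, cpvi_grid, percentile=98.5,
                              site_radius_mm=5.0, max_sites=3)
    m = np.zeros(cpvi_grid.n_nodes, bool)
    m[mask.nodes] = True
    lab, n = ndimage.label(m.reshape(cpvi_grid.shape), np.ones((3, 3)))
    assert n == 2


def test_high_df_undefined_map_warns(cpvi_grid):
    df = np.full(cpvi_grid.shape, np.nan)
    with pytest.warns(UserWarning):
        mask = pr.high_df_targets(df, cpvi_grid)
    assert mask.size == 0
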