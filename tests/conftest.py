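"""Shared fixtures.

The heavy fixture ``af_episode_suite`` runs the matched wild-type /
PITX2-deficient AF episode set (5 substrate seeds x 2 genotypes, desk-scale
episodes) once per session; the sustained-reentry, dominant-frequency and
genotype-contrast checks all consume it.
"""

from __future__ import annotations

import numpy as np
import pytest

import fibwave as fw
from fibwave import geometry as geo
from fibwave import protocols as pr
from fibwave import tissue as ts
from fibwave import wavedynamics as wd

EPISODE_DX = 0.5        # mm, desk-scale episode lattice
EPISODE_DT = 0.2        # ms
EPISODE_SEEDS = (1, 2, 3, 4, 5)
CV_TARGET = 0.6         # m/s


def make_record(act, rep=None, vm=None, rate_hz=1000.0, duration=None,
                n_nodes=None, ablated=None):
    """Assemble a synthetic SimulationRecord from per-node event lists."""
    n = n_nodes if n_nodes is not None else len(act)
    max_ev = max((len(a) for a in act), default=1) or 1
    act_t = np.full((n, max_ev), np.nan)
    rep_t = np.full((n, max_ev), np.nan)
    n_act = np.zeros(n, dtype=np.int32)
    n_rep = np.zeros(n, dtype=np.int32)
    for i, a in enumerate(act):
        act_t[i, :len(a)] = a
        n_act[i] = len(a)
        if rep is not None:
            rep_t[i, :len(rep[i])] = rep[i]
            n_rep[i] = len(rep[i])
    if duration is None:
        duration = float(max((a[-1] for a in act if len(a)), default=0.0) + 100)
    dt_s = 1000.0 / rate_hz
    if vm is None:
        vm = np.zeros((n, int(duration / dt_s)), dtype=np.float32)
    t_samp = np.arange(vm.shape[1]) * dt_s
    if ablated is None:
        ablated = np.zeros(n, dtype=bool)
    return ts.SimulationRecord(t_samp=t_samp, vm=np.asarray(vm, np.float32),
                               rec_nodes=np.arange(n), act_t=act_t,
                               rep_t=rep_t, n_act=n_act, n_rep=n_rep,
                               duration=float(duration), dt=0.1,
                               ablated=np.asarray(ablated))


@pytest.fixture(scope="session")
def small_grid():
    """20 x 20 mm coarse labeled substrate (fast)."""
    return geo.make_geometry(geo.test_scale_config(seed=11))


@pytest.fixture(scope="session")
def cpvi_grid():
    """40 x 40 mm substrate on which CPVI contours can close."""
    return geo.make_geometry(geo.GeometryConfig(
        size_mm=(40.0, 40.0), dx=1.0, pv_radius=3.0, septum_radius=2.5,
        appendage_radius=2.5, corr_length_mm=6.0, n_electrodes=120, seed=21))


def run_af_episode(seed: int, preset, genotype: str):
    """One desk-scale baseline AF episode on substrate ``seed``."""
    grid = geo.make_geometry(geo.GeometryConfig(dx=EPISODE_DX, seed=seed))
    scale = ts.calibrate_diffusion(grid, preset, CV_TARGET, dt=EPISODE_DT)
    plan = pr.episode_plan(genotype, "none", scale="desk")
    rec = ts.simulate(grid, preset, plan.schedule, plan.total_duration,
                      dt=EPISODE_DT, diffusion_scale=scale)
    alive = [rec.activations(int(i))[-1] for i in np.flatnonzero(rec.n_act)]
    sustained = bool(alive) and max(alive) >= plan.total_duration - 1000.0
    result = wd.analyze_episode(rec, plan.analysis_window, smax_stride=3)
    last_vm = rec.vm[:, -1].copy()
    # free the heavy waveform block once analyzed; events stay available
    rec.vm = rec.vm[:, :1]
    return dict(seed=seed, genotype=genotype, grid_shape=grid.shape,
                sustained=sustained, mean_df=result.mean_df,
                mean_smax=result.mean_smax, afcl=result.afcl_ms,
                outcome=result.outcome, plan=plan, last_vm=last_vm)


@pytest.fixture(scope="session")
def af_episode_suite():
    """Matched WT / PITX2-deficient baseline episodes over 5 substrates."""
    out = []
    for seed in EPISODE_SEEDS:
        out.append(run_af_episode(seed, fw.WT_AF, "wild_type"))
        out.append(run_af_episode(seed, fw.PITX2_AF, "pitx2_deficient"))
    return out
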