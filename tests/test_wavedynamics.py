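"""Wave-dynamics estimators against closed-form oracles: dominant
frequency, DF maps, restitution Smax, AFCL, outcome classification."""

import numpy as np
import pytest

import fibwave as fw
from fibwave import wavedynamics as wd

from conftest import make_record


# ---------------------------------------------------------------- DF ----

def test_df_pure_tones_across_band():
    """DF error stays below one spectral bin on pure tones (2.5-20 Hz)."""
    fs = 1000.0
    t = np.arange(0, 6.0, 1 / fs)
    for f0 in (2.5, 4.0, 6.0, 9.5, 13.0, 19.5):
        x = np.sin(2 * np.pi * f0 * t)
        assert wd.dominant_frequency(x, fs) == pytest.approx(f0, abs=0.05)


def test_df_spike_train_fundamental():
    """150 ms spike train -> 6.67 Hz fundamental."""
    fs = 1000.0
    t = np.arange(0, 6.0, 1 / fs)
    x = np.zeros_like(t)
    x[::150] = 1.0
    x = np.convolve(x, np.exp(-np.arange(50) / 10.0), mode="same")
    assert wd.dominant_frequency(x, fs) == pytest.approx(1000 / 150, abs=0.05)


def test_df_constant_signal_undefined():
    x = np.full(6000, -80.0)
    assert np.isnan(wd.dominant_frequency(x, 1000.0))


def test_df_nyquist_guard():
    with pytest.raises(wd.NyquistError):
        wd.dominant_frequency(np.zeros(6000), rate=30.0)


def _sine_record(freqs_hz, duration=6000.0, fs=1000.0):
    t = np.arange(0, duration / 1000.0, 1 / fs)
    vm = np.stack([np.sin(2 * np.pi * f * t) * 40 - 60 for f in freqs_hz])
    acts = [list(np.arange(50.0, duration - 50, 1000.0 / f)) for f in freqs_hz]
    return make_record(acts, vm=vm, duration=duration)


def test_df_map_uniform_and_bimodal():
    rec = _sine_record([5.0] * 6)
    m = wd.df_map(rec, (0.0, 6000.0))
    assert np.allclose(m.node_df, 5.0, atol=0.05)
    assert m.mean_df == pytest.approx(5.0, abs=0.05)
    rec = _sine_record([5.0] * 3 + [8.0] * 3)
    m = wd.df_map(rec, (0.0, 6000.0))
    assert m.mean_df == pytest.approx(6.5, abs=0.05)
    # mean equals the arithmetic mean of defined entries, exactly
    d = m.node_df[np.isfinite(m.node_df)]
    assert m.mean_df == d.mean()


def test_df_map_ablated_nodes_undefined():
    rec = _sine_record([6.0] * 4)
    rec.ablated[:] = True
    m = wd.df_map(rec, (0.0, 6000.0))
    assert np.all(np.isnan(m.node_df))
    assert np.isnan(m.mean_df)


def test_df_map_requires_activations():
    """A node with in-band power but no detected activation is undefined."""
    rec = _sine_record([6.0] * 2)
    rec.n_act[1] = 0
    m = wd.df_map(rec, (0.0, 6000.0))
    assert np.isfinite(m.node_df[0]) and np.isnan(m.node_df[1])


# ------------------------------------------------------------- Smax ----

def test_smax_linear_data_exact():
    """Noiseless linear restitution -> Smax equals the slope to 1e-9."""
    di = np.linspace(40, 300, 12)
    apd = 100.0 + 0.8 * di
    smax, info = wd.fit_smax(di, apd)
    assert info["method"] == "fd"
    assert smax == pytest.approx(0.8, abs=1e-9)


def test_smax_exponential_closed_form():
    """APD = 200 - 120 exp(-DI/60) sampled on [30, 300] ->
    Smax = 2 exp(-0.5) ~ 1.213 at the smallest DI."""
    di = np.linspace(30, 300, 25)
    apd = 200.0 - 120.0 * np.exp(-di / 60.0)
    smax, info = wd.fit_smax(di, apd)
    assert info["method"] == "fit"
    assert smax == pytest.approx(2.0 * np.exp(-0.5), rel=1e-3)


def test_smax_constant_apd_is_zero():
    di = np.linspace(50, 250, 9)
    smax, _ = wd.fit_smax(di, np.full_like(di, 180.0))
    assert smax == pytest.approx(0.0, abs=1e-9)


def test_restitution_pairs_and_node_minimum():
    """DI_n = act_n - rep_{n-1}; nodes below the pair minimum are skipped."""
    act = [100.0, 400.0, 700.0, 1000.0, 1300.0, 1600.0, 1900.0]
    apd = [200.0, 210.0, 205.0, 215.0, 208.0, 212.0, 209.0]
    rep = [a + d for a, d in zip(act, apd)]
    rec = make_record([act, act[:3]], rep=[rep, rep[:3]], duration=2100.0)
    di, ap = wd.restitution_pairs(rec, 0, (0.0, 2100.0))
    assert di[0] == pytest.approx(act[1] - rep[0])
    assert ap[0] == pytest.approx(apd[1])
    rs = wd.restitution_smax(rec, (0.0, 2100.0))
    assert np.isfinite(rs.node_smax[0])
    assert np.isnan(rs.node_smax[1])        # only 2 pairs at node 1
    assert rs.mean_smax == rs.node_smax[0]


def test_restitution_no_pairs_warns():
    rec = make_record([[100.0]], rep=[[300.0]], duration=500.0)
    with pytest.warns(UserWarning):
        rs = wd.restitution_smax(rec, (0.0, 500.0))
    assert np.isnan(rs.mean_smax)


# ------------------------------------------------------------- AFCL ----

def test_afcl_uniform_pacing():
    acts = [list(np.arange(0, 3000, 150.0))] * 5
    rec = make_record(acts, duration=3000.0)
    assert wd.afcl(rec, (0.0, 3000.0)) == pytest.approx(150.0)


def test_afcl_alternating_intervals_and_empty_window():
    t, times = 0.0, [0.0]
    for k in range(20):
        t += 140.0 if k % 2 == 0 else 160.0
        times.append(t)
    rec = make_record([times], duration=4000.0)
    assert wd.afcl(rec, (0.0, 4000.0)) == pytest.approx(150.0)
    assert np.isnan(wd.afcl(rec, (3500.0, 4000.0)))


# ----------------------------------------------------------- outcome ----

def _regular_record(period=240.0, jitter=0.0, n_nodes=12, duration=8000.0,
                    seed=0, frac_regular=1.0):
    rng = np.random.default_rng(seed)
    acts, vms = [], []
    fs = 1000.0
    t = np.arange(0, duration / 1000.0, 1 / fs)
    for i in range(n_nodes):
        jit = jitter if i < int(frac_regular * n_nodes) else period * 0.30
        times = np.arange(100.0, duration - 100.0, period)
        times = times + rng.normal(0, jit, times.size)
        acts.append(np.sort(times))
        f = 1000.0 / period
        vms.append(np.sin(2 * np.pi * f * t) * 40 - 60)
    return make_record(acts, vm=np.stack(vms), duration=duration)


def test_outcome_terminated_when_silent():
    acts = [[100.0, 300.0], [120.0, 320.0]]
    rec = make_record(acts, duration=8000.0)
    assert wd.classify_outcome(rec, (2000.0, 8000.0)) == "terminated"


def test_outcome_at_for_regular_activity():
    rec = _regular_record(period=240.0, jitter=2.0)
    assert wd.classify_outcome(rec, (2000.0, 8000.0)) == "AT"


def test_outcome_af_for_irregular_activity():
    rec = _regular_record(period=240.0, jitter=72.0)  # CV ~ 0.3
    assert wd.classify_outcome(rec, (2000.0, 8000.0)) == "AF"


def test_outcome_monotone_in_jitter():
    """Increasing interval irregularity can only move AT -> AF."""
    order = {"AT": 0, "AF": 1}
    last = 0
    for jit in (1.0, 5.0, 20.0, 50.0, 80.0):
        out = wd.classify_outcome(_regular_record(jitter=jit, seed=3),
                                  (2000.0, 8000.0))
        assert out in order
        assert order[out] >= last
        last = order[out]


def test_outcome_window_validation():
    rec = _regular_record()
    with pytest.raises(ValueError):
        wd.classify_outcome(rec, (2000.0, 9000.0))


def test_episode_result_invariant():
    r = wd.EpisodeResult("AT", 6.0, 0.5, 160.0)
    assert r.defragmented
    r = wd.EpisodeResult("AF", 7.0, 0.8, 140.0)
    assert not r.defragmented
    with pytest.raises(ValueError):
        wd.EpisodeResult("fibrillation", 7.0, 0.8, 140.0)
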