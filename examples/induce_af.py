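"""Induce AF on a fibrotic substrate by ramp pacing and analyze it.

Runs one desk-scale episode (scaled ramp 200->120 ms + 10.24 s
observation) on a 60 x 60 mm wild-type-AF sheet and reports outcome,
dominant frequency, restitution slope and AF cycle length.
Takes a few minutes on one CPU.
"""

import numpy as np

import fibwave as fw
from fibwave import geometry as geo, protocols as pr, tissue as ts
from fibwave import wavedynamics as wd

grid = geo.make_geometry(geo.GeometryConfig(dx=0.5, seed=1))
scale = ts.calibrate_diffusion(grid, fw.WT_AF, target_cv=0.6, dt=0.2)
print(f"diffusion calibrated: scale {scale:.2f} -> CV 0.6 m/s along fibers")

plan = pr.episode_plan("wild_type", "none", scale="desk")
rec = ts.simulate(grid, fw.WT_AF, plan.schedule, plan.total_duration,
                  dt=0.2, diffusion_scale=scale)
res = wd.analyze_episode(rec, plan.analysis_window, smax_stride=3)

last = max(rec.activations(int(i))[-1] for i in np.flatnonzero(rec.n_act))
print(f"episode: {plan.total_duration/1000:.0f} s "
      f"(induction {plan.induction_duration/1000:.2f} s)")
print(f"last activation at t = {last/1000:.2f} s "
      f"-> {'sustained' if last >= plan.total_duration - 1000 else 'not sustained'}")
print(f"outcome: {res.outcome}   mean DF: {res.mean_df:.2f} Hz   "
      f"mean Smax: {res.mean_smax:.3f}   AFCL: {res.afcl_ms:.0f} ms")
print("\nA mean DF in the 4-9 Hz physiological band marks sustained")
print("re-entry; at this desk scale the activity often organizes into an")
print("anchored macro-re-entry (classified AT) rather than multi-wavelet AF.")
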