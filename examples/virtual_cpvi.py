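"""Virtual circumferential pulmonary-vein isolation (CPVI).

Draws the two closed ablation contours around the ipsilateral PV pairs,
then demonstrates electrical isolation: pacing inside a ring excites the
vein antrum but nothing outside it.
"""

import numpy as np

import fibwave as fw
from fibwave import geometry as geo, protocols as pr, tissue as ts

grid = geo.make_geometry(geo.GeometryConfig(
    size_mm=(40.0, 40.0), dx=1.0, pv_radius=3.0, septum_radius=2.5,
    appendage_radius=2.5, corr_length_mm=6.0, n_electrodes=120, seed=21))

mask = pr.cpvi_mask(grid)
print(f"CPVI mask: {mask.size} nodes ({mask.descriptor})")

ablated = ts.apply_ablation(grid, mask)
rec = ts.simulate(ablated, fw.WT_SR, pr.PacingSchedule(np.array([2.0])),
                  300.0, stim_region=ts.PV1, stim_radius_mm=4.0,
                  diffusion_scale=3.0)

ring = np.zeros(grid.n_nodes, bool)
ring[mask.nodes] = True
outside = pr._flood_outside(grid.interior & ~ring.reshape(grid.shape))
n_in = int(rec.n_act[~outside.ravel() & ~ring & grid.interior.ravel()].sum())
n_out = int(rec.n_act[outside.ravel()].sum())
print(f"activations inside the isolated antrum: {n_in}")
print(f"activations outside the ring:           {n_out}")
print("\nZero outside activations = complete conduction block: the vein")
print("pair is electrically disconnected from the atrial body.")
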