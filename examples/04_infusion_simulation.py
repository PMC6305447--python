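"""Simulate a convection-enhanced infusion with the R-model.

Steady Darcy flow from a fixed-rate source (1.8 ul/min into white
matter), then implicit upwind transport of the infusate fraction C.  The
mass ledger accounts for every mm^3 infused.
"""

from cedsim import RunConfig, SimulationConfig, SourceSpec, build_mesh, run_simulation
from cedsim import build_drug_tensors, distribution_volume
from cedsim.workflows import build_phantom, estimate_water_tensors, resolve_source_voxel

cfg = RunConfig(seed=7)
data = build_phantom(cfg)
water = estimate_water_tensors(data)
drug = build_drug_tensors(water.Dw, water.Rw, data.labels)
mesh = build_mesh(data.labels.mask, cfg.voxel_size)
src_vox = resolve_source_voxel(data.labels, "wm_center")
src = SourceSpec.constant(src_vox, 1.8)  # ul/min

sim = SimulationConfig(model="R", dt=5.0, t_end=3600.0, snapshot_times=(1800.0, 3600.0))
res = run_simulation(mesh, drug, src, sim)

print(f"mesh: {mesh.n_cells} cells of ({mesh.voxel_size} mm)^3; source at {src_vox}")
dp = res.pressure[res.flow.source_cells[0]]
print(f"emergent source pressure above boundary: {dp:.3e} Pa")
print("  (calibration-relative: in fixed-rate mode the flow field is set by the")
print("   rate, so the conductivity scale only rescales the reported pressure)")
for row in res.ledger_rows:
    print(
        f"t={row['t']:6.0f} s  infused={row['infused']:7.2f} mm^3  "
        f"in domain={row['in_domain']:7.2f}  outflux={row['outfluxed']:.2e}  "
        f"ledger closure={row['closure']:.1e}"
    )
vd = distribution_volume(res.concentration_volume(3600.0), cfg.voxel_size, 0.05)
print(f"distribution volume (>= 5% of max) after 1 h: {vd:.0f} mm^3")
print("-> the infusate plateau fills the anisotropic WM neighbourhood of the")
print("   catheter; the ledger closes to solver precision.")
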