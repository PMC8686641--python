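"""Solve the no-relief baseline and inspect the mucosal stress field.

Applies the 111 N pain-onset bite force to the plate centre of the
default synthetic palate and reports where the von Mises stress in the
denture-supporting mucosa falls within the 0.02-0.20 MPa range used to
set relief borderlines.
"""

import numpy as np

import palate_relief as pr

cfg = pr.StudyConfig()  # default synthetic palate, 1.5 mm study mesh
thickness = pr.sample_thickness_map(cfg.palate, cfg.seed)
mesh = pr.mesh_layered(pr.build_geometry(cfg.palate, thickness), cfg.mesh_edge)

bc = pr.make_load(mesh, cfg.bite_force, cfg.patch_radius)
u = pr.assemble_and_solve(mesh, cfg.materials, bc)
stress = pr.recover_stress(mesh, cfg.materials, u)

vm = stress.vm[mesh.part == pr.PART_MUCOSA]
print(f"bite force {cfg.bite_force} N over a {cfg.patch_radius} mm central patch")
print(f"mucosal von Mises: min {vm.min():.4f}, median {np.median(vm):.4f}, "
      f"max {vm.max():.4f} MPa")

dist = pr.stress_volume_distribution(stress, mesh, cfg.report_thresholds)
print(f"total mucosa volume: {dist.total_volume:.0f} mm^3")
print("volume at or above each threshold (the stress-distribution volume metric):")
for t, v in zip(dist.thresholds, dist.cumulative):
    print(f"  >= {t:.2f} MPa : {v:9.1f} mm^3")
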