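"""Verify the elasticity solver against a closed-form uniaxial state.

A 10 mm cube of plate resin (E = 2650 MPa, nu = 0.3) on roller supports
under 1 MPa top pressure must carry a uniform stress sigma_zz = -1 MPa,
von Mises exactly 1 MPa, and compress by p*H/E.  The printed relative
errors should sit at solver precision (~1e-14).
"""

import numpy as np

import palate_relief as pr
from palate_relief.elastic_fem import BoundaryConditions

H, p = 10.0, 1.0
resin = pr.PLATE_RESIN
mesh = pr.box_mesh(H, H, H, n=3)

loads = pr.pressure_load(mesh, "top", np.array([0.0, 0.0, -p]))
dofs = []
for name, comp in (("bottom", 2), ("x0", 0), ("y0", 1)):  # rollers
    dofs.extend(3 * n + comp for n in mesh.node_sets[name])
bc = BoundaryConditions(
    fixed_nodes=np.empty(0, dtype=int),
    loads=loads,
    prescribed_dofs=np.array(dofs),
    prescribed_values=np.zeros(len(dofs)),
)

u = pr.assemble_and_solve(mesh, resin, bc)
s = pr.recover_stress(mesh, resin, u)

uz = u.values[mesh.node_sets["top"], 2]
print(f"von Mises: {s.vm.min():.12f} .. {s.vm.max():.12f} MPa (expected 1)")
print(f"top displacement: {uz.mean():.9f} mm (expected {-p * H / resin.young_modulus:.9f})")
print(f"max relative von Mises error: {np.abs(s.vm - p).max():.2e}")
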