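"""Verify the flow solver: Poiseuille flow and the Darcy (clotted) limit.

Drives a 240x60 μm plasma channel with a fixed pressure drop, first with no
platelet mass (parabolic Poiseuille profile) and then filled with a dense
platelet mass (plug-like Darcy flow).  Prints the mid-channel velocities
against the analytic solutions.
"""

import numpy as np

from thrombosim import BlockSpec, BrinkmanFlowSolver, FluidBC, FluidState, build_single_block

NU = 1.2e6     # plasma kinematic viscosity, μm²/s
G = 4e6        # kinematic pressure gradient, μm/s²
L, H = 240.0, 60.0

mesh = build_single_block(
    BlockSpec(0, L, 0, H, 16, 32),
    {"left": "inlet", "right": "outlet", "bottom": "walls", "top": "walls"},
)
solver = BrinkmanFlowSolver(mesh, NU, FluidBC("pressure", p=G * L), FluidBC("pressure", p=0.0))

# open channel → Poiseuille
state = solver.solve_steady(FluidState.zero(mesh, NU), np.zeros(mesh.shape), dt=1e-3)
yc = 0.5 * (mesh.y_faces[:-1] + mesh.y_faces[1:])
u_exact = G * yc * (H - yc) / (2 * NU)
print(f"open channel:  u_max = {state.u[:, 8].max():8.2f} μm/s "
      f"(Poiseuille {u_exact.max():8.2f} μm/s)")

# uniformly clotted channel → Darcy limit u = G/(ν α)
alpha = 0.04  # inverse permeability of the platelet mass, μm⁻²
state = solver.solve_steady(FluidState.zero(mesh, NU), np.full(mesh.shape, alpha), dt=1e-3)
print(f"clotted channel: u_mid = {state.u[16, 8]:8.2f} μm/s "
      f"(Darcy {G / (NU * alpha):8.2f} μm/s)")
print("The porous platelet mass flattens the parabola into a slow plug flow.")
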