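"""Extending the cascade: add a fluid-phase thrombin inhibitor.

The two-step recipe for a new species: (1) register the field(s),
(2) attach the reaction term — here I + E2 → E2_inh at rate k_I·[I]·[E2].
``add_inhibitor_extension`` packages both steps; this script shows the
effect on free fluid thrombin in a well-mixed box.
"""

import numpy as np

from thrombosim import PlateletRates, add_inhibitor_extension
from thrombosim.coagulation import (
    DEFAULT_COAG_PARAMS,
    attach_platelet_model,
    register_reduced_model,
    rk4_react,
)
from thrombosim.platelets import MOLEC_PER_UM3_PER_NM

P_MAX, PB = 0.0667, 0.02


def run(k_I, I0):
    reg = register_reduced_model(dict(DEFAULT_COAG_PARAMS))
    if k_I > 0:
        add_inhibitor_extension(reg, k_I=k_I)   # step 1 + 2 in one call
    attach_platelet_model(reg, PlateletRates(k_adh=0, k_coh=0), None, P_MAX)
    st = {n: np.zeros(1) for n in reg.integrated_names}
    st["E1"][:] = 0.05
    st["S2"][:] = 1400.0
    st["P_ba"][:] = PB
    st["Z1"][:] = DEFAULT_COAG_PARAMS["N1_sites"] / MOLEC_PER_UM3_PER_NM * PB
    st["Z2"][:] = DEFAULT_COAG_PARAMS["N2_sites"] / MOLEC_PER_UM3_PER_NM * PB
    if k_I > 0:
        st["I"][:] = I0
    out = rk4_react(st, reg, h=0.01, n_steps=12000, frozen={"ADP": np.zeros(1)})
    return out


base = run(0.0, 0.0)
inh = run(0.01, 100.0)
print(f"after 120 s, free fluid thrombin E2:")
print(f"  without inhibitor: {base['E2'][0]:8.2f} nM")
print(f"  with 100 nM I:     {inh['E2'][0]:8.2f} nM "
      f"(inhibited complex E2_inh = {inh['E2_inh'][0]:.2f} nM)")
print(f"  inhibitor mass balance: I + E2_inh = "
      f"{inh['I'][0] + inh['E2_inh'][0]:.2f} nM (started at 100)")
print("New chemistry plugs in as data — a species entry plus a reaction term.")
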