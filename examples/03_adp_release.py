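"""ADP release from newly bound platelets: the finite-memory source term.

A cohort of platelets binds during a single sampling interval; the release
source σ(t) then traces the bell-shaped kernel (peak 3 s after binding) and
its time integral returns exactly the per-platelet ADP content Â.
"""

import numpy as np

from thrombosim.adp import (
    MOL_PER_UM3_TO_NM,
    ReleaseHistory,
    release_kernel_R,
    sigma_release,
)

A_HAT = 2.4e-17  # mol ADP per platelet
DTAU = 0.05      # history sampling interval, s

history = ReleaseHistory(dtau=DTAU, tau_f=6.0, shape=(1, 1))

# one platelet/μm³ binds during the first Δτ slot
t = DTAU
history.push(np.full((1, 1), 1.0 / DTAU), t)

trace, total = [], 0.0
while t < 8.0:
    sigma = sigma_release(history, t, A_HAT)[0, 0]
    trace.append((t, sigma))
    total += sigma * DTAU
    t = round(t + DTAU, 12)
    history.push(np.zeros((1, 1)), t)

t_peak, s_peak = max(trace, key=lambda ts: ts[1])
print(f"kernel peak:   R(3) = {release_kernel_R(3.0):.5f} 1/s")
print(f"σ peaks at t = {t_peak:.2f} s after binding, σ_max = {s_peak:.1f} nM/s")
print(f"total ADP released: {total:.1f} nM  (Â as concentration: "
      f"{A_HAT * MOL_PER_UM3_TO_NM:.1f} nM per platelet/μm³)")
print("Release lags binding by ~3 s and integrates to the granule content.")
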