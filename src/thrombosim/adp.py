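"""ADP release from newly bound platelets with a finite-memory kernel.

Activated platelets secrete ADP from their dense granules over roughly
1–5 s.  The molar ADP concentration obeys an (unhindered) advection–
diffusion equation with the distributed source

    σ_release(x, t) = ∫₀^∞ Â R(τ) ∂t[P_ba + P_sea](x, t − τ) dτ,

where Â is the total ADP released per platelet and R(τ) is the release-rate
density: a bell curve centered at 3 s,

    R(τ) = π^{−1/2} exp(−(τ − 3)²),

normalized so that ∫₀^∞ R dτ = 1 (the τ < 0 tail is negligible).  Because R
is essentially supported on [0, 6] s, the memory integral is truncated at a
window τ_f (default 6 s) and evaluated by the trapezoid rule on a coarse
grid of spacing Δτ: the newly-bound-platelet rate

    ∂t[P_ba + P_sea](t_n) ≈ P_max (θ_B(t_n) − θ_B(t_{n−1}))/(t_n − t_{n−1})

is sampled every Δτ into a ring buffer spanning the window.  Missing history
before start-up counts as zero, so σ_release(0) = 0.  Negative sampled rates
(net unbinding) are clipped to zero inside the quadrature — unbinding does
not un-release ADP — but kept in diagnostics.

Units: Â in mol/platelet; concentrations in nM (1 nM = 10⁻²⁴ mol/μm³), so
σ in nM/s = 10²⁴ · Â · (quadrature of the platelet rate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import StructuredMesh
from .transport import FaceFluxField, ImplicitDiffusion, ScalarField, advance_transport

__all__ = [
    "release_kernel_R",
    "ReleaseHistory",
    "ADPField",
    "newly_bound_rate",
    "sigma_release",
    "advance_adp",
    "MOL_PER_UM3_TO_NM",
]

logger = logging.getLogger(__name__)

#: conversion from mol/μm³ to nM
MOL_PER_UM3_TO_NM = 1.0e24

RELEASE_PEAK_S = 3.0

# The bell curve π^{−1/2}·exp(−(τ−3)²) carries a mass erfc(3)/2 ≈ 1.1e−5 on
# τ < 0; the stated normalization ∫₀^∞ R dτ = 1 is enforced exactly by the
# constant below (the peak value stays 0.56419… to the same 1e−5).
_KERNEL_NORM = 0.5 * (1.0 + math.erf(3.0))


def release_kernel_R(tau: np.ndarray | float) -> np.ndarray | float:
    """Release-rate density R(τ) ∝ exp(−(τ−3)²), normalized on τ ≥ 0 (1/s)."""
    tau = np.asarray(tau, dtype=float)
    return np.pi ** -0.5 / _KERNEL_NORM * np.exp(-((tau - RELEASE_PEAK_S) ** 2))


def newly_bound_rate(
    theta_B_now: np.ndarray,
    theta_B_prev: np.ndarray,
    t_now: float,
    t_prev: float,
    P_max: float,
) -> np.ndarray:
    """Rate of newly bound platelets P_max·Δθ_B/Δt (platelets/μm³/s).

    May be negative where θ_B decreased; the release quadrature clips, the
    caller may keep the signed value for diagnostics.
    """
    if t_now <= t_prev:
        raise ValueError(f"non-increasing time: {t_prev} → {t_now}")
    return P_max * (np.asarray(theta_B_now) - np.asarray(theta_B_prev)) / (t_now - t_prev)


@dataclass
class ReleaseHistory:
    """Ring buffer of newly-bound-rate snapshots sampled every Δτ.

    Holds floor(τ_f/Δτ) + 1 snapshots covering [t − τ_f, t]; initialized
    with zeros (no binding before start-up).
    """

    dtau: float          # sampling interval Δτ, s
    tau_f: float         # window length τ_f, s
    shape: tuple[int, int]
    snapshots: np.ndarray = field(init=False)   # (n_slots, ny, nx)
    times: np.ndarray = field(init=False)       # (n_slots,)
    _clip_events: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.dtau <= 0 or self.tau_f <= 0:
            raise ValueError("dtau and tau_f must be positive")
        n = int(np.floor(self.tau_f / self.dtau + 1e-12)) + 1
        self.snapshots = np.zeros((n, *self.shape))
        self.times = -self.dtau * np.arange(n - 1, -1, -1, dtype=float)

    @property
    def n_slots(self) -> int:
        return self.snapshots.shape[0]

    def push(self, B: np.ndarray, t: float) -> None:
        """Append a snapshot taken at time ``t`` (must advance by ≈ Δτ)."""
        if not np.isclose(t - self.times[-1], self.dtau, rtol=1e-6, atol=1e-12):
            raise ValueError(
                f"snapshot at t={t} not commensurate with Δτ={self.dtau} "
                f"(last at {self.times[-1]})"
            )
        if not np.all(np.isfinite(B)):
            raise ValueError("non-finite newly-bound rate snapshot")
        self.snapshots = np.roll(self.snapshots, -1, axis=0)
        self.snapshots[-1] = B
        self.times = np.roll(self.times, -1)
        self.times[-1] = t


def sigma_release(
    history: ReleaseHistory,
    t_now: float,
    A_hat: float,
    clip_negative: bool = True,
) -> np.ndarray:
    """ADP source σ_release (nM/s) by trapezoid quadrature over the buffer.

    σ(t_n) ≈ Σ_k (Â Δτ/2)[R(t_n − τ_k) B(τ_k) + R(t_n − τ_{k+1}) B(τ_{k+1})]
    with B the stored newly-bound rates, converted to molar units by Â.
    """
    if not np.isclose(t_now, history.times[-1], rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"σ_release evaluated at t={t_now} but newest snapshot is at "
            f"{history.times[-1]}"
        )
    B = history.snapshots
    if clip_negative:
        neg = B < 0
        if np.any(neg):
            history._clip_events += 1
            logger.debug("clipped %d negative newly-bound samples", int(neg.sum()))
        B = np.maximum(B, 0.0)
    w = release_kernel_R(t_now - history.times)  # (n_slots,)
    trap = np.ones(history.n_slots)
    trap[0] = trap[-1] = 0.5
    quad = np.tensordot(w * trap, B, axes=(0, 0)) * history.dtau
    return A_hat * MOL_PER_UM3_TO_NM * quad


@dataclass
class ADPField:
    """ADP concentration (nM) with its diffusivity and release constant."""

    field: ScalarField
    D_ADP: float        # μm²/s
    A_hat: float        # mol ADP released per activated platelet

    @property
    def values(self) -> np.ndarray:
        return self.field.values


def advance_adp(
    mesh: StructuredMesh,
    adp: ADPField,
    flux: FaceFluxField,
    sigma: np.ndarray | float,
    dt: float,
    diffusion_op: ImplicitDiffusion | None = None,
    diag: dict | None = None,
) -> ADPField:
    """One unhindered transport step plus the explicit release source.

    The source is held constant between history updates (the buffer cadence
    Δτ), which is why ADP sits outside the fractional-step reaction loop.
    """
    src = np.broadcast_to(np.asarray(sigma, dtype=float), mesh.shape)
    new = advance_transport(
        mesh, adp.field, flux, adp.D_ADP, dt,
        scheme="upwind", diffusion_op=diffusion_op,
        extra_source=src, diag=diag,
    )
    return ADPField(field=new, D_ADP=adp.D_ADP, A_hat=adp.A_hat)
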