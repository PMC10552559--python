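"""Continuum platelet aggregation: four number-density species with hindered
transport and agonist-driven activation.

Species (number densities, platelets/μm³):

* ``P_mu`` — mobile unactivated platelets (advect and diffuse),
* ``P_ma`` — mobile activated platelets (advect and diffuse),
* ``P_ba`` — bound activated platelets (immobile, formed by cohesion),
* ``P_sea`` — subendothelium-bound activated platelets (immobile, formed by
  adhesion to the injured wall).

The mobile species obey the hindered advection–diffusion equation

    ∂P/∂t = −∇·( W(θ_T) (u P − D_P ∇P) ) + S,

where θ_T is the total platelet fraction (all four species over the packing
limit P_max) and W is a hindrance function with W(0) = 1 and W(θ_T ≥ 1) = 0.
The face value of θ_T is interpolated *downwind* for the advective flux (the
flux into a site is throttled by how full the receiving side is) and with a
*localMax* scheme for the diffusive flux (diffusion near a packed region is
limited by the packed side); together these keep θ_T ≤ 1.

Activation by the soluble agonists (ADP and thrombin) follows saturating
Hill kinetics A(c) = k_pla · c/(c* + c); the two agonist rates add.
Adhesion converts mobile platelets inside the adhesion region into
SE-bound platelets up to a surface-site capacity; cohesion converts mobile
activated platelets into bound platelets near existing bound platelets,
scaled by the binding-affinity function g(η) of a platelet-bound enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import AdhesionRegion, StructuredMesh
from .transport import (
    FaceFluxField,
    ImplicitDiffusion,
    ScalarField,
    advance_transport,
    interpolate_to_faces,
)

__all__ = [
    "PlateletState",
    "ActivationKinetics",
    "PlateletRates",
    "compute_fractions",
    "hindrance_W",
    "binding_affinity_g",
    "activation_rate",
    "hindered_platelet_step",
    "platelet_sources",
]

#: molecules/μm³ per nM (Avogadro × 1e-24); converts per-platelet site
#: counts times number density into nM of binding sites.
MOLEC_PER_UM3_PER_NM = 0.6022140857

_TANH_PI = float(np.tanh(np.pi))


@dataclass
class PlateletState:
    P_mu: ScalarField
    P_ma: ScalarField
    P_ba: ScalarField
    P_sea: ScalarField
    P_max: float  # packing limit, platelets/μm³
    D_P: float    # platelet diffusivity, μm²/s

    def species(self) -> dict[str, ScalarField]:
        return {
            "P_mu": self.P_mu, "P_ma": self.P_ma,
            "P_ba": self.P_ba, "P_sea": self.P_sea,
        }

    def total_platelets(self, mesh: StructuredMesh) -> float:
        V = mesh.cell_volumes
        return float(sum(np.sum(f.values * V) for f in self.species().values()))


@dataclass(frozen=True)
class ActivationKinetics:
    """Hill activation A(c) = k_pla · c/(c* + c)."""

    k_pla: float   # maximal activation rate, 1/s
    c_star: float  # half-maximal agonist concentration, nM


def activation_rate(c: np.ndarray | float, kin: ActivationKinetics) -> np.ndarray | float:
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    return kin.k_pla * c / (kin.c_star + c)


@dataclass(frozen=True)
class PlateletRates:
    """Transfer-rate constants of the platelet source terms."""

    k_adh: float = 2.0       # adhesion rate to the exposed SE, 1/s
    k_coh: float = 10.0      # cohesion rate onto existing bound platelets, 1/s
    P_sea_cap: float = 0.047  # SE monolayer capacity, platelets/μm³
    eta_star: float = 0.5    # half-saturation of g(η), nM
    g_form: str = "hill"     # "hill" or "one" (bypass)
    adp: ActivationKinetics = ActivationKinetics(k_pla=0.34, c_star=1000.0)
    thrombin: ActivationKinetics = ActivationKinetics(k_pla=0.5, c_star=1.0)

    def __post_init__(self) -> None:
        for key in ("k_adh", "k_coh", "P_sea_cap", "eta_star"):
            if getattr(self, key) < 0:
                raise ValueError(f"platelet rate constant {key} must be non-negative")


def compute_fractions(state: PlateletState) -> tuple[np.ndarray, np.ndarray]:
    """(θ_B, θ_T): bound and total platelet fractions of the packing limit."""
    pm = state.P_max
    theta_B = (state.P_ba.values + state.P_sea.values) / pm
    theta_T = theta_B + (state.P_mu.values + state.P_ma.values) / pm
    return theta_B, theta_T


def hindrance_W(theta_T: np.ndarray | float, form: str = "tanh") -> np.ndarray:
    """Hindered-transport multiplier: W(0) = 1, non-increasing, W(θ≥1) = 0.

    The default is tanh(π(1 − θ_T))/tanh(π) on [0, 1): smooth, normalized to
    1 at θ_T = 0 and decaying to 0 at the packing limit.  ``form="linear"``
    gives the simpler (1 − θ_T)₊ ramp.
    """
    th = np.asarray(theta_T, dtype=float)
    if form == "tanh":
        w = np.tanh(np.pi * (1.0 - th)) / _TANH_PI
    elif form == "linear":
        w = 1.0 - th
    else:
        raise ValueError(f"unknown hindrance form {form!r}")
    return np.clip(np.where(th >= 1.0, 0.0, w), 0.0, 1.0)


def binding_affinity_g(eta: np.ndarray, eta_star: float, form: str = "hill") -> np.ndarray:
    """Cohesion affinity multiplier g(η) of the chemical η (default Hill)."""
    if form == "one":
        return np.ones_like(np.asarray(eta, dtype=float))
    if form == "hill":
        e = np.maximum(np.asarray(eta, dtype=float), 0.0)
        return e / (eta_star + e)
    raise ValueError(f"unknown binding-affinity form {form!r}")


def hindrance_faces(
    mesh: StructuredMesh,
    theta_T: np.ndarray,
    flux: FaceFluxField,
    form: str = "tanh",
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Per-face hindrance multipliers (advective, diffusive).

    Advective faces use W of the *downwind*-interpolated θ_T; diffusive
    faces use W of the *localMax*-interpolated θ_T.
    """
    thx_a, thy_a = interpolate_to_faces(theta_T, mesh, "downwind", flux)
    thx_d, thy_d = interpolate_to_faces(theta_T, mesh, "localMax")
    W_adv = (hindrance_W(thx_a, form), hindrance_W(thy_a, form))
    W_diff = (hindrance_W(thx_d, form), hindrance_W(thy_d, form))
    return W_adv, W_diff


def hindered_platelet_step(
    mesh: StructuredMesh,
    state: PlateletState,
    flux: FaceFluxField,
    dt: float,
    diffusion_ops: dict[str, ImplicitDiffusion] | None = None,
    hindrance_form: str = "tanh",
    diag: dict | None = None,
) -> PlateletState:
    """Pure transport step: advance the two mobile species with per-face
    hindrance; bound species are immobile and pass through untouched.

    Reaction sources are applied separately (fractional-step coupling).
    """
    _, theta_T = compute_fractions(state)
    W_adv, W_diff = hindrance_faces(mesh, theta_T, flux, hindrance_form)
    new = {}
    influx = clipped = 0.0
    for name in ("P_mu", "P_ma"):
        f = getattr(state, name)
        op = (diffusion_ops or {}).get(name)
        d: dict = {}
        new[name] = advance_transport(
            mesh, f, flux, state.D_P, dt,
            hindrance_faces=W_adv,
            hindrance_faces_diff=W_diff,
            scheme="upwind",
            diffusion_op=op,
            diag=d,
        )
        influx += d.get("boundary_influx", 0.0)
        clipped += d.get("clipped_mass", 0.0)
    if diag is not None:
        diag.update(d)
        diag["plt_influx"] = influx   # platelets/s through the boundary
        diag["plt_clipped"] = clipped
    return replace(state, P_mu=new["P_mu"], P_ma=new["P_ma"])


def platelet_sources(
    state: PlateletState | dict[str, np.ndarray],
    adhesion: AdhesionRegion | None,
    rates: PlateletRates,
    adp_conc: np.ndarray | float = 0.0,
    thrombin_conc: np.ndarray | float = 0.0,
    eta: np.ndarray | float = 0.0,
    P_max: float | None = None,
) -> dict[str, np.ndarray]:
    """Source terms S_k (platelets/μm³/s) for the four platelet species.

    Transitions (each conserves total platelet number):

    * activation: P_mu → P_ma at rate A(ADP) + A(thrombin);
    * adhesion: P_mu, P_ma → P_sea inside the adhesion region, limited by
      the remaining SE capacity and the packing saturation (1 − θ_T)₊;
      unactivated platelets activate upon adhesion;
    * cohesion: P_ma → P_ba at rate k_coh · g(η) · θ_B · (1 − θ_T)₊,
      requiring existing bound platelets (θ_B > 0) nearby.
    """
    if isinstance(state, PlateletState):
        vals = {k: f.values for k, f in state.species().items()}
        pm = state.P_max
    else:
        vals = state
        if P_max is None:
            raise ValueError("P_max required when passing raw arrays")
        pm = P_max
    P_mu, P_ma = vals["P_mu"], vals["P_ma"]
    P_ba, P_sea = vals["P_ba"], vals["P_sea"]
    theta_B = (P_ba + P_sea) / pm
    theta_T = theta_B + (P_mu + P_ma) / pm
    sat = np.maximum(1.0 - theta_T, 0.0)

    A_tot = activation_rate(adp_conc, rates.adp) + activation_rate(
        thrombin_conc, rates.thrombin
    )
    act = A_tot * P_mu

    if adhesion is not None and rates.k_adh > 0:
        se_room = np.maximum(1.0 - P_sea / rates.P_sea_cap, 0.0)
        adh_factor = rates.k_adh * adhesion.indicator * se_room * sat
    else:
        adh_factor = 0.0
    adh_mu = adh_factor * P_mu
    adh_ma = adh_factor * P_ma

    g = binding_affinity_g(np.asarray(eta, dtype=float), rates.eta_star, rates.g_form)
    coh = rates.k_coh * g * theta_B * sat * P_ma

    zero = np.zeros_like(np.asarray(P_mu, dtype=float))
    return {
        "P_mu": zero - act - adh_mu,
        "P_ma": act - adh_ma - coh,
        "P_ba": zero + coh,
        "P_sea": adh_mu + adh_ma,
    }
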