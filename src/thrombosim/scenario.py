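"""Shipped cases, configuration, the main solver loop and clot metrics.

The reference scenario is thrombosis in a 2D rectangular channel:
240 μm × 60 μm, with an ≈ 90 μm adhesive/reactive patch (``injuryWalls``)
centered on the bottom wall, built from three mesh blocks.  The full case
discretizes the channel with 128 × 32 uniform cells (1.875 μm ≤ platelet
diameter); the reduced variant uses 96 × 24 cells (2.5 μm) and a shorter
end time so that a complete run fits in a test suite.

One time step of the coupled solver:

1. update the inverse permeability α from the previous step's θ_B;
2. momentum predictor + pressure correctors (flow);
3. hindered platelet transport and chemical transport (Δt);
4. M_rxn RK4 reaction sub-steps (platelet sources, cascade, surface
   reaction at injuryWalls);
5. at the Δτ cadence, push the newly-bound-platelet rate into the release
   history and refresh σ_release;
6. ADP transport with the (piecewise-constant) release source;
7. diagnostics and optional snapshot output.

Everything is deterministic: identical configurations produce bit-identical
results.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import adp as adp_mod
from . import coagulation as coag
from .fluid import BrinkmanFlowSolver, FluidBC, FluidState, carman_kozeny_alpha
from .mesh import (
    AdhesionRegion,
    BlockSpec,
    StructuredMesh,
    build_multiblock_mesh,
    compute_adhesion_region,
    validate_injury_resolution,
)
from .platelets import (
    ActivationKinetics,
    PlateletRates,
    PlateletState,
    compute_fractions,
)
from .transport import (
    BoundaryConditionSpec,
    ImplicitDiffusion,
    ScalarField,
    _face_patch_map,
    patch_adjacent_cells,
)

__all__ = [
    "SimulationConfig",
    "OutputBundle",
    "Simulation",
    "generate_channel_case",
    "run_simulation",
    "clot_metrics",
]


@dataclass
class SimulationConfig:
    """Flat parameter collection (the analogue of a case's parameter file).

    Units: μm, s, nM unless noted.  The defaults are the shipped channel
    conditions; the mesh is described separately by the case geometry.
    """

    # geometry (used by generate_channel_case)
    length: float = 240.0
    height: float = 60.0
    injury_length: float = 90.0
    nx: int = 128
    ny: int = 32

    # fluid
    nu: float = 1.2e6          # kinematic viscosity, μm²/s (plasma)
    rho: float = 1.0e-15       # density, kg/μm³
    wall_shear: float = 100.0  # inlet wall shear rate, 1/s
    n_correctors: int = 2
    div_tolerance: float = 1e-8
    alpha_rebuild_tol: float = 0.0  # μm⁻²; operator-lag tolerance

    # platelets
    P_max: float = 0.0667      # packing limit, platelets/μm³
    D_P: float = 25.0          # platelet diffusivity, μm²/s
    P_mu_in: float = 2.5e-4    # inlet mobile-unactivated density
    P_ma_in: float = 0.0
    Pdiam: float = 3.0
    k_adh: float = 2.0
    k_coh: float = 10.0
    P_sea_cap: float = 0.047   # SE monolayer capacity, platelets/μm³
    eta_star: float = 0.5
    g_form: str = "hill"
    k_pla_adp: float = 0.34
    cstar_adp: float = 1000.0
    k_pla_e2: float = 0.5
    cstar_e2: float = 1.0
    hindrance_form: str = "tanh"
    hindrance_rebuild_tol: float = 0.0

    # ADP release
    D_ADP: float = 250.0
    A_hat: float = 2.4e-17     # mol ADP per platelet
    sigma_dt: float = 0.05     # Δτ, s
    sigma_Tf: float = 6.0      # τ_f, s

    # coagulation
    D_chem: float = 50.0
    E0_surf: float = 10.0      # SE enzyme density, nM·μm
    S1_in: float = 170.0
    S2_in: float = 1400.0
    kI: float = 0.0            # inhibitor extension (0 = off)
    I_in: float = 0.0
    coag_params: dict = field(default_factory=lambda: dict(coag.DEFAULT_COAG_PARAMS))

    # numerics
    dt: float = 5e-4
    end_time: float = 30.0
    M_rxn: int = 2
    cfl_strict: bool = False
    output_interval: float = 1.0
    label: str = "channel"

    def __post_init__(self) -> None:
        for key in ("nu", "P_max", "dt", "end_time", "sigma_dt", "sigma_Tf", "Pdiam"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config key {key} must be positive")
        if self.M_rxn < 1 or self.n_correctors < 1:
            raise ValueError("M_rxn and n_correctors must be ≥ 1")
        ratio = self.sigma_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("sigma_dt must be an integer multiple of dt")

    # -- derived ------------------------------------------------------------
    @property
    def u_max(self) -> float:
        """Peak inlet velocity of the parabolic profile: γ_w H/4."""
        return self.wall_shear * self.height / 4.0

    def platelet_rates(self) -> PlateletRates:
        return PlateletRates(
            k_adh=self.k_adh, k_coh=self.k_coh, P_sea_cap=self.P_sea_cap,
            eta_star=self.eta_star, g_form=self.g_form,
            adp=ActivationKinetics(self.k_pla_adp, self.cstar_adp),
            thrombin=ActivationKinetics(self.k_pla_e2, self.cstar_e2),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def generate_channel_case(scale: str = "full") -> tuple[StructuredMesh, SimulationConfig]:
    """The 2D thrombosis channel: three blocks, injuryWalls centered below.

    ``full``: 128 × 32 cells (1.875 μm).  ``reduced``: 96 × 24 cells
    (2.5 μm, still below the platelet diameter) with a shortened end time;
    physical parameters are identical between the two.
    """
    if scale == "full":
        nx, ny, end_time = 128, 32, 200.0
    elif scale == "reduced":
        nx, ny, end_time = 96, 24, 30.0
    else:
        raise ValueError(f"unknown scale {scale!r}")
    cfg = SimulationConfig(nx=nx, ny=ny, end_time=end_time,
                           alpha_rebuild_tol=1e-3, hindrance_rebuild_tol=1e-3,
                           label=f"channel-{scale}")
    L, H, Li = cfg.length, cfg.height, cfg.injury_length
    side = (L - Li) / 2.0
    n_side = round(nx * side / L)
    n_mid = nx - 2 * n_side
    blocks = [
        BlockSpec(0.0, side, 0.0, H, n_side, ny),
        BlockSpec(side, side + Li, 0.0, H, n_mid, ny),
        BlockSpec(side + Li, L, 0.0, H, n_side, ny),
    ]
    assignments = {
        (0, "left"): "inlet", (2, "right"): "outlet",
        (0, "top"): "walls", (1, "top"): "walls", (2, "top"): "walls",
        (0, "bottom"): "walls", (2, "bottom"): "walls",
        (1, "bottom"): "injuryWalls",
    }
    mesh = build_multiblock_mesh(blocks, assignments)
    return mesh, cfg


# ---------------------------------------------------------------------------
# simulation state & loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Complete restartable solver state."""

    t: float
    step: int
    fluid: FluidState
    platelets: PlateletState
    chem: dict[str, ScalarField]
    adp: adp_mod.ADPField
    history: adp_mod.ReleaseHistory
    sigma: np.ndarray
    theta_B_snapshot: np.ndarray  # θ_B at the last history push
    t_snapshot: float

    def copy(self) -> "SimulationState":
        return copy.deepcopy(self)


@dataclass
class OutputBundle:
    """Time-stamped snapshots plus scalar time series."""

    mesh: StructuredMesh
    config: SimulationConfig
    times: list[float] = field(default_factory=list)
    snapshots: dict[str, list[np.ndarray]] = field(default_factory=dict)
    series: dict[str, list[float]] = field(default_factory=dict)
    final_state: SimulationState | None = None

    def record_snapshot(self, t: float, fields: dict[str, np.ndarray]) -> None:
        self.times.append(t)
        for k, v in fields.items():
            self.snapshots.setdefault(k, []).append(np.array(v, copy=True))

    def record_series(self, **kwargs: float) -> None:
        for k, v in kwargs.items():
            self.series.setdefault(k, []).append(float(v))

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.series)


class Simulation:
    """Owns the operators and advances the coupled system step by step."""

    def __init__(
        self,
        mesh: StructuredMesh,
        config: SimulationConfig,
        state: SimulationState | None = None,
        enable_injury: bool = True,
    ) -> None:
        self.mesh = mesh
        self.config = config
        self.enable_injury = enable_injury and mesh.has_patch("injuryWalls")
        cfg = config

        if self.enable_injury:
            report = validate_injury_resolution(mesh, cfg.Pdiam)
            if not report.passed:
                raise ValueError(f"mesh fails injury resolution: {report.message}")
            self.adhesion: AdhesionRegion | None = compute_adhesion_region(mesh, cfg.Pdiam)
        else:
            self.adhesion = None

        # fluid
        yc = 0.5 * (mesh.y_faces[:-1] + mesh.y_faces[1:])
        H = mesh.y_faces[-1] - mesh.y_faces[0]
        profile = 4.0 * cfg.u_max * yc * (H - yc) / H**2
        self.flow = BrinkmanFlowSolver(
            mesh, cfg.nu, FluidBC("velocity", profile=profile),
            FluidBC("pressure", p=0.0),
            n_correctors=cfg.n_correctors, div_tolerance=cfg.div_tolerance,
            alpha_rebuild_tol=cfg.alpha_rebuild_tol,
        )

        # registry (surface reaction on the injury-adjacent cells)
        surface = None
        self._E0_faces = None
        if self.enable_injury:
            jj, ii, areas = patch_adjacent_cells(mesh, "injuryWalls")
            E0_cell = np.zeros(mesh.shape)
            AoV = np.zeros(mesh.shape)
            E0_cell[jj, ii] = cfg.E0_surf
            AoV[jj, ii] = areas / mesh.cell_volumes[jj, ii]
            surface = (E0_cell, AoV)
            self._E0_faces = np.full(len(jj), cfg.E0_surf)
        inlet = {"S1": cfg.S1_in, "S2": cfg.S2_in}
        self.registry = coag.register_reduced_model(
            cfg.coag_params, D_chem=cfg.D_chem, inlet=inlet, surface=surface
        )
        if cfg.kI > 0:
            coag.add_inhibitor_extension(
                self.registry, cfg.kI, D_chem=cfg.D_chem,
                inlet_value=cfg.I_in, initial_value=cfg.I_in,
            )
        self.rates = cfg.platelet_rates()
        coag.attach_platelet_model(
            self.registry, self.rates, self.adhesion, cfg.P_max
        )

        # fields / operators
        self.state = state.copy() if state is not None else self._initial_state()
        self._build_transport_ops()
        #: running per-step maxima (conservation & boundedness monitors)
        self.monitors = {
            "max_theta_T": 0.0,
            "max_budget_residual": 0.0,   # platelet budget closure, relative
            "max_reaction_drift": 0.0,    # reaction-stage total drift, relative
        }

    # -- setup --------------------------------------------------------------
    def _bc(self, inlet_value: float) -> dict[str, BoundaryConditionSpec]:
        return {
            "inlet": BoundaryConditionSpec("inflow_value", value=inlet_value),
            "outlet": BoundaryConditionSpec("zero_gradient"),
            "walls": BoundaryConditionSpec("zero_gradient"),
            "injuryWalls": BoundaryConditionSpec("zero_gradient"),
        }

    def _initial_state(self) -> SimulationState:
        mesh, cfg = self.mesh, self.config
        zeros = lambda: np.zeros(mesh.shape)

        def f(name, init, inlet_value, units="nM"):
            return ScalarField(np.full(mesh.shape, float(init)), name=name,
                               units=units, bcs=self._bc(inlet_value))

        plt_state = PlateletState(
            P_mu=f("P_mu", cfg.P_mu_in, cfg.P_mu_in, "platelets/μm³"),
            P_ma=f("P_ma", cfg.P_ma_in, cfg.P_ma_in, "platelets/μm³"),
            P_ba=f("P_ba", 0.0, 0.0, "platelets/μm³"),
            P_sea=f("P_sea", 0.0, 0.0, "platelets/μm³"),
            P_max=cfg.P_max, D_P=cfg.D_P,
        )
        chem = {}
        for e in self.registry.entries:
            if e.category == "fluidPhase":
                chem[e.name] = f(e.name, e.initial_value, e.inlet_value)
            elif e.category == "pltBound":
                chem[e.name] = ScalarField(zeros(), name=e.name, units="nM")
        adp_field = adp_mod.ADPField(
            field=f("ADP", 0.0, 0.0), D_ADP=cfg.D_ADP, A_hat=cfg.A_hat
        )
        history = adp_mod.ReleaseHistory(
            dtau=cfg.sigma_dt, tau_f=cfg.sigma_Tf, shape=mesh.shape
        )
        fluid = FluidState.zero(mesh, cfg.nu, cfg.rho)
        return SimulationState(
            t=0.0, step=0, fluid=fluid, platelets=plt_state, chem=chem,
            adp=adp_field, history=history, sigma=zeros(),
            theta_B_snapshot=zeros(), t_snapshot=0.0,
        )

    def _build_transport_ops(self) -> None:
        mesh, cfg = self.mesh, self.config
        fmap = _face_patch_map(mesh)
        self.chem_ops = {
            name: ImplicitDiffusion(mesh, self.registry.entry(name).diffusivity,
                                    cfg.dt, self.state.chem[name].bcs, fmap)
            for name in self.state.chem
            if self.registry.entry(name).category == "fluidPhase"
        }
        self.adp_op = ImplicitDiffusion(mesh, cfg.D_ADP, cfg.dt,
                                        self.state.adp.field.bcs, fmap)
        self.plt_ops = {
            name: ImplicitDiffusion(mesh, cfg.D_P, cfg.dt,
                                    getattr(self.state.platelets, name).bcs, fmap,
                                    rebuild_tol=cfg.hindrance_rebuild_tol)
            for name in ("P_mu", "P_ma")
        }

    # -- stepping -----------------------------------------------------------
    @property
    def sigma_every(self) -> int:
        return int(round(self.config.sigma_dt / self.config.dt))

    def step(self, diag: dict | None = None) -> None:
        st = self.state
        cfg = self.config
        mesh = self.mesh
        dt = cfg.dt
        diag = diag if diag is not None else {}

        theta_B, theta_T = compute_fractions(st.platelets)
        alpha = carman_kozeny_alpha(theta_B)
        st.fluid = self.flow.step(st.fluid, alpha, dt, diag=diag)
        flux = st.fluid.face_flux(mesh)

        plt_total_before = st.platelets.total_platelets(mesh)
        st.platelets, st.chem = coag.fractional_step(
            mesh, st.platelets, st.chem, self.registry, flux, dt,
            M_rxn=cfg.M_rxn, adp_values=st.adp.values,
            transport_ops=self.chem_ops, platelet_ops=self.plt_ops,
            hindrance_form=cfg.hindrance_form, diag=diag,
        )
        # conservation monitors: transport budget closure and reaction-stage
        # transfer-only property, both relative to the platelet total
        scale = max(plt_total_before, 1e-300)
        budget_res = abs(
            diag.get("plt_total_after_transport", plt_total_before)
            - plt_total_before
            - dt * diag.get("plt_influx", 0.0)
            - diag.get("plt_clipped", 0.0)
        ) / scale
        drift = abs(diag.get("plt_reaction_drift", 0.0)) / scale
        m = self.monitors
        m["max_budget_residual"] = max(m["max_budget_residual"], budget_res)
        m["max_reaction_drift"] = max(m["max_reaction_drift"], drift)
        m["max_theta_T"] = max(m["max_theta_T"], float(theta_T.max()))

        t_new = st.t + dt
        if (st.step + 1) % self.sigma_every == 0:
            theta_B_new, _ = compute_fractions(st.platelets)
            B = adp_mod.newly_bound_rate(
                theta_B_new, st.theta_B_snapshot, t_new, st.t_snapshot, cfg.P_max
            )
            st.history.push(B, t_new)
            st.sigma = adp_mod.sigma_release(st.history, t_new, cfg.A_hat)
            st.theta_B_snapshot = theta_B_new.copy()
            st.t_snapshot = t_new

        st.adp = adp_mod.advance_adp(
            mesh, st.adp, flux, st.sigma, dt, diffusion_op=self.adp_op, diag=diag
        )
        st.t = t_new
        st.step += 1

    def run(
        self,
        end_time: float | None = None,
        bundle: OutputBundle | None = None,
        record_initial: bool = True,
    ) -> OutputBundle:
        cfg = self.config
        end_time = cfg.end_time if end_time is None else end_time
        bundle = bundle or OutputBundle(mesh=self.mesh, config=cfg)
        out_every = max(1, int(round(cfg.output_interval / cfg.dt)))
        if record_initial and not bundle.times:
            self._record(bundle, {})
        n_steps = int(round((end_time - self.state.t) / cfg.dt))
        for _ in range(n_steps):
            diag: dict = {}
            self.step(diag)
            if self.state.step % out_every == 0:
                self._record(bundle, diag)
        bundle.final_state = self.state.copy()
        return bundle

    def _record(self, bundle: OutputBundle, diag: dict) -> None:
        st = self.state
        mesh = self.mesh
        theta_B, theta_T = compute_fractions(st.platelets)
        fields = {
            "u": st.fluid.u, "v": st.fluid.v, "p": st.fluid.p,
            "theta_B": theta_B, "theta_T": theta_T, "ADP": st.adp.values,
        }
        for name, f in st.platelets.species().items():
            fields[name] = f.values
        for name, f in st.chem.items():
            fields[name] = f.values
        bundle.record_snapshot(st.t, fields)
        V = mesh.cell_volumes
        thrombin = st.chem["E2"].values + st.chem["E2b"].values
        bundle.record_series(
            t=st.t,
            theta_T_max=float(theta_T.max()),
            theta_B_max=float(theta_B.max()),
            total_platelets=st.platelets.total_platelets(mesh),
            total_thrombin=float(np.sum(thrombin * V)),
            clot_area=float(np.sum(V[theta_B >= 0.5])),
            max_div=float(diag.get("max_div_normalized", 0.0)),
            clipped_mass=float(diag.get("clipped_mass", 0.0)),
            budget_residual=self.monitors["max_budget_residual"],
            reaction_drift=self.monitors["max_reaction_drift"],
        )


def run_simulation(
    mesh: StructuredMesh,
    config: SimulationConfig,
    enable_injury: bool = True,
) -> OutputBundle:
    """Run a case from rest to ``config.end_time``; returns the bundle."""
    sim = Simulation(mesh, config, enable_injury=enable_injury)
    return sim.run()


def clot_metrics(bundle: OutputBundle, theta_threshold: float = 0.5) -> pd.DataFrame:
    """Clot size/density and thrombin time series from a bundle.

    clot area: total volume (unit-depth area) of cells with θ_B ≥ threshold;
    mean clot density: mean θ_B over those cells; total thrombin:
    ∫(E2 + E2b) dV in nM·μm³.
    """
    need = {"theta_B", "E2", "E2b"}
    if not need.issubset(bundle.snapshots):
        raise ValueError(f"bundle lacks fields: {need - set(bundle.snapshots)}")
    V = bundle.mesh.cell_volumes
    rows = []
    for i, t in enumerate(bundle.times):
        thB = bundle.snapshots["theta_B"][i]
        mask = thB >= theta_threshold
        thrombin = bundle.snapshots["E2"][i] + bundle.snapshots["E2b"][i]
        rows.append({
            "t": t,
            "clot_area": float(np.sum(V[mask])),
            "mean_clot_density": float(thB[mask].mean()) if mask.any() else 0.0,
            "total_thrombin": float(np.sum(thrombin * V)),
        })
    return pd.DataFrame(rows)
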