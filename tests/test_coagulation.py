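"""Reduced coagulation cascade: registry, kinetics, RK4, splitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thrombosim.coagulation import (
    DEFAULT_COAG_PARAMS,
    ReactionWorkspace,
    RegistryError,
    SpeciesEntry,
    add_inhibitor_extension,
    attach_platelet_model,
    fractional_step,
    register_reduced_model,
    rk4_react,
    se_surface_reaction,
    thrombin_burst_diagnostics,
)
from thrombosim.mesh import AdhesionRegion, BlockSpec, build_single_block
from thrombosim.platelets import MOLEC_PER_UM3_PER_NM, PlateletRates, PlateletState
from thrombosim.transport import FaceFluxField, ScalarField

P_MAX = 0.0667


def full_registry(params=None, surface=None):
    reg = register_reduced_model(dict(params or DEFAULT_COAG_PARAMS), surface=surface)
    attach_platelet_model(reg, PlateletRates(k_adh=0.0, k_coh=0.0), None, P_MAX)
    return reg


def seeded_state(reg, n=1, Pb=0.02, E1=0.05, S2=1400.0):
    """Closed-box state with a pre-formed platelet surface and consistent
    free-site pools, initiated by an E1 bolus."""
    st = {name: np.zeros(n) for name in reg.integrated_names}
    st["E1"][:] = E1
    st["S2"][:] = S2
    st["P_ba"][:] = Pb
    st["Z1"][:] = reg.params["N1_sites"] / MOLEC_PER_UM3_PER_NM * Pb
    st["Z2"][:] = reg.params["N2_sites"] / MOLEC_PER_UM3_PER_NM * Pb
    return st


class TestRegistry:
    def test_default_model_has_twelve_coagulation_species(self):
        reg = register_reduced_model(dict(DEFAULT_COAG_PARAMS))
        assert reg.n_coagulation_species == 12
        counts = reg.category_counts()
        assert counts["fluidPhase"] == 4
        assert counts["pltBound"] == 7
        assert counts["seBound"] == 1

    def test_platelet_side_has_five_adr_equations(self):
        reg = full_registry()
        assert reg.n_platelet_adr == 5  # 4 platelet species + ADP

    def test_sebound_species_never_integrated(self):
        reg = full_registry()
        assert "E0" not in reg.integrated_names

    def test_missing_rate_constant_fails_fast(self):
        bad = dict(DEFAULT_COAG_PARAMS)
        del bad["kon1"], bad["krel"]
        with pytest.raises(RegistryError, match="kon1"):
            register_reduced_model(bad)

    def test_negative_rate_constant_rejected(self):
        bad = dict(DEFAULT_COAG_PARAMS)
        bad["k1cat"] = -1.0
        with pytest.raises(RegistryError, match="k1cat"):
            register_reduced_model(bad)

    def test_unknown_keys_warn(self):
        params = dict(DEFAULT_COAG_PARAMS, mystery_rate=1.0)
        with pytest.warns(UserWarning, match="mystery_rate"):
            register_reduced_model(params)

    def test_no_platelets_no_pltbound_rates(self):
        reg = full_registry()
        st = {name: np.zeros(4) for name in reg.integrated_names}
        st["S1"][:] = 170.0
        st["S2"][:] = 1400.0
        st["E1"][:] = 5.0  # fluid enzyme present, but no surface to bind
        rhs = reg.rhs({**st, "ADP": np.zeros(4)})
        for name in ("E1b", "S2b", "E2b", "E1b_inh", "E2b_inh", "Z1", "Z2"):
            assert np.all(rhs[name] == 0.0)

    def test_e2b_production_linear_in_e1b_without_feedback(self):
        params = dict(DEFAULT_COAG_PARAMS, k2cat=0.0)
        reg = full_registry(params)
        base = {name: np.zeros(1) for name in reg.integrated_names}
        base["S2b"][:] = 50.0

        def de2b(e1b):
            st = {k: v.copy() for k, v in base.items()}
            st["E1b"][:] = e1b
            rhs = reg.rhs({**st, "ADP": np.zeros(1)})
            # isolate production (release/inhibition don't act: E2b = 0)
            return float(rhs["E2b"][0])

        assert de2b(2.0) == pytest.approx(2 * de2b(1.0), rel=1e-12)


class TestSurfaceReaction:
    def test_no_enzyme_no_flux(self):
        fS1, fE1 = se_surface_reaction(np.array([100.0]), np.array([0.0]), 2.0, 170.0)
        assert fS1[0] == 0.0 and fE1[0] == 0.0

    def test_one_to_one_conversion_balance(self):
        fS1, fE1 = se_surface_reaction(np.array([50.0]), np.array([10.0]), 2.0, 170.0)
        assert fS1[0] == -fE1[0] < 0

    def test_first_order_in_enzyme_density(self):
        _, a = se_surface_reaction(np.array([5.0]), np.array([10.0]), 2.0, 170.0)
        _, b = se_surface_reaction(np.array([5.0]), np.array([20.0]), 2.0, 170.0)
        assert b[0] == pytest.approx(2 * a[0])

    def test_closed_box_time_integrated_balance(self):
        # S1 lost equals E1 gained along an RK4 trajectory with SE on
        E0 = np.array([10.0])
        AoV = np.array([1 / 30.0])
        reg = full_registry(surface=(E0, AoV))
        st = seeded_state(reg, E1=0.0)
        st["S1"][:] = 170.0
        total0 = st["S1"][0] + st["E1"][0] + st["E1b"][0] + st["E1b_inh"][0]
        ws = ReactionWorkspace(st)
        rk4_react(ws, reg, h=0.01, n_steps=2000, frozen={"ADP": np.zeros(1)})
        f = ws.fields
        total = f["S1"][0] + f["E1"][0] + f["E1b"][0] + f["E1b_inh"][0]
        assert total == pytest.approx(total0, rel=1e-8)
        assert f["S1"][0] < 170.0  # the wall actually consumed substrate


class TestRK4:
    def test_zero_rhs_is_bitwise_identity(self):
        reg = full_registry(dict(DEFAULT_COAG_PARAMS, **{
            k: 0.0 for k in ("kon1", "koff1", "kon2", "koff2", "k1cat",
                             "k2cat", "krel", "kinh1", "kinh2")}))
        st = seeded_state(reg)
        before = {k: v.copy() for k, v in st.items()}
        out = rk4_react(st, reg, h=0.1, n_steps=5, frozen={"ADP": np.zeros(1)})
        for k in before:
            assert np.array_equal(out[k], before[k])

    def test_linear_decay_matches_degree4_taylor_exactly(self):
        # dC/dt = −λC through the registry machinery via the inhibitor path
        lam = 0.7
        reg = register_reduced_model(dict(DEFAULT_COAG_PARAMS, **{
            k: 0.0 for k in ("kon1", "koff1", "kon2", "koff2", "k1cat",
                             "k2cat", "krel", "kinh1")}, kinh2=lam))
        st = {name: np.zeros(1) for name in reg.integrated_names}
        st["E2b"][:] = 1.0
        h = 0.3
        out = rk4_react(st, reg, h=h, n_steps=1)
        z = -lam * h
        taylor4 = 1 + z + z**2 / 2 + z**3 / 6 + z**4 / 24
        assert out["E2b"][0] == pytest.approx(taylor4, rel=1e-14)

    def test_fourth_order_convergence_on_full_network(self):
        reg = full_registry()
        T = 2.0
        keys = ("E2b", "E2", "S2b", "E1b", "S2", "Z2")
        sols = []
        for h in (0.04, 0.02, 0.01):
            out = rk4_react(seeded_state(reg), reg, h=h, n_steps=int(round(T / h)),
                            frozen={"ADP": np.zeros(1)})
            sols.append(np.array([out[k][0] for k in keys]))
        fine = rk4_react(seeded_state(reg), reg, h=0.00125,
                         n_steps=int(round(T / 0.00125)),
                         frozen={"ADP": np.zeros(1)})
        fv = np.array([fine[k][0] for k in keys])
        e = [np.max(np.abs(s - fv)) for s in sols]
        orders = [np.log2(e[i] / e[i + 1]) for i in range(2)]
        # Richardson estimate on the finest pair; coarser pair is still
        # leaving the fast initial binding transient
        assert orders[-1] >= 3.9
        assert min(orders) >= 3.7

    def test_nonfinite_stage_names_species(self):
        reg = full_registry(dict(DEFAULT_COAG_PARAMS, k2cat=1e9))
        st = seeded_state(reg, E1=1e6, S2=1e9)
        with pytest.raises(FloatingPointError, match="non-finite value for species"):
            rk4_react(st, reg, h=10.0, n_steps=50, frozen={"ADP": np.zeros(1)})


class TestStoichiometricInvariants:
    def test_linear_invariants_hold_along_trajectories(self):
        reg = full_registry()
        st = seeded_state(reg)
        inv1_0 = st["E1"] + st["E1b"] + st["E1b_inh"]
        inv2_0 = st["S2"] + st["S2b"] + st["E2b"] + st["E2"] + st["E2b_inh"]
        inv3_0 = st["Z1"] + st["E1b"] + st["E1b_inh"]
        inv4_0 = st["Z2"] + st["S2b"] + st["E2b"] + st["E2b_inh"]
        ws = ReactionWorkspace(st)
        rk4_react(ws, reg, h=0.01, n_steps=3000, frozen={"ADP": np.zeros(1)})
        f = ws.fields
        assert f["E1"] + f["E1b"] + f["E1b_inh"] == pytest.approx(inv1_0, rel=1e-8)
        assert (f["S2"] + f["S2b"] + f["E2b"] + f["E2"] + f["E2b_inh"]
                == pytest.approx(inv2_0, rel=1e-8))
        assert f["Z1"] + f["E1b"] + f["E1b_inh"] == pytest.approx(inv3_0, rel=1e-8)
        assert (f["Z2"] + f["S2b"] + f["E2b"] + f["E2b_inh"]
                == pytest.approx(inv4_0, rel=1e-8))
        assert f["E2b"][0] > 1.0  # the cascade actually ran


class TestInhibitorExtension:
    def test_zero_rate_leaves_dynamics_unchanged(self):
        reg_a = full_registry()
        reg_b = full_registry()
        add_inhibitor_extension(reg_b, k_I=0.0)
        st_a = seeded_state(reg_a)
        st_b = seeded_state(reg_b)
        st_b["I"] = np.full(1, 50.0)
        st_b["E2_inh"] = np.zeros(1)
        out_a = rk4_react(st_a, reg_a, 0.01, 500, frozen={"ADP": np.zeros(1)})
        out_b = rk4_react(st_b, reg_b, 0.01, 500, frozen={"ADP": np.zeros(1)})
        for k in out_a:
            assert np.array_equal(out_a[k], out_b[k])
        assert out_b["I"][0] == 50.0

    def test_exponential_decay_against_held_thrombin(self):
        # isolate the new reaction: every base rate off, E2 held by symmetry
        params = dict(DEFAULT_COAG_PARAMS, **{
            k: 0.0 for k in ("kon1", "koff1", "kon2", "koff2", "k1cat",
                             "k2cat", "krel", "kinh1", "kinh2")})
        reg = register_reduced_model(params)
        kI = 0.004
        add_inhibitor_extension(reg, k_I=kI)
        st = {name: np.zeros(1) for name in reg.integrated_names}
        st["I"][:] = 0.1
        st["E2"][:] = 100.0
        T = 10.0
        out = rk4_react(st, reg, h=0.01, n_steps=int(T / 0.01))
        # E2 ≫ I: E2 stays ≈ constant, I decays exponentially at kI·E2
        assert out["I"][0] == pytest.approx(0.1 * np.exp(-kI * 100.0 * T), rel=2e-2)

    def test_inhibited_mass_conserved(self):
        reg = full_registry()
        add_inhibitor_extension(reg, k_I=0.01)
        st = seeded_state(reg)
        st["I"] = np.full(1, 20.0)
        st["E2_inh"] = np.zeros(1)
        out = rk4_react(st, reg, h=0.01, n_steps=3000, frozen={"ADP": np.zeros(1)})
        assert out["I"][0] + out["E2_inh"][0] == pytest.approx(20.0, rel=1e-10)
        assert out["E2_inh"][0] > 0  # inhibition actually occurred

    def test_name_collision_rejected(self):
        reg = full_registry()
        add_inhibitor_extension(reg, k_I=0.01)
        with pytest.raises(RegistryError, match="already registered"):
            add_inhibitor_extension(reg, k_I=0.01)


class TestFractionalStep:
    def _setup(self, mesh):
        reg = register_reduced_model(dict(DEFAULT_COAG_PARAMS))
        rates = PlateletRates(k_adh=0.0, k_coh=0.0)
        attach_platelet_model(reg, rates, None, P_MAX)
        chem = {}
        for e in reg.entries:
            if e.category in ("fluidPhase", "pltBound"):
                chem[e.name] = ScalarField(np.zeros(mesh.shape), name=e.name)
        Pb = 0.02
        chem["E1"].values[:] = 0.05
        chem["S2"].values[:] = 1400.0
        chem["Z1"].values[:] = DEFAULT_COAG_PARAMS["N1_sites"] / MOLEC_PER_UM3_PER_NM * Pb
        chem["Z2"].values[:] = DEFAULT_COAG_PARAMS["N2_sites"] / MOLEC_PER_UM3_PER_NM * Pb
        def f(v):
            return ScalarField(np.full(mesh.shape, float(v)))
        plt = PlateletState(P_mu=f(0.0), P_ma=f(0.0), P_ba=f(Pb), P_sea=f(0.0),
                           P_max=P_MAX, D_P=25.0)
        return reg, plt, chem

    def test_reactions_off_equals_pure_transport(self, box_mesh):
        reg = register_reduced_model(dict(DEFAULT_COAG_PARAMS, **{
            k: 0.0 for k in ("kon1", "koff1", "kon2", "koff2", "k1cat",
                             "k2cat", "krel", "kinh1", "kinh2")}))
        rates = PlateletRates(k_adh=0.0, k_coh=0.0, adp=None, thrombin=None)
        # zero platelet activation too
        from thrombosim.platelets import ActivationKinetics
        rates = PlateletRates(k_adh=0.0, k_coh=0.0,
                              adp=ActivationKinetics(0.0, 1.0),
                              thrombin=ActivationKinetics(0.0, 1.0))
        attach_platelet_model(reg, rates, None, P_MAX)
        chem = {e.name: ScalarField(np.zeros(box_mesh.shape), name=e.name)
                for e in reg.entries if e.category in ("fluidPhase", "pltBound")}
        rng = np.random.default_rng(1)
        chem["S1"].values[:] = rng.uniform(10, 20, box_mesh.shape)
        def f(v):
            return ScalarField(np.full(box_mesh.shape, float(v)))
        plt = PlateletState(P_mu=f(1e-4), P_ma=f(0.0), P_ba=f(0.0), P_sea=f(0.0),
                           P_max=P_MAX, D_P=25.0)
        flux = FaceFluxField.zero(box_mesh)
        plt2, chem2 = fractional_step(box_mesh, plt, chem, reg, flux, dt=0.01)

        from thrombosim.transport import advance_transport
        s1_ref = advance_transport(
            box_mesh, ScalarField(chem["S1"].values.copy()), flux,
            reg.entry("S1").diffusivity, 0.01)
        assert np.allclose(chem2["S1"].values, s1_ref.values, rtol=1e-13)

    def test_transport_disabled_matches_wellmixed_ode_oracle(self, box_mesh):
        reg, plt, chem = self._setup(box_mesh)
        flux = FaceFluxField.zero(box_mesh)
        dt, T = 0.02, 20.0
        for _ in range(int(T / dt)):
            plt, chem = fractional_step(box_mesh, plt, chem, reg, flux, dt, M_rxn=2)

        # independent oracle: stiff ODE solver on the same network
        names = reg.integrated_names
        reg2, plt2, chem2 = self._setup(box_mesh)
        y0 = []
        for n in names:
            if n in chem2:
                y0.append(float(chem2[n].values.flat[0]))
            else:
                y0.append(float(getattr(plt2, n).values.flat[0]))

        def rhs(t, y):
            s = {n: np.atleast_1d(y[i]) for i, n in enumerate(names)}
            s["ADP"] = np.zeros(1)
            out = reg2.rhs(s)
            return [float(np.atleast_1d(out[n])[0]) for n in names]

        sol = solve_ivp(rhs, [0, T], y0, method="LSODA", rtol=1e-10, atol=1e-12)
        for n in ("E2b", "E2", "S2b", "E1b"):
            ours = float(chem[n].values.flat[0])
            ref = sol.y[names.index(n), -1]
            assert ours == pytest.approx(ref, rel=1e-4, abs=1e-10)

    def test_splitting_error_first_order_on_linear_reaction_diffusion(self):
        # ∂C/∂t = D ∇²C − λ C on a closed box vs a fine-Δt reference
        mesh = build_single_block(
            BlockSpec(0, 20, 0, 20, 10, 10),
            {"left": "w", "right": "w", "bottom": "w", "top": "w"},
        )
        lam, D, T = 0.9, 40.0, 1.0
        params = dict(DEFAULT_COAG_PARAMS, **{
            k: 0.0 for k in ("kon1", "koff1", "kon2", "koff2", "k1cat",
                             "k2cat", "krel", "kinh1")}, kinh2=lam)
        x = mesh.cell_centers[0]
        init = 1.0 + np.cos(np.pi * x / 20.0)

        def run(dt):
            reg = register_reduced_model(params, D_chem=D)
            # make E2b diffusive for this test by treating it via E2? — use
            # fluid-phase S1 decaying at λ through a custom reaction instead
            from thrombosim.coagulation import Reaction
            reg.add_reaction(Reaction("decay_S1", lambda s: lam * s["S1"], {"S1": -1}))
            chem = {e.name: ScalarField(np.zeros(mesh.shape), name=e.name)
                    for e in reg.entries if e.category in ("fluidPhase", "pltBound")}
            chem["S1"].values[:] = init
            def f(v):
                return ScalarField(np.full(mesh.shape, float(v)))
            plt = PlateletState(P_mu=f(0.0), P_ma=f(0.0), P_ba=f(0.0), P_sea=f(0.0),
                               P_max=P_MAX, D_P=25.0)
            flux = FaceFluxField.zero(mesh)
            for _ in range(int(round(T / dt))):
                plt, chem = fractional_step(mesh, plt, chem, reg, flux, dt, M_rxn=2)
            return chem["S1"].values.copy()

        ref = run(T / 512)
        errs = [np.max(np.abs(run(dt) - ref)) for dt in (T / 8, T / 16, T / 32)]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert 0.7 < np.mean(orders) < 1.6  # first order in Δt


class TestBurstDiagnostics:
    def run_wellmixed(self, k2cat, E1=0.05, T=120.0):
        reg = full_registry(dict(DEFAULT_COAG_PARAMS, k2cat=k2cat))
        ws = ReactionWorkspace(seeded_state(reg, E1=E1))
        h, nsave = 0.01, 480
        sps = int(T / nsave / h)
        tt, tr = [0.0], [0.0]
        for i in range(nsave):
            rk4_react(ws, reg, h, n_steps=sps, frozen={"ADP": np.zeros(1)})
            tt.append((i + 1) * T / nsave)
            tr.append(float(ws.fields["E2"][0] + ws.fields["E2b"][0]))
        return np.array(tt), np.array(tr)

    def test_feedback_off_is_graded_on_is_sigmoidal(self):
        d_off = thrombin_burst_diagnostics(*self.run_wellmixed(0.0))
        d_on = thrombin_burst_diagnostics(*self.run_wellmixed(
            DEFAULT_COAG_PARAMS["k2cat"]))
        assert not d_off.sigmoidal
        assert d_on.sigmoidal
        assert d_on.plateau > d_off.plateau

    def test_lag_strictly_decreases_with_feedback_rate(self):
        lags = [thrombin_burst_diagnostics(*self.run_wellmixed(k)).lag_time
                for k in (0.01, 0.05, 0.25)]
        assert lags[0] > lags[1] > lags[2]

    def test_no_initiation_no_thrombin(self):
        reg = full_registry()  # no SE surface, no E1 bolus
        st = seeded_state(reg, E1=0.0)
        out = rk4_react(st, reg, h=0.05, n_steps=1000, frozen={"ADP": np.zeros(1)})
        assert out["E2"][0] == 0.0 and out["E2b"][0] == 0.0
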