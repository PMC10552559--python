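"""Finite-volume transport operators: interpolation, conservation, orders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrombosim.mesh import BlockSpec, build_single_block
from thrombosim.transport import (
    BoundaryConditionSpec,
    FaceFluxField,
    ScalarField,
    TransportError,
    advance_transport,
    apply_reactive_robin,
    diffusion_operator_apply,
    divergence,
    interpolate_to_faces,
)


def two_cell_mesh():
    return build_single_block(
        BlockSpec(0, 2, 0, 1, 2, 1),
        {"left": "walls", "right": "walls", "bottom": "walls", "top": "walls"},
    )


def uniform_flux(mesh, ux, uy=0.0):
    return FaceFluxField(
        fx=np.full((mesh.ny, mesh.nx + 1), ux * mesh.dy[0]),
        fy=np.full((mesh.ny + 1, mesh.nx), uy * mesh.dx[0]),
    )


class TestInterpolation:
    @pytest.mark.parametrize("scheme", ["linear", "upwind", "downwind", "localMax"])
    def test_constant_field_preserved_on_all_schemes(self, box_mesh, scheme):
        c = np.full(box_mesh.shape, 0.7)
        flux = uniform_flux(box_mesh, 3.0, -2.0)
        fx, fy = interpolate_to_faces(c, box_mesh, scheme, flux)
        assert np.allclose(fx, 0.7) and np.allclose(fy, 0.7)

    @pytest.mark.parametrize(
        "left,right,scheme,expected",
        [
            (0.2, 0.8, "downwind", 0.8),
            (0.2, 0.8, "upwind", 0.2),
            (0.2, 0.8, "localMax", 0.8),
            (0.2, 0.8, "linear", 0.5),
            # larger value upstream: downwind and localMax differ
            (0.8, 0.2, "downwind", 0.2),
            (0.8, 0.2, "upwind", 0.8),
            (0.8, 0.2, "localMax", 0.8),
        ],
    )
    def test_two_cell_definitions_positive_flux(self, left, right, scheme, expected):
        mesh = two_cell_mesh()
        c = np.array([[left, right]])
        flux = uniform_flux(mesh, 1.0)
        fx, _ = interpolate_to_faces(c, mesh, scheme, flux)
        assert fx[0, 1] == pytest.approx(expected)

    def test_zero_flux_ties_fall_back_to_linear(self):
        mesh = two_cell_mesh()
        c = np.array([[0.2, 0.8]])
        flux = FaceFluxField.zero(mesh)
        for scheme in ("upwind", "downwind"):
            fx, _ = interpolate_to_faces(c, mesh, scheme, flux)
            assert fx[0, 1] == pytest.approx(0.5)

    def test_upwind_requires_flux(self, box_mesh):
        with pytest.raises(TransportError):
            interpolate_to_faces(np.zeros(box_mesh.shape), box_mesh, "upwind")

    def test_unknown_scheme_rejected(self, box_mesh):
        with pytest.raises(TransportError):
            interpolate_to_faces(np.zeros(box_mesh.shape), box_mesh, "QUICK")

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=48, max_size=48))
    def test_localmax_dominates_linear(self, vals):
        mesh = build_single_block(
            BlockSpec(0, 8, 0, 6, 8, 6),
            {"left": "w", "right": "w", "bottom": "w", "top": "w"},
        )
        c = np.array(vals).reshape(6, 8)
        fx_m, fy_m = interpolate_to_faces(c, mesh, "localMax")
        fx_l, fy_l = interpolate_to_faces(c, mesh, "linear")
        assert np.all(fx_m >= fx_l - 1e-15)
        assert np.all(fy_m >= fy_l - 1e-15)


class TestDivergence:
    def test_uniform_flux_has_zero_interior_divergence(self, box_mesh):
        d = divergence(box_mesh, uniform_flux(box_mesh, 2.0, 1.0))
        assert np.allclose(d, 0.0)

    def test_global_budget_identity_random_flux(self, box_mesh, rng):
        flux = FaceFluxField(
            fx=rng.normal(size=(box_mesh.ny, box_mesh.nx + 1)),
            fy=rng.normal(size=(box_mesh.ny + 1, box_mesh.nx)),
        )
        total = np.sum(divergence(box_mesh, flux) * box_mesh.cell_volumes)
        boundary = (
            flux.fx[:, -1].sum() - flux.fx[:, 0].sum()
            + flux.fy[-1, :].sum() - flux.fy[0, :].sum()
        )
        assert total == pytest.approx(boundary, rel=1e-12)

    def test_point_source_integrates_to_strength(self, box_mesh):
        flux = FaceFluxField.zero(box_mesh)
        # one interior face carries flux: equal and opposite sources appear
        # in the two cells sharing it, and their divergences telescope
        flux.fx[3, 4] = -2.5
        d = divergence(box_mesh, flux)
        assert np.sum(d * box_mesh.cell_volumes) == pytest.approx(0.0, abs=1e-14)
        assert d[3, 4] * box_mesh.cell_volumes[3, 4] == pytest.approx(2.5)
        assert d[3, 3] * box_mesh.cell_volumes[3, 3] == pytest.approx(-2.5)


class TestAdvanceTransport:
    def test_no_flux_no_diffusion_is_identity(self, box_mesh):
        f = ScalarField(np.linspace(0, 1, box_mesh.n_cells).reshape(box_mesh.shape))
        out = advance_transport(box_mesh, f, FaceFluxField.zero(box_mesh), 0.0, 1e-3)
        assert np.array_equal(out.values, f.values)

    def test_pure_diffusion_conserves_mass_and_spreads(self, box_mesh):
        vals = np.zeros(box_mesh.shape)
        vals[2, 3] = 5.0
        f = ScalarField(vals)
        V = box_mesh.cell_volumes
        total0 = np.sum(vals * V)
        var_prev = np.var(vals)
        for _ in range(20):
            f = advance_transport(box_mesh, f, FaceFluxField.zero(box_mesh), 10.0, 0.01)
            assert np.sum(f.values * V) == pytest.approx(total0, rel=1e-12)
            var = np.var(f.values)
            assert var <= var_prev + 1e-15
            var_prev = var

    def test_tophat_advection_matches_1d_reference(self):
        # long thin channel; compare against an independent 1D upwind update
        n = 64
        mesh = build_single_block(
            BlockSpec(0, 64, 0, 1, n, 1),
            {"left": "inlet", "right": "outlet", "bottom": "w", "top": "w"},
        )
        u, dt, dx = 1.0, 0.5, 1.0
        c0 = np.zeros(n)
        c0[10:20] = 1.0
        f = ScalarField(c0.reshape(1, n).copy(),
                        bcs={"inlet": BoundaryConditionSpec("inflow_value", value=0.0)})
        flux = uniform_flux(mesh, u)
        ref = c0.copy()
        nsteps = 30
        for _ in range(nsteps):
            f = advance_transport(mesh, f, flux, 0.0, dt, scheme="upwind")
            ref[1:] = ref[1:] - u * dt / dx * (ref[1:] - ref[:-1])
            ref[0] = ref[0] - u * dt / dx * ref[0]
        assert np.allclose(f.values[0], ref, atol=1e-12)
        x = mesh.cell_centers[0][0]
        centroid = np.sum(x * f.values[0]) / np.sum(f.values[0])
        assert centroid == pytest.approx(14.5 + u * nsteps * dt, abs=1.0)

    def test_dirichlet_inlet_feeds_mass_at_known_rate(self, channel_mesh):
        cin = 2.0
        f = ScalarField(np.zeros(channel_mesh.shape),
                        bcs={"inlet": BoundaryConditionSpec("inflow_value", value=cin)})
        u = 1.0
        flux = uniform_flux(channel_mesh, u)
        V = channel_mesh.cell_volumes
        dt = 0.5
        out = advance_transport(channel_mesh, f, flux, 0.0, dt, scheme="upwind")
        influx = cin * u * 40.0  # inlet area = height × unit depth
        assert np.sum(out.values * V) == pytest.approx(influx * dt, rel=1e-12)

    def test_cfl_violation_raises_in_strict_mode(self, channel_mesh):
        f = ScalarField(np.ones(channel_mesh.shape))
        flux = uniform_flux(channel_mesh, 100.0)
        with pytest.raises(TransportError, match="Courant"):
            advance_transport(channel_mesh, f, flux, 0.0, 1.0, cfl_strict=True)

    def test_nonpositive_dt_rejected(self, box_mesh):
        f = ScalarField(np.ones(box_mesh.shape))
        with pytest.raises(TransportError):
            advance_transport(box_mesh, f, FaceFluxField.zero(box_mesh), 0.0, 0.0)


class TestReactiveRobin:
    def test_zero_rate_equals_zero_gradient_wall(self, injury_box):
        f = ScalarField(np.random.default_rng(0).uniform(1, 2, injury_box.shape))
        src = apply_reactive_robin(injury_box, f, "injuryWalls", lambda c: 0.0 * c)
        assert np.all(src == 0.0)

    def test_linear_uptake_closed_box_budget(self, injury_box):
        # dC/dt = −k C A_patch / V_total at equilibrium-mixed state;
        # with D large the box stays well mixed and the budget is exact
        k = 0.05  # uptake velocity, μm/s
        f = ScalarField(np.full(injury_box.shape, 4.0))
        V = injury_box.cell_volumes
        A_patch = injury_box.patch_span("injuryWalls")
        dt, T = 0.01, 2.0
        removed = 0.0
        for _ in range(int(T / dt)):
            src = apply_reactive_robin(
                injury_box, f, "injuryWalls", lambda c: -k * c
            )
            removed += -np.sum(src * V) * dt
            f = advance_transport(
                injury_box, f, FaceFluxField.zero(injury_box), 500.0, dt,
                extra_source=src,
            )
        c_mean = np.sum(f.values * V) / V.sum()
        # analytic well-mixed decay
        expected = 4.0 * np.exp(-k * A_patch / V.sum() * T)
        assert c_mean == pytest.approx(expected, rel=2e-3)
        assert removed == pytest.approx(4.0 * V.sum() - np.sum(f.values * V), rel=1e-10)

    def test_uptake_additive_over_patch_length(self):
        def make(width_cells):
            return build_single_block(
                BlockSpec(0, 2.5 * width_cells, 0, 5, width_cells, 2),
                {"left": "walls", "right": "walls", "bottom": "injuryWalls", "top": "walls"},
            )

        k = 0.1
        uptakes = []
        for w in (4, 8):
            mesh = make(w)
            f = ScalarField(np.full(mesh.shape, 1.0))
            src = apply_reactive_robin(mesh, f, "injuryWalls", lambda c: -k * c)
            uptakes.append(-np.sum(src * mesh.cell_volumes))
        assert uptakes[1] == pytest.approx(2 * uptakes[0], rel=1e-12)

    def test_restricted_to_injury_patch(self, channel_mesh):
        f = ScalarField(np.ones(channel_mesh.shape))
        with pytest.raises(TransportError):
            apply_reactive_robin(channel_mesh, f, "walls", lambda c: -c)


class TestSchemeOrders:
    def test_diffusion_operator_second_order_on_sine(self):
        errs = []
        for n in (16, 32, 64):
            mesh = build_single_block(
                BlockSpec(0, 2 * np.pi, 0, 1, n, 1),
                {"left": "w", "right": "w", "bottom": "w", "top": "w"},
            )
            x = mesh.cell_centers[0][0]
            c = np.sin(x).reshape(1, n)
            lap = diffusion_operator_apply(mesh, c, 1.0)[0]
            # compare away from the (zero-flux) boundaries
            interior = slice(2, n - 2)
            errs.append(np.max(np.abs(lap[interior] + np.sin(x)[interior])))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) > 1.9

    def test_upwind_advection_first_order_linear_interp_second(self):
        # steady-state truncation error of the face interpolation itself
        for scheme, expected in (("upwind", 1.0), ("linear", 2.0)):
            errs = []
            for n in (32, 64, 128):
                mesh = build_single_block(
                    BlockSpec(0, 2 * np.pi, 0, 1, n, 1),
                    {"left": "w", "right": "w", "bottom": "w", "top": "w"},
                )
                x = mesh.cell_centers[0][0]
                xf = mesh.x_faces[1:-1]
                c = np.sin(x).reshape(1, n)
                flux = uniform_flux(mesh, 1.0)
                fx, _ = interpolate_to_faces(c, mesh, scheme, flux)
                errs.append(np.max(np.abs(fx[0, 1:-1] - np.sin(xf))))
            order = np.log2(errs[0] / errs[1])
            assert order == pytest.approx(expected, abs=0.35)
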