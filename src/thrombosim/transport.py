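"""Cell-centered finite-volume operators for advection–diffusion transport.

Implements the generic scalar transport step

    ∂C/∂t = −∇·( W v C − W D ∇C )

on a structured rectangular mesh, where ``W`` is an optional per-face
hindrance multiplier in [0, 1] (used by the platelet equations to shut off
transport into fully packed regions; 1 for plain chemical species).

Face interpolation schemes:

``linear``
    distance-weighted average of the two adjacent cells (2nd order).
``upwind``
    value of the cell the flux comes from (bounded, 1st order).
``downwind``
    value of the cell the flux goes to.  Used for the advective hindrance of
    platelets: the flux into a location is throttled by how full the
    *receiving* cell already is.
``localMax``
    maximum of the two adjacent cells.  Used for the diffusive hindrance of
    platelets: diffusion across a face next to a packed cell is limited by
    the packed side.

Time integration: explicit (scheme-selectable) advection plus backward-Euler
diffusion, which is unconditionally stable and strictly conservative on
zero-flux boundaries.  Advection is subject to a CFL check (warn by default,
raise in strict mode).  Negative undershoots from advection are clipped to
zero at the end of the step and the clipped mass is reported so callers can
monitor it.

Units: lengths μm, time s, fluxes μm³/s (unit depth), concentrations carried
as metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import StructuredMesh

__all__ = [
    "ScalarField",
    "FaceFluxField",
    "BoundaryConditionSpec",
    "TransportError",
    "interpolate_to_faces",
    "divergence",
    "advance_transport",
    "apply_reactive_robin",
    "ImplicitDiffusion",
    "patch_adjacent_cells",
    "diffusion_operator_apply",
]

logger = logging.getLogger(__name__)

SCHEMES = ("linear", "upwind", "downwind", "localMax")


class TransportError(ValueError):
    pass


@dataclass
class BoundaryConditionSpec:
    """Per-patch boundary behaviour of a scalar field.

    kind:
      * ``fixed_value`` / ``inflow_value`` — Dirichlet value at the patch.
      * ``zero_gradient`` — homogeneous Neumann (default wall/outflow).
      * ``reactive_robin`` — flux set by a surface reaction rate; only
        admitted on the ``injuryWalls`` patch.
    """

    kind: str = "zero_gradient"
    value: float = 0.0
    rate_fn: Callable[..., np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_value", "inflow_value", "zero_gradient", "reactive_robin"):
            raise TransportError(f"unknown boundary condition kind {self.kind!r}")


@dataclass
class ScalarField:
    """Named per-cell scalar with units metadata and per-patch BCs."""

    values: np.ndarray  # (ny, nx)
    name: str = ""
    units: str = ""
    bcs: dict[str, BoundaryConditionSpec] = field(default_factory=dict)

    def bc_for(self, patch_name: str) -> BoundaryConditionSpec:
        return self.bcs.get(patch_name, BoundaryConditionSpec())

    def copy_with(self, values: np.ndarray) -> "ScalarField":
        return replace(self, values=values)


@dataclass
class FaceFluxField:
    """Signed volumetric fluxes through faces (μm³/s, unit depth).

    ``fx`` has shape (ny, nx+1) — flux through vertical faces, positive in +x.
    ``fy`` has shape (ny+1, nx) — flux through horizontal faces, positive in +y.
    """

    fx: np.ndarray
    fy: np.ndarray

    @classmethod
    def zero(cls, mesh: StructuredMesh) -> "FaceFluxField":
        return cls(
            fx=np.zeros((mesh.ny, mesh.nx + 1)),
            fy=np.zeros((mesh.ny + 1, mesh.nx)),
        )


# ---------------------------------------------------------------------------
# face interpolation
# ---------------------------------------------------------------------------

def _face_values_1d(cl, cr, dl, dr, scheme, flux):
    """Interpolate adjacent-cell values (cl upstream-of-axis, cr) to faces."""
    lin = (cl * dr + cr * dl) / (dl + dr)
    if scheme == "linear":
        return lin
    if scheme == "localMax":
        return np.maximum(cl, cr)
    up = np.where(flux > 0, cl, cr)
    down = np.where(flux > 0, cr, cl)
    pick = up if scheme == "upwind" else down
    return np.where(flux == 0.0, lin, pick)  # exactly-zero flux: tie-break to linear


def interpolate_to_faces(
    field: ScalarField | np.ndarray,
    mesh: StructuredMesh,
    scheme: str,
    flux: FaceFluxField | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a cell field to faces; boundary faces take the adjacent
    cell value (one-sided).

    Returns (x-face values (ny, nx+1), y-face values (ny+1, nx)).
    """
    if scheme not in SCHEMES:
        raise TransportError(f"unknown interpolation scheme {scheme!r}")
    if scheme in ("upwind", "downwind") and flux is None:
        raise TransportError(f"scheme {scheme!r} requires a face flux field")
    c = field.values if isinstance(field, ScalarField) else np.asarray(field)
    dx, dy = mesh.dx, mesh.dy

    fxv = np.empty((mesh.ny, mesh.nx + 1))
    fyv = np.empty((mesh.ny + 1, mesh.nx))
    fxv[:, 0], fxv[:, -1] = c[:, 0], c[:, -1]
    fyv[0, :], fyv[-1, :] = c[0, :], c[-1, :]

    dl = 0.5 * dx[:-1]
    dr = 0.5 * dx[1:]
    fflux = flux.fx[:, 1:-1] if flux is not None else 0.0
    fxv[:, 1:-1] = _face_values_1d(c[:, :-1], c[:, 1:], dl[None, :], dr[None, :], scheme, fflux)

    dl = 0.5 * dy[:-1]
    dr = 0.5 * dy[1:]
    fflux = flux.fy[1:-1, :] if flux is not None else 0.0
    fyv[1:-1, :] = _face_values_1d(c[:-1, :], c[1:, :], dl[:, None], dr[:, None], scheme, fflux)
    return fxv, fyv


def divergence(mesh: StructuredMesh, flux: FaceFluxField) -> np.ndarray:
    """Per-cell net outflow divided by cell volume (1/s)."""
    V = mesh.cell_volumes
    return (
        flux.fx[:, 1:] - flux.fx[:, :-1] + flux.fy[1:, :] - flux.fy[:-1, :]
    ) / V


# ---------------------------------------------------------------------------
# boundary helpers
# ---------------------------------------------------------------------------

def patch_adjacent_cells(
    mesh: StructuredMesh, patch_name: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(j, i) indices of cells adjacent to each patch face, and face areas."""
    jj, ii, areas = [], [], []
    dx, dy = mesh.dx, mesh.dy
    for side, k in mesh.patch(patch_name).faces:
        if side == "left":
            jj.append(k); ii.append(0); areas.append(dy[k])
        elif side == "right":
            jj.append(k); ii.append(mesh.nx - 1); areas.append(dy[k])
        elif side == "bottom":
            jj.append(0); ii.append(k); areas.append(dx[k])
        else:
            jj.append(mesh.ny - 1); ii.append(k); areas.append(dx[k])
    return np.array(jj, dtype=int), np.array(ii, dtype=int), np.array(areas)


def apply_reactive_robin(
    mesh: StructuredMesh,
    field: ScalarField,
    patch_name: str,
    surface_rate: Callable[..., np.ndarray],
    **wall_state: np.ndarray,
) -> np.ndarray:
    """Per-cell source (units of C per second) from a reactive wall flux.

    ``surface_rate`` receives the wall-adjacent field values (one per patch
    face) plus any wall-bound species arrays passed as keyword arguments, and
    returns the boundary flux per unit face area (units of C × μm/s).
    Negative rate = consumption of the fluid-phase species at the wall.
    Only admitted on the ``injuryWalls`` patch, where surface chemistry lives.
    """
    if patch_name != "injuryWalls":
        raise TransportError(
            f"reactive boundary conditions are restricted to injuryWalls, got {patch_name!r}"
        )
    jj, ii, areas = patch_adjacent_cells(mesh, patch_name)
    c_wall = field.values[jj, ii]
    q = np.asarray(surface_rate(c_wall, **wall_state), dtype=float)
    if q.shape != c_wall.shape:
        raise TransportError("surface_rate must return one flux per patch face")
    src = np.zeros(mesh.shape)
    np.add.at(src, (jj, ii), q * areas / mesh.cell_volumes[jj, ii])
    return src


# ---------------------------------------------------------------------------
# implicit diffusion operator (cached factorization)
# ---------------------------------------------------------------------------

class ImplicitDiffusion:
    """Backward-Euler diffusion solve with per-face hindrance.

    Builds and LU-factorizes (I + dt·L) where L discretizes −∇·(W D ∇·).
    The factorization is reused across steps and rebuilt only when the
    hindrance multipliers drift beyond ``rebuild_tol`` (0 = rebuild on any
    change), which keeps long runs cheap while bounding the coefficient lag.
    """

    def __init__(
        self,
        mesh: StructuredMesh,
        D: float,
        dt: float,
        bcs: dict[str, BoundaryConditionSpec],
        patch_of_face: dict[tuple[str, int], str],
        rebuild_tol: float = 0.0,
    ) -> None:
        self.mesh = mesh
        self.D = D
        self.dt = dt
        self.bcs = bcs
        self.patch_of_face = patch_of_face
        self.rebuild_tol = rebuild_tol
        self._Wx: np.ndarray | None = None
        self._Wy: np.ndarray | None = None
        self._lu = None
        self._rhs_bc: np.ndarray | None = None

    def _needs_rebuild(self, Wx: np.ndarray, Wy: np.ndarray) -> bool:
        if self._lu is None:
            return True
        dev = max(
            float(np.max(np.abs(Wx - self._Wx))),
            float(np.max(np.abs(Wy - self._Wy))),
        )
        return dev > self.rebuild_tol

    def _build(self, Wx: np.ndarray, Wy: np.ndarray) -> None:
        mesh, D, dt = self.mesh, self.D, self.dt
        ny, nx = mesh.shape
        dx, dy = mesh.dx, mesh.dy
        V = mesh.cell_volumes
        N = nx * ny
        idx = np.arange(N).reshape(ny, nx)

        rows, cols, vals = [], [], []
        diag = np.zeros((ny, nx))

        # interior x-faces
        gx = Wx[:, 1:-1] * D * dy[:, None] / (0.5 * (dx[:-1] + dx[1:]))[None, :]
        l, r = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        g = gx.ravel()
        rows += [l, r]; cols += [r, l]; vals += [-g, -g]
        diag[:, : nx - 1] += gx
        diag[:, 1:] += gx

        # interior y-faces
        gy = Wy[1:-1, :] * D * dx[None, :] / (0.5 * (dy[:-1] + dy[1:]))[:, None]
        b, t = idx[:-1, :].ravel(), idx[1:, :].ravel()
        g = gy.ravel()
        rows += [b, t]; cols += [t, b]; vals += [-g, -g]
        diag[:-1, :] += gy
        diag[1:, :] += gy

        # boundary faces: Dirichlet patches add a half-cell conductance
        rhs_bc = np.zeros((ny, nx))
        bc_faces: list[tuple[int, int, float, float]] = []
        for (side, k), pname in self.patch_of_face.items():
            bc = self.bcs.get(pname, BoundaryConditionSpec())
            if bc.kind not in ("fixed_value", "inflow_value"):
                continue  # zero_gradient & reactive_robin: no matrix entry
            if side == "left":
                j, i, A, d, wf = k, 0, dy[k], 0.5 * dx[0], Wx[k, 0]
            elif side == "right":
                j, i, A, d, wf = k, nx - 1, dy[k], 0.5 * dx[-1], Wx[k, -1]
            elif side == "bottom":
                j, i, A, d, wf = 0, k, dx[k], 0.5 * dy[0], Wy[0, k]
            else:
                j, i, A, d, wf = ny - 1, k, dx[k], 0.5 * dy[-1], Wy[-1, k]
            gbc = wf * D * A / d
            diag[j, i] += gbc
            rhs_bc[j, i] += gbc * bc.value / V[j, i]
            bc_faces.append((j, i, gbc, bc.value))

        rows.append(idx.ravel()); cols.append(idx.ravel())
        vals.append(diag.ravel())

        # assemble L scaled by 1/V, then I + dt L
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        L = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
        Vflat = V.ravel()
        L = sp.diags(1.0 / Vflat) @ L
        A_sys = (sp.identity(N) + dt * L).tocsc()
        self._lu = spla.splu(A_sys)
        self._rhs_bc = rhs_bc
        self._bc_faces = bc_faces
        self._Wx = Wx.copy()
        self._Wy = Wy.copy()

    #: amount/s entering through Dirichlet boundaries in the latest solve
    last_boundary_influx: float = 0.0

    def solve(self, c_star: np.ndarray, Wx: np.ndarray, Wy: np.ndarray) -> np.ndarray:
        if self.D == 0.0:
            self.last_boundary_influx = 0.0
            return c_star
        if self._needs_rebuild(Wx, Wy):
            self._build(Wx, Wy)
        rhs = c_star + self.dt * self._rhs_bc
        out = self._lu.solve(rhs.ravel()).reshape(self.mesh.shape)
        self.last_boundary_influx = float(
            sum(g * (val - out[j, i]) for j, i, g, val in self._bc_faces)
        )
        return out


def _face_patch_map(mesh: StructuredMesh) -> dict[tuple[str, int], str]:
    m: dict[tuple[str, int], str] = {}
    for p in mesh.patches:
        for f in p.faces:
            m[f] = p.name
    return m


def diffusion_operator_apply(
    mesh: StructuredMesh, c: np.ndarray, D: float
) -> np.ndarray:
    """Apply the discrete ∇·(D ∇c) with zero-gradient boundaries (for
    truncation-error studies)."""
    ones_x = np.ones((mesh.ny, mesh.nx + 1))
    ones_y = np.ones((mesh.ny + 1, mesh.nx))
    dx, dy = mesh.dx, mesh.dy
    Fx = np.zeros_like(ones_x)
    Fx[:, 1:-1] = D * dy[:, None] * (c[:, 1:] - c[:, :-1]) / (0.5 * (dx[:-1] + dx[1:]))[None, :]
    Fy = np.zeros_like(ones_y)
    Fy[1:-1, :] = D * dx[None, :] * (c[1:, :] - c[:-1, :]) / (0.5 * (dy[:-1] + dy[1:]))[:, None]
    return divergence(mesh, FaceFluxField(fx=Fx, fy=Fy))


# ---------------------------------------------------------------------------
# full transport step
# ---------------------------------------------------------------------------

def _advective_face_values(
    mesh: StructuredMesh,
    field: ScalarField,
    flux: FaceFluxField,
    scheme: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Face values of C for the advective flux, honouring boundary kinds."""
    fxv, fyv = interpolate_to_faces(field, mesh, scheme, flux)
    # Dirichlet-type patches impose the boundary value on their faces;
    # zero_gradient / reactive walls keep the one-sided interior value.
    dxf = {"left": 0, "right": -1}
    dyf = {"bottom": 0, "top": -1}
    for p in mesh.patches:
        bc = field.bc_for(p.name)
        if bc.kind not in ("fixed_value", "inflow_value"):
            continue
        for side, k in p.faces:
            if side in dxf:
                fxv[k, dxf[side]] = bc.value
            else:
                fyv[dyf[side], k] = bc.value
    return fxv, fyv


def advance_transport(
    mesh: StructuredMesh,
    field: ScalarField,
    flux: FaceFluxField,
    D: float,
    dt: float,
    hindrance_faces: tuple[np.ndarray, np.ndarray] | None = None,
    hindrance_faces_diff: tuple[np.ndarray, np.ndarray] | None = None,
    scheme: str = "upwind",
    diffusion_op: ImplicitDiffusion | None = None,
    extra_source: np.ndarray | None = None,
    cfl_strict: bool = False,
    clip_negative: bool = True,
    diag: dict | None = None,
) -> ScalarField:
    """One conservative transport step of ∂C/∂t = −∇·(W v C − W D ∇C).

    ``hindrance_faces`` multiplies the advective face flux,
    ``hindrance_faces_diff`` (defaulting to the advective one) the diffusive
    conductances; both are (x-faces, y-faces) arrays in [0, 1], 1 when
    absent.  ``extra_source`` is a per-cell rate added explicitly (used for
    reactive wall fluxes and release sources).
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    ny, nx = mesh.shape
    V = mesh.cell_volumes
    ones_x = np.ones((ny, nx + 1))
    ones_y = np.ones((ny + 1, nx))
    # hindrance multipliers are expected in [0, 1] (hindrance_W clips)
    Wax, Way = hindrance_faces if hindrance_faces is not None else (ones_x, ones_y)
    Wdx, Wdy = (
        hindrance_faces_diff
        if hindrance_faces_diff is not None
        else ((Wax, Way) if hindrance_faces is not None else (ones_x, ones_y))
    )

    # CFL (advective)
    with np.errstate(divide="ignore", invalid="ignore"):
        out_x = np.maximum(flux.fx[:, 1:], 0) - np.minimum(flux.fx[:, :-1], 0)
        out_y = np.maximum(flux.fy[1:, :], 0) - np.minimum(flux.fy[:-1, :], 0)
    co = float(np.max((out_x + out_y) * dt / V)) if V.size else 0.0
    if co > 0.9:
        msg = f"advective Courant number {co:.3f} exceeds 0.9"
        if cfl_strict:
            raise TransportError(msg)
        logger.warning(msg)

    # explicit advection
    fxv, fyv = _advective_face_values(mesh, field, flux, scheme)
    Fx = flux.fx * Wax * fxv
    Fy = flux.fy * Way * fyv
    c_star = field.values - dt * divergence(mesh, FaceFluxField(fx=Fx, fy=Fy))
    adv_influx = -float(
        Fx[:, -1].sum() - Fx[:, 0].sum() + Fy[-1, :].sum() - Fy[0, :].sum()
    )

    if extra_source is not None:
        c_star = c_star + dt * extra_source

    # implicit diffusion
    if D > 0:
        if diffusion_op is None:
            diffusion_op = ImplicitDiffusion(
                mesh, D, dt, field.bcs, _face_patch_map(mesh)
            )
        c_new = diffusion_op.solve(c_star, Wdx, Wdy)
    else:
        c_new = c_star

    clipped = 0.0
    if clip_negative:
        neg = np.minimum(c_new, 0.0)
        clipped = float(-np.sum(neg * V))
        if clipped > 0:
            c_new = np.maximum(c_new, 0.0)
    if diag is not None:
        diag["courant"] = co
        diag["clipped_mass"] = clipped
        diff_influx = diffusion_op.last_boundary_influx if (D > 0 and diffusion_op) else 0.0
        diag["boundary_influx"] = adv_influx + diff_influx
    return field.copy_with(c_new)
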