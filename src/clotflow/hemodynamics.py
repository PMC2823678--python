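"""Steady pressure-driven channel flow around the growing clot.

The plasma is driven through a 2D rectangular channel by a fixed pressure
drop ("constant pressure" drive): as the fibrin gel obstructs the channel
the flux drops rather than the pressure rising.  At these scales
(h ~ 1 mm, U ~ mm/s, plasma) the Reynolds number is ≪ 1, so the steady
Stokes (creeping-flow) limit is solved on a marker-and-cell staggered grid;
gelled cells are excluded from the flow by volume penalization (a large
Darcy drag that drives their velocity to zero).

Viscosity is set to 1 in internal units: parameterizing the drive by the
clean-channel wall shear rate γ_w makes the viscosity cancel exactly for
the unobstructed channel, and only redistributes the (small) clotted-channel
correction.

Unit conventions: lengths μm, velocities μm/s, shear rates s⁻¹; pressure in
the consistent internal unit (μ·s⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DomainSpec",
    "FlowState",
    "shear_to_drive",
    "solve_flow",
    "measure_wall_shear",
    "save_flow_csv",
    "save_flow_vtk",
]

#: gel-cell velocities are penalized down to ~PENALTY_RATIO of the
#: clean-channel mean velocity
PENALTY_RATIO = 1e-6


@dataclass(frozen=True)
class DomainSpec:
    """Channel geometry and activator patch.

    Cell-centered grid, 0-based indices; x ∈ [0, length_x] downstream,
    y ∈ [0, height_y] with the activator on the y = 0 wall.  ``dx`` is the
    (square) grid spacing and must divide every extent.
    """

    length_x: float = 6000.0
    height_y: float = 1000.0
    activator_start: float = 1000.0
    activator_length: float = 1000.0
    dx: float = 25.0

    def __post_init__(self):
        for name in ("length_x", "height_y", "dx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("length_x", "height_y", "activator_start", "activator_length"):
            if abs(getattr(self, name) / self.dx - round(getattr(self, name) / self.dx)) > 1e-9:
                raise ValueError(f"dx must divide {name}")
        if self.activator_start < 0 or self.activator_start + self.activator_length > self.length_x:
            raise ValueError("activator interval must lie within [0, length_x]")

    @property
    def nx(self) -> int:
        return round(self.length_x / self.dx)

    @property
    def ny(self) -> int:
        return round(self.height_y / self.dx)

    @property
    def activator_slice(self) -> slice:
        i0 = round(self.activator_start / self.dx)
        return slice(i0, i0 + round(self.activator_length / self.dx))

    def activator_mask(self) -> np.ndarray:
        """(nx,) boolean mask of wall-adjacent activator columns."""
        m = np.zeros(self.nx, dtype=bool)
        m[self.activator_slice] = True
        return m


@dataclass
class FlowState:
    """Steady velocity/pressure fields on the staggered grid.

    ``u`` lives on vertical faces, shape (ny, nx+1); ``v`` on horizontal
    faces, shape (ny+1, nx), with the wall rows identically zero; ``p`` at
    cell centers.  ``drive`` is the imposed pressure gradient; the pressure
    drop is held constant as the clot grows.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    drive: float
    target_wall_shear: float
    occluded: bool = False

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(initial=0.0), np.abs(self.v).max(initial=0.0)))

    def flux(self, domain: DomainSpec, column: int = 0) -> float:
        """Volumetric flux (per unit depth, μm²/s) through u-face column ``column``."""
        return float(self.u[:, column].sum() * domain.dx)


def shear_to_drive(gamma_w: float, domain: DomainSpec) -> tuple[float, float]:
    """Pressure gradient and clean-channel mean velocity for wall shear γ_w.

    Plane Poiseuille flow in a channel of height h gives
    γ_w = G·h/(2μ) and U_mean = G·h²/(12μ), hence U_mean = γ_w·h/6.  The
    returned ``drive`` (G, with μ = 1) is then held fixed for the whole run.
    """
    if gamma_w < 0:
        raise ValueError("wall shear rate must be ≥ 0")
    h = domain.height_y
    drive = 2.0 * gamma_w / h
    u_mean = gamma_w * h / 6.0
    return drive, u_mean


def _zero_flow(domain: DomainSpec, drive: float, gamma: float) -> FlowState:
    return FlowState(
        u=np.zeros((domain.ny, domain.nx + 1)),
        v=np.zeros((domain.ny + 1, domain.nx)),
        p=np.zeros((domain.ny, domain.nx)),
        drive=drive,
        target_wall_shear=gamma,
        occluded=False,
    )


def solve_flow(
    domain: DomainSpec,
    permeability: np.ndarray | None,
    drive: float,
    target_wall_shear: float | None = None,
) -> FlowState:
    """Steady Stokes flow at fixed pressure drop around impermeable cells.

    ``permeability`` is a (ny, nx) binary field (1 = open, 0 = gel); ``None``
    means a clean channel.  No-slip on both walls; the pressure drop implied
    by ``drive`` is imposed between inlet and outlet ghost cells.  Gelled
    cells are penalized so their speed is ≤ ~1e-3 of the clean-channel mean.
    A fully blocked cross-section returns an all-near-zero-flux state with
    ``occluded`` set.  Deterministic (sparse direct solve).
    """
    if not np.isfinite(drive):
        raise ValueError("drive must be finite")
    nx, ny, dx = domain.nx, domain.ny, domain.dx
    gamma = target_wall_shear if target_wall_shear is not None else drive * domain.height_y / 2.0
    if drive == 0.0:
        return _zero_flow(domain, drive, gamma)

    if permeability is None:
        solid = np.zeros((ny, nx), dtype=bool)
    else:
        perm = np.asarray(permeability)
        if perm.shape != (ny, nx):
            raise ValueError(f"permeability must have shape {(ny, nx)}")
        if not np.isin(perm, (0, 1)).all():
            raise ValueError("permeability must be binary")
        solid = perm == 0

    u_mean_clean = drive * domain.height_y**2 / 12.0
    # Darcy drag sized so penalized speeds are ~PENALTY_RATIO of U_mean
    eta = 12.0 / (PENALTY_RATIO * domain.height_y**2)

    p_in = drive * (nx + 1) * dx  # ghost-to-ghost pressure drop
    p_out = 0.0

    Nu = ny * (nx + 1)
    Nv = (ny - 1) * nx
    Np = ny * nx

    def iu(j, i):
        return j * (nx + 1) + i

    def iv(j, i):  # j = 1..ny-1 interior horizontal faces
        return Nu + (j - 1) * nx + i

    def ip(j, i):
        return Nu + Nv + j * nx + i

    rows, cols, vals = [], [], []
    b = np.zeros(Nu + Nv + Np)
    inv_dx2 = 1.0 / dx**2

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    solid_pad = np.pad(solid, ((0, 0), (1, 1)), mode="edge")  # ghost cells copy edge

    # --- x-momentum on u faces ---------------------------------------
    for j in range(ny):
        for i in range(nx + 1):
            r = iu(j, i)
            diag = -4.0 * inv_dx2
            # x neighbours (zero-gradient ghosts at inlet/outlet)
            if i > 0:
                add(r, iu(j, i - 1), inv_dx2)
            else:
                diag += inv_dx2
            if i < nx:
                add(r, iu(j, i + 1), inv_dx2)
            else:
                diag += inv_dx2
            # y neighbours (no-slip wall ghosts: u_ghost = -u)
            if j > 0:
                add(r, iu(j - 1, i), inv_dx2)
            else:
                diag -= inv_dx2
            if j < ny - 1:
                add(r, iu(j + 1, i), inv_dx2)
            else:
                diag -= inv_dx2
            # penalization if either adjacent cell is solid
            if solid_pad[j, i] or solid_pad[j, i + 1]:
                diag -= eta
            add(r, r, diag)
            # pressure gradient -(p_e - p_w)/dx; ghost pressures to RHS
            if i > 0:
                add(r, ip(j, i - 1), 1.0 / dx)
            else:
                b[r] -= p_in / dx
            if i < nx:
                add(r, ip(j, i), -1.0 / dx)
            else:
                b[r] += p_out / dx

    # --- y-momentum on interior v faces ------------------------------
    for j in range(1, ny):
        for i in range(nx):
            r = iv(j, i)
            diag = -4.0 * inv_dx2
            if i > 0:
                add(r, iv(j, i - 1), inv_dx2)
            else:
                diag -= inv_dx2  # v = 0 at the inlet plane
            if i < nx - 1:
                add(r, iv(j, i + 1), inv_dx2)
            else:
                diag += inv_dx2  # zero-gradient at outlet
            if j > 1:
                add(r, iv(j - 1, i), inv_dx2)
            # wall faces carry v = 0 and are eliminated
            if j < ny - 1:
                add(r, iv(j + 1, i), inv_dx2)
            if solid[j - 1, i] or solid[j, i]:
                diag -= eta
            add(r, r, diag)
            add(r, ip(j - 1, i), 1.0 / dx)
            add(r, ip(j, i), -1.0 / dx)

    # --- continuity at every cell -------------------------------------
    for j in range(ny):
        for i in range(nx):
            r = ip(j, i)
            add(r, iu(j, i), -1.0 / dx)
            add(r, iu(j, i + 1), 1.0 / dx)
            if j > 0:
                add(r, iv(j, i), -1.0 / dx)
            if j < ny - 1:
                add(r, iv(j + 1, i), 1.0 / dx)

    A = sp.csc_matrix(
        (vals, (rows, cols)), shape=(Nu + Nv + Np, Nu + Nv + Np)
    )
    x = spla.spsolve(A, b)

    u = x[:Nu].reshape(ny, nx + 1)
    v = np.zeros((ny + 1, nx))
    v[1:ny, :] = x[Nu : Nu + Nv].reshape(ny - 1, nx)
    p = x[Nu + Nv :].reshape(ny, nx)

    blocked = bool(np.any(solid.all(axis=0)))
    q_clean = u_mean_clean * domain.height_y
    q_now = abs(float(u[:, 0].sum() * dx))
    occluded = blocked or q_now <= 1e-4 * q_clean
    return FlowState(u=u, v=v, p=p, drive=drive, target_wall_shear=gamma, occluded=occluded)


def _cell_centered(flow: FlowState) -> tuple[np.ndarray, np.ndarray]:
    u_c = 0.5 * (flow.u[:, :-1] + flow.u[:, 1:])
    v_c = 0.5 * (flow.v[:-1, :] + flow.v[1:, :])
    return u_c, v_c


def save_flow_csv(flow: FlowState, domain: DomainSpec, path) -> None:
    """Write cell-centered x, y, u, v, p as a CSV grid."""
    import pandas as pd

    u_c, v_c = _cell_centered(flow)
    jj, ii = np.meshgrid(np.arange(domain.ny), np.arange(domain.nx), indexing="ij")
    pd.DataFrame(
        {
            "x_um": (ii.ravel() + 0.5) * domain.dx,
            "y_um": (jj.ravel() + 0.5) * domain.dx,
            "u_um_s": u_c.ravel(),
            "v_um_s": v_c.ravel(),
            "p": flow.p.ravel(),
        }
    ).to_csv(path, index=False)


def save_flow_vtk(flow: FlowState, domain: DomainSpec, path) -> None:
    """Write the cell-centered flow as a legacy-ASCII VTK structured-points
    file (velocity vector field plus pressure)."""
    u_c, v_c = _cell_centered(flow)
    n = domain.nx * domain.ny
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nchannel flow\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {domain.nx} {domain.ny} 1\n")
        fh.write(f"ORIGIN {domain.dx / 2} {domain.dx / 2} 0\n")
        fh.write(f"SPACING {domain.dx} {domain.dx} 1\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS velocity float\n")
        for j in range(domain.ny):
            for i in range(domain.nx):
                fh.write(f"{u_c[j, i]:.6g} {v_c[j, i]:.6g} 0\n")
        fh.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        for j in range(domain.ny):
            for i in range(domain.nx):
                fh.write(f"{flow.p[j, i]:.6g}\n")


def measure_wall_shear(flow: FlowState, domain: DomainSpec) -> float:
    """du/dy at the y = 0 wall, averaged over the clean region upstream of
    the activator (second-order one-sided difference, exact for a parabola)."""
    i_stop = max(domain.activator_slice.start, 1)
    u0 = flow.u[0, 1:i_stop + 1]
    u1 = flow.u[1, 1:i_stop + 1] if domain.ny > 1 else np.zeros_like(u0)
    gamma = (9.0 * u0 - u1) / (3.0 * domain.dx)
    return float(gamma.mean())
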