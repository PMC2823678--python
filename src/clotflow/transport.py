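"""Coupled advection–diffusion–reaction integration with fibrin gelation.

The clotting cascade is integrated on the channel grid by operator
splitting: first-order upwind advection (per-species, honouring the
``convects`` toggles), explicit diffusion (the fibrin gel does not hinder
diffusion), and a vectorised adaptive Runge–Kutta reaction sub-step.
Tissue-factor species are confined to the wall-adjacent activator cells in
a thin-layer representation: a surface loading σ (nmole/mm²) appears as a
volumetric concentration σ/Δx in its boundary cell, so surface and bulk
chemistry share one rate evaluation.

Fibrin above the gel point flips the local permeability to zero, which
triggers a quasi-static re-solve of the Stokes flow (chemistry timescales
are far longer than flow relaxation).  Masks only ever grow: there is no
fibrinolysis in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clotflow import _kernels
from clotflow.hemodynamics import DomainSpec, FlowState, shear_to_drive, solve_flow
from clotflow.scheme import KineticScheme

__all__ = [
    "GelationParams",
    "IntegratorConfig",
    "SimState",
    "SimResult",
    "IntegrationError",
    "save_fields_vtk",
    "initialize_state",
    "advance",
    "apply_boundary_conditions",
    "update_gel",
    "run_simulation",
]

#: nM per (nmole/mm²)/μm — thin-layer surface-to-volume conversion factor
SURFACE_TO_NM = 1.0e9
#: (nmole/mm) per nM·μm² — line-integral conversion for surface densities
CELL_TO_NMOLE_PER_MM = 1.0e-12
#: concentrations below this (nM) are flushed to zero — far below one
#: molecule per cell, and it keeps products of small fields out of the
#: subnormal float range where arithmetic slows by orders of magnitude
CONC_FLOOR = 1.0e-30


class IntegrationError(RuntimeError):
    """Integration blew up (NaN or runaway mass clipping)."""


@dataclass(frozen=True)
class GelationParams:
    """Fibrin thresholds (nM): the gel point switches permeability 1 → 0,
    the solid threshold defines the high-density clot used for the lagtime."""

    gel_threshold: float = 450.0
    solid_threshold: float = 3800.0

    def __post_init__(self):
        if not 0 < self.gel_threshold:
            raise ValueError("gel_threshold must be positive")
        if self.solid_threshold < self.gel_threshold:
            raise ValueError("solid_threshold must be ≥ gel_threshold")


@dataclass(frozen=True)
class IntegratorConfig:
    """Time-stepping policy.

    ``cfl`` limits the advective step; ``dt_max`` caps it (and sets the step
    in stagnant runs); ``reaction_rtol``/``reaction_atol`` control the
    embedded-Runge–Kutta reaction sub-stepping error; ``end_time`` (s) is
    the no-clot cap.  ``closed_box`` switches every boundary to reflective
    and disables in/outflow (verification runs).
    """

    cfl: float = 0.8
    dt_max: float = 1.0
    diffusion_safety: float = 0.4
    reaction_rtol: float = 2e-7
    reaction_atol: float = 1e-10
    end_time: float = 150.0 * 60.0
    snapshot_interval: float = 5.0
    closed_box: bool = False
    coverage_threshold: float = 0.5
    stop_margin: float = 20.0
    run_to_end: bool = False
    mass_error_tol: float = 1e-3
    #: minimum simulated seconds between Stokes re-solves after a gel-mask
    #: change; clot growth is quasi-static on this timescale
    flow_resolve_interval: float = 5.0

    def __post_init__(self):
        if not 0 < self.cfl <= 1:
            raise ValueError("cfl must be in (0, 1]")
        for name in ("dt_max", "diffusion_safety", "reaction_rtol", "snapshot_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimState:
    """Gridded concentrations (nM) plus gelation masks and the clock.

    ``conc`` has shape (n_species, ny, nx); surface-bound species are
    nonzero only in wall-adjacent activator cells.  ``solid_mask`` ⊆
    ``gel_mask``; both are monotone non-decreasing in time.  ``clip_error``
    accumulates mass removed by non-negativity clipping, per species, in
    nM·cells.
    """

    conc: np.ndarray
    time: float
    permeability: np.ndarray
    gel_mask: np.ndarray
    solid_mask: np.ndarray
    clip_error: np.ndarray

    def copy(self) -> "SimState":
        return SimState(
            conc=self.conc.copy(),
            time=self.time,
            permeability=self.permeability.copy(),
            gel_mask=self.gel_mask.copy(),
            solid_mask=self.solid_mask.copy(),
            clip_error=self.clip_error.copy(),
        )


@dataclass
class SimResult:
    """Trajectory record of one run.

    ``record`` columns: time_min, coverage (solid-clot fraction of the
    wall-adjacent activator row), integral_tenase (nmole/mm), tf_active
    (total uninhibited TF, nmole/mm), gel_cells.  ``status`` is ``clotted``,
    ``no_clot`` or ``error``; ``lagtime_min`` is the interpolated first
    crossing of the coverage threshold (NaN when never crossed).
    """

    record: pd.DataFrame
    status: str
    lagtime_min: float
    state: SimState | None = None
    gamma_w: float = 0.0
    error: str | None = None

    def to_csv(self, path) -> None:
        self.record.to_csv(path, index=False)


def save_fields_vtk(state: SimState, scheme: KineticScheme, domain: DomainSpec,
                    path, species=("Fn", "IIa", "Xa")) -> None:
    """Write selected concentration fields (plus the gel mask) as a
    legacy-ASCII VTK structured-points snapshot."""
    n = domain.nx * domain.ny
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"concentration fields t={state.time:.1f}s\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {domain.nx} {domain.ny} 1\n")
        fh.write(f"ORIGIN {domain.dx / 2} {domain.dx / 2} 0\n")
        fh.write(f"SPACING {domain.dx} {domain.dx} 1\n")
        fh.write(f"POINT_DATA {n}\n")
        for name in species:
            field = state.conc[scheme.index(name)]
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for j in range(domain.ny):
                for i in range(domain.nx):
                    fh.write(f"{field[j, i]:.6g}\n")
        fh.write("SCALARS gel float 1\nLOOKUP_TABLE default\n")
        for j in range(domain.ny):
            for i in range(domain.nx):
                fh.write(f"{float(state.gel_mask[j, i]):.0f}\n")


# ---------------------------------------------------------------------------


def _species_flags(scheme: KineticScheme):
    conv = np.array([sp.convects and not sp.surface_bound for sp in scheme.species])
    surf = np.array([sp.surface_bound for sp in scheme.species])
    return conv, surf


def initialize_state(domain: DomainSpec, scheme: KineticScheme) -> SimState:
    """Plasma everywhere, zero fibrin, TF loaded uniformly on the activator."""
    ny, nx = domain.ny, domain.nx
    conc = np.zeros((scheme.n_species, ny, nx))
    plasma = scheme.plasma_vector()
    conc[:] = plasma[:, None, None]
    act = domain.activator_mask()
    for k, sp in enumerate(scheme.species):
        if sp.surface_bound and sp.surface_density > 0:
            conc[k, 0, act] = sp.surface_density * SURFACE_TO_NM / domain.dx
    return SimState(
        conc=conc,
        time=0.0,
        permeability=np.ones((ny, nx)),
        gel_mask=np.zeros((ny, nx), dtype=bool),
        solid_mask=np.zeros((ny, nx), dtype=bool),
        clip_error=np.zeros(scheme.n_species),
    )


def apply_boundary_conditions(
    state: SimState,
    flow: FlowState,
    scheme: KineticScheme,
    domain: DomainSpec,
    config: IntegratorConfig = IntegratorConfig(),
) -> SimState:
    """Enforce the boundary policy on a state.

    The inlet Dirichlet (plasma composition), advective outflow and
    zero-diffusive-flux walls are imposed flux-wise inside :func:`advance`;
    this operation enforces the parts that live on the state itself:
    surface-bound species stay confined to the activator boundary cells and
    concentrations stay non-negative.  In ``closed_box`` mode there is no
    inflow/outflow and the state passes through under the same constraints.
    """
    out = state.copy()
    _, surf = _species_flags(scheme)
    act = domain.activator_mask()
    keep = np.zeros_like(out.conc[0], dtype=bool)
    keep[0, act] = True
    for k in np.flatnonzero(surf):
        out.conc[k][~keep] = 0.0
    np.maximum(out.conc, 0.0, out=out.conc)
    return out


def _advect(conc, stack_idx, flow, domain, plasma, dt, closed_box):
    """Conservative first-order upwind step for the convecting species."""
    dx = domain.dx
    if _kernels.HAVE_NUMBA:
        C = np.ascontiguousarray(conc[stack_idx])
        conc[stack_idx] = _kernels.upwind_advect(
            C, flow.u, flow.v, plasma[stack_idx], dt / dx, closed_box
        )
        return
    C = conc[stack_idx]
    u, v = flow.u, flow.v
    up, um = np.maximum(u, 0.0), np.minimum(u, 0.0)
    inflow = np.zeros((C.shape[0], domain.ny, 1))
    if not closed_box:
        inflow[:] = plasma[stack_idx][:, None, None]
    Cpad = np.concatenate([inflow, C, C[:, :, -1:]], axis=2)
    Fx = up[None, :, :] * Cpad[:, :, :-1] + um[None, :, :] * Cpad[:, :, 1:]
    if closed_box:
        Fx[:, :, 0] = 0.0
        Fx[:, :, -1] = 0.0
    vp, vm = np.maximum(v, 0.0), np.minimum(v, 0.0)
    Cpady = np.concatenate([C[:, :1, :], C, C[:, -1:, :]], axis=1)
    Fy = vp[None, :, :] * Cpady[:, :-1, :] + vm[None, :, :] * Cpady[:, 1:, :]
    C = C - (dt / dx) * (Fx[:, :, 1:] - Fx[:, :, :-1]) - (dt / dx) * (
        Fy[:, 1:, :] - Fy[:, :-1, :]
    )
    conc[stack_idx] = C


def _diffuse(conc, scheme, domain, plasma, dt, closed_box):
    diff = np.array([sp.diffusion_coeff for sp in scheme.species])
    dx2 = domain.dx**2
    if _kernels.HAVE_NUMBA:
        conc[:] = _kernels.diffuse_step(conc, diff, plasma, dt / dx2, closed_box)
        return
    for d in np.unique(diff[diff > 0]):
        idx = np.flatnonzero(diff == d)
        C = conc[idx]
        # ghost layers: walls reflective; outlet zero-gradient; inlet Dirichlet
        Cp = np.pad(C, ((0, 0), (1, 1), (1, 1)), mode="edge")
        if not closed_box:
            Cp[:, 1:-1, 0] = 2.0 * plasma[idx][:, None] - C[:, :, 0]
        lap = (
            Cp[:, 1:-1, 2:]
            + Cp[:, 1:-1, :-2]
            + Cp[:, 2:, 1:-1]
            + Cp[:, :-2, 1:-1]
            - 4.0 * C
        ) / dx2
        conc[idx] = C + dt * d * lap


def _react(conc, scheme, surface_mask, dt, rtol, atol, clip_error):
    """Adaptive embedded Runge–Kutta (Bogacki–Shampine 3(2)) chemistry sub-step.

    The whole grid advances with a shared step size controlled by the worst
    local error estimate; instability during the thrombin burst shows up as
    error and shrinks the step.  Negative excursions are clipped to zero
    and the removed mass logged per species.
    """
    packed = scheme._evaluator().packed
    if _kernels.HAVE_NUMBA and packed is not None:
        clip = np.zeros(conc.shape[0])
        flat = conc.reshape(conc.shape[0], -1)
        _kernels.react_bs23_packed(
            flat, np.asarray(surface_mask, dtype=float).reshape(-1),
            dt, rtol, atol, *packed, clip,
        )
        clip_error += clip
        return
    tau = 0.0
    h = dt
    k1 = scheme.rates(conc, surface_mask)
    while tau < dt - 1e-12:
        h = min(h, dt - tau)
        k2 = scheme.rates(np.maximum(conc + 0.5 * h * k1, 0.0), surface_mask)
        k3 = scheme.rates(np.maximum(conc + 0.75 * h * k2, 0.0), surface_mask)
        cand = conc + h * ((2.0 / 9.0) * k1 + (1.0 / 3.0) * k2 + (4.0 / 9.0) * k3)
        cand_clip = np.maximum(cand, 0.0)
        k4 = scheme.rates(cand_clip, surface_mask)
        err = h * (
            (-5.0 / 72.0) * k1 + (1.0 / 12.0) * k2 + (1.0 / 9.0) * k3 - (1.0 / 8.0) * k4
        )
        scale = atol + rtol * np.maximum(np.abs(conc), np.abs(cand_clip))
        err_norm = float(np.max(np.abs(err) / scale))
        if err_norm <= 1.0 or h <= 1e-9:
            neg = np.minimum(cand, 0.0)
            if neg.any():
                clip_error -= neg.sum(axis=tuple(range(1, conc.ndim)))
            conc[...] = cand_clip
            tau += h
            k1 = k4  # first-same-as-last
        factor = 0.9 * err_norm ** (-1.0 / 3.0) if err_norm > 0 else 5.0
        h *= min(max(factor, 0.2), 5.0)


def advance(
    state: SimState,
    scheme: KineticScheme,
    flow: FlowState,
    dt: float,
    domain: DomainSpec,
    config: IntegratorConfig = IntegratorConfig(),
) -> SimState:
    """One operator-split step: advection → diffusion → reactions.

    ``dt`` must respect the CFL limit of the current flow.  Returns a new
    state advanced by ``dt``; raises :class:`IntegrationError` on NaN with
    a diagnostic naming the offending species and cell.
    """
    max_speed = flow.max_speed()
    if max_speed > 0 and dt > config.cfl * domain.dx / max_speed * (1 + 1e-9):
        raise ValueError("dt violates the advective CFL limit")
    out = state.copy()
    plasma = scheme.plasma_vector()
    conv, _ = _species_flags(scheme)
    if max_speed > 0 and conv.any():
        _advect(out.conc, np.flatnonzero(conv), flow, domain, plasma, dt, config.closed_box)
    _diffuse(out.conc, scheme, domain, plasma, dt, config.closed_box)
    surface_mask = np.zeros((domain.ny, domain.nx))
    surface_mask[0, domain.activator_mask()] = 1.0
    _react(
        out.conc, scheme, surface_mask, dt,
        config.reaction_rtol, config.reaction_atol, out.clip_error,
    )
    out.conc[out.conc < CONC_FLOOR] = 0.0
    if np.isnan(out.conc).any():
        k, j, i = np.argwhere(np.isnan(out.conc))[0]
        raise IntegrationError(
            f"NaN in species {scheme.names[k]} at cell (y={j}, x={i}), t={state.time:.3f}s"
        )
    out.time = state.time + dt
    return out


def update_gel(
    state: SimState, gel: GelationParams, scheme: KineticScheme
) -> tuple[SimState, bool]:
    """Refresh gel/solid masks and permeability from the fibrin field.

    Masks are monotone (no fibrinolysis).  Returns the new state and
    whether the permeability mask changed (to trigger a flow re-solve).
    """
    fn = state.conc[scheme.index("Fn")]
    out = state.copy()
    out.gel_mask = state.gel_mask | (fn >= gel.gel_threshold)
    out.solid_mask = state.solid_mask | (fn >= gel.solid_threshold)
    out.permeability = np.where(out.gel_mask, 0.0, 1.0)
    changed = bool((out.gel_mask != state.gel_mask).any())
    return out, changed


def _coverage(state: SimState, domain: DomainSpec) -> float:
    act = domain.activator_mask()
    return float(state.solid_mask[0, act].mean())


def _integral_surface(state, domain, scheme, names) -> float:
    act = domain.activator_mask()
    total = 0.0
    for name in names:
        total += state.conc[scheme.index(name), 0, act].sum()
    return total * domain.dx**2 * CELL_TO_NMOLE_PER_MM


def _timestep(flow, domain, scheme, config) -> float:
    dt = config.dt_max
    dmax = max(sp.diffusion_coeff for sp in scheme.species)
    if dmax > 0:
        dt = min(dt, config.diffusion_safety * domain.dx**2 / (4.0 * dmax))
    speed = flow.max_speed()
    if speed > 0:
        dt = min(dt, config.cfl * domain.dx / speed)
    return dt


def _clip_fraction(state: SimState, scheme: KineticScheme, domain: DomainSpec) -> float:
    """Worst clipped-mass fraction across conservation groups, measured
    against the initial domain inventory of the group."""
    if not state.clip_error.any() or not scheme.conservation_groups:
        return 0.0
    plasma = scheme.plasma_vector()
    ncell = domain.ny * domain.nx
    worst = 0.0
    for members in scheme.conservation_groups.values():
        cols = [scheme.index(sp) for sp in members]
        inventory = plasma[cols].sum() * ncell
        for name in members:
            sp = scheme.get_species(name)
            if sp.surface_bound and sp.surface_density > 0:
                inventory += (
                    sp.surface_density * SURFACE_TO_NM / domain.dx
                ) * domain.activator_mask().sum()
        if inventory > 0:
            worst = max(worst, float(state.clip_error[cols].sum()) / inventory)
    return worst


def run_simulation(scenario, gamma_w: float | None = None) -> SimResult:
    """Run one scenario at one wall shear rate to clot detection or the cap.

    ``scenario`` provides ``scheme`` (a resolved :class:`KineticScheme`),
    ``domain``, ``gel``, ``integrator`` and optionally ``save_fields``; see
    :class:`clotflow.experiments.ScenarioConfig`.  The run terminates a
    short margin after the coverage threshold is crossed, or at the end-time
    cap with status ``no_clot``.
    """
    scheme: KineticScheme = scenario.scheme
    domain: DomainSpec = scenario.domain
    gel: GelationParams = scenario.gel
    config: IntegratorConfig = scenario.integrator
    if gamma_w is None:
        if len(scenario.gamma_w) != 1:
            raise ValueError("gamma_w must be given when the scenario lists several")
        gamma_w = scenario.gamma_w[0]

    drive, _ = shear_to_drive(gamma_w, domain)
    state = initialize_state(domain, scheme)
    flow = solve_flow(domain, state.permeability, drive, gamma_w)
    last_solve = 0.0
    pending_resolve = False

    rows: list[dict] = []
    status = "running"
    lag_min = np.nan
    prev_cov, prev_t = 0.0, 0.0
    detect_time = None
    err = None

    def snap():
        rows.append(
            {
                "time_min": state.time / 60.0,
                "coverage": _coverage(state, domain),
                "integral_tenase": _integral_surface(state, domain, scheme, ["TF_VIIa"]),
                "tf_active": _integral_surface(
                    state, domain, scheme, ["TF", "TF_VII", "TF_VIIa"]
                ),
                "gel_cells": int(state.gel_mask.sum()),
            }
        )

    try:
        snap()
        next_snap = config.snapshot_interval
        dt = _timestep(flow, domain, scheme, config)
        while True:
            state = advance(state, scheme, flow, dt, domain, config)
            state = apply_boundary_conditions(state, flow, scheme, domain, config)
            state, changed = update_gel(state, gel, scheme)
            pending_resolve = pending_resolve or changed
            if pending_resolve and drive != 0.0 and not flow.occluded:
                if state.time - last_solve >= config.flow_resolve_interval:
                    flow = solve_flow(domain, state.permeability, drive, gamma_w)
                    last_solve = state.time
                    pending_resolve = False
                    dt = _timestep(flow, domain, scheme, config)
            cov = _coverage(state, domain)
            if detect_time is None and cov >= config.coverage_threshold:
                if cov > prev_cov:
                    frac = (config.coverage_threshold - prev_cov) / (cov - prev_cov)
                else:
                    frac = 1.0
                detect_time = prev_t + frac * (state.time - prev_t)
                lag_min = detect_time / 60.0
            prev_cov, prev_t = cov, state.time
            if state.time >= next_snap - 1e-9:
                snap()
                next_snap += config.snapshot_interval
            if _clip_fraction(state, scheme, domain) > config.mass_error_tol:
                raise IntegrationError(
                    f"clipped mass exceeds {config.mass_error_tol:.1e} of a conservation group"
                )
            if (
                not config.run_to_end
                and detect_time is not None
                and state.time >= detect_time + config.stop_margin
            ):
                status = "clotted"
                break
            if state.time >= config.end_time:
                status = "clotted" if detect_time is not None else "no_clot"
                break
    except IntegrationError as exc:
        status = "error"
        err = str(exc)
    snap()
    record = pd.DataFrame(rows).drop_duplicates(subset="time_min", keep="last")
    keep_state = state if getattr(scenario, "save_fields", False) else None
    return SimResult(
        record=record,
        status=status,
        lagtime_min=float(lag_min),
        state=keep_state,
        gamma_w=float(gamma_w),
        error=err,
    )
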