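"""Analytic oracles and fixture generators for the numerical components.

Every case is self-contained and generated at call time (never stored), so
the oracles cannot drift from the packaged scheme.  The well-mixed
reference trajectory uses a naive per-reaction rate loop and scipy's stiff
LSODA integrator — a codepath fully independent of both the compiled rate
evaluator and the spatial reaction sub-stepper it is used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from clotflow.hemodynamics import DomainSpec
from clotflow.scheme import KineticScheme

__all__ = [
    "AnalyticCase",
    "make_advection_case",
    "make_diffusion_case",
    "make_reaction_case",
    "make_zerod_oracle",
    "make_coverage_fixture",
    "naive_rates",
]


@dataclass
class AnalyticCase:
    """A closed-form verification case.

    ``solution(x, y, t)`` is the exact field; ``initial(x, y)`` the t = 0
    state; ``tolerance`` the acceptable error in ``norm`` ('l2_rel' or
    'abs').  ``meta`` carries the scenario fragment needed to run it.
    """

    name: str
    initial: Callable
    solution: Callable
    tolerance: float
    norm: str = "l2_rel"
    meta: dict = field(default_factory=dict)

    def error(self, numeric: np.ndarray, x: np.ndarray, y: np.ndarray, t: float) -> float:
        exact = self.solution(x, y, t)
        if self.norm == "l2_rel":
            return float(np.linalg.norm(numeric - exact) / np.linalg.norm(exact))
        return float(np.max(np.abs(numeric - exact)))


def make_advection_case(u: float = 1000.0, sigma0: float = 200.0, dx: float = 25.0) -> AnalyticCase:
    """Translated Gaussian under uniform advection.

    The exact solution is the initial profile shifted by u·t.  The
    tolerance budgets the smearing of first-order upwind: for a Gaussian of
    width σ0 advected N cells at CFL c, the added numerical variance is
    ≈ N·(1−c)·Δx²/2... in practice a 15% L2 budget at σ0 ≥ 4Δx over a
    1000 μm transit.
    """
    if u < 0:
        raise ValueError("u must be ≥ 0")
    if sigma0 < 3 * dx:
        raise ValueError("sigma0 must be at least 3 grid cells for a resolved pulse")
    x0 = 1500.0

    def initial(x, y):
        return np.exp(-((x - x0) ** 2) / (2 * sigma0**2))

    def solution(x, y, t):
        return np.exp(-((x - x0 - u * t) ** 2) / (2 * sigma0**2))

    return AnalyticCase(
        name=f"advect-u{u:g}",
        initial=initial,
        solution=solution,
        tolerance=0.15 if u > 0 else 1e-12,
        meta={"u": u, "sigma0": sigma0, "dx": dx, "x0": x0},
    )


def make_diffusion_case(D: float = 50.0, sigma0: float = 100.0, dx: float = 25.0) -> AnalyticCase:
    """Gaussian spreading by pure diffusion: σ²(t) = σ0² + 2Dt (heat kernel)."""
    x0, y0 = 1500.0, 500.0

    def initial(x, y):
        return np.exp(-(((x - x0) ** 2) + (y - y0) ** 2) / (2 * sigma0**2))

    def solution(x, y, t):
        s2 = sigma0**2 + 2.0 * D * t
        return (sigma0**2 / s2) * np.exp(-(((x - x0) ** 2) + (y - y0) ** 2) / (2 * s2))

    return AnalyticCase(
        name=f"diffuse-D{D:g}",
        initial=initial,
        solution=solution,
        tolerance=0.05,
        meta={"D": D, "sigma0": sigma0, "dx": dx},
    )


def make_reaction_case(motif: str = "decay", **params) -> AnalyticCase:
    """Closed-form chemistry motifs for the reaction sub-integrator.

    Motifs: ``decay`` (A → B, first order, k), ``binding`` (A + B ⇌ AB to
    the quadratic equilibrium, k_on/k_off), ``mm_excess`` (Michaelis–Menten
    with substrate ≫ enzyme: zero-order region then exponential tail is
    avoided by comparing at early time where [S] ≈ S0 − kcat·E·t·S0/(Km+S0)).
    """
    if motif == "decay":
        k = params.get("k", 0.1)
        a0 = params.get("a0", 1.0)

        def solution_t(t):
            return {"A": a0 * np.exp(-k * t), "B": a0 * (1 - np.exp(-k * t))}

        return AnalyticCase(
            name="decay", initial=lambda *a: a0, solution=lambda x, y, t: solution_t(t),
            tolerance=1e-6, norm="abs", meta={"k": k, "a0": a0, "motif": motif},
        )
    if motif == "binding":
        kon = params.get("k_on", 0.01)
        koff = params.get("k_off", 0.002)
        a0 = params.get("a0", 10.0)
        b0 = params.get("b0", 10.0)
        kd = koff / kon

        # equilibrium AB from the quadratic: AB² − AB(a0+b0+Kd) + a0·b0 = 0
        s = a0 + b0 + kd
        ab_eq = 0.5 * (s - np.sqrt(s * s - 4 * a0 * b0))

        def solution_t(t):
            return {"AB_eq": ab_eq}

        return AnalyticCase(
            name="binding", initial=lambda *a: (a0, b0), solution=lambda x, y, t: solution_t(t),
            tolerance=1e-8, norm="abs",
            meta={"k_on": kon, "k_off": koff, "a0": a0, "b0": b0, "motif": motif},
        )
    raise ValueError(f"unknown motif '{motif}'")


def naive_rates(conc: np.ndarray, scheme: KineticScheme) -> np.ndarray:
    """Brute-force per-reaction rate summation (oracle for the compiled
    evaluator): a plain python loop over reactions and stoichiometry."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    names = list(scheme.names)
    for rx in scheme.reactions:
        if rx.rate_law == "mass_action":
            rate = rx.params["k"]
            for sp, n in rx.reactants.items():
                rate = rate * conc[names.index(sp)] ** n
        elif rx.rate_law == "michaelis_menten":
            (sub,) = rx.reactants
            s = conc[names.index(sub)]
            e = conc[names.index(rx.params["enzyme"])]
            rate = rx.params["kcat"] * e * s / (rx.params["Km"] + s)
        else:
            a, b = rx.reactants
            (ab,) = rx.products
            rate = (
                rx.params["k_on"] * conc[names.index(a)] * conc[names.index(b)]
                - rx.params["k_off"] * conc[names.index(ab)]
            )
        for sp, n in rx.net_stoich().items():
            out[names.index(sp)] += n * rate
    return out


def make_zerod_oracle(
    scheme: KineticScheme,
    t_end: float,
    c0: np.ndarray | None = None,
    t_eval: np.ndarray | None = None,
):
    """High-accuracy well-mixed (0-D) reference trajectory of a scheme.

    Returns (times, trajectory (n_times, n_species)).  Uses LSODA at
    rtol 1e-10 on the naive rate loop — independent of the spatial
    reaction sub-stepper in both rate evaluation and integration.
    """
    if c0 is None:
        raise ValueError("c0 (initial concentrations, nM) is required")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)

    def rhs(t, y):
        return naive_rates(np.maximum(y, 0.0), scheme)

    sol = solve_ivp(
        rhs, (0.0, t_end), np.asarray(c0, dtype=float),
        method="LSODA", rtol=1e-10, atol=1e-13, t_eval=t_eval,
    )
    if sol.status != 0:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol.t, sol.y.T


def single_cell_domain(dx: float = 50.0) -> DomainSpec:
    """A one-cell closed-box domain whose whole wall is activator."""
    return DomainSpec(length_x=dx, height_y=dx, activator_start=0.0,
                      activator_length=dx, dx=dx)


def _inert_scheme(diffusion: float, convects: bool = True) -> KineticScheme:
    from clotflow.scheme import SpeciesSpec

    return KineticScheme(
        species=(
            SpeciesSpec(
                name="A", role="complex", plasma_conc=0.0,
                diffusion_coeff=diffusion, convects=convects,
            ),
        ),
        reactions=(),
    )


def run_advection_case(case: AnalyticCase, t_end: float = 1.0) -> float:
    """Integrate a pure-advection case with the production upwind stepper
    under a uniform plug flow and return the error in the case's norm."""
    from clotflow.hemodynamics import FlowState
    from clotflow.transport import IntegratorConfig, advance, initialize_state

    dx = case.meta["dx"]
    u = case.meta["u"]
    dom = DomainSpec(length_x=4000.0, height_y=200.0, activator_start=0.0,
                     activator_length=dx, dx=dx)
    scheme = _inert_scheme(diffusion=0.0)
    flow = FlowState(
        u=np.full((dom.ny, dom.nx + 1), u),
        v=np.zeros((dom.ny + 1, dom.nx)),
        p=np.zeros((dom.ny, dom.nx)),
        drive=0.0, target_wall_shear=0.0,
    )
    state = initialize_state(dom, scheme)
    x = (np.arange(dom.nx) + 0.5) * dx
    state.conc[0] = case.initial(x, None)[None, :]
    cfg = IntegratorConfig(cfl=0.8, dt_max=1.0)
    dt = 0.8 * dx / u if u > 0 else t_end
    n = max(int(round(t_end / dt)), 1)
    dt = t_end / n
    mass0 = state.conc[0].sum()
    for _ in range(n):
        state = advance(state, scheme, flow, dt, dom, cfg)
    profile = state.conc[0, 0]
    err = case.error(profile, x, None, t_end)
    case.meta["mass_ratio"] = float(state.conc[0].sum() / mass0)
    return err


def run_diffusion_case(case: AnalyticCase, t_end: float = 50.0) -> float:
    """Integrate a pure-diffusion case (no flow) and return the field error."""
    from clotflow.hemodynamics import FlowState
    from clotflow.transport import IntegratorConfig, advance, initialize_state

    dx = case.meta["dx"]
    dom = DomainSpec(length_x=3000.0, height_y=1000.0, activator_start=0.0,
                     activator_length=dx, dx=dx)
    scheme = _inert_scheme(diffusion=case.meta["D"])
    flow = FlowState(
        u=np.zeros((dom.ny, dom.nx + 1)),
        v=np.zeros((dom.ny + 1, dom.nx)),
        p=np.zeros((dom.ny, dom.nx)),
        drive=0.0, target_wall_shear=0.0,
    )
    state = initialize_state(dom, scheme)
    x = (np.arange(dom.nx) + 0.5) * dx
    y = (np.arange(dom.ny) + 0.5) * dx
    X, Y = np.meshgrid(x, y)
    state.conc[0] = case.initial(X, Y)
    cfg = IntegratorConfig(closed_box=True)
    dt = min(1.0, 0.4 * dx * dx / (4.0 * case.meta["D"]))
    n = max(int(round(t_end / dt)), 1)
    dt = t_end / n
    for _ in range(n):
        state = advance(state, scheme, flow, dt, dom, cfg)
    return case.error(state.conc[0], X, Y, t_end)


def make_coverage_fixture(crossing_time: float, t_end: float | None = None, n: int = 61):
    """Piecewise-linear activator-coverage series crossing 0.5 exactly at
    ``crossing_time`` (min): 0 up to 0.8·t_c, then linear through (t_c, 0.5)
    saturating at 1."""
    if crossing_time <= 0:
        raise ValueError("crossing_time must be positive")
    t_end = t_end if t_end is not None else 2.0 * crossing_time
    t = np.linspace(0.0, t_end, n)
    t0 = 0.8 * crossing_time
    slope = 0.5 / (crossing_time - t0)
    f = np.clip((t - t0) * slope, 0.0, 1.0)
    return np.column_stack([t, f])


def make_lagtime_family(
    shears=np.arange(0.0, 28.1, 4.0), y0: float = 1.54, A: float = 2.86, R: float = 0.129
):
    """A family of coverage fixtures whose lagtimes follow
    y = y0 + A·e^(R·x) — the canonical control-curve shape — for testing
    the full metrics pipeline without simulations."""
    shears = np.asarray(shears, dtype=float)
    lags = y0 + A * np.exp(R * shears)
    return shears, [make_coverage_fixture(lag) for lag in lags]
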