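"""Quantitative analysis of clotting-onset simulations.

The central readout is the *lagtime*: the time for solid fibrin to cover
half of the activator patch.  Its dependence on the wall shear rate γ_w is
summarised two ways:

* an exponential fit  y = y0 + A·e^(R·x)  of lagtime vs shear, whose
  exponent R (s) measures how steeply flow suppresses clotting;
* a comparative flow-influence coefficient over a shear interval [i, j],

      R_range = ∫_i^j [L_pert(x) − L_pert(0)] dx
              / ∫_i^j [L_ctrl(x) − L_ctrl(0)] dx ,

  the integrated lagtime elevation of a perturbed system relative to the
  control (trapezoidal, on the shared shear grid).  A control compared to
  itself gives exactly 1; a perturbation whose lagtime ignores flow gives 0.

The sensitivity ratio R′ = R_pert / R_ctrl compares the fitted exponents;
for a flat perturbed curve the fit is degenerate and R′ is not computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "NO_CLOT",
    "LagtimeCurve",
    "ExponentialFit",
    "FlowSensitivity",
    "DegenerateFitError",
    "lagtime",
    "fit_exponential",
    "flow_influence",
    "sensitivity_ratio",
    "integral_extrinsic_tenase",
    "tf_inhibition_series",
]

#: sentinel lagtime for runs that never clot before the end-time cap
NO_CLOT = float("nan")


class DegenerateFitError(ValueError):
    """The lagtime curve is flat: the exponential exponent is undefined."""


def _is_no_clot(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass
class LagtimeCurve:
    """Lagtime (min) vs wall shear rate (s⁻¹); NaN marks capped (no-clot) runs."""

    shears: np.ndarray
    lagtimes: np.ndarray
    scenario_id: str = ""

    def __post_init__(self):
        self.shears = np.asarray(self.shears, dtype=float)
        self.lagtimes = np.asarray(self.lagtimes, dtype=float)
        if self.shears.shape != self.lagtimes.shape or self.shears.ndim != 1:
            raise ValueError("shears and lagtimes must be matching 1D arrays")
        if len(self.shears) and np.any(np.diff(self.shears) <= 0):
            raise ValueError("shear rates must be strictly increasing")
        finite = self.lagtimes[np.isfinite(self.lagtimes)]
        if np.any(finite <= 0):
            raise ValueError("lagtimes must be positive (or the no-clot sentinel)")

    def finite_prefix(self) -> "LagtimeCurve":
        """Truncate at the first no-clot point (capped runs end the usable range)."""
        bad = np.flatnonzero(~np.isfinite(self.lagtimes))
        stop = bad[0] if len(bad) else len(self.lagtimes)
        return LagtimeCurve(self.shears[:stop], self.lagtimes[:stop], self.scenario_id)


@dataclass
class ExponentialFit:
    """Parameters of y = y0 + A·e^(R·x) fitted to a lagtime curve."""

    y0: float
    A: float
    R: float
    residual: float
    degenerate: bool = False
    excluded_shears: tuple = ()

    def __call__(self, x):
        return self.y0 + self.A * np.exp(self.R * np.asarray(x, dtype=float))


@dataclass
class FlowSensitivity:
    """Flow-influence coefficient R_range over [i, j] and sensitivity ratio R′.

    ``r_prime`` is None when the perturbed fit is degenerate (the curve is
    flat and the exponent undefined).
    """

    r_range: float
    r_prime: float | None
    interval: tuple[float, float]


def lagtime(coverage_series, threshold: float = 0.5, cap: float | None = None) -> float:
    """First crossing (min) of the coverage threshold, linearly interpolated.

    ``coverage_series`` is a sequence of (time_min, fraction) pairs in time
    order with fractions in [0, 1].  Returns :data:`NO_CLOT` if the
    threshold is never reached before ``cap`` (or at all).
    """
    pts = np.asarray(list(coverage_series), dtype=float)
    if pts.size == 0:
        raise ValueError("empty coverage series")
    t, f = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) < 0):
        raise ValueError("coverage series must be time-ordered")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("coverage fractions must lie in [0, 1]")
    for k in range(len(t)):
        if f[k] >= threshold:
            if k == 0:
                crossing = t[0]
            else:
                frac = (threshold - f[k - 1]) / (f[k] - f[k - 1])
                crossing = t[k - 1] + frac * (t[k] - t[k - 1])
            if cap is not None and crossing > cap:
                return NO_CLOT
            return float(crossing)
    return NO_CLOT


def fit_exponential(
    curve: LagtimeCurve, flat_rtol: float = 0.02
) -> ExponentialFit:
    """Deterministic nonlinear least-squares fit of y = y0 + A·e^(R·x).

    No-clot points are excluded (and recorded on the result).  The initial
    guess is fixed — y0 = min y, A = range, R from the log-slope of the last
    two points — so identical curves give bit-identical fits.  A curve whose
    range is below ``flat_rtol`` of its mean is flagged ``degenerate``: the
    exponent is undefined for a flat response.
    """
    finite = np.isfinite(curve.lagtimes)
    x = curve.shears[finite]
    y = curve.lagtimes[finite]
    excluded = tuple(curve.shears[~finite])
    if len(x) < 4:
        raise ValueError("need at least 4 finite points to fit")
    span = float(y.max() - y.min())
    if span < flat_rtol * float(np.mean(y)):
        return ExponentialFit(
            y0=float(np.mean(y)), A=0.0, R=float("nan"), residual=span,
            degenerate=True, excluded_shears=excluded,
        )
    y0_init = float(y.min()) * 0.99
    a_init = max(span, 1e-12)
    tail = max((y[-1] - y0_init) / max(y[-2] - y0_init, 1e-12), 1.0 + 1e-9)
    r_init = math.log(tail) / max(x[-1] - x[-2], 1e-12)

    def model(xv, y0, a, r):
        return y0 + a * np.exp(r * xv)

    popt, _ = curve_fit(
        model, x, y, p0=[y0_init, a_init, r_init], maxfev=20000
    )
    resid = float(np.sqrt(np.mean((model(x, *popt) - y) ** 2)))
    return ExponentialFit(
        y0=float(popt[0]), A=float(popt[1]), R=float(popt[2]),
        residual=resid, degenerate=False, excluded_shears=excluded,
    )


def _shared_interval(pert: LagtimeCurve, ctrl: LagtimeCurve, interval):
    """Clip [i, j] to the finite prefix of both curves."""
    i, j = interval
    pj = pert.finite_prefix()
    cj = ctrl.finite_prefix()
    if len(pj.shears) == 0 or len(cj.shears) == 0:
        raise ValueError("curve has no finite points")
    j_eff = min(j, pj.shears[-1], cj.shears[-1])
    if j_eff <= i:
        raise ValueError("no overlap between the requested interval and finite data")
    return i, float(j_eff)


def _elevation_integral(curve: LagtimeCurve, i: float, j: float) -> float:
    """∫_i^j [L(x) − L(0)] dx on the curve's grid, trapezoidal."""
    c = curve.finite_prefix()
    x, y = c.shears, c.lagtimes
    if x[0] > 0:
        raise ValueError("curve must include the zero-shear point")
    grid = np.unique(np.concatenate([x[(x >= i) & (x <= j)], [i, j]]))
    vals = np.interp(grid, x, y) - np.interp(0.0, x, y)
    return float(np.trapezoid(vals, grid))


def flow_influence(
    pert: LagtimeCurve, ctrl: LagtimeCurve, interval: tuple[float, float] = (0.0, 28.0)
) -> FlowSensitivity:
    """Comparative flow-influence coefficient R_range over shear interval [i, j].

    The interval is auto-truncated at the first no-clot point of either
    curve.  Control vs itself gives exactly 1; a perturbation insensitive to
    flow gives 0.  Raises if the control curve is flat (zero denominator).
    """
    i, j = _shared_interval(pert, ctrl, interval)
    num = _elevation_integral(pert, i, j)
    den = _elevation_integral(ctrl, i, j)
    if den == 0.0:
        raise ValueError("control curve flat: flow-influence undefined")
    return FlowSensitivity(r_range=num / den, r_prime=None, interval=(i, j))


def sensitivity_ratio(pert_fit: ExponentialFit, ctrl_fit: ExponentialFit) -> float | None:
    """R′ = R_pert / R_ctrl; None (not computable) if the perturbed fit is
    degenerate, mirroring '-' entries for flat perturbed curves."""
    if ctrl_fit.degenerate:
        raise DegenerateFitError("control fit degenerate: R′ undefined")
    if pert_fit.degenerate:
        return None
    return float(pert_fit.R / ctrl_fit.R)


def integral_extrinsic_tenase(state, domain, scheme) -> float:
    """Line integral of TF·VIIa surface density along the activator (nmole/mm).

    The thin-layer volumetric concentration C (nM) in each wall cell maps
    back to a surface density C·Δx, so the line integral is Σ C·Δx²
    (converted to nmole/mm)."""
    from clotflow.transport import _integral_surface

    return _integral_surface(state, domain, scheme, ["TF_VIIa"])


def tf_inhibition_series(record, normalized: bool = False):
    """(time_min, total active TF) from a run record.

    Active TF = free TF + TF·VII + TF·VIIa (everything not captured in the
    quaternary TFPI complex), in nmole/mm; optionally normalised to the
    initial TF level.
    """
    t = np.asarray(record["time_min"], dtype=float)
    tf = np.asarray(record["tf_active"], dtype=float)
    if normalized:
        tf = tf / tf[0]
    return t, tf
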