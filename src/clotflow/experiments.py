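"""Scenario orchestration: the computational experiments, end to end.

A :class:`ScenarioConfig` bundles everything one run needs — scheme +
perturbations, geometry, shear list, gelation thresholds, numerics — and
named presets mirror the classic perturbation vocabulary (convection
knockouts per species class, feedback knockouts, factor/inhibitor
additions).  Sweeps cache completed points by a content hash of the fully
resolved scenario, so editing any field invalidates the cache.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clotflow.hemodynamics import DomainSpec
from clotflow.metrics import (
    LagtimeCurve,
    fit_exponential,
    flow_influence,
    sensitivity_ratio,
)
from clotflow.scheme import (
    KineticScheme,
    Perturbation,
    SCENARIO_OPS,
    apply_perturbations,
    default_scheme,
    load_scheme,
)
from clotflow.transport import GelationParams, IntegratorConfig, SimResult, run_simulation

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "ENZYMES",
    "ZYMOGENS",
    "make_scenario",
    "run_sweep",
    "run_table1",
    "run_activator_size_sweep",
    "run_tenase_kinetics",
]

#: active proteases/cofactors whose convection can be toggled as a class
ENZYMES = ("IIa", "Va", "VIIa", "VIIIa", "IXa", "Xa", "XIa", "APC")
#: mobile complexes carrying an active-enzyme core: switching off a
#: factor's convection also pins the complexes that contain it
ENZYME_COMPLEXES = ("Xa_Va", "IXa_VIIIa", "TFPI_Xa")
#: inactive precursors (zymogens) as a class
ZYMOGENS = ("II", "V", "VII", "VIII", "IX", "X", "XI", "PC", "Fg")

DEFAULT_SHEARS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0)

#: named perturbation sets mirroring the classic sensitivity table rows
PRESETS: dict[str, list[dict]] = {
    "control": [],
    "gel_380": [{"op": "set_gel_threshold", "value": 380.0}],
    "gel_760": [{"op": "set_gel_threshold", "value": 760.0}],
    "solid_450": [{"op": "set_solid_threshold", "value": 450.0}],
    "solid_7600": [{"op": "set_solid_threshold", "value": 7600.0}],
    "activator_500": [{"op": "set_activator_length", "value": 500.0}],
    "no_convection_zymogens": [
        {"op": "set_convection", "species": list(ZYMOGENS), "on": False}
    ],
    "no_convection_enzymes": [
        {"op": "set_convection", "species": list(ENZYMES + ENZYME_COMPLEXES), "on": False}
    ],
    # Xa-containing complexes stay mobile when Xa itself does
    "no_convection_enzymes_except_iia_xa": [
        {
            "op": "set_convection",
            "species": [s for s in ENZYMES if s not in ("IIa", "Xa")] + ["IXa_VIIIa"],
            "on": False,
        }
    ],
    "no_convection_iia_xa": [
        {"op": "set_convection", "species": ["IIa", "Xa", "Xa_Va", "TFPI_Xa"], "on": False}
    ],
    "no_xa_tf_vii_activation": [{"op": "zero_rate", "reaction": "xa_activates_tf_vii"}],
    "no_iia_feedbacks": [
        {"op": "zero_rate", "reaction": "iia_activates_V"},
        {"op": "zero_rate", "reaction": "iia_activates_VII"},
        {"op": "zero_rate", "reaction": "iia_activates_VIII"},
        {"op": "zero_rate", "reaction": "iia_activates_XI"},
    ],
    "tfpi_plus_5nM": [{"op": "add_species_conc", "species": "TFPI", "delta": 5.0}],
    "at3_plus_6800nM": [{"op": "add_species_conc", "species": "AT", "delta": 6800.0}],
    "viia_plus_10nM": [{"op": "add_species_conc", "species": "VIIa", "delta": 10.0}],
    "no_fibrinogen_cleavage": [
        {"op": "zero_rate", "reaction": "iia_cleaves_fibrinogen"}
    ],
}


@dataclass
class ScenarioConfig:
    """A complete, reproducible experiment description.

    Scenario-level perturbations (activator length, gel thresholds) are
    applied to ``domain``/``gel`` on construction; scheme-level ones are
    applied lazily when :attr:`scheme` is first resolved.  Everything is
    deterministic: identical configs give bit-identical runs.
    """

    scenario_id: str
    base_scheme: KineticScheme | None = None
    perturbations: tuple = ()
    domain: DomainSpec = field(default_factory=DomainSpec)
    gamma_w: tuple = DEFAULT_SHEARS
    gel: GelationParams = field(default_factory=GelationParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    output_dir: str | None = None
    save_fields: bool = False
    _scheme: KineticScheme | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.scenario_id:
            raise ValueError("scenario_id must be non-empty")
        self.gamma_w = tuple(float(g) for g in self.gamma_w)
        if len(self.gamma_w) == 0:
            raise ValueError("gamma_w list must be non-empty")
        if any(b <= a for a, b in zip(self.gamma_w, self.gamma_w[1:])):
            raise ValueError("gamma_w list must be strictly increasing")
        perts = [
            p if isinstance(p, Perturbation) else Perturbation.from_dict(p)
            for p in self.perturbations
        ]
        self.perturbations = tuple(perts)
        for p in perts:
            if p.op == "set_activator_length":
                self.domain = replace(self.domain, activator_length=float(p.args["value"]))
            elif p.op == "set_gel_threshold":
                self.gel = replace(self.gel, gel_threshold=float(p.args["value"]))
            elif p.op == "set_solid_threshold":
                self.gel = replace(self.gel, solid_threshold=float(p.args["value"]))

    @property
    def scheme(self) -> KineticScheme:
        if self._scheme is None:
            base = self.base_scheme if self.base_scheme is not None else default_scheme()
            scheme_perts = [p for p in self.perturbations if p.op not in SCENARIO_OPS]
            self._scheme = apply_perturbations(base, scheme_perts) if scheme_perts else base
        return self._scheme

    # -- reproducibility ----------------------------------------------
    def canonical(self) -> dict:
        """Canonical nested-plain-type form of the fully resolved scenario."""
        scheme = self.scheme
        return {
            "species": [vars(sp) | {} for sp in scheme.species],
            "reactions": [
                {
                    "id": rx.id,
                    "rate_law": rx.rate_law,
                    "reactants": dict(rx.reactants),
                    "products": dict(rx.products),
                    "params": dict(rx.params),
                    "localization": rx.localization,
                }
                for rx in scheme.reactions
            ],
            "domain": vars(self.domain) | {},
            "gel": vars(self.gel) | {},
            "integrator": vars(self.integrator) | {},
        }

    def content_hash(self, gamma_w: float | None = None) -> str:
        doc = self.canonical()
        if gamma_w is not None:
            doc["gamma_w"] = float(gamma_w)
        payload = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        """Build a scenario from a YAML document.

        Keys: ``id``; optional ``scheme`` (path to a scheme YAML; packaged
        default otherwise), ``preset`` (a :data:`PRESETS` name),
        ``perturbations``, ``domain``, ``shears``, ``gel``, ``integrator``.
        """
        doc = yaml.safe_load(Path(path).read_text())
        perts = list(PRESETS.get(doc.get("preset", ""), []))
        perts += list(doc.get("perturbations", []))
        kwargs = dict(
            scenario_id=str(doc.get("id", Path(path).stem)),
            perturbations=tuple(perts),
        )
        if "scheme" in doc:
            kwargs["base_scheme"] = load_scheme(doc["scheme"])
        if "domain" in doc:
            kwargs["domain"] = DomainSpec(**doc["domain"])
        if "shears" in doc:
            kwargs["gamma_w"] = tuple(doc["shears"])
        if "gel" in doc:
            kwargs["gel"] = GelationParams(**doc["gel"])
        if "integrator" in doc:
            kwargs["integrator"] = IntegratorConfig(**doc["integrator"])
        if "output_dir" in doc:
            kwargs["output_dir"] = doc["output_dir"]
        return cls(**kwargs)


def make_scenario(preset: str = "control", scenario_id: str | None = None, **overrides) -> ScenarioConfig:
    """Convenience constructor from a preset name plus field overrides."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset '{preset}'; known: {sorted(PRESETS)}")
    extra = tuple(overrides.pop("perturbations", ()))
    return ScenarioConfig(
        scenario_id=scenario_id or preset,
        perturbations=tuple(PRESETS[preset]) + extra,
        **overrides,
    )


# ---------------------------------------------------------------------------
# sweeps


def _cache_path(scenario: ScenarioConfig, gamma: float) -> Path | None:
    if scenario.output_dir is None:
        return None
    d = Path(scenario.output_dir) / "cache"
    d.mkdir(parents=True, exist_ok=True)
    return d / f"{scenario.scenario_id}-{scenario.content_hash(gamma)}.json"


def run_point(scenario: ScenarioConfig, gamma: float) -> dict:
    """One cached simulation point: {'gamma', 'lagtime_min', 'status'}."""
    path = _cache_path(scenario, gamma)
    if path is not None and path.exists():
        return json.loads(path.read_text())
    res = run_simulation(scenario, gamma)
    point = {
        "gamma": float(gamma),
        "lagtime_min": None if np.isnan(res.lagtime_min) else float(res.lagtime_min),
        "status": res.status,
        "error": res.error,
    }
    if path is not None:
        path.write_text(json.dumps(point))
    return point


def run_sweep(scenario: ScenarioConfig) -> LagtimeCurve:
    """One simulation per listed shear rate, assembled into a lagtime curve.

    Failed points are flagged (no-clot sentinel + status in the metadata)
    and the sweep continues.  Points are cached under
    ``scenario.output_dir`` keyed by the resolved-config hash.
    """
    points = [run_point(scenario, g) for g in scenario.gamma_w]
    lags = [p["lagtime_min"] if p["lagtime_min"] is not None else np.nan for p in points]
    curve = LagtimeCurve(np.array(scenario.gamma_w), np.array(lags), scenario.scenario_id)
    curve.meta = points  # per-point run metadata
    return curve


def run_table1(
    scenarios: dict[str, ScenarioConfig],
    interval: tuple[float, float] = (0.0, 28.0),
) -> pd.DataFrame:
    """Flow-influence table: one row per perturbed scenario vs the control.

    ``scenarios`` must contain the key ``control``; every other entry is
    swept, the shear interval auto-truncated at the first no-clot point of
    either curve, and (R_range, R′) computed.  Emitted in the classic
    (label, R, i–j, R′) layout.
    """
    if "control" not in scenarios:
        raise ValueError("a 'control' scenario is required")
    ctrl_curve = run_sweep(scenarios["control"])
    try:
        ctrl_fit = fit_exponential(ctrl_curve)
    except ValueError:
        ctrl_fit = None
    rows = []
    for label, scen in scenarios.items():
        if label == "control":
            curve, sens = ctrl_curve, flow_influence(ctrl_curve, ctrl_curve, interval)
            fit = ctrl_fit
        else:
            curve = run_sweep(scen)
            sens = flow_influence(curve, ctrl_curve, interval)
            try:
                fit = fit_exponential(curve)
            except ValueError:
                fit = None
        if fit is None or ctrl_fit is None:
            rp = None
        else:
            rp = sensitivity_ratio(fit, ctrl_fit)
        rows.append(
            {
                "label": label,
                "R_range": sens.r_range,
                "interval": f"{sens.interval[0]:g}-{sens.interval[1]:g}",
                "R_prime": rp if rp is not None else np.nan,
                "R_prime_computable": rp is not None,
                "y0": fit.y0 if fit is not None else np.nan,
                "A": fit.A if fit is not None else np.nan,
                "R_exp": fit.R if fit is not None else np.nan,
                "degenerate_fit": fit.degenerate if fit is not None else True,
            }
        )
    return pd.DataFrame(rows)


def run_activator_size_sweep(
    lengths=(500.0, 750.0, 1000.0, 1500.0, 2000.0),
    gamma_w: float = 17.0,
    base: ScenarioConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Lagtime vs activator length at fixed shear, plus semi-reciprocal
    regression diagnostics (lagtime vs 1/length — linear for a hyperbolic
    dependence)."""
    base = base or make_scenario("control")
    rows = []
    for L in lengths:
        scen = replace(
            base,
            scenario_id=f"{base.scenario_id}-act{L:g}",
            domain=replace(base.domain, activator_length=float(L)),
            _scheme=base.scheme,
        )
        point = run_point(scen, gamma_w)
        rows.append({"length_um": float(L), "lagtime_min": point["lagtime_min"],
                     "status": point["status"]})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["lagtime_min"])
    diag = {"n_finite": int(len(ok))}
    if len(ok) >= 2:
        xr = 1.0 / ok["length_um"].to_numpy()
        yr = ok["lagtime_min"].to_numpy()
        coef = np.polyfit(xr, yr, 1)
        pred = np.polyval(coef, xr)
        ss_res = float(np.sum((yr - pred) ** 2))
        ss_tot = float(np.sum((yr - yr.mean()) ** 2))
        diag |= {
            "slope": float(coef[0]),
            "intercept": float(coef[1]),
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        }
    return table, diag


def run_tenase_kinetics(
    shears=(0.0, 7.0, 23.0),
    include_no_cleavage: bool = True,
    base: ScenarioConfig | None = None,
) -> dict[str, SimResult]:
    """Integral extrinsic tenase and active-TF kinetics per shear rate.

    Returns run results keyed by label, including (optionally) the
    no-fibrinogen-cleavage variant at the highest shear, in which no clot
    can form and the late tenase peak is absent.
    """
    base = base or make_scenario("control")
    base = replace(base, integrator=replace(base.integrator, run_to_end=True))
    out: dict[str, SimResult] = {}
    for g in shears:
        out[f"shear_{g:g}"] = run_simulation(base, g)
    if include_no_cleavage:
        scen = make_scenario(
            "no_fibrinogen_cleavage",
            scenario_id=f"{base.scenario_id}-nofn",
            domain=base.domain,
            gel=base.gel,
            integrator=base.integrator,
            gamma_w=base.gamma_w,
            output_dir=base.output_dir,
        )
        out["no_cleavage"] = run_simulation(scen, max(shears))
    return out
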