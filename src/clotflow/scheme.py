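"""Declarative coagulation reaction networks.

A :class:`KineticScheme` is a validated, immutable description of the
clotting cascade: the species (zymogens, enzymes, cofactors, inhibitors,
fibrin(ogen) and the surface-bound tissue-factor complexes) plus the
reactions connecting them.  Concentration units are nM, time s, length μm;
surface loadings are nmole/mm².

The scheme is deliberately config-driven: the packaged default
(``data/default_scheme.yaml``) encodes the tissue-factor pathway —
TF·VIIa-driven X and IX activation on the activator patch, the positive
feedback of TF·VII activation by factor Xa, intrinsic tenase,
prothrombinase, the thrombin feedback loops, fibrinogen cleavage, the
two-step Xa-dependent TFPI mechanism and AT-III inactivation — but any
network obeying the same grammar can be loaded.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "KineticScheme",
    "Perturbation",
    "SchemeValidationError",
    "PerturbationError",
    "load_scheme",
    "default_scheme",
    "apply_perturbations",
    "evaluate_rates",
    "check_conservation",
]

ROLES = {
    "zymogen",
    "enzyme",
    "cofactor",
    "complex",
    "inhibitor",
    "fibrinogen",
    "fibrin",
    "surface-bound",
}

RATE_LAWS = {"mass_action", "michaelis_menten", "reversible_binding"}
LOCALIZATIONS = {"bulk", "activator_surface"}

#: perturbation ops that edit the kinetic scheme itself
SCHEME_OPS = {"zero_rate", "add_species_conc", "set_convection"}
#: perturbation ops that edit the physical scenario (see :mod:`clotflow.experiments`)
SCENARIO_OPS = {"set_activator_length", "set_gel_threshold", "set_solid_threshold"}


class SchemeValidationError(ValueError):
    """Raised when a scheme fails validation.

    ``issues`` holds one machine-parsable line per problem; ``str()`` joins
    them newline-separated.
    """

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        super().__init__("\n".join(self.issues))


class PerturbationError(ValueError):
    """A perturbation edit referenced something that does not exist."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species of the network.

    ``plasma_conc`` (nM) is used both as the initial bulk value and the
    inflow (inlet Dirichlet) value.  ``surface_density`` (nmole/mm²) is the
    initial loading on the activator patch and is only meaningful for
    ``surface_bound`` species, which neither diffuse nor convect.
    """

    name: str
    role: str
    plasma_conc: float = 0.0
    diffusion_coeff: float = 50.0
    convects: bool = True
    surface_bound: bool = False
    surface_density: float = 0.0

    def issues(self) -> list[str]:
        out = []
        if not self.name or not self.name.replace("_", "").isalnum():
            out.append(f"species:{self.name}: name must be a simple identifier")
        if self.role not in ROLES:
            out.append(f"species:{self.name}: unknown role '{self.role}'")
        if self.plasma_conc < 0:
            out.append(f"species:{self.name}: plasma_conc < 0")
        if self.diffusion_coeff < 0:
            out.append(f"species:{self.name}: diffusion_coeff < 0")
        if self.surface_density < 0:
            out.append(f"species:{self.name}: surface_density < 0")
        if self.surface_bound and (self.convects or self.diffusion_coeff != 0):
            out.append(
                f"species:{self.name}: surface-bound species must have "
                "convects=false and diffusion_coeff=0"
            )
        return out


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction.  ``reactants``/``products`` map species name → stoichiometry.

    Rate laws:

    ``mass_action``
        rate = k · ∏ [reactant]^stoich, params ``k`` (nM^(1-n)·s⁻¹).
    ``michaelis_menten``
        rate = kcat·[E]·[S]/(Km+[S]); params ``kcat`` (s⁻¹), ``Km`` (nM),
        ``enzyme`` (species name, unchanged by the reaction); exactly one
        substrate with stoichiometry 1.
    ``reversible_binding``
        A + B ⇌ AB; params ``k_on`` (nM⁻¹s⁻¹), ``k_off`` (s⁻¹); the signed
        rate k_on·[A][B] − k_off·[AB] is applied with binding stoichiometry.

    A species appearing with equal stoichiometry on both sides acts as a
    catalyst/modifier (it enters the rate but is not consumed).
    """

    id: str
    rate_law: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    params: Mapping[str, float]
    localization: str = "bulk"

    def net_stoich(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for sp, n in self.products.items():
            net[sp] = net.get(sp, 0) + int(n)
        for sp, n in self.reactants.items():
            net[sp] = net.get(sp, 0) - int(n)
        return {sp: n for sp, n in net.items() if n != 0}

    def participants(self) -> set[str]:
        out = set(self.reactants) | set(self.products)
        if self.rate_law == "michaelis_menten":
            out.add(str(self.params["enzyme"]))
        return out

    def issues(self, known_species: set[str]) -> list[str]:
        out = []
        if self.rate_law not in RATE_LAWS:
            out.append(f"reaction:{self.id}: unknown rate_law '{self.rate_law}'")
            return out
        if self.localization not in LOCALIZATIONS:
            out.append(f"reaction:{self.id}: unknown localization '{self.localization}'")
        for sp in set(self.reactants) | set(self.products):
            if sp not in known_species:
                out.append(f"reaction:{self.id}: unknown species '{sp}'")
        for key, val in self.params.items():
            if key == "enzyme":
                if val not in known_species:
                    out.append(f"reaction:{self.id}: unknown enzyme '{val}'")
                continue
            if not np.isfinite(val) or val < 0:
                out.append(f"reaction:{self.id}: constant {key} must be ≥ 0")
        if self.rate_law == "mass_action" and "k" not in self.params:
            out.append(f"reaction:{self.id}: mass_action needs param k")
        if self.rate_law == "michaelis_menten":
            for key in ("kcat", "Km", "enzyme"):
                if key not in self.params:
                    out.append(f"reaction:{self.id}: michaelis_menten needs param {key}")
            if self.params.get("Km", 1.0) <= 0:
                out.append(f"reaction:{self.id}: michaelis_menten needs Km > 0")
            if len(self.reactants) != 1 or set(self.reactants.values()) != {1}:
                out.append(
                    f"reaction:{self.id}: michaelis_menten needs exactly one substrate"
                )
        if self.rate_law == "reversible_binding":
            for key in ("k_on", "k_off"):
                if key not in self.params:
                    out.append(f"reaction:{self.id}: reversible_binding needs param {key}")
            if len(self.reactants) != 2 or len(self.products) != 1:
                out.append(
                    f"reaction:{self.id}: reversible_binding is A + B ⇌ AB"
                )
        return out


@dataclass
class Perturbation:
    """One edit of a scheme or scenario (see the ops in the class doc).

    ``op`` is one of ``zero_rate`` (args: ``reaction``), ``add_species_conc``
    (``species``, ``delta``), ``set_convection`` (``species`` list, ``on``),
    ``set_activator_length`` (``value`` μm), ``set_gel_threshold`` /
    ``set_solid_threshold`` (``value`` nM).
    """

    op: str
    args: dict

    @classmethod
    def from_dict(cls, d: Mapping) -> "Perturbation":
        d = dict(d)
        op = d.pop("op", None)
        if op is None or op not in SCHEME_OPS | SCENARIO_OPS:
            raise PerturbationError(f"unknown perturbation op: {op!r}")
        return cls(op=op, args=d)


@dataclass
class KineticScheme:
    """A validated reaction network.

    ``conservation_groups`` maps a group name to the species whose summed
    total is invariant in a closed system (e.g. every factor-X-containing
    form).  Group consistency is audited symbolically on construction.
    """

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    conservation_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    _compiled: object = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        self.conservation_groups = {
            k: tuple(v) for k, v in self.conservation_groups.items()
        }
        self.validate()

    # -- introspection -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species: {name}") from None

    def get_species(self, name: str) -> SpeciesSpec:
        return self.species[self.index(name)]

    def get_reaction(self, rid: str) -> ReactionSpec:
        for rx in self.reactions:
            if rx.id == rid:
                return rx
        raise KeyError(f"unknown reaction: {rid}")

    def plasma_vector(self) -> np.ndarray:
        """Initial/inflow bulk concentrations (nM); zero for surface species."""
        return np.array(
            [0.0 if sp.surface_bound else sp.plasma_conc for sp in self.species]
        )

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        issues: list[str] = []
        seen: set[str] = set()
        for sp in self.species:
            if sp.name in seen:
                issues.append(f"species:{sp.name}: duplicate definition")
            seen.add(sp.name)
            issues.extend(sp.issues())
        rids: set[str] = set()
        for rx in self.reactions:
            if rx.id in rids:
                issues.append(f"reaction:{rx.id}: duplicate id")
            rids.add(rx.id)
            issues.extend(rx.issues(seen))
        for gname, members in self.conservation_groups.items():
            for sp in members:
                if sp not in seen:
                    issues.append(f"group:{gname}: unknown species '{sp}'")
        if not issues:
            # stoichiometric audit: every reaction leaves every group total
            # unchanged in a closed system
            for rx in self.reactions:
                net = rx.net_stoich()
                for gname, members in self.conservation_groups.items():
                    drift = sum(net.get(sp, 0) for sp in members)
                    if drift != 0:
                        issues.append(
                            f"group:{gname}: reaction {rx.id} changes total by {drift}"
                        )
        if issues:
            raise SchemeValidationError(issues)

    # -- rate evaluation ------------------------------------------------
    def _evaluator(self) -> "_CompiledRates":
        if self._compiled is None:
            object.__setattr__(self, "_compiled", _CompiledRates(self))
        return self._compiled

    def rates(self, conc: np.ndarray, surface_mask=None) -> np.ndarray:
        """Net production rates (nM/s); see :func:`evaluate_rates`."""
        return self._evaluator()(conc, surface_mask)


class _CompiledRates:
    """Pre-indexed, fully vectorised rate evaluator.

    Reactions are batched by rate law into gather-index arrays, all
    per-reaction rates computed in a few whole-grid numpy operations, and
    net production assembled with one stoichiometry-matrix product.
    ``conc`` has shape ``(n_species, ...grid)``.
    """

    def __init__(self, scheme: KineticScheme):
        self.scheme = scheme
        idx = {name: i for i, name in enumerate(scheme.names)}
        n_rx = len(scheme.reactions)
        self.S = np.zeros((scheme.n_species, n_rx))
        self.surface_rows = []
        ma1, ma2, mm, rb, general = [], [], [], [], []
        for r, rx in enumerate(scheme.reactions):
            for sp, n in rx.net_stoich().items():
                self.S[idx[sp], r] = float(n)
            if rx.localization == "activator_surface":
                self.surface_rows.append(r)
            if rx.rate_law == "mass_action":
                factors = [(idx[sp], int(n)) for sp, n in rx.reactants.items()]
                order = sum(n for _, n in factors)
                if order <= 1:
                    ma1.append((r, float(rx.params["k"]), factors[0][0] if factors else -1))
                elif order == 2 and len(factors) == 2:
                    ma2.append((r, float(rx.params["k"]), factors[0][0], factors[1][0]))
                else:
                    general.append((r, float(rx.params["k"]), factors))
            elif rx.rate_law == "michaelis_menten":
                (sub,) = rx.reactants
                mm.append(
                    (r, float(rx.params["kcat"]), float(rx.params["Km"]),
                     idx[str(rx.params["enzyme"])], idx[sub])
                )
            else:  # reversible_binding
                a, b = rx.reactants
                (ab,) = rx.products
                rb.append(
                    (r, float(rx.params["k_on"]), float(rx.params["k_off"]),
                     idx[a], idx[b], idx[ab])
                )
        self.surface_rows = np.array(self.surface_rows, dtype=int)

        def cols(batch):
            return tuple(np.array(c) for c in zip(*batch)) if batch else None

        self.ma1 = cols(ma1)
        self.ma2 = cols(ma2)
        self.mm = cols(mm)
        self.rb = cols(rb)
        self.general = general
        self.n_rx = n_rx
        self.packed = None if general else self._pack(scheme, idx)

    def _pack(self, scheme: KineticScheme, idx: dict):
        """Flat-array encoding of the network for the numba kernels."""
        n_rx = len(scheme.reactions)
        law = np.zeros(n_rx, dtype=np.int64)
        pa = np.zeros(n_rx)
        pb = np.zeros(n_rx)
        ia = np.full(n_rx, -1, dtype=np.int64)
        ib = np.full(n_rx, -1, dtype=np.int64)
        ic = np.full(n_rx, -1, dtype=np.int64)
        surf = np.zeros(n_rx, dtype=np.bool_)
        ptr, nidx, ncoef = [0], [], []
        for r, rx in enumerate(scheme.reactions):
            surf[r] = rx.localization == "activator_surface"
            if rx.rate_law == "mass_action":
                factors = []
                for sp, n in rx.reactants.items():
                    factors.extend([idx[sp]] * int(n))
                pa[r] = float(rx.params["k"])
                if len(factors) <= 1:
                    law[r] = 0
                    if factors:
                        ia[r] = factors[0]
                else:
                    law[r] = 1
                    ia[r], ib[r] = factors[0], factors[1]
            elif rx.rate_law == "michaelis_menten":
                (sub,) = rx.reactants
                law[r] = 2
                pa[r] = float(rx.params["kcat"])
                pb[r] = float(rx.params["Km"])
                ia[r] = idx[str(rx.params["enzyme"])]
                ib[r] = idx[sub]
            else:
                a, b = rx.reactants
                (ab,) = rx.products
                law[r] = 3
                pa[r] = float(rx.params["k_on"])
                pb[r] = float(rx.params["k_off"])
                ia[r], ib[r], ic[r] = idx[a], idx[b], idx[ab]
            for sp, n in rx.net_stoich().items():
                nidx.append(idx[sp])
                ncoef.append(float(n))
            ptr.append(len(nidx))
        return (
            law, pa, pb, ia, ib, ic,
            np.array(ptr, dtype=np.int64),
            np.array(nidx, dtype=np.int64),
            np.array(ncoef),
            surf,
        )

    def __call__(self, conc: np.ndarray, surface_mask=None) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if conc.shape[0] != self.scheme.n_species:
            raise ValueError(
                f"conc has {conc.shape[0]} rows, scheme has {self.scheme.n_species} species"
            )
        if np.any(conc < 0):
            raise ValueError("negative concentration passed to rate evaluation")
        grid_shape = conc.shape[1:]
        flat = conc.reshape(conc.shape[0], -1)
        R = np.zeros((self.n_rx, flat.shape[1]))
        if self.ma1 is not None:
            r, k, a = self.ma1
            R[r] = np.where(a[:, None] >= 0, k[:, None] * flat[a], k[:, None])
        if self.ma2 is not None:
            r, k, a, b = self.ma2
            R[r] = k[:, None] * flat[a] * flat[b]
        if self.mm is not None:
            r, kcat, km, e, s = self.mm
            sv = flat[s]
            R[r] = kcat[:, None] * flat[e] * sv / (km[:, None] + sv)
        if self.rb is not None:
            r, kon, koff, a, b, ab = self.rb
            R[r] = kon[:, None] * flat[a] * flat[b] - koff[:, None] * flat[ab]
        for r, k, factors in self.general:
            rate = np.full(flat.shape[1], k)
            for i, n in factors:
                rate = rate * (flat[i] if n == 1 else flat[i] ** n)
            R[r] = rate
        if surface_mask is not None and len(self.surface_rows):
            R[self.surface_rows] *= np.asarray(surface_mask, dtype=float).reshape(-1)
        return (self.S @ R).reshape(conc.shape[0], *grid_shape)


def evaluate_rates(conc, scheme: KineticScheme, surface_mask=None) -> np.ndarray:
    """Net per-species production rates (nM/s) at concentrations ``conc`` (nM).

    ``conc`` is ``(n_species,)`` or ``(n_species, ...grid)``.  For reactions
    localized to the activator surface, ``surface_mask`` (broadcastable to
    the grid axes, 1 on activator cells) gates the rate; surface reactions
    are evaluated everywhere when it is omitted (their TF-containing
    participants vanish off-patch anyway).
    """
    return scheme.rates(np.asarray(conc, dtype=float), surface_mask)


# ---------------------------------------------------------------------------
# loading / perturbation


def _parse_species(entries: Iterable[Mapping]) -> list[SpeciesSpec]:
    out = []
    for e in entries:
        e = dict(e)
        out.append(
            SpeciesSpec(
                name=str(e.pop("name")),
                role=str(e.pop("role", "complex")),
                plasma_conc=float(e.pop("plasma_conc", 0.0)),
                diffusion_coeff=float(e.pop("diffusion_coeff", 50.0)),
                convects=bool(e.pop("convects", True)),
                surface_bound=bool(e.pop("surface_bound", False)),
                surface_density=float(e.pop("surface_density", 0.0)),
            )
        )
        if e:
            raise SchemeValidationError(
                [f"species:{out[-1].name}: unknown keys {sorted(e)}"]
            )
    return out


def _parse_reactions(entries: Iterable[Mapping]) -> list[ReactionSpec]:
    out = []
    for e in entries:
        e = dict(e)
        out.append(
            ReactionSpec(
                id=str(e.pop("id")),
                rate_law=str(e.pop("rate_law")),
                reactants={str(k): int(v) for k, v in dict(e.pop("reactants", {})).items()},
                products={str(k): int(v) for k, v in dict(e.pop("products", {})).items()},
                params={str(k): v for k, v in dict(e.pop("params", {})).items()},
                localization=str(e.pop("localization", "bulk")),
            )
        )
        if e:
            raise SchemeValidationError(
                [f"reaction:{out[-1].id}: unknown keys {sorted(e)}"]
            )
    return out


def load_scheme(source) -> KineticScheme:
    """Load and validate a scheme from YAML (path, text, file object or dict).

    Top-level keys: ``species``, ``reactions``, optional
    ``conservation_groups``, optional ``plasma`` (name → nM overrides of
    initial/inflow concentrations) and optional ``perturbations`` (scheme-level
    edits applied after loading).
    """
    if isinstance(source, Mapping):
        doc = copy.deepcopy(dict(source))
    elif isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
        doc = yaml.safe_load(Path(source).read_text())
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        doc = yaml.safe_load(str(source))
    if not isinstance(doc, Mapping):
        raise SchemeValidationError(["document: not a mapping"])
    for key in ("species", "reactions"):
        if key not in doc:
            raise SchemeValidationError([f"document: missing required key '{key}'"])
    species = _parse_species(doc["species"])
    if "plasma" in doc and doc["plasma"]:
        overrides = {str(k): float(v) for k, v in dict(doc["plasma"]).items()}
        byname = {sp.name for sp in species}
        for name in overrides:
            if name not in byname:
                raise SchemeValidationError([f"plasma:{name}: unknown species"])
        species = [
            replace(sp, plasma_conc=overrides.get(sp.name, sp.plasma_conc))
            for sp in species
        ]
    groups = {
        str(k): tuple(v) for k, v in dict(doc.get("conservation_groups", {})).items()
    }
    scheme = KineticScheme(tuple(species), tuple(_parse_reactions(doc["reactions"])), groups)
    perts = [Perturbation.from_dict(p) for p in doc.get("perturbations", [])]
    if perts:
        scheme = apply_perturbations(scheme, perts)
    return scheme


def default_scheme() -> KineticScheme:
    """The packaged tissue-factor-pathway scheme (see the module docstring)."""
    with resources.files("clotflow.data").joinpath("default_scheme.yaml").open() as fh:
        return load_scheme(fh)


def apply_perturbations(
    scheme: KineticScheme, perturbations: Sequence[Perturbation | Mapping]
) -> KineticScheme:
    """Return a new scheme with the scheme-level edits applied in order.

    Scenario-level ops (activator length, gel thresholds) must be applied
    through a :class:`clotflow.experiments.ScenarioConfig`; passing one here
    raises :class:`PerturbationError`.  The input scheme is never mutated.
    """
    species = list(scheme.species)
    reactions = list(scheme.reactions)
    for p in perturbations:
        if not isinstance(p, Perturbation):
            p = Perturbation.from_dict(p)
        if p.op in SCENARIO_OPS:
            raise PerturbationError(
                f"edit {p.op}: scenario-level perturbation needs a ScenarioConfig"
            )
        if p.op == "zero_rate":
            rid = p.args["reaction"]
            hit = [i for i, rx in enumerate(reactions) if rx.id == rid]
            if not hit:
                raise PerturbationError(f"edit zero_rate: unknown reaction '{rid}'")
            rate_keys = {"k", "kcat", "k_on", "k_off"}
            for i in hit:
                rx = reactions[i]
                params = {
                    k: (0.0 if k in rate_keys else v) for k, v in rx.params.items()
                }
                reactions[i] = replace(rx, params=params)
        elif p.op == "add_species_conc":
            name, delta = p.args["species"], float(p.args["delta"])
            hit = [i for i, sp in enumerate(species) if sp.name == name]
            if not hit:
                raise PerturbationError(f"edit add_species_conc: unknown species '{name}'")
            (i,) = hit
            new_conc = species[i].plasma_conc + delta
            if new_conc < 0:
                raise PerturbationError(
                    f"edit add_species_conc: {name} concentration would go negative"
                )
            species[i] = replace(species[i], plasma_conc=new_conc)
        elif p.op == "set_convection":
            wanted = list(p.args["species"])
            on = bool(p.args["on"])
            byname = {sp.name: i for i, sp in enumerate(species)}
            for name in wanted:
                if name not in byname:
                    raise PerturbationError(
                        f"edit set_convection: unknown species '{name}'"
                    )
                i = byname[name]
                if species[i].surface_bound and on:
                    raise PerturbationError(
                        f"edit set_convection: {name} is surface-bound"
                    )
                species[i] = replace(species[i], convects=on)
        else:
            raise PerturbationError(f"unknown perturbation op: {p.op!r}")
    return KineticScheme(tuple(species), tuple(reactions), dict(scheme.conservation_groups))


def check_conservation(scheme: KineticScheme, trajectory: np.ndarray) -> dict[str, float]:
    """Max relative drift of each conservation-group total over a closed-system run.

    ``trajectory`` is ``(n_times, n_species)`` (columns ordered as
    ``scheme.names``).  For a group whose initial total is zero the absolute
    drift is reported instead.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] == 0:
        raise ValueError("trajectory must be a non-empty (n_times, n_species) array")
    if traj.shape[1] != scheme.n_species:
        raise ValueError("trajectory column count does not match scheme species")
    report = {}
    for gname, members in scheme.conservation_groups.items():
        cols = [scheme.index(sp) for sp in members]
        total = traj[:, cols].sum(axis=1)
        if total[0] > 0:
            report[gname] = float(np.max(np.abs(total - total[0])) / total[0])
        else:
            report[gname] = float(np.max(np.abs(total)))
    return report
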