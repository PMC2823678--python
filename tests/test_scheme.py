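"""Kinetic-scheme loading, validation, perturbation and rate evaluation."""

import numpy as np
import pytest

import clotflow as cf
from clotflow.fixtures import naive_rates
from clotflow.scheme import (
    Perturbation,
    PerturbationError,
    SchemeValidationError,
)


@pytest.fixture(scope="module")
def scheme():
    return cf.default_scheme()


class TestLoading:
    def test_default_scheme_has_the_xa_feedback(self, scheme):
        """The packaged network contains the Xa-catalysed activation of the
        TF-bound VII zymogen complex — the positive feedback."""
        rx = scheme.get_reaction("xa_activates_tf_vii")
        assert "Xa" in rx.reactants and "TF_VII" in rx.reactants
        assert "TF_VIIa" in rx.products and "Xa" in rx.products

    def test_feedback_is_the_only_tf_vii_to_tf_viia_path(self, scheme):
        """TF·VII converts to TF·VIIa only through the Xa feedback; the only
        other route to TF·VIIa is direct VIIa binding to TF."""
        producers = [
            rx for rx in scheme.reactions if rx.net_stoich().get("TF_VIIa", 0) > 0
        ]
        assert sorted(rx.id for rx in producers) == [
            "tf_viia_binding",
            "xa_activates_tf_vii",
        ]
        from_tfvii = [rx for rx in producers if rx.net_stoich().get("TF_VII", 0) < 0]
        assert [rx.id for rx in from_tfvii] == ["xa_activates_tf_vii"]

    def test_unknown_species_in_reaction_is_reported(self):
        doc = {
            "species": [{"name": "A", "role": "enzyme", "plasma_conc": 1.0}],
            "reactions": [
                {
                    "id": "bad",
                    "rate_law": "mass_action",
                    "reactants": {"FZz": 1},
                    "products": {"A": 1},
                    "params": {"k": 1.0},
                }
            ],
        }
        with pytest.raises(SchemeValidationError) as exc:
            cf.load_scheme(doc)
        assert "FZz" in str(exc.value)

    def test_negative_constant_is_rejected(self):
        doc = {
            "species": [{"name": "A", "role": "enzyme"}],
            "reactions": [
                {
                    "id": "bad",
                    "rate_law": "mass_action",
                    "reactants": {"A": 1},
                    "products": {},
                    "params": {"k": -1.0},
                }
            ],
        }
        with pytest.raises(SchemeValidationError):
            cf.load_scheme(doc)

    def test_minimal_two_species_scheme(self):
        doc = {
            "species": [
                {"name": "A", "role": "zymogen", "plasma_conc": 1.0},
                {"name": "B", "role": "enzyme"},
            ],
            "reactions": [
                {
                    "id": "a_to_b",
                    "rate_law": "mass_action",
                    "reactants": {"A": 1},
                    "products": {"B": 1},
                    "params": {"k": 0.1},
                }
            ],
        }
        s = cf.load_scheme(doc)
        assert s.n_species == 2 and len(s.reactions) == 1

    def test_validation_report_is_one_issue_per_line(self):
        doc = {
            "species": [{"name": "A", "role": "wrong", "plasma_conc": -1.0}],
            "reactions": [],
        }
        with pytest.raises(SchemeValidationError) as exc:
            cf.load_scheme(doc)
        lines = str(exc.value).splitlines()
        assert len(lines) == len(exc.value.issues) >= 2
        assert all(line.startswith("species:A:") for line in lines)

    def test_stoichiometric_audit_rejects_inconsistent_group(self):
        doc = {
            "species": [
                {"name": "A", "role": "zymogen", "plasma_conc": 1.0},
                {"name": "B", "role": "enzyme"},
            ],
            "reactions": [
                {
                    "id": "leak",
                    "rate_law": "mass_action",
                    "reactants": {"A": 1},
                    "products": {},
                    "params": {"k": 0.1},
                }
            ],
            "conservation_groups": {"ab": ["A", "B"]},
        }
        with pytest.raises(SchemeValidationError) as exc:
            cf.load_scheme(doc)
        assert "leak" in str(exc.value)

    def test_default_groups_are_audited_at_load(self, scheme):
        # loading succeeded, so every reaction conserves every group; spot-check
        for rx in scheme.reactions:
            net = rx.net_stoich()
            for members in scheme.conservation_groups.values():
                assert sum(net.get(sp, 0) for sp in members) == 0


class TestPerturbations:
    def test_zero_rate_only_touches_that_reaction(self, scheme):
        out = cf.apply_perturbations(
            scheme, [{"op": "zero_rate", "reaction": "xa_activates_tf_vii"}]
        )
        assert out.get_reaction("xa_activates_tf_vii").params["k"] == 0.0
        for rx in scheme.reactions:
            if rx.id != "xa_activates_tf_vii":
                assert out.get_reaction(rx.id).params == rx.params
        # original untouched
        assert scheme.get_reaction("xa_activates_tf_vii").params["k"] > 0

    def test_zero_rate_is_idempotent(self, scheme):
        p = [{"op": "zero_rate", "reaction": "iia_cleaves_fibrinogen"}]
        once = cf.apply_perturbations(scheme, p)
        twice = cf.apply_perturbations(once, p)
        assert once == twice

    def test_add_species_conc_raises_inflow_and_initial(self, scheme):
        out = cf.apply_perturbations(
            scheme, [{"op": "add_species_conc", "species": "VIIa", "delta": 10.0}]
        )
        assert out.get_species("VIIa").plasma_conc == pytest.approx(10.1)
        i = out.index("VIIa")
        assert out.plasma_vector()[i] == pytest.approx(10.1)

    def test_empty_perturbation_list_is_identity(self, scheme):
        assert cf.apply_perturbations(scheme, []) == scheme

    def test_unresolvable_reference_names_the_edit(self, scheme):
        with pytest.raises(PerturbationError) as exc:
            cf.apply_perturbations(scheme, [{"op": "zero_rate", "reaction": "nope"}])
        assert "zero_rate" in str(exc.value) and "nope" in str(exc.value)

    def test_convection_toggle(self, scheme):
        out = cf.apply_perturbations(
            scheme, [{"op": "set_convection", "species": ["Xa", "IIa"], "on": False}]
        )
        assert not out.get_species("Xa").convects
        assert not out.get_species("IIa").convects
        assert out.get_species("Va").convects

    def test_surface_species_cannot_convect(self, scheme):
        with pytest.raises(PerturbationError):
            cf.apply_perturbations(
                scheme, [{"op": "set_convection", "species": ["TF"], "on": True}]
            )

    def test_scenario_level_edit_requires_scenario(self, scheme):
        with pytest.raises(PerturbationError):
            cf.apply_perturbations(
                scheme, [{"op": "set_gel_threshold", "value": 760.0}]
            )


class TestRates:
    def test_zero_concentrations_give_zero_rates(self, scheme):
        rates = cf.evaluate_rates(np.zeros(scheme.n_species), scheme)
        assert np.all(rates == 0.0)

    def test_bimolecular_unit_rate(self):
        doc = {
            "species": [
                {"name": "A", "role": "enzyme", "plasma_conc": 1.0},
                {"name": "B", "role": "enzyme", "plasma_conc": 1.0},
                {"name": "C", "role": "complex"},
            ],
            "reactions": [
                {
                    "id": "ab",
                    "rate_law": "mass_action",
                    "reactants": {"A": 1, "B": 1},
                    "products": {"C": 1},
                    "params": {"k": 1.0},
                }
            ],
        }
        s = cf.load_scheme(doc)
        rates = cf.evaluate_rates(np.array([1.0, 1.0, 0.0]), s)
        assert rates[s.index("C")] == pytest.approx(1.0)
        assert rates[s.index("A")] == pytest.approx(-1.0)

    def test_matches_naive_per_reaction_oracle(self, scheme):
        """Compiled evaluator vs an independent brute-force loop, at the
        plasma state and at random positive states."""
        plasma = scheme.plasma_vector()
        ref = naive_rates(plasma, scheme)
        got = cf.evaluate_rates(plasma, scheme)
        np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-14)
        rng = np.random.default_rng(42)
        for _ in range(10):
            c = rng.uniform(0.0, 500.0, scheme.n_species)
            np.testing.assert_allclose(
                cf.evaluate_rates(c, scheme), naive_rates(c, scheme),
                rtol=1e-12, atol=1e-10,
            )

    def test_gridded_evaluation_matches_per_cell(self, scheme):
        rng = np.random.default_rng(7)
        C = rng.uniform(0.0, 50.0, (scheme.n_species, 3, 4))
        got = cf.evaluate_rates(C, scheme)
        for j in range(3):
            for i in range(4):
                np.testing.assert_allclose(
                    got[:, j, i], naive_rates(C[:, j, i], scheme), rtol=1e-12, atol=1e-10
                )

    def test_negative_concentration_rejected(self, scheme):
        c = scheme.plasma_vector()
        c[0] = -1.0
        with pytest.raises(ValueError):
            cf.evaluate_rates(c, scheme)


class TestConservationCheck:
    def test_constant_trajectory_has_zero_drift(self, scheme):
        c = scheme.plasma_vector()
        traj = np.tile(c, (5, 1))
        report = cf.check_conservation(scheme, traj)
        assert max(report.values()) == 0.0

    def test_injected_violation_is_reported(self, scheme):
        c = scheme.plasma_vector()
        traj = np.tile(c, (3, 1))
        traj[-1, scheme.index("X")] *= 2.0  # break the X group by construction
        report = cf.check_conservation(scheme, traj)
        assert report["X_core"] > 0.1

    def test_empty_trajectory_is_an_error(self, scheme):
        with pytest.raises(ValueError):
            cf.check_conservation(scheme, np.empty((0, scheme.n_species)))
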