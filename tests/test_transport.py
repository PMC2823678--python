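"""Transport/reaction integrator: advection, diffusion, gelation, boundary
behaviour and conservation."""

import numpy as np
import pytest

import clotflow as cf
from clotflow.fixtures import (
    make_advection_case,
    make_diffusion_case,
    make_zerod_oracle,
    run_advection_case,
    run_diffusion_case,
    single_cell_domain,
)
from clotflow.hemodynamics import DomainSpec, FlowState, shear_to_drive, solve_flow
from clotflow.scheme import KineticScheme, SpeciesSpec
from clotflow.transport import (
    GelationParams,
    IntegratorConfig,
    advance,
    initialize_state,
    update_gel,
)


def inert_scheme(D=50.0, convects=True, plasma=1.0):
    return KineticScheme(
        species=(
            SpeciesSpec(name="A", role="complex", plasma_conc=plasma,
                        diffusion_coeff=D, convects=convects),
        ),
        reactions=(),
    )


def uniform_flow(dom, u):
    return FlowState(
        u=np.full((dom.ny, dom.nx + 1), float(u)),
        v=np.zeros((dom.ny + 1, dom.nx)),
        p=np.zeros((dom.ny, dom.nx)),
        drive=0.0,
        target_wall_shear=0.0,
    )


class TestInitializeState:
    def test_plasma_everywhere_and_tf_on_activator(self):
        scheme = cf.default_scheme()
        dom = DomainSpec(dx=50.0)
        state = initialize_state(dom, scheme)
        viia = state.conc[scheme.index("VIIa")]
        assert np.all(viia == pytest.approx(0.1))
        tf = state.conc[scheme.index("TF")]
        act = dom.activator_mask()
        assert np.all(tf[0, act] > 0)
        assert np.all(tf[0, ~act] == 0) and np.all(tf[1:] == 0)
        assert state.time == 0.0 and np.all(state.conc[scheme.index("Fn")] == 0)

    def test_zero_activator_length_means_no_tf(self):
        scheme = cf.default_scheme()
        dom = DomainSpec(activator_length=0.0, dx=50.0)
        state = initialize_state(dom, scheme)
        assert np.all(state.conc[scheme.index("TF")] == 0)

    def test_states_identical_outside_the_activator_interval(self):
        scheme = cf.default_scheme()
        s1 = initialize_state(DomainSpec(activator_length=500.0, dx=50.0), scheme)
        s2 = initialize_state(DomainSpec(activator_length=1000.0, dx=50.0), scheme)
        # columns past the longer activator agree everywhere
        np.testing.assert_array_equal(s1.conc[:, :, 40:], s2.conc[:, :, 40:])


class TestAdvance:
    def test_uniform_field_is_invariant(self):
        """Advection + diffusion of a constant field with matching inlet
        composition changes nothing."""
        scheme = inert_scheme(plasma=3.7)
        dom = DomainSpec(length_x=2000, height_y=500, activator_start=0,
                         activator_length=50, dx=50.0)
        flow = uniform_flow(dom, 400.0)
        state = initialize_state(dom, scheme)
        out = advance(state, scheme, flow, 0.05, dom, IntegratorConfig())
        np.testing.assert_allclose(out.conc, state.conc, rtol=1e-13)

    def test_gaussian_pulse_advects_at_the_flow_speed(self):
        case = make_advection_case(u=1000.0, sigma0=200.0, dx=25.0)
        err = run_advection_case(case, t_end=1.0)
        assert err <= case.tolerance
        assert err > case.tolerance / 100  # tolerance is not vacuous
        assert case.meta["mass_ratio"] == pytest.approx(1.0, abs=1e-10)

    def test_point_release_follows_the_heat_kernel(self):
        case = make_diffusion_case(D=50.0, sigma0=100.0, dx=25.0)
        err = run_diffusion_case(case, t_end=50.0)
        assert err <= case.tolerance
        assert err > case.tolerance / 100

    def test_non_convecting_species_ignores_the_flow(self):
        scheme = inert_scheme(D=0.0, convects=False, plasma=0.0)
        dom = DomainSpec(length_x=2000, height_y=500, activator_start=0,
                         activator_length=50, dx=50.0)
        flow = uniform_flow(dom, 500.0)
        state = initialize_state(dom, scheme)
        state.conc[0, 3, 10] = 42.0
        out = state
        for _ in range(20):
            out = advance(out, scheme, flow, 0.05, dom, IntegratorConfig())
        np.testing.assert_array_equal(out.conc, state.conc)

    def test_cfl_violation_is_rejected(self):
        scheme = inert_scheme()
        dom = DomainSpec(length_x=2000, height_y=500, activator_start=0,
                         activator_length=50, dx=50.0)
        flow = uniform_flow(dom, 1000.0)
        state = initialize_state(dom, scheme)
        with pytest.raises(ValueError, match="CFL"):
            advance(state, scheme, flow, 1.0, dom, IntegratorConfig())

    def test_inlet_washout_relaxes_to_plasma(self):
        """An initially empty channel perfused with plasma approaches the
        inlet composition throughout."""
        scheme = inert_scheme(D=50.0, plasma=5.0)
        dom = DomainSpec(length_x=1000, height_y=200, activator_start=0,
                         activator_length=50, dx=50.0)
        flow = uniform_flow(dom, 500.0)
        state = initialize_state(dom, scheme)
        state.conc[:] = 0.0
        cfg = IntegratorConfig()
        for _ in range(100):
            state = advance(state, scheme, flow, 0.05, dom, cfg)
        assert np.all(state.conc[0] > 4.9)


class TestClosedBoxConservation:
    def test_default_scheme_groups_conserved(self):
        """A closed-box run of the full cascade keeps every conservation
        group total within 1e-6 relative drift."""
        scheme = cf.default_scheme()
        dom = DomainSpec(length_x=200, height_y=200, activator_start=0,
                         activator_length=200, dx=50.0)
        cfg = IntegratorConfig(closed_box=True)
        flow = uniform_flow(dom, 0.0)
        state = initialize_state(dom, scheme)
        totals = [state.conc.sum(axis=(1, 2))]
        for _ in range(60):
            state = advance(state, scheme, flow, 1.0, dom, cfg)
            totals.append(state.conc.sum(axis=(1, 2)))
        report = cf.check_conservation(scheme, np.array(totals))
        assert max(report.values()) <= 1e-6


class TestZeroDOracle:
    def test_single_cell_matches_reference_integration(self):
        """The spatial reaction sub-stepper in a one-cell closed box agrees
        with an independent LSODA reference to 0.1% at all output times."""
        scheme = cf.default_scheme()
        dom = single_cell_domain(dx=50.0)
        state = initialize_state(dom, scheme)
        c0 = state.conc[:, 0, 0].copy()
        t_end = 240.0
        flow = uniform_flow(dom, 0.0)
        cfg = IntegratorConfig(closed_box=True, dt_max=1.0)
        times, traj = [0.0], [c0.copy()]
        while state.time < t_end - 1e-9:
            state = advance(state, scheme, flow, 1.0, dom, cfg)
            times.append(state.time)
            traj.append(state.conc[:, 0, 0].copy())
        ref_t, ref = make_zerod_oracle(scheme, t_end, c0, t_eval=np.array(times))
        traj = np.array(traj)
        mask = ref > 1e-6  # nM floor: relative error on resolvable levels
        rel = np.abs(traj - ref) / np.maximum(ref, 1e-6)
        assert rel[mask].max() <= 1e-3

    def test_oracle_conserves_groups(self):
        scheme = cf.default_scheme()
        dom = single_cell_domain(dx=50.0)
        c0 = initialize_state(dom, scheme).conc[:, 0, 0]
        _, ref = make_zerod_oracle(scheme, 120.0, c0)
        report = cf.check_conservation(scheme, ref)
        assert max(report.values()) <= 1e-9


class TestGelation:
    def make_state(self, fn_value):
        scheme = cf.default_scheme()
        dom = DomainSpec(dx=50.0)
        state = initialize_state(dom, scheme)
        state.conc[scheme.index("Fn"), 0, 25] = fn_value
        return scheme, dom, state

    def test_above_gel_point_blocks_permeability(self):
        scheme, dom, state = self.make_state(500.0)
        out, changed = update_gel(state, GelationParams(), scheme)
        assert changed and out.permeability[0, 25] == 0.0
        assert out.gel_mask[0, 25] and not out.solid_mask[0, 25]

    def test_below_gel_point_stays_open(self):
        scheme, dom, state = self.make_state(400.0)
        out, changed = update_gel(state, GelationParams(), scheme)
        assert not changed and np.all(out.permeability == 1.0)

    def test_zero_fibrin_is_fully_permeable(self):
        scheme, dom, state = self.make_state(0.0)
        out, changed = update_gel(state, GelationParams(), scheme)
        assert not changed and np.all(out.permeability == 1.0)

    def test_solid_threshold(self):
        scheme, dom, state = self.make_state(4000.0)
        out, _ = update_gel(state, GelationParams(), scheme)
        assert out.solid_mask[0, 25] and out.gel_mask[0, 25]

    def test_masks_are_monotone(self):
        scheme, dom, state = self.make_state(500.0)
        out, _ = update_gel(state, GelationParams(), scheme)
        out.conc[scheme.index("Fn"), 0, 25] = 0.0  # fibrin cannot un-gel a cell
        out2, changed = update_gel(out, GelationParams(), scheme)
        assert not changed and out2.gel_mask[0, 25]

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            GelationParams(gel_threshold=0.0)
        with pytest.raises(ValueError):
            GelationParams(gel_threshold=1000.0, solid_threshold=500.0)


def test_field_vtk_snapshot(tmp_path):
    from clotflow.transport import save_fields_vtk

    scheme = cf.default_scheme()
    dom = DomainSpec(dx=50.0)
    state = initialize_state(dom, scheme)
    path = tmp_path / "fields.vtk"
    save_fields_vtk(state, scheme, dom, path, species=("Fn", "VIIa"))
    text = path.read_text()
    assert "SCALARS Fn" in text and "SCALARS VIIa" in text and "SCALARS gel" in text


def test_numpy_fallback_matches_numba_kernels():
    """The pure-numpy transport path is the reference for the compiled
    kernels: both must produce the same fields step for step."""
    from clotflow import _kernels

    if not _kernels.HAVE_NUMBA:
        return  # already running on the reference path
    scheme = cf.default_scheme()
    dom = DomainSpec(length_x=1000, height_y=500, activator_start=250,
                     activator_length=500, dx=50.0)
    drive, _ = shear_to_drive(2.0, dom)
    flow = solve_flow(dom, None, drive, 2.0)
    cfg = IntegratorConfig()
    dt = 0.05
    s_fast = initialize_state(dom, scheme)
    for _ in range(10):
        s_fast = advance(s_fast, scheme, flow, dt, dom, cfg)
    _kernels.HAVE_NUMBA = False
    try:
        s_ref = initialize_state(dom, scheme)
        for _ in range(10):
            s_ref = advance(s_ref, scheme, flow, dt, dom, cfg)
    finally:
        _kernels.HAVE_NUMBA = True
    np.testing.assert_allclose(s_fast.conc, s_ref.conc, rtol=1e-9, atol=1e-12)
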