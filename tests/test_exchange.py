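"""Isotopologue transfer matrix, simulation, eigenvalues and calibration."""

import numpy as np
import pytest
from scipy.linalg import expm

from mims18o.carbonate import AssayConditions, speciate, uncatalyzed_rates
from mims18o.exchange import (
    EnzymePool,
    Event,
    IsotopologueState,
    Layout,
    NonEquilibriumError,
    atom_exchange_eigenvalue,
    build_transfer_matrix,
    calibrate_activity_to_kobs,
    catalyzed_flux,
    initial_isotope_state,
    run_assay,
    simulate_trace,
    slow_eigenvalue,
    titration_factor,
)
from mims18o.fitting import fit_first_order
from mims18o.synthetic import build_layout, standard_conditions


def make_pool(concentration=4.1e-9, a=3.8e7, pka=6.2, compartment="exofacial"):
    return EnzymePool(
        name="CA",
        compartment=compartment,
        concentration=concentration,
        efficiency_max=a,
        pKa_apparent=pka,
    )


class TestInitialState:
    def test_full_enrichment_occupies_top_states(self, conditions):
        spec = speciate(conditions)
        st = initial_isotope_state(spec, 1.0)
        assert st.co2[0] == pytest.approx([0.0, 0.0, spec.co2])
        assert st.hco3[0] == pytest.approx([0.0, 0.0, 0.0, spec.hco3])

    def test_zero_enrichment_is_unlabeled(self, conditions):
        st = initial_isotope_state(speciate(conditions), 0.0)
        assert st.alpha() == 0.0
        assert st.co2[0][1:] == pytest.approx([0.0, 0.0])

    def test_half_enrichment_is_binomial(self, conditions):
        spec = speciate(conditions)
        st = initial_isotope_state(spec, 0.5)
        assert st.co2[0] / spec.co2 == pytest.approx([0.25, 0.5, 0.25])
        assert st.hco3[0] / spec.hco3 == pytest.approx([0.125, 0.375, 0.375, 0.125])
        assert st.alpha() == pytest.approx(0.5)


class TestCatalyzedFlux:
    def test_zero_enzyme_gives_zero_flux(self, conditions):
        pool = make_pool(concentration=0.0)
        assert catalyzed_flux(pool, speciate(conditions), 7.4) == 0.0

    def test_high_ph_reaches_maximal_efficiency(self, conditions):
        spec = speciate(conditions.at_ph(9.0))
        pool = make_pool(pka=5.0)
        r1 = catalyzed_flux(pool, spec, 9.0)
        assert r1 == pytest.approx(
            pool.efficiency_max * pool.concentration * spec.co2, rel=1e-4
        )

    def test_caix_flux_matches_direct_arithmetic(self, conditions):
        spec = speciate(conditions)
        pool = make_pool()
        r1_over_e = catalyzed_flux(pool, spec, 7.4) / pool.concentration
        expected = 3.8e7 * spec.co2 / (1.0 + 10.0 ** (6.2 - 7.4))
        assert r1_over_e == pytest.approx(expected, rel=1e-12)

    def test_negative_inhibitor_concentration_rejected(self, conditions, caix_ghost):
        pool = caix_ghost.pools[0]
        with pytest.raises(ValueError, match="negative"):
            catalyzed_flux(pool, speciate(conditions), 7.4, {"N-3500": -1e-6})


class TestTransferMatrix:
    def test_no_fluxes_give_zero_matrix(self, conditions):
        tm = build_transfer_matrix(Layout(pools=()), conditions, k_h_16c=0.0)
        assert np.all(tm.matrix == 0.0)

    def test_chemical_columns_conserve_molecules(self, conditions, caix_ghost):
        # every column of the chemical block sums to zero: interconversion
        # moves molecules between species, never creates or destroys them
        tm = build_transfer_matrix(caix_ghost, conditions)
        chem = tm.matrix[:-1, :-1]
        assert np.abs(chem.sum(axis=0)).max() < 1e-15 * np.abs(chem).max()

    def test_rejects_non_equilibrium_speciation(self, conditions, caix_ghost):
        from mims18o.carbonate import CarbonateSpeciation

        bad = CarbonateSpeciation(co2=0.01, hco3=0.015, pk1_apparent=6.35)
        with pytest.raises(NonEquilibriumError, match="equilibrium"):
            build_transfer_matrix(caix_ghost, conditions, speciation=bad)

    def test_rejects_pool_outside_layout_compartments(self, conditions):
        # an intracellular pool forces a two-compartment layout, which then
        # requires positive cell volume; removing the cell density must fail
        lay = Layout(pools=(make_pool(compartment="intracellular"),))
        no_cells = AssayConditions(ph=7.4, cell_density=0.0)
        with pytest.raises(ValueError, match="cell"):
            build_transfer_matrix(lay, no_cells)


class TestSimulation:
    def test_alpha_never_increases(self, conditions, caix_ghost):
        trace = run_assay(caix_ghost, conditions)
        assert np.all(np.diff(trace.alpha) <= 1e-12)

    def test_expm_and_ivp_agree(self, conditions):
        layout = build_layout("UFH001_hypoxic", conditions)
        t1 = run_assay(layout, conditions, method="expm")
        t2 = run_assay(layout, conditions, method="ivp")
        assert np.abs(t1.alpha - t2.alpha).max() < 1e-8

    def test_whole_cell_curve_is_biphasic(self, conditions):
        layout = build_layout("UFH001_hypoxic", conditions)
        trace = run_assay(layout, conditions)
        early = fit_first_order(trace, (130, 180))
        late = fit_first_order(trace, (250, 450))
        assert early.k_obs > 2.0 * late.k_obs

    def test_ghost_curve_is_log_linear_late(self, conditions, caix_ghost):
        trace = run_assay(caix_ghost, conditions)
        late = fit_first_order(trace, (250, 450))
        assert late.r_squared > 1.0 - 1e-8

    def test_conservation_and_label_budget(self, conditions):
        layout = build_layout("UFH001_hypoxic", conditions)
        tm = build_transfer_matrix(layout, conditions)
        spec = speciate(conditions)
        st0 = initial_isotope_state(spec, 0.2, n_compartments=2)
        v = st0.to_vector()
        budget0 = st0.labeled_atoms(tm.volumes)
        prop = expm(tm.matrix * 100.0)
        for _ in range(5):
            v = prop @ v
        st = IsotopologueState.from_vector(v, 2)
        assert st.co2.sum(axis=1) == pytest.approx(st0.co2.sum(axis=1), rel=1e-9)
        assert st.hco3.sum(axis=1) == pytest.approx(st0.hco3.sum(axis=1), rel=1e-9)
        budget = st.labeled_atoms(tm.volumes) + st.released_18o
        assert budget == pytest.approx(budget0, rel=1e-9)

    def test_event_outside_span_rejected(self, conditions, caix_ghost):
        tm = build_transfer_matrix(caix_ghost, conditions)
        st0 = initial_isotope_state(tm.speciation, 0.2)
        ev = Event(time=999.0, matrix=tm, transform=lambda s: s)
        with pytest.raises(ValueError, match="outside"):
            simulate_trace(st0, tm, np.arange(0.0, 100.0), events=[ev])


class TestSlowEigenvalue:
    def test_zero_matrix_has_zero_eigenvalue(self, conditions):
        tm = build_transfer_matrix(Layout(pools=()), conditions, k_h_16c=0.0)
        assert slow_eigenvalue(tm) == 0.0

    def test_scales_linearly_with_fluxes(self, conditions, caix_ghost):
        from dataclasses import replace

        tm1 = build_transfer_matrix(caix_ghost, conditions, k_h_16c=0.0)
        doubled = caix_ghost.scale_exofacial(2.0)
        tm2 = build_transfer_matrix(doubled, conditions, k_h_16c=0.0)
        assert slow_eigenvalue(tm2) == pytest.approx(
            2.0 * slow_eigenvalue(tm1), rel=1e-9
        )

    def test_matches_closed_form_atom_eigenvalue(self, conditions, caix_ghost):
        spec = speciate(conditions)
        rates = uncatalyzed_rates(spec)
        flux = catalyzed_flux(caix_ghost.pools[0], spec, 7.4) + rates.k_h * spec.co2
        expected = atom_exchange_eigenvalue(flux / spec.co2, flux / spec.hco3)
        tm = build_transfer_matrix(caix_ghost, conditions)
        assert slow_eigenvalue(tm) == pytest.approx(expected, rel=1e-10)

    def test_matches_uncatalyzed_trace_decay(self, conditions):
        # enzyme-free system: simulated decay equals the eigenvalue to <0.1%
        layout = Layout(pools=())
        tm = build_transfer_matrix(layout, conditions)
        spec = speciate(conditions)
        st0 = initial_isotope_state(spec, 0.2)
        times = np.arange(0.0, 20001.0, 50.0)  # background is slow (~3e-5 1/s)
        trace = simulate_trace(st0, tm, times)
        fit = fit_first_order(trace, (10000, 20000))
        assert fit.k_obs == pytest.approx(slow_eigenvalue(tm), rel=1e-3)

    def test_larger_enzyme_concentration_raises_eigenvalue(self, conditions, caix_ghost):
        eigs = [
            slow_eigenvalue(
                build_transfer_matrix(caix_ghost.scale_exofacial(s), conditions)
            )
            for s in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(eigs, eigs[1:]))


class TestCalibration:
    def test_background_target_returns_zero_concentration(self, conditions, caix_ghost):
        bg = slow_eigenvalue(
            build_transfer_matrix(
                caix_ghost.with_exofacial_concentration(0.0), conditions
            )
        )
        lay = calibrate_activity_to_kobs(bg, caix_ghost, conditions)
        assert lay.pools[0].concentration == 0.0

    def test_below_background_rejected_with_value(self, conditions, caix_ghost):
        with pytest.raises(ValueError, match="background"):
            calibrate_activity_to_kobs(1e-9, caix_ghost, conditions)

    def test_concentration_monotone_in_target(self, conditions, caix_ghost):
        ks = (5e-4, 1e-3, 2e-3, 4e-3)
        concs = [
            calibrate_activity_to_kobs(k, caix_ghost, conditions).pools[0].concentration
            for k in ks
        ]
        assert all(a < b for a, b in zip(concs, concs[1:]))

    def test_round_trip_through_simulation(self, conditions, caix_ghost):
        k_target = 2.5e-3
        lay = calibrate_activity_to_kobs(k_target, caix_ghost, conditions)
        assert slow_eigenvalue(
            build_transfer_matrix(lay, conditions)
        ) == pytest.approx(k_target, rel=1e-6)
        trace = run_assay(lay, conditions)
        fit = fit_first_order(trace, (250, 450))
        assert fit.k_obs == pytest.approx(k_target, rel=1e-3)


class TestTitrationFactor:
    def test_half_activation_at_pka(self):
        assert titration_factor(6.2, 6.2) == 0.5

    def test_monotone_in_ph(self):
        fs = [titration_factor(6.2, ph) for ph in (5.0, 6.0, 7.0, 8.0)]
        assert all(a < b for a, b in zip(fs, fs[1:]))
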