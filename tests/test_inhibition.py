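"""Classical and tight-binding inhibition, enzyme quantification, compartment
selectivity of impermeant inhibitors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mims18o.exchange import build_transfer_matrix, slow_eigenvalue
from mims18o.inhibition import (
    InhibitionSeries,
    UnidentifiableError,
    apply_impermeant_inhibitor,
    estimate_enzyme_conc,
    fit_classical_ki,
    fractional_activity,
)
from mims18o.synthetic import build_layout, generate_inhibition_series


class TestFractionalActivity:
    def test_no_inhibitor_full_activity(self):
        assert fractional_activity(1e-9, 0.0, 1e-6, "classical") == 1.0
        assert fractional_activity(1e-9, 0.0, 1e-9, "tight") == 1.0

    def test_classical_half_at_ki(self):
        assert fractional_activity(1e-9, 12.6e-6, 12.6e-6, "classical") == 0.5

    def test_tight_stoichiometric_titration(self):
        # Kd -> 0 with I >= E: every active site is occupied
        act = fractional_activity(4.1e-9, 4.1e-9, 1e-18, "tight")
        assert act == pytest.approx(0.0, abs=1e-4)

    def test_tight_converges_to_classical_when_enzyme_dilute(self):
        kd = 1e-6
        for i in (1e-7, 1e-6, 1e-5):
            tight = fractional_activity(kd / 200.0, i, kd, "tight")
            classical = fractional_activity(0.0, i, kd, "classical")
            assert tight == pytest.approx(classical, rel=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(
        e=st.floats(1e-12, 1e-6),
        k=st.floats(1e-12, 1e-3),
        mode=st.sampled_from(["classical", "tight"]),
    )
    def test_monotone_non_increasing_in_inhibitor(self, e, k, mode):
        grid = np.logspace(-12, -2, 12)
        acts = [fractional_activity(e, i, k, mode) for i in grid]
        assert all(a >= b - 1e-12 for a, b in zip(acts, acts[1:]))

    def test_tight_mode_requires_enzyme(self):
        with pytest.raises(ValueError, match="enzyme"):
            fractional_activity(0.0, 1e-9, 1e-9, "tight")


class TestEstimateEnzymeConc:
    def test_caix_ghost_titration_recovers_4_1_nM(self):
        series = generate_inhibition_series("CAIX", "ethoxzolamide")
        fit = estimate_enzyme_conc(series)
        assert fit.e_total == pytest.approx(4.1e-9, rel=1e-6)

    def test_caxii_ghost_titration_recovers_31_4_nM(self):
        series = generate_inhibition_series("CAXII", "ethoxzolamide")
        fit = estimate_enzyme_conc(series)
        assert fit.e_total == pytest.approx(31.4e-9, rel=1e-6)

    def test_known_kd_variant(self):
        series = generate_inhibition_series("CAIX", "ethoxzolamide")
        fit = estimate_enzyme_conc(series, kd_known=1e-9)
        assert fit.e_total == pytest.approx(4.1e-9, rel=1e-9)

    def test_classical_regime_unidentifiable(self):
        # E far below Kd: the dose-response carries no information on E_total
        e, kd = 1e-12, 1e-6
        conc = (0.0, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5)
        act = tuple(fractional_activity(e, c, kd, "tight") for c in conc)
        series = InhibitionSeries("ez", conc, act)
        with pytest.raises(UnidentifiableError, match="classical"):
            estimate_enzyme_conc(series)

    def test_series_not_spanning_titration_rejected(self):
        conc = (0.0, 1e-10, 2e-10, 3e-10, 4e-10, 5e-10)
        act = tuple(fractional_activity(4.1e-9, c, 1e-9, "tight") for c in conc)
        series = InhibitionSeries("ez", conc, act)
        with pytest.raises(ValueError, match="span"):
            estimate_enzyme_conc(series)

    def test_noisy_round_trip_median_bias_under_5_percent(self):
        """2% activity noise, 200 seeds: median recovered E within 5% of 4.1 nM."""
        estimates = []
        for seed in range(200):
            series = generate_inhibition_series(
                "CAIX", "ethoxzolamide", noise_sd=0.02, seed=seed
            )
            try:
                estimates.append(estimate_enzyme_conc(series).e_total)
            except (UnidentifiableError, RuntimeError, ValueError):
                continue
        assert len(estimates) > 150
        assert abs(np.median(estimates) / 4.1e-9 - 1.0) < 0.05


class TestClassicalKiFit:
    def test_n3500_series_recovers_ki(self):
        series = generate_inhibition_series("CAIX", "N-3500")
        ki, _se = fit_classical_ki(series)
        assert ki == pytest.approx(12.6e-6, rel=1e-6)


class TestApplyImpermeantInhibitor:
    def test_zero_concentration_leaves_layout_unchanged(self, caix_ghost):
        out = apply_impermeant_inhibitor(caix_ghost, "N-3500", 0.0)
        assert out == caix_ghost

    def test_millimolar_n3500_blocks_ghost_activity(self, conditions, caix_ghost):
        """1 mM N-3500 (Ki 12.6 uM) leaves ~1.2% exofacial activity and drives
        the observed rate essentially to the uncatalyzed background."""
        blocked = apply_impermeant_inhibitor(caix_ghost, "N-3500", 1e-3)
        frac = blocked.pools[0].concentration / caix_ghost.pools[0].concentration
        assert frac == pytest.approx(1.0 / (1.0 + 1e-3 / 12.6e-6), rel=1e-9)
        assert frac < 0.02
        k_full = slow_eigenvalue(build_transfer_matrix(caix_ghost, conditions))
        k_blocked = slow_eigenvalue(build_transfer_matrix(blocked, conditions))
        k_bg = slow_eigenvalue(
            build_transfer_matrix(
                caix_ghost.with_exofacial_concentration(0.0), conditions
            )
        )
        assert (k_blocked - k_bg) / (k_full - k_bg) < 0.03

    def test_full_inhibition_recovers_background_exactly(self, conditions, caix_ghost):
        saturated = apply_impermeant_inhibitor(caix_ghost, "N-3500", float("inf"))
        k_sat = slow_eigenvalue(build_transfer_matrix(saturated, conditions))
        k_bg = slow_eigenvalue(
            build_transfer_matrix(
                caix_ghost.with_exofacial_concentration(0.0), conditions
            )
        )
        assert k_sat == pytest.approx(k_bg, rel=1e-3)

    def test_impermeant_inhibitor_spares_intracellular_pool(self, conditions):
        layout = build_layout("UFH001_hypoxic", conditions)
        blocked = apply_impermeant_inhibitor(layout, "N-3500", 1e-3)
        caii_before = [p for p in layout.pools if p.compartment == "intracellular"]
        caii_after = [p for p in blocked.pools if p.compartment == "intracellular"]
        assert caii_after == caii_before
        exo_after = [p for p in blocked.pools if p.compartment == "exofacial"]
        exo_before = [p for p in layout.pools if p.compartment == "exofacial"]
        assert exo_after[0].concentration < 0.02 * exo_before[0].concentration

    def test_unknown_inhibitor_rejected(self, caix_ghost):
        with pytest.raises(KeyError, match="mystery"):
            apply_impermeant_inhibitor(caix_ghost, "mystery", 1e-6)
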