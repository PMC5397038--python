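"""Generator contracts: determinism, hierarchy, forward-inverse consistency."""

import numpy as np
import pytest

from cellmech import FitConfig, gaussian_trim_fit
from cellmech.pipeline import process_curve, process_curves, qc_filter
from cellmech.simulate import (
    AfmGroupSpec,
    CohortSpec,
    simulate_afm_experiment,
    simulate_beta_cohort,
    simulate_force_curve,
)


class TestForceCurveGenerator:
    def test_same_seed_bit_identical(self, probe):
        spec = AfmGroupSpec(label="g", e_mean=1.0, e_sd_between_cells=0.1)
        a = simulate_force_curve(1.0, probe, spec, seed=9)
        b = simulate_force_curve(1.0, probe, spec, seed=9)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.deflection, b.deflection)

    def test_noise_free_recovery(self, probe, fit_config):
        spec = AfmGroupSpec(label="g", e_mean=0.8, e_sd_between_cells=0,
                            deflection_noise_sd=0, substrate_stiffening=0)
        est = process_curve(simulate_force_curve(0.8, probe, spec, 3),
                            probe, fit_config)
        assert est.young_modulus == pytest.approx(0.8, rel=1e-6)

    def test_substrate_regime_inflates_full_depth_fit(self, probe):
        spec = AfmGroupSpec(label="g", e_mean=1.0, e_sd_between_cells=0,
                            deflection_noise_sd=0, substrate_stiffening=3.0)
        c = simulate_force_curve(1.0, probe, spec, 4)
        e_win = process_curve(c, probe, FitConfig(max_indentation=300)).young_modulus
        e_full = process_curve(
            c, probe, FitConfig(max_indentation=600, r2_min=0.5)
        ).young_modulus
        assert e_full > e_win


class TestExperimentHierarchy:
    def test_curve_counting(self, probe):
        spec = AfmGroupSpec(label="g", e_mean=1.0, e_sd_between_cells=0.1,
                            n_cells=3, points_per_cell=4, curves_per_point=2)
        curves, truth = simulate_afm_experiment([spec], probe)
        assert len(curves) == 3 * 4 * 2
        assert len(truth) == 24
        assert {c.meta.cell for c in curves} == {0, 1, 2}

    def test_degenerate_hierarchy_tracks_group_mean(self, probe, fit_config):
        spec = AfmGroupSpec(label="g", e_mean=1.5, e_sd_between_cells=0,
                            n_cells=2, points_per_cell=3, curves_per_point=4,
                            deflection_noise_sd=0.003)
        curves, _ = simulate_afm_experiment([spec], probe)
        ests = process_curves(curves, probe, fit_config)
        E = np.array([e.young_modulus for e in ests if e.accepted])
        assert np.allclose(E, 1.5, rtol=0.05)

    def test_equal_specs_different_seeds_agree(self, probe, fit_config):
        """Group-mean recovered moduli from two independently seeded
        replicates of the same conditions differ by < 3 SE."""
        results = []
        for seed in (11, 22):
            spec = AfmGroupSpec.from_reported("g", 1.28, 0.37, seed=seed,
                                              n_cells=6)
            curves, _ = simulate_afm_experiment([spec], probe)
            acc, _ = qc_filter(process_curves(curves, probe, fit_config), fit_config)
            E = np.array([e.young_modulus for e in acc])
            results.append(E)
        a, b = results
        # hierarchy-aware SE: cells dominate the group-mean uncertainty
        se = np.sqrt(sum(
            np.var([e for e in x]) / x.size + (0.15 * 0.37) ** 2 / 6
            for x in (a, b)
        ))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_truth_table_matches_metadata(self, probe):
        spec = AfmGroupSpec(label="g", e_mean=1.0, e_sd_between_cells=0.05,
                            n_cells=2, points_per_cell=2, curves_per_point=2)
        curves, truth = simulate_afm_experiment([spec], probe)
        for c, (_, row) in zip(curves, truth.iterrows()):
            assert (c.meta.cell, c.meta.point, c.meta.curve) == (
                row["cell"], row["point"], row["curve"])


class TestBetaCohort:
    def test_constructed_promoter_truth(self):
        res = simulate_beta_cohort(CohortSpec(seed=1))
        assert len(res.promoter_methylated) == 3
        assert len(res.beta.samples) == 105
        assert len(res.beta.probes) == 25

    def test_deterministic(self):
        a = simulate_beta_cohort(CohortSpec(seed=2))
        b = simulate_beta_cohort(CohortSpec(seed=2))
        assert a.beta.beta.equals(b.beta.beta)
        assert a.clinical.table.equals(b.clinical.table)

    def test_zero_failure_rate_nothing_dropped(self):
        from cellmech import filter_probes

        res = simulate_beta_cohort(CohortSpec(seed=4, detection_fail_rate=0.0))
        out, report = filter_probes(res.beta)
        assert not report["dropped"].any()
        assert out.beta.notna().all().all()

    def test_risk_labels_valid(self):
        res = simulate_beta_cohort(CohortSpec(seed=6))
        assert res.clinical.table["risk"].isin(
            ["low", "intermediate", "high"]).all()


class TestGroupSummaryRecovery:
    def test_post_trim_mean_within_five_percent(self, probe, fit_config):
        """Full synthetic pipeline recovers a generating group mean within
        5% at the 2000-curve scale."""
        spec = AfmGroupSpec.from_reported("g", 1.28, 0.37, seed=77)
        curves, _ = simulate_afm_experiment([spec], probe)
        acc, _ = qc_filter(process_curves(curves, probe, fit_config), fit_config)
        res = gaussian_trim_fit([e.young_modulus for e in acc])
        assert res.mean_E == pytest.approx(1.28, rel=0.05)
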