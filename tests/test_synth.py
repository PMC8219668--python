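"""Synthetic generators: determinism, design fidelity, mechanistic limits."""

import math

import numpy as np
import pytest

import kinscale as ks

RT = ks.Constants().rt


class TestEnsemble:
    def test_exact_line_when_noise_free(self):
        spec = ks.EnsembleSpec(n_enzymes=200, vertical_sd=0.0,
                               outlier_fraction=0.0, seed=3)
        ens = ks.generate_lfer_ensemble(spec)
        fit = ks.fit_scaling(ens.params)
        assert fit.slope_a == pytest.approx(spec.true_slope_a, abs=1e-10)
        assert fit.n_outliers == 0

    def test_same_seed_reproduces_bitwise(self):
        a = ks.generate_lfer_ensemble(ks.EnsembleSpec(seed=17))
        b = ks.generate_lfer_ensemble(ks.EnsembleSpec(seed=17))
        assert a == b

    def test_outlier_count_and_direction(self):
        spec = ks.EnsembleSpec(n_enzymes=83, outlier_fraction=0.05, seed=4)
        ens = ks.generate_lfer_ensemble(spec)
        assert len(ens.outlier_ids) == int(83 * 0.05)
        by_id = {p.enzyme_id: p for p in ens.params}
        for oid in ens.outlier_ids:
            p = by_id[oid]
            line = spec.true_intercept_lnA + spec.true_slope_a * math.log(p.K_M)
            assert math.log(p.k_cat) < line  # displaced below the line only

    def test_invalid_specs_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.EnsembleSpec(n_enzymes=2)
        with pytest.raises(ks.ValidationError):
            ks.EnsembleSpec(outlier_offset=1.0)
        with pytest.raises(ks.ValidationError):
            ks.EnsembleSpec(outlier_fraction=1.0)

    def test_planted_outliers_flagged_by_scaling_fit(self):
        hits = 0
        for seed in range(30):
            ens = ks.generate_lfer_ensemble(ks.EnsembleSpec(seed=seed))
            fit = ks.fit_scaling(ens.params)
            if set(ens.outlier_ids) <= set(fit.outlier_ids):
                hits += 1
        assert hits >= 27  # planted sub-line outliers are almost always caught


class TestMMGeneration:
    def test_noise_free_inverse_consistency(self):
        truth = ks.KineticParams("T", 7.5, 33.0, source="synthetic-truth")
        ds = ks.generate_mm_dataset(truth, ks.MeasurementSpec(noise_cv=0.0, seed=0))
        p = ks.fit_michaelis_menten(ds)
        assert p.k_cat == pytest.approx(truth.k_cat, rel=1e-6)
        assert p.K_M == pytest.approx(truth.K_M, rel=1e-6)

    def test_replicate_and_load_counts(self):
        truth = ks.KineticParams("T", 1.0, 10.0, source="synthetic-truth")
        ds = ks.generate_mm_dataset(truth, ks.MeasurementSpec(seed=1))
        assert len(ds.loads) == 9
        assert ds.n_points == 27

    def test_noise_is_multiplicative_mean_one(self):
        # at one load, many replicates: sample mean near the clean rate
        truth = ks.KineticParams("T", 5.0, 20.0, source="synthetic-truth")
        spec = ks.MeasurementSpec(replicates=4000, noise_cv=0.05, seed=8)
        ds = ks.generate_mm_dataset(truth, spec)
        clean = spec.E0 * 5.0 * np.array(ds.loads) / (np.array(ds.loads) + 20.0)
        means = np.array([np.mean(r) for r in ds.rates])
        assert np.allclose(means / clean, 1.0, atol=0.005)

    def test_confidence_interval_coverage_of_kcat(self):
        """~95% normal intervals from the fit SD should cover the
        generating k_cat in at least 90% of simulated enzymes."""
        ens = ks.generate_lfer_ensemble(
            ks.EnsembleSpec(n_enzymes=250, seed=7, outlier_fraction=0.0))
        covered = total = 0
        for i, truth in enumerate(ens.params):
            ds = ks.generate_mm_dataset(truth, ks.MeasurementSpec(seed=50_000 + i))
            p = ks.fit_michaelis_menten(ds)
            total += 1
            if abs(p.k_cat - truth.k_cat) <= 1.96 * p.sd_kcat:
                covered += 1
        assert covered / total >= 0.90


class TestMechanisticSimulator:
    def test_direct_evaluation_of_off_rate(self):
        spec = ks.MechanisticSpec(k_off0=100.0, ts_coupling_c=0.0,
                                  dG_b=-RT * math.log(100.0),
                                  products_per_visit=4.0)
        p = ks.simulate_mechanistic_enzyme(spec)
        assert p.k_cat == pytest.approx(4.0, rel=1e-12)  # k_off = 1/s, n_p = 4

    def test_uniform_binding_keeps_turnover_constant(self):
        kcats = [
            ks.simulate_mechanistic_enzyme(
                ks.MechanisticSpec(ts_coupling_c=1.0, dG_b=g)).k_cat
            for g in (-30.0, -15.0, -5.0)
        ]
        assert len(set(kcats)) == 1

    @pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_phi_interpolates_regimes(self, c):
        """An ensemble varying only in binding energy shows phi = c - 1:
        pure GS stabilization at c=0, uniform binding at c=1."""
        params = [
            ks.simulate_mechanistic_enzyme(
                ks.MechanisticSpec(ts_coupling_c=c, dG_b=g), enzyme_id=f"M{i}")
            for i, g in enumerate(np.linspace(-30, -5, 20))
        ]
        fit = ks.fit_scaling(params)
        assert fit.phi == pytest.approx(c - 1.0, abs=1e-9)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.MechanisticSpec(ts_coupling_c=1.5)


class TestEndToEnd:
    def test_pipeline_recovers_generating_slope(self):
        ens = ks.generate_lfer_ensemble(ks.EnsembleSpec(seed=21))
        datasets = ks.generate_rate_tables(ens, ks.MeasurementSpec(seed=22))
        params = ks.fit_all(datasets)
        entries = [(rec, p) for (rec, _), p in zip(ens.members, params)]
        cfg = ks.AnalysisConfig(reference_enzyme_id=params[0].enzyme_id)
        result = ks.run_pipeline(entries, cfg)
        assert abs(result.scaling.slope_a - 0.74) <= 3 * result.scaling.se_slope
        assert result.scaling.phi == -result.scaling.slope_a

    def test_rate_tables_reproducible(self):
        ens = ks.generate_lfer_ensemble(ks.EnsembleSpec(n_enzymes=5, seed=1))
        a = ks.generate_rate_tables(ens, ks.MeasurementSpec(seed=2))
        b = ks.generate_rate_tables(ens, ks.MeasurementSpec(seed=2))
        assert a == b
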