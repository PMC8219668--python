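"""Free-energy mapping, scaling-line fit, outlier rejection, regimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kinscale as ks
from kinscale.lfer import fit_scaling_energies

RT = 0.0083145 * 298.15  # kJ/mol at 25 C


class TestEnergyMapping:
    def test_identity_cases_are_zero(self):
        assert ks.ddg_binding(20.0, 20.0) == 0.0
        assert ks.ddg_activation(5.0, 5.0) == 0.0

    def test_rt_scale(self):
        # K_M ratio of e isolates one unit of RT
        assert ks.ddg_binding(math.e * 7.0, 7.0) == pytest.approx(2.4790, abs=1e-4)

    def test_tenfold_tighter_binding(self):
        assert ks.ddg_binding(10.0, 100.0) == pytest.approx(-5.7080, abs=1e-4)

    def test_twofold_faster_turnover(self):
        assert ks.ddg_activation(2.0, 1.0) == pytest.approx(-1.71829, abs=1e-4)

    def test_antisymmetry_under_argument_swap(self):
        assert ks.ddg_activation(3.0, 7.0) == -ks.ddg_activation(7.0, 3.0)
        assert ks.ddg_binding(3.0, 7.0) == -ks.ddg_binding(7.0, 3.0)

    def test_temperature_override_propagates(self):
        c = ks.Constants(temperature=310.0)
        assert ks.ddg_binding(math.e, 1.0, constants=c) == pytest.approx(c.rt)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ks.DomainError):
            ks.ddg_binding(bad, 1.0)
        with pytest.raises(ks.DomainError):
            ks.ddg_activation(1.0, bad)

    def test_reference_enzyme_sits_at_origin(self, line_points):
        ref = line_points[3]
        deltas = ks.energy_deltas(line_points, ref)
        d_ref = next(d for d in deltas if d.enzyme_id == ref.enzyme_id)
        assert d_ref.ddg_binding == 0.0
        assert d_ref.ddg_activation == 0.0


class TestScalingFit:
    def test_exact_line_recovered(self, line_points):
        fit = ks.fit_scaling(line_points)
        assert fit.slope_a == pytest.approx(0.74, abs=1e-12)
        assert fit.intercept_lnA == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_outliers == 0
        assert fit.phi == -fit.slope_a

    def test_planted_outlier_removed_and_fit_matches_clean_refit(self, line_points):
        displaced = ks.KineticParams(
            "OUT", line_points[10].k_cat * math.exp(-5.0), line_points[10].K_M,
            source="synthetic-truth")
        fit = ks.fit_scaling(line_points + [displaced])
        clean = ks.fit_scaling(line_points)
        assert fit.outlier_ids == ("OUT",)
        assert fit.slope_a == pytest.approx(clean.slope_a, abs=1e-12)
        assert fit.n_used == len(line_points)

    def test_two_points_insufficient(self, line_points):
        with pytest.raises(ks.InsufficientDataError):
            ks.fit_scaling(line_points[:2])

    def test_zero_x_variance_degenerate(self):
        pts = [ks.KineticParams(f"D{i}", 1.0 + i, 5.0, source="table") for i in range(4)]
        with pytest.raises(ks.DegenerateDesignError):
            ks.fit_scaling(pts)

    def test_infinite_cutoff_equals_plain_ols(self, small_ensemble):
        import statsmodels.api as sm

        params = small_ensemble.params
        fit = ks.fit_scaling(params, ks.AnalysisConfig(outlier_cutoff=1e12))
        x = np.log([p.K_M for p in params])
        y = np.log([p.k_cat for p in params])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.n_outliers == 0
        assert fit.slope_a == pytest.approx(res.params[1], abs=1e-14)

    def test_outlier_set_invariant_under_row_permutation(self, small_ensemble):
        params = list(small_ensemble.params)
        fit0 = ks.fit_scaling(params)
        rng = np.random.default_rng(9)
        for _ in range(3):
            rng.shuffle(params)
            fit = ks.fit_scaling(params)
            assert set(fit.outlier_ids) == set(fit0.outlier_ids)
            assert fit.slope_a == pytest.approx(fit0.slope_a, abs=1e-12)

    def test_single_pass_mode_removes_all_flagged_at_once(self, line_points):
        bad = [
            ks.KineticParams("B1", line_points[2].k_cat * math.exp(-4.0),
                             line_points[2].K_M, source="table"),
            ks.KineticParams("B2", line_points[15].k_cat * math.exp(-6.0),
                             line_points[15].K_M, source="table"),
        ]
        fit = ks.fit_scaling(line_points + bad,
                             ks.AnalysisConfig(outlier_iterate=False))
        assert set(fit.outlier_ids) == {"B1", "B2"}

    def test_bands_bracket_the_fit_and_nest(self, small_ensemble):
        fit = ks.fit_scaling(small_ensemble.params)
        b = fit.bands
        assert len(b.x) == 200
        for lo, f, hi, plo, phi_ in zip(b.conf_lo, b.fit, b.conf_hi, b.pred_lo, b.pred_hi):
            assert plo <= lo <= f <= hi <= phi_


class TestDuality:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_energy_slope_is_minus_log_slope(self, seed):
        """OLS in (ddG_B, ddG_act) space has slope exactly -(log-space
        slope): RT cancels from both axes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        params = [
            ks.KineticParams(f"R{i}", float(np.exp(rng.normal(1, 1))),
                             float(np.exp(rng.normal(2, 1.5))), source="table")
            for i in range(n)
        ]
        T = float(rng.uniform(273, 373))
        ref = params[int(rng.integers(n))]
        log_fit = ks.fit_scaling(params, ks.AnalysisConfig(
            reference_enzyme_id=ref.enzyme_id, outlier_cutoff=1e12))
        deltas = ks.energy_deltas(params, ref, ks.Constants(temperature=T))
        energy_fit = fit_scaling_energies(deltas)
        assert energy_fit.params[1] == pytest.approx(-log_fit.slope_a, abs=1e-12)

    def test_reference_change_shifts_energies_not_phi(self, small_ensemble):
        params = small_ensemble.params
        fits = [
            ks.fit_scaling(params, ks.AnalysisConfig(reference_enzyme_id=params[k].enzyme_id))
            for k in (0, 7)
        ]
        assert fits[0].phi == pytest.approx(fits[1].phi, abs=1e-12)


class TestPhiAndRegimes:
    @pytest.mark.parametrize("slope,phi", [(0.74, -0.74), (0.0, 0.0), (1.0, -1.0)])
    def test_phi_is_negated_slope(self, line_points, slope, phi):
        fit = ks.fit_scaling(line_points)
        object.__setattr__(fit, "slope_a", slope)
        value, se = ks.phi_from_scaling(fit)
        assert value == phi
        assert se == fit.se_slope

    @pytest.mark.parametrize(
        "phi,label,annotation",
        [
            (0.0, "uniform_binding", None),
            (0.1, "uniform_binding", None),
            (-1.0, "gs_stabilization", None),
            (-0.9, "gs_stabilization", None),
            (-0.74, "intermediate", "gs_dominated"),
            (-0.3, "intermediate", None),
            (5.0, "ts_stabilization", None),
            (-4.0, "ts_stabilization", None),
        ],
    )
    def test_regime_classification(self, phi, label, annotation):
        assert ks.classify_regime(phi) == (label, annotation)

    def test_non_finite_phi_rejected(self):
        with pytest.raises(ks.DomainError):
            ks.classify_regime(float("nan"))
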