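import numpy as np
import pytest
from scipy import stats

from liposcatter import (
    ContrastDataset,
    SLBFitModel,
    f_test_model_comparison,
    fit_global,
    joint_chi_square,
    layer_mma,
    mc_uncertainty,
)
from liposcatter.contrast_refinement import FitResult, mma_mismatch
from liposcatter.slab_reflectivity import ReflectivityCurve
from liposcatter.synthetic_data import GeneratorRecipe, simulate_reflectivity

FAST_FIT = dict(maxiter=60, popsize=8, tol=1e-6)


def _bounds(**overrides):
    base = {"tail_sld_material": (2.0, 7.1), "head_coverage": (0.3, 1.0),
            "tail_coverage": (0.5, 1.0), "tail_thickness": (20.0, 35.0),
            "head_thickness": (5.0, 14.0)}
    base.update(overrides)
    return base


class TestJointChiSquare:
    def test_zero_at_generating_model(self, ddmpc_model, nr_datasets_noiseless):
        assert joint_chi_square(ddmpc_model, nr_datasets_noiseless) < 1e-6

    def test_increases_when_tail_sld_perturbed(self, ddmpc_model,
                                               nr_datasets_noiseless):
        h_tbs = [ds for ds in nr_datasets_noiseless if ds.d2o_fraction == 0.0]
        at_truth = joint_chi_square(ddmpc_model, h_tbs)
        perturbed = ddmpc_model.with_params(
            tail_sld_material=ddmpc_model.tail_sld_material + 1.0)
        assert joint_chi_square(perturbed, h_tbs) > at_truth

    def test_reduced_chi_square_near_one_for_honest_noise(self, ddmpc_model):
        """χ²/dof ≈ 1 ± 3/sqrt(dof) on average over seeds when the data are
        generated from the model with the stated uncertainties."""
        values = []
        for seed in range(20):
            ds = simulate_reflectivity(GeneratorRecipe(truth=ddmpc_model,
                                                       seed=seed))
            dof = sum(len(d.curve.q) for d in ds)
            values.append(joint_chi_square(ddmpc_model, ds) / dof)
        mean = np.mean(values)
        assert abs(mean - 1.0) < 3.0 / np.sqrt(360)

    def test_zero_uncertainty_rejected(self, ddmpc_model, nr_datasets_noiseless):
        ds = nr_datasets_noiseless[0]
        bad_curve = ReflectivityCurve(ds.curve.q, ds.curve.R,
                                      np.zeros_like(ds.curve.R), ds.curve.dq)
        bad = ContrastDataset(ds.label, ds.d2o_fraction, bad_curve)
        with pytest.raises(ValueError, match="dR"):
            joint_chi_square(ddmpc_model, [bad])

    def test_empty_dataset_list_rejected(self, ddmpc_model):
        with pytest.raises(ValueError):
            joint_chi_square(ddmpc_model, [])


class TestFitGlobal:
    def test_recovers_structure_from_noiseless_three_contrasts(
            self, ddmpc_model, nr_datasets_noiseless):
        """Head/tail thickness recovered to <= 1 % from noiseless data."""
        start = ddmpc_model.with_params(head_thickness=11.0,
                                        tail_thickness=30.0)
        fit = fit_global(nr_datasets_noiseless, start,
                         ["head_thickness", "tail_thickness"], _bounds(),
                         seed=3, **FAST_FIT)
        assert fit.parameters["head_thickness"] == pytest.approx(9.0, rel=0.01)
        assert fit.parameters["tail_thickness"] == pytest.approx(27.2, rel=0.01)

    def test_empty_free_set_returns_template_chi_square(
            self, ddmpc_model, nr_datasets_noiseless):
        fit = fit_global(nr_datasets_noiseless, ddmpc_model, [], {}, seed=0)
        assert fit.parameters == {}
        assert fit.chi_square == pytest.approx(
            joint_chi_square(ddmpc_model, nr_datasets_noiseless), abs=1e-12)

    def test_same_seed_reproduces_parameters_exactly(
            self, exchanged_model, nr_datasets_noisy):
        free = ["tail_sld_material", "tail_coverage"]
        kwargs = dict(maxiter=15, popsize=6, tol=1e-6)
        a = fit_global(nr_datasets_noisy, exchanged_model, free, _bounds(),
                       seed=11, **kwargs)
        b = fit_global(nr_datasets_noisy, exchanged_model, free, _bounds(),
                       seed=11, **kwargs)
        assert a.parameters == b.parameters

    def test_missing_bounds_raise(self, ddmpc_model, nr_datasets_noiseless):
        with pytest.raises(ValueError, match="bounds"):
            fit_global(nr_datasets_noiseless, ddmpc_model,
                       ["tail_sld_material"], {}, seed=0)

    def test_unknown_parameter_name_raises(self, ddmpc_model,
                                           nr_datasets_noiseless):
        with pytest.raises(ValueError, match="unknown"):
            fit_global(nr_datasets_noiseless, ddmpc_model, ["bogus"],
                       {"bogus": (0, 1)}, seed=0)

    def test_accepted_fit_satisfies_mma_consistency(
            self, ddmpc_model, nr_datasets_noiseless):
        """Co-refined coverages keep head and tail mean molecular areas
        equal within 5 % (the physical packing constraint)."""
        start = ddmpc_model.with_params(head_coverage=0.5, tail_coverage=0.8)
        fit = fit_global(nr_datasets_noiseless, start,
                         ["head_coverage", "tail_coverage"], _bounds(),
                         seed=5, mma_volumes=(319.0, 782.0), **FAST_FIT)
        assert mma_mismatch(fit.model, 319.0, 782.0) < 0.05


class TestMcUncertainty:
    def test_zero_noise_data_give_zero_sigma(self, ddmpc_model,
                                             nr_datasets_noiseless):
        """dR = 0 everywhere: resampling perturbs nothing, so σ = 0."""
        fit = fit_global(nr_datasets_noiseless, ddmpc_model,
                         ["tail_sld_material"], _bounds(), seed=1,
                         maxiter=10, popsize=6)
        exact = []
        for ds in nr_datasets_noiseless:
            c = ds.curve
            exact.append(ContrastDataset(
                ds.label, ds.d2o_fraction,
                ReflectivityCurve(c.q, c.R, np.zeros_like(c.R), c.dq)))
        sigma = mc_uncertainty(fit, exact, 5, seed=2)
        assert sigma["tail_sld_material"] == 0.0
        assert fit.resample_table.shape == (5, 1)

    def test_sigma_scale_matches_mc_noise(self, exchanged_model,
                                          nr_datasets_noisy):
        """σ(tail SLD) from resampling is small but nonzero at 3 % noise,
        and doubling all dR inflates every σ."""
        fit = fit_global(nr_datasets_noisy, exchanged_model,
                         ["tail_sld_material", "tail_coverage"], _bounds(),
                         seed=4, **FAST_FIT)
        sigma = mc_uncertainty(fit, nr_datasets_noisy, 15, seed=5)
        assert 1e-4 < sigma["tail_sld_material"] < 0.1

        doubled = []
        for ds in nr_datasets_noisy:
            c = ds.curve
            doubled.append(ContrastDataset(
                ds.label, ds.d2o_fraction,
                ReflectivityCurve(c.q, c.R, 2.0 * c.dR, c.dq)))
        sigma2 = mc_uncertainty(fit, doubled, 15, seed=5)
        assert all(sigma2[k] > sigma[k] for k in sigma)

    def test_too_few_resamples_rejected(self, ddmpc_model,
                                        nr_datasets_noiseless):
        fit = fit_global(nr_datasets_noiseless, ddmpc_model, [], {}, seed=0)
        with pytest.raises(ValueError):
            mc_uncertainty(fit, nr_datasets_noiseless, 1, seed=0)


def _stub_fit(chi2, dof):
    return FitResult(parameters={"x": 0.0}, chi_square=chi2,
                     degrees_of_freedom=dof, model=SLBFitModel(), datasets=[])


class TestFTest:
    def test_equal_chi_square_gives_p_one(self):
        assert f_test_model_comparison(_stub_fit(100.0, 101),
                                       _stub_fit(100.0, 100)) == 1.0

    def test_known_f_statistic_value(self):
        """χ²_r=120, χ²_f=100, dof 101 vs 100 → F=20, p = SF_{F(1,100)}(20)."""
        p = f_test_model_comparison(_stub_fit(120.0, 101),
                                    _stub_fit(100.0, 100))
        assert p == pytest.approx(stats.f.sf(20.0, 1, 100), rel=1e-12)
        assert p == pytest.approx(2e-5, rel=0.2)

    def test_non_nested_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            f_test_model_comparison(_stub_fit(10.0, 100), _stub_fit(9.0, 100))
        with pytest.raises(ValueError):
            f_test_model_comparison(_stub_fit(10.0, 101), _stub_fit(0.0, 100))

    def test_type_i_error_rate_on_simulated_nulls(self, rng):
        """Restricted (constant) vs full (constant+slope) least-squares fits
        on pure-noise data: rejection rate at p = 0.05 is 0.05 ± 0.03
        over 400 simulated null comparisons."""
        n, n_sim, rejections = 50, 400, 0
        t = np.linspace(0.0, 1.0, n)
        design = np.column_stack([np.ones(n), t])
        for _ in range(n_sim):
            y = rng.normal(0.0, 1.0, n)
            chi_r = np.sum((y - y.mean()) ** 2)
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            chi_f = np.sum((y - design @ coef) ** 2)
            p = f_test_model_comparison(_stub_fit(chi_r, n - 1),
                                        _stub_fit(chi_f, n - 2))
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) < 0.03


class TestLayerMma:
    def test_ddmpc_tail_region_reproduces_reported_area(self):
        """782 Å³ chains over a 13.6 Å leaflet at 96 % coverage → ~59.9 Å²,
        consistent with 59 ± 2 Å²."""
        assert layer_mma(27.2 / 2.0, 0.96, 782.0) == pytest.approx(59.9, abs=0.1)

    def test_head_region_matches_tail_within_reported_error(self):
        mma_head = layer_mma(9.0, 0.62, 319.0)
        mma_tail = layer_mma(13.6, 0.96, 782.0)
        assert mma_head == pytest.approx(57.2, abs=0.1)
        assert abs(mma_head - mma_tail) < 4.0  # within ±2 Å² on each

    def test_exact_inverse_relation(self):
        assert layer_mma(10.0, 1.0, 10.0 * 55.0) == pytest.approx(55.0)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            layer_mma(10.0, 0.0, 700.0)


def test_corefinement_tightens_tail_sld_over_single_contrast(exchanged_model):
    """Three contrasts constrain the tail SLD better than h-TBS alone."""
    ds3 = simulate_reflectivity(GeneratorRecipe(truth=exchanged_model, seed=9))
    ds1 = [d for d in ds3 if d.d2o_fraction == 0.0]
    free = ["tail_sld_material", "tail_coverage", "head_coverage"]
    fit3 = fit_global(ds3, exchanged_model, free, _bounds(), seed=2, **FAST_FIT)
    fit1 = fit_global(ds1, exchanged_model, free, _bounds(), seed=2, **FAST_FIT)
    s3 = mc_uncertainty(fit3, ds3, 12, seed=3)
    s1 = mc_uncertainty(fit1, ds1, 12, seed=3)
    assert s3["tail_sld_material"] < s1["tail_sld_material"]
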