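"""Composite likelihood, model comparison, unit conversion, bootstrap."""

import math

import numpy as np
import pytest

from divflow.demography import (
    FitResult,
    bootstrap_ci,
    compare_models,
    composite_loglik,
    convert_units,
    expected_sfs,
    fit_model,
)
from divflow.models import (
    ConversionConstants,
    DemographicModel,
    SampleConfig,
    Scenario,
)
from divflow.sfs import JointSFS


def spectrum(values, folded=True):
    """1-D toy spectrum wrapped as a JointSFS row with only corners masked."""
    arr = np.zeros((1, len(values) + 2))
    arr[0, 1:-1] = values
    mask = np.zeros(arr.shape, dtype=bool)
    return JointSFS(arr, folded=folded, mask=mask)


class TestCompositeLoglik:
    def test_saturated_single_cell(self):
        data, model = spectrum([1.0]), spectrum([1.0])
        ll, theta = composite_loglik(data, model)
        assert theta == pytest.approx(1.0)
        assert ll == pytest.approx(-1.0)

    def test_hand_evaluated_two_cell_case(self):
        """data [2,4], model [1,2]: theta=2, ll = -2.9398 by hand."""
        ll, theta = composite_loglik(spectrum([2.0, 4.0]), spectrum([1.0, 2.0]))
        assert theta == pytest.approx(2.0)
        want = (2 * math.log(2) - 2 - math.log(2)) + (
            4 * math.log(4) - 4 - math.log(24)
        )
        assert ll == pytest.approx(want)
        assert ll == pytest.approx(-2.9398, abs=1e-4)

    def test_model_scaling_invariance(self, rng):
        d = spectrum(rng.integers(1, 50, size=6).astype(float))
        m1 = spectrum(rng.random(6) + 0.1)
        m2 = JointSFS(m1.data * 17.3, folded=True, mask=m1.mask.copy())
        assert composite_loglik(d, m1)[0] == pytest.approx(
            composite_loglik(d, m2)[0], rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loglik(spectrum([1.0]), spectrum([1.0, 2.0]))

    def test_fold_state_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            composite_loglik(spectrum([1.0]), spectrum([1.0], folded=False))


class TestExpectedSFS:
    def test_collapsed_si_model_folds_to_one_deme_spectrum(self):
        """SI with nu=1 and tiny t_iso is one deme: folded n=4 is [4/3, 1/2]."""
        model = DemographicModel("SI", 1.0, 1.0, t_iso=1e-9)
        spec = expected_sfs(model, SampleConfig(2, 2), 4000, seed=3, fold=True)
        marg = np.zeros(5)
        for i in range(3):
            for j in range(3):
                if not spec.mask[i, j]:
                    marg[i + j] += spec.data[i, j]
        assert marg[1] == pytest.approx(1.0 + 1.0 / 3.0, rel=0.02)
        assert marg[2] == pytest.approx(0.5, rel=0.02)

    def test_matches_empirical_sfs_from_simulated_dataset(self):
        """Simulator self-consistency: branch expectations predict SNP counts."""
        from divflow.simgen import simulate_dataset
        from divflow.sfs import joint_sfs

        model = DemographicModel("SC_ASYM", 1.0, 0.6, 1.5, 0.3, 3.0, 1.0)
        theta = 2.0
        n_loci = 3000
        gm, _ = simulate_dataset(model, SampleConfig(4, 4), n_loci, theta, seed=13)
        emp = joint_sfs(gm).data
        exp = expected_sfs(model, SampleConfig(4, 4), 150_000, seed=29, fold=False)
        lam = n_loci * theta * exp.data
        keep = ~exp.mask & (lam > 50)
        # SNPs within a locus share one genealogy, so cell counts are
        # overdispersed relative to Poisson: allow a generous z band
        z = (emp[keep] - lam[keep]) / np.sqrt(lam[keep])
        assert np.all(np.abs(z) < 6.0)
        assert emp[~exp.mask].sum() == pytest.approx(lam[~exp.mask].sum(), rel=0.03)


class TestCompareModels:
    def fit(self, ll, n_params, scenario=Scenario.SI, shape=(3, 3)):
        return FitResult(
            model=DemographicModel(scenario, 1, 1, 1.0),
            loglik=ll,
            theta_hat=1.0,
            n_params=n_params,
            data_shape=shape,
        )

    def test_printed_likelihood_ordering(self):
        """The three printed log-likelihoods rank SC_ASYM > IM > SI."""
        fits = [self.fit(-472_672, 3), self.fit(-86_672, 4), self.fit(-31_804, 6)]
        ranked = compare_models(fits)
        assert [f.loglik for f in ranked] == [-31_804, -86_672, -472_672]

    def test_single_fit(self):
        f = self.fit(-10, 3)
        assert compare_models([f]) == [f]

    def test_tie_broken_by_fewer_parameters(self):
        a, b = self.fit(-5.0, 6), self.fit(-5.0, 4)
        assert compare_models([a, b])[0].n_params == 4

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            compare_models([self.fit(-1, 3, shape=(3, 3)), self.fit(-2, 3, shape=(5, 5))])


class TestConvertUnits:
    CONSTS = ConversionConstants(mu=1e-9, gen_time=2.0, L_eff=1e7)

    def make_fit(self, **kw):
        model = DemographicModel(
            "SC_ASYM",
            kw.get("nu1", 1.0),
            kw.get("nu2", 1.0),
            kw.get("t_iso", 1.0),
            kw.get("t_sc", 0.0),
            kw.get("m12", 1.0),
            kw.get("m21", 0.5),
        )
        return FitResult(model=model, loglik=-1.0, theta_hat=kw.get("theta", 40.0),
                         n_params=6)

    def test_reference_size_and_time_arithmetic(self):
        out = convert_units(self.make_fit(theta=40.0, t_iso=1.0), self.CONSTS)
        assert out.N_ref == pytest.approx(1000.0)
        assert out.T_div_years == pytest.approx(4000.0)

    def test_population_size_scaling(self):
        out = convert_units(self.make_fit(nu1=2.0), self.CONSTS)
        assert out.N1 == pytest.approx(2000.0)

    def test_migration_rate_convention(self):
        out = convert_units(self.make_fit(m12=1.0), self.CONSTS)
        assert out.m12 == pytest.approx(1.0 / (2.0 * 1000.0))

    def test_roundtrip_inverse_conversion(self):
        fit = self.make_fit(nu1=1.7, nu2=0.4, t_iso=2.3, t_sc=0.21, theta=55.0)
        out = convert_units(fit, self.CONSTS)
        # invert: recover coalescent-unit parameters from absolute ones
        N_ref = out.N_ref
        assert out.N1 / N_ref == pytest.approx(1.7, rel=1e-9)
        assert out.T_div_years / (2 * N_ref * self.CONSTS.gen_time) == pytest.approx(
            2.51, rel=1e-9
        )
        assert out.m12 * 2 * N_ref == pytest.approx(fit.model.m12, rel=1e-9)

    def test_nonpositive_theta_rejected(self):
        fit = self.make_fit()
        object.__setattr__(fit, "theta_hat", 0.0) if False else None
        fit.theta_hat = 0.0
        with pytest.raises(ValueError):
            convert_units(fit, self.CONSTS)


class TestFitModel:
    def test_warm_start_does_not_worsen_on_model_data(self):
        """Starting at the generating parameters, the refit cannot do worse."""
        truth = DemographicModel("SC_ASYM", 1.2, 0.7, 2.0, 0.25, 5.0, 1.5)
        samples = SampleConfig(6, 6)
        exp = expected_sfs(truth, samples, 60_000, seed=101, fold=True)
        data = JointSFS(np.round(exp.data * 3e4), folded=True, mask=exp.mask.copy())
        start = np.array(truth.param_vector())
        fit = fit_model(data, "SC_ASYM", seed=5, n_reps=20_000,
                        n_reps_polish=20_000, starts=[start])
        ll_start, _ = composite_loglik(
            data, expected_sfs(truth, samples, 20_000, seed=0, fold=True)
        )
        assert fit.loglik >= ll_start - 30  # CRN noise allowance

    def test_unfolded_data_rejected(self, rng):
        spec = JointSFS(rng.random((4, 4)), folded=False)
        with pytest.raises(ValueError, match="folded"):
            fit_model(spec, "SI")

    def test_deterministic_given_seed(self):
        truth = DemographicModel("SI", 1.0, 0.8, 1.5)
        exp = expected_sfs(truth, SampleConfig(4, 4), 30_000, seed=7, fold=True)
        data = JointSFS(np.round(exp.data * 1e4), folded=True, mask=exp.mask.copy())
        kw = dict(seed=11, n_reps=1500, n_reps_polish=4000, n_grid=5, n_pass=2,
                  maxfev=40, refine=False)
        a = fit_model(data, "SI", **kw)
        b = fit_model(data, "SI", **kw)
        assert a.loglik == b.loglik
        assert a.model.param_vector() == b.model.param_vector()


class TestBootstrap:
    def test_zero_iterations_rejected(self, rng):
        spec = JointSFS(rng.random((3, 3))).fold()
        mle = FitResult(model=DemographicModel("SI", 1, 1, 1.0), loglik=-1,
                        theta_hat=1.0, n_params=3)
        with pytest.raises(ValueError):
            bootstrap_ci(spec, "SI", mle, n_boot=0)

    def test_degenerate_resampling_gives_tight_intervals(self):
        """A spectrum with all mass in one cell resamples to itself."""
        truth = DemographicModel("SI", 1.0, 1.0, 2.0)
        samples = SampleConfig(4, 4)
        exp = expected_sfs(truth, samples, 40_000, seed=19, fold=True)
        data = JointSFS(np.round(exp.data * 2e4), folded=True, mask=exp.mask.copy())
        mle = fit_model(data, "SI", seed=3, n_reps=4000, n_reps_polish=4000,
                        starts=[np.array(truth.param_vector())])
        out = bootstrap_ci(data, "SI", mle, n_boot=3, n_snps=int(data.total()),
                           seed=23, n_reps=4000)
        assert out["n_failures"] == 0
        for lo_v, hi_v in out["intervals"].values():
            assert lo_v <= hi_v
        lo_t, hi_t = out["intervals"]["t_iso"]
        assert hi_t / max(lo_t, 1e-9) < 2.0  # resamples of the same SFS stay close
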