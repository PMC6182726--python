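"""Virtual-population sampling distributions and virtual twins."""

import numpy as np
import pytest
from scipy import stats

from cardiotwin.params import CaseRecord
from cardiotwin.population import (FAFG_CV, FAFG_MEAN, NORMAL_IONS_MM,
                                   lognormal_params, make_population,
                                   make_virtual_twin, sample_F, sample_faFg,
                                   sample_tlag)


class TestSampleF:
    def test_all_draws_within_truncation_bounds(self, rng):
        x = sample_F(rng, size=10_000)
        assert x.min() >= 0.33 and x.max() <= 0.62

    def test_seeded_sequence_reproducible(self):
        a = sample_F(np.random.default_rng(42), size=100)
        b = sample_F(np.random.default_rng(42), size=100)
        assert np.array_equal(a, b)

    def test_mean_matches_truncated_normal_formula(self, rng):
        """Empirical mean of 1e6 draws against the analytic truncated-normal
        mean (independent closed form from scipy.stats)."""
        a, b = (0.33 - 0.459) / 0.093, (0.62 - 0.459) / 0.093
        expected = stats.truncnorm.mean(a, b, loc=0.459, scale=0.093)
        assert expected == pytest.approx(0.4658, abs=5e-4)
        x = sample_F(rng, size=1_000_000)
        assert x.mean() == pytest.approx(expected, abs=1e-3)


class TestSampleFaFg:
    def test_moment_matched_lognormal_parameters(self):
        mu, sigma = lognormal_params(FAFG_MEAN, FAFG_CV)
        # oracle: sigma = sqrt(ln(1 + 0.131^2)), mu = ln(0.832) - sigma^2/2
        assert sigma == pytest.approx(np.sqrt(np.log1p(0.131 ** 2)), rel=1e-12)
        assert sigma == pytest.approx(0.13044, abs=1e-5)
        assert mu == pytest.approx(np.log(0.832) - 0.5 * np.log1p(0.131 ** 2),
                                   rel=1e-12)
        assert mu == pytest.approx(-0.19243, abs=1e-5)

    def test_empirical_mean(self, rng):
        x = sample_faFg(rng, size=1_000_000)
        assert x.mean() == pytest.approx(0.832, abs=1e-3)
        assert (x > 1).any()  # untruncated: values above 1 are allowed

    def test_zero_cv_degenerates_to_constant(self, rng):
        assert sample_faFg(rng, cv=0.0) == 0.832


class TestSampleTlag:
    def test_mean_and_positivity(self, rng):
        x = sample_tlag(1.33, rng, size=1_000_000)
        assert x.mean() == pytest.approx(1.33, abs=5e-3)
        assert x.min() > 0

    def test_requires_positive_mean(self, rng):
        with pytest.raises(ValueError):
            sample_tlag(0.0, rng)

    def test_lag_constant_across_doses_of_one_individual(self, model):
        """A subject's lag applies identically to every dose: each dose's
        contribution starts exactly t_lag after administration."""
        import numpy as np
        from cardiotwin import DoseEvent
        pop = make_population(1, rng_seed=7)
        ind = pop.individuals[0]
        tlag = ind.absorption.t_lag
        t = np.linspace(0.05, 40.0, 800)
        s = model.simulate([DoseEvent(time=0.0, dose_po=50.0),
                            DoseEvent(time=24.0, dose_po=50.0)], t,
                           individual=ind, method="expm")
        at = s["AT", "plasma"]
        assert np.all(at[t < tlag] == 0.0)
        # a fresh rise (positive slope) begins right after 24 h + t_lag
        k0 = np.searchsorted(t, 24.0 + tlag)
        assert at[k0 + 10] > at[k0 - 1]
        # the per-individual lag is immutable once sampled
        import pydantic
        with pytest.raises(pydantic.ValidationError):
            ind.absorption.t_lag = 2.0


class TestMakePopulation:
    def test_seeded_populations_bit_identical(self):
        a = make_population(10, rng_seed=1111).to_frame()
        b = make_population(10, rng_seed=1111).to_frame()
        assert a.equals(b)
        assert len(a) == 10

    def test_zero_variability_yields_mean_individual(self):
        pop = make_population(1, rng_seed=0, sd_F=0, cv_faFg=0, cv_tlag=0)
        ab = pop.individuals[0].absorption
        assert ab.F == 0.459 and ab.fa_Fg == 0.832 and ab.t_lag == 1.33

    def test_invariants_hold_over_seed_sweep(self):
        for seed in range(30):
            pop = make_population(20, rng_seed=seed)
            df = pop.to_frame()
            assert df["F"].between(0.33, 0.62).all()
            assert (df["fa_Fg"] > 0).all()
            assert (df["t_lag"] > 0).all()
            assert df["Fh"].between(0, 1).all()

    def test_rejections_only_when_F_exceeds_faFg(self):
        # brute-force the joint rejection rate: P(F > fa*Fg) is small but
        # non-zero under the stated distributions
        rng = np.random.default_rng(3)
        F = sample_F(rng, size=200_000)
        fa = sample_faFg(rng, size=200_000)
        expected_rate = np.mean(F > fa)
        assert 0 < expected_rate < 0.05
        pop = make_population(2000, rng_seed=5)
        assert pop.resample_count >= 0

    def test_invalid_demographics_config(self):
        with pytest.raises(ValueError, match="demographics"):
            make_population(2, age_range=(60, 50))


class TestVirtualTwin:
    CASE = CaseRecord(id="c1", age=67, sex="F", estimated_dose_mg=2500.0)

    def test_known_covariates_fixed_unknown_sampled(self):
        twin = make_virtual_twin(self.CASE, np.random.default_rng(1111))
        assert twin.age == 67 and twin.sex == "F"
        assert 0.33 <= twin.absorption.F <= 0.62

    def test_recorded_ion_passes_through_missing_defaults(self):
        case = CaseRecord(id="c2", age=40, sex="M", at_plasma_ngml=300.0, K_mM=2.9)
        twin = make_virtual_twin(case, np.random.default_rng(0))
        assert twin.K_mM == 2.9
        assert twin.Na_mM == NORMAL_IONS_MM["Na"]
        assert twin.Ca_mM == NORMAL_IONS_MM["Ca"]

    def test_ten_twins_have_distinct_absorption(self):
        rng = np.random.default_rng(1111)
        twins = [make_virtual_twin(self.CASE, rng) for _ in range(10)]
        assert len({t.absorption.F for t in twins}) == 10

    def test_contradictory_record_rejected(self):
        with pytest.raises(ValueError):
            CaseRecord(id="bad", age=50, sex="M", estimated_dose_mg=100.0, RR_ms=-10)
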