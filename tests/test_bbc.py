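import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp
from scipy.stats import norm

from metabias import (
    MetaDataset,
    QuadratureSpec,
    SpikeSlabPrior,
    StudyRecord,
    bbc_analyze,
    censored_loglik,
    constant_rate,
    default_models,
    extreme_censoring,
    log_marginal_lik,
    no_bias,
    p_graded,
    two_sided_p,
)


def oracle_censored_loglik(data, delta, model, nuisance):
    """Brute-force oracle: per-study censored density with the normalizer
    evaluated by adaptive quadrature, split at the significance boundaries."""
    total = 0.0
    for r in data:
        zc = norm.ppf(1 - model.alpha / 2)

        def integrand(u):
            return norm.pdf(u, delta, r.se) * model.weight(two_sided_p(u, r.se), nuisance)

        cuts = [-np.inf, -zc * r.se, zc * r.se, np.inf]
        denom = sum(quad(integrand, a, b, limit=200)[0] for a, b in zip(cuts, cuts[1:]))
        num = norm.pdf(r.effect_g, delta, r.se) * model.weight(
            two_sided_p(r.effect_g, r.se), nuisance
        )
        total += math.log(num / denom)
    return total


class TestTwoSidedP:
    def test_zero_effect_gives_one(self):
        assert two_sided_p(0.0, 0.3) == pytest.approx(1.0)

    def test_critical_ratio_gives_alpha(self):
        assert two_sided_p(1.959964 * 0.2, 0.2) == pytest.approx(0.05, abs=1e-6)

    def test_normal_cdf_oracle(self):
        assert two_sided_p(0.4, 0.25) == pytest.approx(0.10959858339911595, abs=1e-12)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            two_sided_p(0.4, 0.0)


class TestCensoredLoglik:
    def test_no_bias_reduces_to_uncensored(self, tiny_dataset):
        ll = censored_loglik(tiny_dataset, 0.2, no_bias())
        expected = sum(
            norm.logpdf(r.effect_g, 0.2, r.se) for r in tiny_dataset
        )
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_nonsignificant_study_impossible_under_extreme_censoring(self):
        ds = MetaDataset((StudyRecord("ns", 0.1, 0.3),))  # p = 0.74
        assert censored_loglik(ds, 0.0, extreme_censoring()) == -np.inf

    def test_constant_rate_matches_quadrature_oracle(self, tiny_dataset):
        ll = censored_loglik(tiny_dataset, 0.25, constant_rate(), nuisance=0.5)
        oracle = oracle_censored_loglik(tiny_dataset, 0.25, constant_rate(), 0.5)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_p_graded_matches_quadrature_oracle(self, tiny_dataset):
        model = p_graded()
        ll = censored_loglik(tiny_dataset, 0.1, model, nuisance=8.0)
        oracle = oracle_censored_loglik(tiny_dataset, 0.1, model, 8.0)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_nuisance_required_iff_model_has_one(self, tiny_dataset):
        with pytest.raises(ValueError):
            censored_loglik(tiny_dataset, 0.1, constant_rate())
        with pytest.raises(ValueError):
            censored_loglik(tiny_dataset, 0.1, no_bias(), nuisance=0.5)


class TestMarginalLik:
    def test_no_bias_null_closed_form(self, tiny_dataset):
        lml = log_marginal_lik(tiny_dataset, no_bias(), "null")
        expected = sum(norm.logpdf(r.effect_g, 0.0, r.se) for r in tiny_dataset)
        assert lml == pytest.approx(expected, abs=1e-12)

    def test_uninformative_data_bf_near_one(self):
        ds = MetaDataset((StudyRecord("vague", 0.05, 50.0),))
        res = bbc_analyze(ds, models=[no_bias()], model_prior=[0.5, 0.5])
        assert res.bf_01 == pytest.approx(1.0, abs=0.01)
        assert np.allclose(res.posterior_probs, res.prior_probs, atol=0.01)

    def test_constant_rate_alt_matches_2d_grid_oracle(self, tiny_dataset):
        """Marginal over (delta, pi) agrees with an independent brute-force
        grid of different resolution to 3 significant digits."""
        prior = SpikeSlabPrior()
        lml = log_marginal_lik(tiny_dataset, constant_rate(), "alt", prior=prior)

        deltas = np.linspace(-3, 3, 4801)
        pis = (np.arange(501) + 0.5) / 501
        zc = norm.ppf(0.975)
        g, se = tiny_dataset.g, tiny_dataset.se
        p = two_sided_p(g, se)
        loglik = np.zeros((len(deltas), len(pis)))
        for i, d in enumerate(deltas):
            base = norm.logpdf(g, d, se).sum()
            psig = norm.sf(zc - d / se) + norm.cdf(-zc - d / se)
            for j, pi in enumerate(pis):
                num = np.sum(np.where(p < 0.05, 0.0, math.log(pi)))
                den = np.log(psig + pi * (1 - psig)).sum()
                loglik[i, j] = base + num - den
        # average over pi (uniform midpoint), integrate over delta slab (Riemann)
        lf = logsumexp(loglik, axis=1) - math.log(len(pis))
        step = deltas[1] - deltas[0]
        oracle = logsumexp(lf + norm.logpdf(deltas, 0, prior.slab_sd)) + math.log(step)
        assert np.exp(lml) == pytest.approx(np.exp(oracle), rel=1e-3)

    def test_spike_slab_matches_conjugate_closed_form(self, tiny_dataset):
        """With no selection, the machinery is an ordinary fixed-effect
        spike-and-slab meta-analysis; BF and slab posterior mean must match
        the known-variance conjugate normal results."""
        prior = SpikeSlabPrior(slab_sd=2 / 3)
        res = bbc_analyze(tiny_dataset, prior=prior, models=[no_bias()], model_prior=[0.5, 0.5])

        w = 1.0 / tiny_dataset.se**2
        s2 = 1.0 / w.sum()
        ghat = float(np.sum(w * tiny_dataset.g) * s2)
        # marginal ratio: N(ghat; 0, s2) vs N(ghat; 0, s2 + slab_sd^2)
        bf_closed = norm.pdf(ghat, 0, math.sqrt(s2)) / norm.pdf(
            ghat, 0, math.sqrt(s2 + prior.slab_sd**2)
        )
        assert res.bf_01 == pytest.approx(bf_closed, rel=1e-6)
        post_var = 1.0 / (1.0 / s2 + 1.0 / prior.slab_sd**2)
        conj_mean = ghat * post_var / s2
        assert res.posterior_mean_nonnull == pytest.approx(conj_mean, abs=1e-6)


class TestBbcAnalyze:
    def test_posterior_sums_to_one(self, m3_literature):
        res = bbc_analyze(m3_literature)
        assert res.posterior_probs.sum() == pytest.approx(1.0, abs=1e-8)
        assert res.prior_probs.sum() == pytest.approx(1.0, abs=1e-8)
        assert res.bf_01 >= 0
        assert res.point_mass_at_zero == pytest.approx(
            res.posterior_probs[[0, 2, 4, 6]].sum(), abs=1e-12
        )

    def test_extreme_censoring_zeroed_by_nonsignificant_study(self, tiny_dataset):
        # study "b" has p = 0.21: impossible under M2 in either effect state
        res = bbc_analyze(tiny_dataset)
        assert res.posterior_prob_of("M2-") == 0.0
        assert res.posterior_prob_of("M2+") == 0.0

    def test_bf_invariant_to_common_marginal_rescaling(self, tiny_dataset):
        res = bbc_analyze(tiny_dataset)
        lml = res.log_marginals
        pri = np.log(res.prior_probs)
        is_null = np.array([s.endswith("-") for s in res.scenario_labels])

        def bf(shift):
            shifted = lml + shift
            return math.exp(
                logsumexp(pri[is_null] + shifted[is_null])
                - logsumexp(pri[~is_null] + shifted[~is_null])
            ) * math.exp(logsumexp(pri[~is_null]) - logsumexp(pri[is_null]))

        assert bf(0.0) == pytest.approx(res.bf_01, rel=1e-9)
        assert bf(123.4) == pytest.approx(res.bf_01, rel=1e-9)

    def test_all_scenarios_impossible_raises(self):
        ds = MetaDataset((StudyRecord("ns", 0.1, 0.3),))
        with pytest.raises(ArithmeticError, match="impossible"):
            bbc_analyze(ds, models=[extreme_censoring()], model_prior=[0.5, 0.5])

    def test_posterior_density_integrates_to_continuous_mass(self, m3_literature):
        res = bbc_analyze(m3_literature)
        cont = float(np.trapezoid(res.posterior_density, res.delta_grid))
        assert cont == pytest.approx(1.0 - res.point_mass_at_zero, abs=1e-4)

    def test_prior_sensitivity_direction_stable(self, m3_literature):
        """On a strong-signal literature the BF direction does not depend on
        the slab SD within a reasonable range."""
        for sd in (0.1, 1 / 3, 2 / 3):
            res = bbc_analyze(m3_literature, prior=SpikeSlabPrior(slab_sd=sd))
            assert res.bf_01 < 1e-3  # decisive evidence for an effect

    def test_strong_signal_recovers_scenario_and_effect(self, m3_literature):
        res = bbc_analyze(m3_literature)
        assert res.modal_scenario == "M3+"
        assert res.posterior_mean_nonnull == pytest.approx(0.3, abs=0.12)
        assert res.point_mass_at_zero < 0.01
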