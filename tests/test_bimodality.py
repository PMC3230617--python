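import math

import numpy as np
import pytest

from locustmeth import (
    GaussianMixtureModel,
    OERecord,
    class_boundary,
    classify_genes,
    fit_mixture,
    unimodality_test,
)
from locustmeth.bimodality import _em_k2_batch, _k2_inits


def sample_mixture(rng, n, weights, means, sds):
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


def make_fit(weights, means, sds, equal_var=True):
    """A MixtureResults with prescribed parameters for boundary checks."""
    from locustmeth.bimodality import MixtureResults

    return MixtureResults(
        k=2, weights=tuple(weights), means=tuple(means), sds=tuple(sds),
        loglik=0.0, n_iter=1, converged=True, seed=0, n_obs=0,
        equal_var=equal_var,
    )


class TestFitMixture:
    def test_k1_closed_form(self, rng):
        x = rng.normal(2.0, 0.5, 500)
        fit = fit_mixture(x, k=1)
        assert fit.means[0] == pytest.approx(x.mean())
        assert fit.sds[0] == pytest.approx(x.std())  # MLE, divisor n
        assert fit.converged and fit.n_iter == 0

    def test_recovers_separated_components(self, rng):
        x = sample_mixture(rng, 2000, [0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
        fit = fit_mixture(x, k=2, seed=1)
        assert fit.converged
        assert abs(fit.means[0] - 0.4) < 0.05
        assert abs(fit.means[1] - 0.9) < 0.05
        assert fit.means[0] < fit.means[1]
        assert math.isclose(sum(fit.weights), 1.0, abs_tol=1e-12)

    def test_mean_recovery_error_across_datasets(self):
        # separation >= 3 pooled sds; mean absolute error of means <= 0.03
        errs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            x = sample_mixture(rng, 2000, [0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
            fit = fit_mixture(x, k=2, seed=s)
            errs += [abs(fit.means[0] - 0.4), abs(fit.means[1] - 0.9)]
        assert np.mean(errs) <= 0.03

    def test_determinism_same_seed(self, rng):
        x = sample_mixture(rng, 400, [0.6, 0.4], [0.3, 1.0], [0.1, 0.2])
        a = fit_mixture(x, k=2, seed=7)
        b = fit_mixture(x, k=2, seed=7)
        assert a == b

    def test_loglik_k2_dominates_k1(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 300)
            m = GaussianMixtureModel(x)
            assert m.fit(2).loglik >= m.fit(1).loglik - 1e-6

    def test_em_loglik_monotone_per_iteration(self, rng):
        x = sample_mixture(rng, 300, [0.5, 0.5], [0.0, 1.0], [0.3, 0.3])
        ws, mus, vs = _k2_inits(x, 1, np.random.default_rng(0))
        lls = []
        for m_iter in range(1, 40):
            _, _, _, ll, _, _ = _em_k2_batch(
                x[None, :], ws, mus, vs, True, tol=0.0, max_iter=m_iter
            )
            lls.append(ll[0])
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture([1.0] * 5, k=1)
        with pytest.raises(ValueError):
            fit_mixture([1.0] * 20, k=2)  # all identical


class TestUnimodalityTest:
    def test_gaussian_not_rejected(self):
        rejections = 0
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            x = rng.normal(0, 1, 500)
            t = unimodality_test(x, n_bootstrap=99, seed=s, alpha=0.05)
            rejections += t.reject_unimodal
            assert t.lrt_stat >= 0.0
        assert rejections == 0

    def test_separated_mixture_rejected(self, rng):
        x = sample_mixture(rng, 500, [0.5, 0.5], [0.4, 0.9], [0.12, 0.12])
        t = unimodality_test(x, n_bootstrap=99, seed=1)
        assert t.reject_unimodal
        assert t.p_value <= 0.05

    def test_type_i_rate_calibrated(self):
        # deterministic replicate grid; nominal rate 0.05
        rejections = 0
        n_rep = 25
        for s in range(n_rep):
            rng = np.random.default_rng(7000 + s)
            x = rng.normal(0, 1, 500)
            t = unimodality_test(x, n_bootstrap=99, seed=s, alpha=0.05)
            rejections += t.reject_unimodal
        assert rejections / n_rep <= 0.12

    def test_p_value_definition(self, rng):
        x = rng.normal(0, 1, 200)
        t = unimodality_test(x, n_bootstrap=99, seed=3)
        # p = (1 + #{boot >= obs}) / (B + 1) is a multiple of 1/(B+1)
        assert (t.p_value * (t.n_bootstrap + 1)) == pytest.approx(
            round(t.p_value * (t.n_bootstrap + 1))
        )
        assert 0 < t.p_value <= 1

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            unimodality_test(rng.normal(0, 1, 20))
        with pytest.raises(ValueError):
            unimodality_test(rng.normal(0, 1, 100), n_bootstrap=10)


class TestClassBoundary:
    def test_symmetric_midpoint(self):
        fit = make_fit([0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
        assert class_boundary(fit) == pytest.approx(0.65, abs=1e-8)

    def test_unequal_weights_shift_toward_lighter_component(self):
        heavy_low = make_fit([0.8, 0.2], [0.4, 0.9], [0.15, 0.15])
        boundary = class_boundary(heavy_low)
        assert boundary > 0.65  # boundary moves toward the lighter component
        # numeric cross-check against a dense grid scan of the posterior
        grid = np.linspace(0.4, 0.9, 200001)
        post = heavy_low.posterior_low(grid)
        crossing = grid[np.argmin(np.abs(post - 0.5))]
        assert boundary == pytest.approx(crossing, abs=1e-4)

    def test_boundary_strictly_between_means(self):
        for w in (0.3, 0.5, 0.7):
            fit = make_fit([w, 1 - w], [0.2, 1.1], [0.2, 0.2])
            b = class_boundary(fit)
            assert 0.2 < b < 1.1

    def test_requires_converged_k2(self, rng):
        fit1 = fit_mixture(rng.normal(0, 1, 100), k=1)
        with pytest.raises(ValueError):
            class_boundary(fit1)


class TestClassifyGenes:
    def _records(self, values):
        return [
            OERecord(
                gene_id=f"g{i}", dinucleotide="CG", oe=v,
                reason=None if not math.isnan(v) else "no_windows",
                L_eff=500, W=499, mono_x=100, mono_y=100,
            )
            for i, v in enumerate(values)
        ]

    def test_gene_at_lower_mean_is_low(self):
        fit = make_fit([0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
        out = classify_genes(self._records([0.4, 0.9]), fit)
        assert out[0].label == "low" and out[0].posterior_low > 0.5
        assert out[1].label == "high" and out[1].posterior_low < 0.5

    def test_tie_at_boundary_goes_low(self):
        fit = make_fit([0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
        b = class_boundary(fit)
        out = classify_genes(self._records([b]), fit)
        assert out[0].posterior_low == pytest.approx(0.5, abs=1e-9)
        assert out[0].label == "low"

    def test_posteriors_are_probabilities(self, rng):
        fit = make_fit([0.6, 0.4], [0.4, 0.9], [0.15, 0.15])
        vals = rng.uniform(0, 1.5, 200)
        out = classify_genes(self._records(vals), fit)
        assert all(0.0 <= a.posterior_low <= 1.0 for a in out)

    def test_labels_match_boundary_threshold_for_equal_sds(self, rng):
        fit = make_fit([0.55, 0.45], [0.4, 0.9], [0.15, 0.15])
        b = class_boundary(fit)
        vals = rng.uniform(0, 1.5, 500)
        out = classify_genes(self._records(vals), fit)
        for a in out:
            assert a.label == ("low" if a.oe <= b else "high")

    def test_undefined_oe_omitted(self):
        fit = make_fit([0.5, 0.5], [0.4, 0.9], [0.15, 0.15])
        recs = self._records([0.4, math.nan, 0.9])
        out = classify_genes(recs, fit)
        assert [a.gene_id for a in out] == ["g0", "g2"]
        with pytest.raises(ValueError):
            classify_genes(self._records([math.nan]), fit)


def test_summaries_render(rng):
    x = sample_mixture(rng, 300, [0.5, 0.5], [0.4, 0.9], [0.12, 0.12])
    t = unimodality_test(x, n_bootstrap=99, seed=1)
    assert "Bootstrap LRT" in t.summary()
    assert "comp" in t.fit2.summary()
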