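import numpy as np
import pytest
from sklearn.base import clone

import cdmscreen as cs
from cdmscreen.estimation import DataError, _split_responses
from cdmscreen.models import ItemParameters

from conftest import make_qmatrix


def two_item_setup(p0=0.2, p1=0.8):
    """K=1 mini-instrument with two identical items."""
    q = make_qmatrix([[1], [1]])
    items = [
        ItemParameters.from_probs("i0", "GDINA", 1, [p0, p1]),
        ItemParameters.from_probs("i1", "GDINA", 1, [p0, p1]),
    ]
    return q, items


class TestProfileLikelihood:
    def test_all_missing_gives_empty_product(self):
        q, items = two_item_setup()
        lik = cs.profile_likelihood([np.nan, np.nan], items, q, [1])
        assert lik == pytest.approx(1.0)

    def test_two_endorsements(self):
        q, items = two_item_setup()
        lik = cs.profile_likelihood([1, 1], items, q, [1])
        assert lik == pytest.approx(0.64)

    def test_mixed_responses(self):
        q, items = two_item_setup()
        lik = cs.profile_likelihood([1, 0], items, q, [1])
        assert lik == pytest.approx(0.8 * 0.2)

    def test_bad_value_rejected(self):
        q, items = two_item_setup()
        with pytest.raises(DataError):
            cs.profile_likelihood([2, 0], items, q, [1])


class TestPosteriorProfiles:
    def test_uninformative_items_give_uniform_posterior(self):
        q = make_qmatrix([[1, 0], [0, 1]])
        items = [
            ItemParameters.from_probs("i0", "GDINA", 1, [0.5, 0.5]),
            ItemParameters.from_probs("i1", "GDINA", 1, [0.5, 0.5]),
        ]
        structural = cs.StructuralParameters(np.full(4, 0.25))
        post = cs.posterior_profiles([1, 0], items, q, structural)
        np.testing.assert_allclose(post, 0.25)

    def test_hand_bayes_oracle(self):
        # K=1, both items P(0)=.2, P(1)=.8, uniform prior, responses (1,1):
        # P(alpha=1|X) = .5*.64 / (.5*.64 + .5*.04) = 0.64/0.68
        q, items = two_item_setup()
        structural = cs.StructuralParameters(np.array([0.5, 0.5]))
        post = cs.posterior_profiles([1, 1], items, q, structural)
        assert post[1] == pytest.approx(0.64 / 0.68, abs=1e-12)

    def test_degenerate_prior_dominates(self):
        q, items = two_item_setup()
        structural = cs.StructuralParameters(np.array([1.0, 0.0]))
        post = cs.posterior_profiles([1, 1], items, q, structural)
        np.testing.assert_allclose(post, [1.0, 0.0], atol=1e-9)


class TestMarginalsAndClassification:
    def test_point_mass_recovers_profile(self):
        profile = np.array([0, 1, 1, 0, 0, 0, 1, 1, 0, 0])
        idx = int(profile @ (1 << np.arange(10)))
        post = np.zeros(1024)
        post[idx] = 1.0
        marg = cs.marginal_criterion_posterior(post, 10)
        np.testing.assert_allclose(marg, profile)

    def test_uniform_and_split_posteriors_give_half(self):
        uniform = np.full(16, 1 / 16)
        np.testing.assert_allclose(
            cs.marginal_criterion_posterior(uniform, 4), 0.5
        )
        split = np.zeros(16)
        split[0] = split[-1] = 0.5
        np.testing.assert_allclose(
            cs.marginal_criterion_posterior(split, 4), 0.5
        )

    def test_eap_thresholds_marginals(self):
        post = np.array([[0.05, 0.85, 0.05, 0.05]])  # K=2
        assert cs.eap_map_classify(post, 2, "EAP").tolist() == [[1, 0]]

    def test_exact_half_classified_present(self):
        post = np.array([[0.5, 0.5]])  # K=1, marginal exactly 0.5
        assert cs.eap_map_classify(post, 1, "EAP").tolist() == [[1]]

    def test_map_and_eap_agree_on_bimodal_mass(self):
        post = np.zeros((1, 4))
        post[0, 3] = 0.6  # (1,1)
        post[0, 0] = 0.4  # (0,0)
        assert cs.eap_map_classify(post, 2, "MAP").tolist() == [[1, 1]]
        assert cs.eap_map_classify(post, 2, "EAP").tolist() == [[1, 1]]


class TestEMFit:
    def test_matches_bruteforce_enumeration(self, small_fit, small_study):
        X = small_study.responses.to_numpy(float)[:50]
        total = 0.0
        for row in X:
            s = 0.0
            for w, alpha in enumerate(cs.enumerate_profiles(3)):
                s += small_fit.structural.pi[w] * cs.profile_likelihood(
                    row, small_fit.items, small_fit.q, alpha
                )
            total += np.log(s)
        A1, A0 = _split_responses(X)
        from cdmscreen.estimation import _posterior

        _, ll = _posterior(
            A1, A0, small_fit.item_probs_full(), small_fit.structural.pi
        )
        assert ll == pytest.approx(total, abs=1e-8)

    def test_posterior_rows_and_pi_normalized(self, small_fit):
        np.testing.assert_allclose(
            small_fit.posterior.sum(axis=1), 1.0, atol=1e-8
        )
        assert small_fit.structural.pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loglik_trace_nondecreasing(self, small_fit):
        diffs = np.diff(small_fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_single_item_recovery(self):
        rng = np.random.default_rng(5)
        q = make_qmatrix([[1], [1], [1], [1]])
        truth = [0.2, 0.8]
        items = [
            ItemParameters.from_probs(f"i{j}", "GDINA", 1, truth)
            for j in range(4)
        ]
        alpha = (rng.random(5000) < 0.5).astype(int)
        P = np.where(alpha[:, None] == 1, truth[1], truth[0])
        X = (rng.random((5000, 4)) < P).astype(float)
        fit = cs.em_fit(X, q, "GDINA", compute_covariances=False)
        for est in fit.items:
            p = est.probs()
            lo, hi = min(p), max(p)
            assert lo == pytest.approx(0.2, abs=0.03)
            assert hi == pytest.approx(0.8, abs=0.03)

    def test_constant_item_hits_smoothing_bound_without_crash(self):
        rng = np.random.default_rng(0)
        q = make_qmatrix([[1], [1]])
        X = np.column_stack(
            [np.ones(200), (rng.random(200) < 0.5).astype(float)]
        )
        fit = cs.em_fit(X, q, "GDINA", compute_covariances=False)
        assert fit.items[0].probs().min() > 0.9

    def test_missing_entries_ignored(self):
        q, items = two_item_setup()
        X = np.array([[1.0, np.nan], [np.nan, np.nan]])
        fit = cs.em_fit(
            X, q, "GDINA",
            config=cs.PipelineConfig(em_max_iter=5),
            compute_covariances=False,
        )
        assert np.isfinite(fit.loglik)

    def test_shape_mismatch_rejected(self):
        q, _ = two_item_setup()
        with pytest.raises(DataError):
            cs.em_fit(np.zeros((5, 3)), q)

    def test_missing_fraction_filter(self):
        X = np.array(
            [[1, 0, 1, 0], [1, np.nan, 1, 0], [np.nan, np.nan, np.nan, 0]]
        )
        kept, mask = cs.filter_missing_respondents(X, max_missing_fraction=0.3)
        assert mask.tolist() == [True, True, False]
        assert kept.shape == (2, 4)


class TestItemCovariance:
    def test_duplicating_respondents_halves_covariance(self, small_fit, small_study):
        import dataclasses

        X = small_study.responses.to_numpy(float)
        doubled = dataclasses.replace(
            small_fit,
            posterior=np.vstack([small_fit.posterior, small_fit.posterior]),
            responses=np.vstack([X, X]),
            item_covariances={},
        )
        c1 = cs.item_covariance(small_fit, "item01")
        c2 = cs.item_covariance(doubled, "item01")
        np.testing.assert_allclose(c2, c1 / 2, rtol=1e-10)

    def test_variances_nonnegative(self, small_fit):
        for item_id in small_fit.q.item_ids:
            cov = small_fit.item_covariances[item_id]
            assert (np.diag(cov) >= 0).all()


class TestEstimatorFacade:
    def test_sklearn_contract(self, small_study):
        est = cs.GDINAEstimator(q=small_study.q, max_iter=50)
        cloned = clone(est)
        assert cloned.get_params()["max_iter"] == 50
        X = small_study.responses.to_numpy(float)
        est.fit(X)
        assert est.pi_.shape == (8,)
        assert est.converged_ in (True, False)
        proba = est.predict_proba(X[:10])
        assert proba.shape == (10, 8)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
        profiles = est.predict(X[:10])
        assert profiles.shape == (10, 3)
        assert set(np.unique(profiles)) <= {0, 1}
        assert np.isfinite(est.score(X[:10]))

    def test_unfitted_raises(self, small_study):
        est = cs.GDINAEstimator(q=small_study.q)
        with pytest.raises(RuntimeError):
            est.predict(np.zeros((1, 12)))
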