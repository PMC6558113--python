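from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cdmscreen as cs
from cdmscreen.screening import (
    CATEGORIES,
    profile_categories,
    severity_probabilities_from_marginals,
)


def oracle_category(profile, taxonomy):
    """Independent re-coding of the ICD-10 counting rules."""
    names_present = {
        taxonomy.criteria[k] for k in range(len(profile)) if profile[k]
    }
    t = len(names_present & set(taxonomy.typical))
    c = len(names_present & set(taxonomy.common))
    if t == 3 and c >= 4:
        return "severe"
    elif (t >= 2 and c >= 3):
        return "moderate"
    elif t >= 2 and c >= 2:
        return "mild"
    else:
        return "none"


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "t,c,expected",
        [
            (0, 0, "none"),
            (2, 2, "mild"),
            (2, 3, "moderate"),
            (3, 3, "moderate"),
            (3, 4, "severe"),
            (1, 7, "none"),
            (2, 7, "moderate"),
            (3, 2, "mild"),
        ],
    )
    def test_count_thresholds(self, t, c, expected, taxonomy10):
        profile = np.zeros(10, dtype=int)
        profile[:t] = 1
        profile[3 : 3 + c] = 1
        assert cs.classify_profile(profile, taxonomy10) == expected

    def test_matches_oracle_on_all_profiles(self, taxonomy10):
        cats = profile_categories(taxonomy10)
        for w, profile in enumerate(cs.enumerate_profiles(10)):
            assert CATEGORIES[cats[w]] == oracle_category(profile, taxonomy10)

    def test_category_counts_over_profile_space(self, taxonomy10):
        # combinatorial oracle: severe = C(7,4)+C(7,5)+C(7,6)+C(7,7) = 64;
        # mild = 4 typical-configs x C(7,2) = 84; moderate = 3*99+35 = 332
        cats = profile_categories(taxonomy10)
        counts = dict(zip(CATEGORIES, np.bincount(cats, minlength=4)))
        assert counts == {"none": 544, "mild": 84, "moderate": 332, "severe": 64}


class TestSeverityProbabilities:
    def test_point_mass_on_healthy_profile(self, taxonomy10):
        post = np.zeros(1024)
        post[0] = 1.0
        sev = cs.severity_probabilities(post, taxonomy10)
        assert sev == {"none": 1.0, "mild": 0.0, "moderate": 0.0, "severe": 0.0}

    def test_uniform_posterior_matches_category_counts(self, taxonomy10):
        sev = cs.severity_probabilities(np.full(1024, 1 / 1024), taxonomy10)
        assert sev["severe"] == pytest.approx(64 / 1024)
        assert sev["moderate"] == pytest.approx(332 / 1024)
        assert sev["mild"] == pytest.approx(84 / 1024)
        assert sev["none"] == pytest.approx(544 / 1024)

    def test_two_point_split(self, taxonomy10):
        mild_profile = np.array([1, 1, 0, 1, 1, 0, 0, 0, 0, 0])
        severe_profile = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        post = np.zeros(1024)
        post[int(mild_profile @ (1 << np.arange(10)))] = 0.5
        post[int(severe_profile @ (1 << np.arange(10)))] = 0.5
        sev = cs.severity_probabilities(post, taxonomy10)
        assert sev["mild"] == pytest.approx(0.5)
        assert sev["severe"] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_posterior(self, seed, lam):
        taxonomy10 = cs.default_taxonomy()
        rng = np.random.default_rng(seed)
        p1 = rng.dirichlet(np.ones(1024))
        p2 = rng.dirichlet(np.ones(1024))
        mix = cs.severity_probabilities(lam * p1 + (1 - lam) * p2, taxonomy10)
        s1 = cs.severity_probabilities(p1, taxonomy10)
        s2 = cs.severity_probabilities(p2, taxonomy10)
        for cat in CATEGORIES:
            assert mix[cat] == pytest.approx(
                lam * s1[cat] + (1 - lam) * s2[cat], abs=1e-10
            )

    def test_permutation_invariance_within_common_block(self, taxonomy10):
        rng = np.random.default_rng(1)
        marg = rng.random(10)
        sev1 = severity_probabilities_from_marginals(marg, taxonomy10)
        marg2 = marg.copy()
        marg2[3:] = marg[3:][::-1]  # permute common-criteria marginals
        sev2 = severity_probabilities_from_marginals(marg2, taxonomy10)
        for cat in CATEGORIES:
            assert sev1[cat] == pytest.approx(sev2[cat], abs=1e-10)


class TestBuildReport:
    @pytest.fixture(scope="class")
    def fitted(self):
        design = cs.SimulationDesign(
            n_respondents=600, n_items=30, n_criteria=10,
            guessing_range=(0.05, 0.15), slip_range=(0.05, 0.15), seed=5,
        )
        study = cs.simulate_study(design)
        fit = cs.em_fit(
            study.responses.to_numpy(float), study.q,
            [p.model_tag for p in study.items], compute_covariances=False,
        )
        return study, fit

    def test_severity_sums_to_one(self, fitted, taxonomy10):
        study, fit = fitted
        X = study.responses.to_numpy(float)
        for i in range(20):
            rep = cs.build_report(X[i], fit, taxonomy10, f"r{i}")
            assert sum(rep.severity.values()) == pytest.approx(1.0, abs=1e-8)

    def test_all_missing_flags_insufficient_data(self, fitted, taxonomy10):
        study, fit = fitted
        rep = cs.build_report(
            np.full(study.q.n_items, np.nan), fit, taxonomy10, "empty"
        )
        assert "insufficient_data" in rep.flags
        prior_sev = cs.severity_probabilities(fit.structural.pi, taxonomy10)
        assert rep.severity["none"] == pytest.approx(prior_sev["none"])

    def test_suicidality_flag_from_marginal(self, fitted, taxonomy10):
        study, fit = fitted
        # find a respondent endorsing every C8 item
        c8 = taxonomy10.criteria.index("C8")
        c8_items = [
            j for j in range(study.q.n_items) if study.q.entries[j, c8]
        ]
        X = study.responses.to_numpy(float)
        marg = fit.marginal_posteriors()
        hi = int(np.argmax(marg[:, c8]))
        if marg[hi, c8] > 0.5:
            rep = cs.build_report(X[hi], fit, taxonomy10, "hi")
            assert "suicidality" in rep.flags
        lo = int(np.argmin(marg[:, c8]))
        rep_lo = cs.build_report(X[lo], fit, taxonomy10, "lo")
        assert "suicidality" not in rep_lo.flags

    def test_disorder_probabilities_exposed(self, fitted, taxonomy10):
        study, fit = fitted
        rep = cs.build_report(
            study.responses.to_numpy(float)[0], fit, taxonomy10, "r0"
        )
        assert rep.p_disorder == pytest.approx(1 - rep.severity["none"])
        assert rep.p_moderate_or_severe == pytest.approx(
            rep.severity["moderate"] + rep.severity["severe"]
        )
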