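import numpy as np
import pandas as pd
import pytest

import cdmscreen as cs
from cdmscreen.models import ItemParameters
from cdmscreen.simulate import (
    DesignError,
    sample_item_parameters,
    sample_profiles,
    sample_qmatrix,
    sample_responses,
    simulate_responses_from_items,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        d = cs.SimulationDesign(
            n_respondents=100, n_items=15, n_criteria=4, n_low_disc=2, seed=9
        )
        s1, s2 = cs.simulate_study(d), cs.simulate_study(d)
        pd.testing.assert_frame_equal(s1.responses, s2.responses)
        pd.testing.assert_frame_equal(s1.groups, s2.groups)
        np.testing.assert_array_equal(s1.q.entries, s2.q.entries)
        np.testing.assert_array_equal(s1.profiles, s2.profiles)
        assert s1.contamination == s2.contamination

    def test_different_seed_differs(self):
        d1 = cs.SimulationDesign(n_respondents=100, n_items=15, n_criteria=4, seed=9)
        d2 = cs.SimulationDesign(n_respondents=100, n_items=15, n_criteria=4, seed=10)
        assert not cs.simulate_study(d1).responses.equals(
            cs.simulate_study(d2).responses
        )


class TestSampleQMatrix:
    def test_every_criterion_covered(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(n_respondents=1, n_items=20, n_criteria=8)
        q = sample_qmatrix(d, rng)
        assert (q.entries.sum(axis=0) > 0).all()
        assert (q.entries.sum(axis=1) >= 1).all()

    def test_single_criterion_rows_give_permutation_like_q(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=1, n_items=10, n_criteria=10,
            criteria_per_item_probs={1: 1.0},
        )
        q = sample_qmatrix(d, rng)
        assert (q.entries.sum(axis=1) == 1).all()
        assert (q.entries.sum(axis=0) == 1).all()

    def test_infeasible_design_rejected(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=1, n_items=5, n_criteria=10,
            criteria_per_item_probs={1: 1.0},
        )
        with pytest.raises(DesignError):
            sample_qmatrix(d, rng)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pool_mean_criteria_per_item(self, seed):
        # the default histogram targets the initial pool's 1.67 average
        rng = np.random.default_rng(seed)
        d = cs.SimulationDesign(n_respondents=1)
        q = sample_qmatrix(d, rng)
        mean = q.entries.sum(axis=1).mean()
        assert mean == pytest.approx(1.67, abs=0.15)


class TestSampleProfiles:
    def test_independent_half_prevalence(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=20000, n_items=2, n_criteria=2,
            prevalence=0.5, latent_correlation=0.0,
        )
        profs = sample_profiles(d, rng)
        _, counts = np.unique(profs @ [1, 2], return_counts=True)
        np.testing.assert_allclose(counts / 20000, 0.25, atol=0.02)

    def test_high_correlation_concentrates_on_extremes(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=5000, n_items=2, n_criteria=5,
            prevalence=0.5, latent_correlation=0.98,
        )
        profs = sample_profiles(d, rng)
        frac_extreme = np.mean(
            (profs.sum(axis=1) == 0) | (profs.sum(axis=1) == 5)
        )
        assert frac_extreme > 0.8

    def test_marginal_prevalence(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=10000, n_items=2, n_criteria=4, prevalence=0.4
        )
        profs = sample_profiles(d, rng)
        np.testing.assert_allclose(profs.mean(axis=0), 0.4, atol=0.02)


class TestSampleItemParameters:
    def test_degenerate_ranges_fix_disc(self):
        rng = np.random.default_rng(0)
        d = cs.SimulationDesign(
            n_respondents=1, n_items=10, n_criteria=3,
            guessing_range=(0.1, 0.1), slip_range=(0.1, 0.1),
        )
        q = sample_qmatrix(d, rng)
        items = sample_item_parameters(d, q, rng)
        for p in items:
            assert cs.discrimination_index(p) == pytest.approx(0.8, abs=1e-9)

    def test_low_disc_items_below_threshold(self):
        rng = np.random.default_rng(1)
        d = cs.SimulationDesign(n_respondents=1, n_items=20, n_criteria=5)
        q = sample_qmatrix(d, rng)
        low = list(q.item_ids[:4])
        items = sample_item_parameters(d, q, rng, low_disc_items=low)
        for p in items:
            disc = cs.discrimination_index(p)
            if p.item_id in low:
                assert disc < 0.4
            else:
                assert disc >= 0.6

    def test_dina_interior_cells_at_null(self):
        rng = np.random.default_rng(2)
        d = cs.SimulationDesign(
            n_respondents=1, n_items=12, n_criteria=4,
            model_mixture={"DINA": 1.0},
            criteria_per_item_probs={2: 1.0},
        )
        q = sample_qmatrix(d, rng)
        items = sample_item_parameters(d, q, rng)
        for p in items:
            probs = p.probs()
            np.testing.assert_allclose(probs[1:3], probs[0], atol=1e-9)

    def test_infeasible_noise_ranges_rejected(self):
        with pytest.raises(DesignError):
            cs.SimulationDesign(guessing_range=(0.3, 0.6), slip_range=(0.3, 0.6))


class TestSampleResponses:
    def test_deterministic_items_reproduce_profiles(self):
        rng = np.random.default_rng(3)
        d = cs.SimulationDesign(
            n_respondents=200, n_items=4, n_criteria=4,
            criteria_per_item_probs={1: 1.0},
        )
        q = sample_qmatrix(d, rng)
        items = [
            ItemParameters.from_probs(i, "GDINA", 1, [0.0, 1.0])
            for i in q.item_ids
        ]
        profs = sample_profiles(d, rng)
        X = simulate_responses_from_items(items, q, profs, rng)
        order = [int(np.flatnonzero(q.entries[j])[0]) for j in range(4)]
        np.testing.assert_array_equal(X, profs[:, order])

    def test_endorsement_rate_matches_p_full(self):
        rng = np.random.default_rng(4)
        d = cs.SimulationDesign(
            n_respondents=20000, n_items=3, n_criteria=2,
            guessing_range=(0.1, 0.1), slip_range=(0.15, 0.15),
            prevalence=0.5,
        )
        q = sample_qmatrix(d, rng)
        items = sample_item_parameters(d, q, rng)
        profs = sample_profiles(d, rng)
        X = simulate_responses_from_items(items, q, profs, rng)
        j = 0
        req = q.required(j)
        holders = profs[:, req].all(axis=1)
        assert X[holders, j].mean() == pytest.approx(0.85, abs=0.02)

    def test_dif_shift_raises_focal_endorsement(self):
        rng = np.random.default_rng(5)
        d = cs.SimulationDesign(
            n_respondents=20000, n_items=3, n_criteria=2,
            guessing_range=(0.2, 0.2), slip_range=(0.3, 0.3),
            dif_shift=0.25, prevalence=0.5,
        )
        q = sample_qmatrix(d, rng)
        items = sample_item_parameters(d, q, rng)
        profs = sample_profiles(d, rng)
        focal = rng.integers(0, 2, 20000)
        X = sample_responses(
            profs, items, q, d, rng,
            dif_items=[q.item_ids[0]], focal=focal,
        ).to_numpy()
        req = q.required(0)
        null_holders = ~profs[:, req].any(axis=1)
        ref = X[null_holders & (focal == 0), 0].mean()
        foc = X[null_holders & (focal == 1), 0].mean()
        assert foc - ref == pytest.approx(0.25, abs=0.03)
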