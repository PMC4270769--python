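import numpy as np
import pytest

from emochoice.loocv import (loocv_predict, predict_left_out, probs_to_ranks,
                             rank_distribution)
from emochoice.synthetic_data import SynthConfig, generate_panel


class TestProbsToRanks:
    def test_uniform_ties_break_by_alternative_order(self):
        ranks = probs_to_ranks(np.full(7, 1 / 7))
        np.testing.assert_array_equal(ranks, np.arange(1, 8))

    def test_hand_example_with_tied_tail(self):
        probs = np.array([0.4, 0.3, 0.1, 0.05, 0.05, 0.05, 0.05])
        np.testing.assert_array_equal(probs_to_ranks(probs),
                                      [1, 2, 3, 4, 5, 6, 7])

    def test_strictly_decreasing_vector_is_identity(self):
        probs = np.array([0.5, 0.25, 0.15, 0.1])
        np.testing.assert_array_equal(probs_to_ranks(probs), [1, 2, 3, 4])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            probs_to_ranks(np.array([0.5, np.nan, 0.5]))

    def test_always_a_permutation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(7))
            assert sorted(probs_to_ranks(p)) == list(range(1, 8))


class TestRankDistribution:
    def _pred(self, chosen_rank):
        from emochoice.loocv import RankPrediction

        return RankPrediction("s", np.full(7, 1 / 7), np.arange(1, 8),
                              chosen_rank, "A")

    def test_all_rank_one_gives_hundred_percent(self):
        dist = rank_distribution([self._pred(1)] * 5)
        np.testing.assert_allclose(dist.percent_at_rank,
                                   [100, 0, 0, 0, 0, 0, 0])

    def test_percentages_sum_to_hundred(self):
        preds = [self._pred(r) for r in (1, 1, 2, 3, 7)]
        dist = rank_distribution(preds)
        assert dist.percent_at_rank.sum() == pytest.approx(100.0)
        assert dist.chance_level == pytest.approx(100 / 7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no predictions"):
            rank_distribution([])


class TestLoocvPredict:
    def test_dominant_alternative_ranked_first_for_everyone(self):
        # product F towers over the rest in valence (hence liking) for every
        # subject, while choices stay mixed enough for stable fold fits
        cfg = SynthConfig(seed=2, n_subjects=12,
                          product_valence=(-0.5, -0.5, -0.5, -0.5, -0.5, 1.6, -0.5),
                          product_arousal=(0.0,) * 7, subject_sd=0.4)
        panel, _ = generate_panel(cfg)
        result = loocv_predict(panel, predictors=("liking", "pc1"))
        assert not result.failures
        f_index = panel.alternatives.index("F")
        for pred in result.predictions:
            assert pred.ranks[f_index] == 1

    def test_predictions_beat_chance_under_default_conditions(self, small_panel):
        panel, _ = small_panel
        result = loocv_predict(panel, predictors=("liking", "pc1"))
        dist = result.distribution()
        assert not result.failures
        assert dist.percent_at_rank[0] > dist.chance_level

    def test_fold_output_depends_only_on_training_and_own_rows(self, small_panel):
        """No-leakage contract: the held-out subject's prediction equals the
        one recomputed from a training panel that never contained them, even
        when that subject's rows are corrupted before being dropped."""
        panel, _ = small_panel
        result = loocv_predict(panel, predictors=("liking", "pc1"))
        for subject in panel.subjects[:3]:
            corrupted = panel.copy()
            rows = corrupted.data["subject"] == subject
            corrupted.data.loc[rows, corrupted.emotion_names] = 0.0
            corrupted.data.loc[rows, "liking"] = 50.0
            train = corrupted.drop_subject(subject)
            probs, _, _ = predict_left_out(train, panel.subject_rows(subject),
                                           predictors=("liking", "pc1"))
            got = next(p for p in result.predictions if p.subject_id == subject)
            np.testing.assert_allclose(got.probs, probs, atol=1e-12)

    def test_permuting_subject_order_leaves_predictions_unchanged(self, small_panel):
        panel, _ = small_panel
        r1 = loocv_predict(panel, predictors=("liking", "pc1"))
        shuffled = panel.copy()
        rng = np.random.default_rng(1)
        order = {s: i for i, s in enumerate(rng.permutation(panel.subjects))}
        shuffled.data["__o"] = shuffled.data["subject"].map(order)
        shuffled.data = (shuffled.data.sort_values("__o", kind="stable")
                         .drop(columns="__o").reset_index(drop=True))
        r2 = loocv_predict(shuffled, predictors=("liking", "pc1"))
        by_subject = {p.subject_id: p for p in r2.predictions}
        for p in r1.predictions:
            np.testing.assert_allclose(p.probs, by_subject[p.subject_id].probs,
                                       atol=1e-10)

    def test_scaling_convention_cannot_change_predictions(self, small_panel):
        """Standardization is a shared affine map of the covariates, and the
        conditional logit is equivariant under those: the slopes rescale but
        the fitted probabilities are identical.  The fold-wise vs global
        scaling choice therefore only affects reported coefficients."""
        panel, _ = small_panel
        fold = loocv_predict(panel, predictors=("liking", "pc1"), scaling="fold")
        glob = loocv_predict(panel, predictors=("liking", "pc1"), scaling="global")
        a = np.stack([p.probs for p in fold.predictions])
        b = np.stack([p.probs for p in glob.predictions])
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_higher_valence_effect_improves_rank_one_share(self):
        shares = []
        for beta in (0.2, 2.0):
            cfg = SynthConfig(seed=17, n_subjects=60, beta_valence=beta)
            panel, _ = generate_panel(cfg)
            dist = loocv_predict(panel, predictors=("liking", "pc1")).distribution()
            shares.append(dist.percent_at_rank[0])
        assert shares[1] > shares[0]

    def test_panel_without_choice_rejected(self, small_panel):
        panel, _ = small_panel
        bare = panel.copy()
        bare.data = bare.data.drop(columns=["chosen"])
        with pytest.raises(ValueError, match="choice"):
            loocv_predict(bare)
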