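"""Condition summaries, format main-effect test, and benefit correlations."""

import numpy as np
import pandas as pd
import pytest

from avsin.cohort import (
    benefit_correlation,
    summarize_conditions,
    test_format_effect,
)


def make_scored(rows):
    df = pd.DataFrame(
        rows, columns=["participant", "batch", "word", "format", "word_correct", "jaccard"]
    )
    return df


class TestSummarizeConditions:
    def test_simple_proportion(self):
        rows = [("p1", "b1", f"w{i}", "An", i < 2, 0.5) for i in range(4)]
        summary, grand = summarize_conditions(make_scored(rows))
        assert summary.loc[0, "mean_word_accuracy"] == 0.5
        assert summary.loc[0, "n_trials"] == 4

    def test_ceiling(self):
        rows = [(p, "b1", f"w{i}", "An", True, 1.0) for p in ("p1", "p2") for i in range(3)]
        _, grand = summarize_conditions(make_scored(rows))
        assert (grand["mean_word_accuracy"] == 1.0).all()
        assert (grand["mean_phoneme_accuracy"] == 1.0).all()

    def test_grand_mean_order_invariant(self, small_experiment):
        _, scored = small_experiment
        _, g1 = summarize_conditions(scored)
        _, g2 = summarize_conditions(scored.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            g1.sort_values("format").reset_index(drop=True),
            g2.sort_values("format").reset_index(drop=True),
        )

    def test_equal_trial_counts_match_pooled_proportion(self, small_experiment):
        # counterbalanced design gives every participant the same per-format
        # trial count, so participant-then-average equals the pooled mean
        _, scored = small_experiment
        _, grand = summarize_conditions(scored)
        pooled = scored.groupby("format")["word_correct"].mean()
        for fmt in pooled.index:
            row = grand[grand["format"] == fmt]
            assert row["mean_word_accuracy"].iloc[0] == pytest.approx(pooled[fmt])


class TestFormatEffect:
    def test_detects_planted_format_effect(self, small_experiment):
        _, scored = small_experiment
        for measure in ("word", "phoneme"):
            res = test_format_effect(scored, measure=measure)
            assert res.df == 3
            assert res.p_value < 1e-6
            assert len(res.contrasts) == 6

    def test_face_formats_beat_auditory_only(self, small_experiment):
        _, scored = small_experiment
        res = test_format_effect(scored, measure="word")
        an_contrasts = [c for c in res.contrasts if "An" in (c[0], c[1])]
        assert len(an_contrasts) == 3
        assert all(p < 0.001 for *_, p in an_contrasts)

    def test_requires_multiple_participants(self):
        rows = [("p1", "b1", f"w{i}", f, i % 2 == 0, 0.5)
                for i in range(4) for f in ("An", "AnV_Real")]
        with pytest.raises(ValueError):
            test_format_effect(make_scored(rows))

    def test_mixed_and_fixed_agree_on_strong_effect(self, small_experiment):
        _, scored = small_experiment
        mixed = test_format_effect(scored, measure="phoneme", method="mixed")
        fixed = test_format_effect(scored, measure="phoneme", method="fixed")
        assert mixed.p_value < 1e-6 and fixed.p_value < 1e-6


class TestBenefitCorrelation:
    @staticmethod
    def _summary(rng, n=30, shared=0.0):
        ability = rng.normal(0, 0.1, n) * shared
        rows = []
        for i in range(n):
            base = 0.2 + rng.normal(0, 0.03)
            rows.append((f"p{i}", "An", base, base, 16))
            for fmt, lift in (("AnV_Real", 0.4), ("AnV_FACS", 0.2), ("AnV_DNN", 0.2)):
                noise = rng.normal(0, 0.05)
                acc = np.clip(base + lift + ability[i] + noise, 0, 1)
                rows.append((f"p{i}", fmt, acc, acc, 16))
        return pd.DataFrame(
            rows,
            columns=["participant", "format", "mean_word_accuracy",
                     "mean_phoneme_accuracy", "n_trials"],
        )

    def test_identical_benefits_give_r_one(self):
        rng = np.random.default_rng(0)
        summary = self._summary(rng, shared=1.0)
        # force real benefit == synthetic benefit exactly
        wide = summary.pivot(index="participant", columns="format",
                             values="mean_word_accuracy")
        wide["AnV_Real"] = (wide["AnV_FACS"] + wide["AnV_DNN"]) / 2
        rebuilt = wide.reset_index().melt(
            id_vars="participant", var_name="format", value_name="mean_word_accuracy"
        )
        rebuilt["mean_phoneme_accuracy"] = rebuilt["mean_word_accuracy"]
        rebuilt["n_trials"] = 16
        r, p, n = benefit_correlation(rebuilt, "real_vs_synthetic", "word")
        assert r == pytest.approx(1.0)

    def test_shared_ability_detected(self):
        rng = np.random.default_rng(1)
        r, p, n = benefit_correlation(self._summary(rng, n=60, shared=1.0))
        assert r > 0.3 and p < 0.05

    def test_null_correlation_small(self):
        rng = np.random.default_rng(2)
        rs = [benefit_correlation(self._summary(rng, n=40, shared=0.0))[0]
              for _ in range(20)]
        assert abs(np.mean(rs)) < 0.15

    def test_degenerate_benefits_raise(self):
        rows = [(f"p{i}", fmt, 0.5, 0.5, 16)
                for i in range(5)
                for fmt in ("An", "AnV_Real", "AnV_FACS", "AnV_DNN")]
        summary = pd.DataFrame(
            rows, columns=["participant", "format", "mean_word_accuracy",
                           "mean_phoneme_accuracy", "n_trials"])
        with pytest.raises(ValueError, match="degenerate"):
            benefit_correlation(summary)
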