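"""Synthetic-experiment generator: design, determinism, transmission limits."""

import numpy as np
import pandas as pd
import pytest

import avsin
from avsin.phonemes import ARPABET
from avsin.simulate import (
    SimConfig,
    assign_formats,
    default_transmission,
    load_viseme_map,
    make_stimulus_set,
    pseudo_word,
    simulate_experiment,
)


class TestVisemeMap:
    def test_total_over_39_phonemes(self):
        vm = load_viseme_map()
        assert set(vm) == ARPABET

    def test_dental_and_labiodental_are_separate_classes(self):
        vm = load_viseme_map()
        assert vm["F"] == vm["V"]
        assert vm["TH"] == vm["DH"]
        assert vm["F"] != vm["TH"]


class TestAssignFormats:
    def test_latin_square_core(self):
        a = assign_formats(4, ["w1", "w2", "w3", "w4"])
        counts = a.groupby(["word", "format"]).size()
        assert (counts == 1).all()

    def test_study_design_16_words_per_format(self):
        a = assign_formats(61, [f"w{i}" for i in range(64)])
        per_participant = a.groupby(["participant_index", "format"]).size()
        assert (per_participant == 16).all()

    def test_full_crossing_balance(self):
        a = assign_formats(61, [f"w{i}" for i in range(64)])
        per_word = a.groupby(["word", "format"]).size().unstack()
        assert int(per_word.max().max() - per_word.min().min()) <= 1
        # every word appears in every format at least once
        assert per_word.notna().all().all() and (per_word > 0).all().all()

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            assign_formats(4, ["w1", "w2", "w3"])


class TestStimulusSet:
    def test_deterministic_under_seed(self, lexicon):
        cfg = SimConfig(seed=42)
        s1 = make_stimulus_set(cfg, lexicon, np.random.default_rng(42))
        s2 = make_stimulus_set(cfg, lexicon, np.random.default_rng(42))
        pd.testing.assert_frame_equal(s1, s2)

    def test_talker_split_and_disjoint_catch(self, lexicon):
        cfg = SimConfig(n_words=64, catch_trials_per_participant=9)
        s = make_stimulus_set(cfg, lexicon, np.random.default_rng(0))
        main = s[~s["is_catch"]]
        assert (main["talker"] == "female").sum() == 32
        assert (main["talker"] == "male").sum() == 32
        assert not set(main["word"]) & set(s[s["is_catch"]]["word"])
        assert main["word"].is_unique

    def test_viseme_coverage(self, lexicon):
        vm = load_viseme_map()
        cfg = SimConfig(n_words=64)
        s = make_stimulus_set(cfg, lexicon, np.random.default_rng(3))
        covered = {vm[p] for ph in s[~s["is_catch"]]["phonemes"] for p in ph.split()}
        assert covered == set(vm.values())


class TestSimulateExperiment:
    def test_default_design_73_trials_per_participant(self, lexicon):
        res = simulate_experiment(SimConfig(n_participants=3, seed=0), lexicon)
        per = res.trials.groupby("participant").size()
        assert (per == 73).all()
        catch = res.trials[res.trials["format"] == "AV_catch"]
        assert (catch.groupby("participant").size() == 9).all()

    def test_byte_identical_under_same_seed(self, lexicon):
        r1 = simulate_experiment(SimConfig(n_participants=4, seed=9), lexicon)
        r2 = simulate_experiment(SimConfig(n_participants=4, seed=9), lexicon)
        assert r1.trials.to_csv(index=False) == r2.trials.to_csv(index=False)

    def test_noiseless_limit_reproduces_stimuli(self, lexicon):
        vm = load_viseme_map()
        trans = {k: 1.0 for k in default_transmission(vm)}
        res = simulate_experiment(
            SimConfig(n_participants=2, transmission=trans, seed=1), lexicon
        )
        # reconstruction may return a homophone of the stimulus (sea/see) under
        # the alphabetical tie-break, so assert word-level correctness, which
        # treats homophones as correct by design
        scored = avsin.scored_to_frame(avsin.score_trials(res.trials, res.lexicon))
        assert scored["word_correct"].all()
        assert (scored["jaccard"] == 1.0).all()

    def test_total_loss_limit_zero_overlap(self, lexicon):
        vm = load_viseme_map()
        trans = {k: 0.0 for k in default_transmission(vm)}
        cfg = SimConfig(
            n_participants=2, transmission=trans, seed=1,
            lexical_reconstruction=False, slip_model="delete",
            catch_trials_per_participant=0,
        )
        res = simulate_experiment(cfg, lexicon)
        scored = avsin.scored_to_frame(avsin.score_trials(res.trials, res.lexicon))
        # every phoneme deleted: responses are random fallback words, which can
        # share phonemes with the stimulus only by chance; identification
        # counting must credit none of the planted transmissions
        assert scored["jaccard"].mean() < 0.25

    def test_catch_trials_near_ceiling(self, small_experiment):
        _, scored = small_experiment
        catch = scored[scored["format"] == "AV_catch"]
        assert catch["word_correct"].mean() > 0.95

    def test_pseudo_word_round_trips_through_scoring(self, lexicon):
        cfg = SimConfig(
            n_participants=2, seed=5, lexical_reconstruction=False,
            slip_model="delete", catch_trials_per_participant=0,
        )
        res = simulate_experiment(cfg, lexicon)
        pseudo = res.trials[res.trials["response"].str.startswith("qq")]
        assert len(pseudo) > 0
        row = pseudo.iloc[0]
        variants = res.lexicon.variants(row["response"])
        assert len(variants) == 1
        assert pseudo_word(variants[0]) == row["response"]

    def test_reconstruction_monotone_in_transmission(self, lexicon):
        """Raising every transmission probability cannot hurt word accuracy."""
        vm = load_viseme_map()
        lo = {k: 0.35 for k in default_transmission(vm)}
        hi = {k: 0.75 for k in default_transmission(vm)}
        accs = []
        for trans in (lo, hi):
            res = simulate_experiment(
                SimConfig(n_participants=8, transmission=trans, seed=2), lexicon
            )
            scored = avsin.scored_to_frame(avsin.score_trials(res.trials, res.lexicon))
            accs.append(scored["word_correct"].mean())
        assert accs[1] > accs[0]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_words=63)
        with pytest.raises(ValueError):
            SimConfig(slip_model="typo")
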