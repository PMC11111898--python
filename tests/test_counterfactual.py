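"""Phoneme-presence logistic model, counterfactual substitution, prevalence."""

import numpy as np
import pandas as pd
import pytest

from avsin.counterfactual import (
    PhonemePresenceModel,
    build_design,
    fit_model,
    load_prevalence,
    prevalence_extrapolation,
)
from avsin.phoneme_rates import count_identifications, pooled_rates


class TestBuildDesign:
    def test_presence_coding(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        av = scored[scored["format"].isin(("AnV_Real", "AnV_FACS", "AnV_DNN"))]
        assert len(design) == len(av)
        row = design.iloc[0]
        present = set(av.iloc[0]["stimulus_phonemes"].split())
        for col in design.columns:
            if col.startswith("ph_"):
                assert row[col] == (1.0 if col[3:] in present else 0.0)

    def test_repeated_phoneme_still_presence_one(self):
        scored = pd.DataFrame(
            [{"participant": "p1", "batch": "b1", "word": "teeth",
              "format": "AnV_Real", "stimulus_phonemes": "T IY TH",
              "response_phonemes": "T IY TH", "word_correct": True, "jaccard": 1.0},
             {"participant": "p1", "batch": "b1", "word": "cotton",
              "format": "AnV_FACS", "stimulus_phonemes": "K AA T AH N",
              "response_phonemes": "K AA T AH N", "word_correct": True, "jaccard": 1.0}]
        )
        design = build_design(scored)
        assert design["ph_T"].tolist() == [1.0, 1.0]

    def test_excludes_auditory_only_trials(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        assert set(design["face_class"]) == {"real", "synthetic"}


class TestFit:
    def test_calibration_in_the_large(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = fit_model(design)
        for cls in ("real", "synthetic"):
            sub = design[design["face_class"] == cls]
            observed = sub["word_correct"].mean()
            predicted = model.predict_proba(sub).mean()
            assert predicted == pytest.approx(observed, abs=0.01)

    def test_predictions_strictly_inside_unit_interval(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = fit_model(design)
        p = model.predict_proba(design)
        assert np.all(p > 0) and np.all(p < 1)

    def test_parameter_recovery(self):
        """Coefficients recovered from data generated by a known model."""
        rng = np.random.default_rng(5)
        phonemes = ["B", "F", "K", "S", "TH", "V"]
        true_real = {p: 1.0 for p in phonemes}
        true_synth = {"B": 1.0, "K": 1.0, "S": 1.0, "F": -1.0, "TH": -1.0, "V": -1.0}
        rows = []
        for i in range(5000):
            cls = "real" if i % 2 == 0 else "synthetic"
            present = rng.choice([0.0, 1.0], size=len(phonemes))
            while present.sum() == 0:
                present = rng.choice([0.0, 1.0], size=len(phonemes))
            beta = true_real if cls == "real" else true_synth
            eta = -1.0 + sum(b * beta[p] for p, b in zip(phonemes, present))
            y = float(rng.random() < 1 / (1 + np.exp(-eta)))
            row = {"word": f"w{i}", "face_class": cls, "word_correct": y}
            row.update({f"ph_{p}": b for p, b in zip(phonemes, present)})
            rows.append(row)
        model = PhonemePresenceModel(ridge=0.1).fit(pd.DataFrame(rows))
        err_real = [abs(model.beta_real_[p] - true_real[p]) for p in phonemes]
        err_synth = [abs(model.beta_synthetic_[p] - true_synth[p]) for p in phonemes]
        # ~2 SE tolerance at n=2500 per class
        assert np.mean(np.array(err_real + err_synth) < 0.35) >= 0.9

    def test_all_correct_outcomes_stay_finite(self):
        rows = []
        for i in range(40):
            rows.append({"word": f"w{i}", "face_class": "real" if i % 2 else "synthetic",
                         "word_correct": 1.0, "ph_B": float(i % 3 == 0),
                         "ph_TH": float(i % 3 != 0)})
        model = fit_model(pd.DataFrame(rows))
        coefs = list(model.beta_real_.values()) + list(model.beta_synthetic_.values())
        assert np.all(np.isfinite(coefs))

    def test_fit_r2_high_on_generated_data(self, small_experiment):
        _, scored = small_experiment
        model = fit_model(build_design(scored))
        assert 0.3 < model.fit_r2_ <= 1.0


class TestCounterfactual:
    def test_empty_improved_set_is_identity(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = fit_model(design)
        baseline, cf = model.counterfactual_accuracy(design, ())
        assert cf == baseline

    def test_improving_degraded_phonemes_helps(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = fit_model(design)
        improved = tuple(p for p in ("TH", "DH", "F", "V") if p in model.phonemes_)
        assert all(model.beta_real_[p] > model.beta_synthetic_[p] for p in improved)
        baseline, cf = model.counterfactual_accuracy(design, improved)
        assert cf > baseline

    def test_full_substitution_limit_shared_intercept(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = PhonemePresenceModel(separate_intercepts=False).fit(design)
        _, cf = model.counterfactual_accuracy(design, tuple(model.phonemes_))
        synth = design[design["face_class"] == "synthetic"].copy()
        as_real = synth.assign(face_class="real")
        expected = model.predict_proba(as_real).mean()
        assert cf == pytest.approx(expected, abs=1e-12)

    def test_unknown_phoneme_rejected(self, small_experiment):
        _, scored = small_experiment
        design = build_design(scored)
        model = fit_model(design)
        with pytest.raises(KeyError):
            model.counterfactual_accuracy(design, ("ZZ",))


class TestPrevalence:
    def test_uniform_weights_give_unweighted_mean(self, small_experiment):
        _, scored = small_experiment
        pooled = pooled_rates(count_identifications(scored))
        phonemes = sorted(pooled["phoneme"].unique())
        uniform = pd.Series(1.0, index=phonemes)
        out = prevalence_extrapolation(pooled, uniform)
        real = pooled[pooled["face_type"] == "Real"]
        assert out.loc["Real", "predicted_accuracy"] == pytest.approx(
            real["rate"].mean()
        )

    def test_degenerate_weights_select_single_phoneme(self, small_experiment):
        _, scored = small_experiment
        pooled = pooled_rates(count_identifications(scored))
        real = pooled[pooled["face_type"] == "Real"]
        target = real.iloc[0]
        weights = pd.Series(0.0, index=sorted(pooled["phoneme"].unique()))
        weights[target["phoneme"]] = 1.0
        out = prevalence_extrapolation(pooled, weights)
        assert out.loc["Real", "predicted_accuracy"] == pytest.approx(target["rate"])

    def test_linear_in_rates(self, small_experiment):
        _, scored = small_experiment
        pooled = pooled_rates(count_identifications(scored))
        prevalence = load_prevalence()
        out1 = prevalence_extrapolation(pooled, prevalence)
        scaled = pooled.copy()
        scaled["rate"] = scaled["rate"] * 0.5
        out2 = prevalence_extrapolation(scaled, prevalence)
        for face in out1.index:
            assert out2.loc[face, "predicted_accuracy"] == pytest.approx(
                0.5 * out1.loc[face, "predicted_accuracy"]
            )

    def test_packaged_table_loads_and_is_nonnegative(self):
        w = load_prevalence()
        assert (w >= 0).all()
        assert len(w) == 39
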