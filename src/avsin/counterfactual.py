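"""Counterfactual phoneme-presence model of word accuracy.

A logistic model predicts whether a trial's word was reported correctly from
the presence or absence of each phoneme in the stimulus word, with a separate
coefficient per phoneme for real-face and synthetic-face (DNN and FACS
pooled) trials and one intercept per face class. Replacing selected synthetic
coefficients with their real-face counterparts predicts the word accuracy
that would be obtained if synthetic faces rendered those phonemes as well as
real faces do. A prevalence-weighting utility extrapolates per-phoneme
identification rates to a corpus with a different phoneme frequency profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from importlib import resources

logger = logging.getLogger(__name__)

_FACE_CLASS = {"AnV_Real": "real", "AnV_FACS": "synthetic", "AnV_DNN": "synthetic"}


def build_design(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-trial design rows for the phoneme-presence model.

    Only audiovisual (AnV) trials enter; DNN and FACS are pooled as the
    synthetic face class. Each phoneme gets a 0/1 presence indicator (1 iff
    it occurs at least once in the stimulus word's phonemization, regardless
    of multiplicity).

    Returns a DataFrame with columns ``word``, ``face_class``,
    ``word_correct`` and one ``ph_<SYMBOL>`` indicator per phoneme observed.
    """
    av = scored[scored["format"].isin(_FACE_CLASS)].copy()
    if av.empty:
        raise ValueError("no audiovisual (AnV) trials in input")
    av["face_class"] = av["format"].map(_FACE_CLASS)
    phonemes = sorted(
        {p for s in av["stimulus_phonemes"] for p in str(s).split()}
    )
    rows = []
    for row in av.itertuples(index=False):
        present = set(str(row.stimulus_phonemes).split())
        if not present:
            logger.warning("word %r has no phonemization; excluded", row.word)
            continue
        rec = {
            "word": row.word,
            "face_class": row.face_class,
            "word_correct": float(row.word_correct),
        }
        for p in phonemes:
            rec[f"ph_{p}"] = 1.0 if p in present else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class PhonemePresenceModel:
    """Logistic phoneme-presence model with per-face-class coefficients.

    Fit by penalized maximum likelihood (a small ridge penalty on the
    phoneme coefficients stabilizes the fit under quasi-separation, which is
    routine here because presence indicators are collinear across the small
    word set). Follows the fit/predict convention: construct, ``fit`` on a
    design table, then ``predict_proba`` / ``counterfactual_accuracy``.

    Parameters
    ----------
    ridge
        L2 penalty strength on phoneme coefficients (intercepts unpenalized).
    separate_intercepts
        One intercept per face class (default; aids identifiability, since
        presence indicators are near-collinear across words) or a single
        shared intercept.
    max_iter, tol
        Newton iteration controls.

    Attributes (set by :meth:`fit`)
    -------------------------------
    phonemes_ : list of phoneme symbols in the design
    beta_real_, beta_synthetic_ : dict phoneme -> log-odds coefficient
    intercept_real_, intercept_synthetic_ : per-class intercepts
    fit_r2_ : squared Pearson correlation between observed and predicted
        per-word-per-face-class accuracy
    fit_p_ : two-tailed p for that correlation
    n_trials_fit_ : number of trials used
    """

    ridge: float = 1.0
    separate_intercepts: bool = True
    max_iter: int = 500
    tol: float = 1e-8

    phonemes_: list[str] = field(default_factory=list, repr=False)
    beta_real_: dict[str, float] = field(default_factory=dict, repr=False)
    beta_synthetic_: dict[str, float] = field(default_factory=dict, repr=False)
    intercept_real_: float = field(default=0.0, repr=False)
    intercept_synthetic_: float = field(default=0.0, repr=False)
    fit_r2_: float = field(default=np.nan, repr=False)
    fit_p_: float = field(default=np.nan, repr=False)
    n_trials_fit_: int = field(default=0, repr=False)

    # -- matrix assembly -------------------------------------------------
    @property
    def _n_icpt(self) -> int:
        return 2 if self.separate_intercepts else 1

    def _matrix(self, design: pd.DataFrame) -> np.ndarray:
        """[intercept column(s), real phoneme block, synthetic phoneme block]."""
        ind = design[[f"ph_{p}" for p in self.phonemes_]].to_numpy(float)
        is_real = (design["face_class"] == "real").to_numpy(float)[:, None]
        if self.separate_intercepts:
            icpt = [is_real, 1.0 - is_real]
        else:
            icpt = [np.ones_like(is_real)]
        return np.hstack(icpt + [ind * is_real, ind * (1.0 - is_real)])

    def fit(self, design: pd.DataFrame) -> "PhonemePresenceModel":
        """Fit by ridge-penalized Newton-Raphson maximum likelihood."""
        self.phonemes_ = sorted(
            c[3:] for c in design.columns if c.startswith("ph_")
        )
        y = design["word_correct"].to_numpy(float)
        X = self._matrix(design)
        n, k = X.shape
        penalty = np.full(k, self.ridge)
        penalty[: self._n_icpt] = 0.0  # intercepts unpenalized
        beta = np.zeros(k)
        for _ in range(self.max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            grad = X.T @ (y - mu) - penalty * beta
            hess = (X * w[:, None]).T @ X + np.diag(penalty + 1e-10)
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                break
        else:
            # saturated cells converge slowly; accept near-stationary points
            if np.max(np.abs(step)) > 1e-2:
                raise RuntimeError(
                    "phoneme-presence model failed to converge "
                    f"(last step {np.max(np.abs(step)):.2g})"
                )
        if not np.all(np.isfinite(beta)):
            raise RuntimeError("non-finite coefficients in phoneme-presence model")
        ni = self._n_icpt
        self.intercept_real_ = float(beta[0])
        self.intercept_synthetic_ = float(beta[1] if ni == 2 else beta[0])
        m = len(self.phonemes_)
        self.beta_real_ = dict(zip(self.phonemes_, beta[ni : ni + m]))
        self.beta_synthetic_ = dict(zip(self.phonemes_, beta[ni + m :]))
        self.n_trials_fit_ = n
        self._score_fit(design)
        return self

    def _score_fit(self, design: pd.DataFrame) -> None:
        """Observed vs predicted accuracy per word x face class."""
        pred = self.predict_proba(design)
        frame = design[["word", "face_class", "word_correct"]].copy()
        frame["pred"] = pred
        cell = frame.groupby(["word", "face_class"]).mean(numeric_only=True)
        if len(cell) > 2 and cell["word_correct"].std() > 0:
            r, p = stats.pearsonr(cell["word_correct"], cell["pred"])
            self.fit_r2_, self.fit_p_ = float(r**2), float(p)
        else:
            self.fit_r2_, self.fit_p_ = np.nan, np.nan

    def predict_proba(
        self,
        design: pd.DataFrame,
        beta_synthetic: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Predicted correct-report probability per design row.

        ``beta_synthetic`` optionally overrides the fitted synthetic-face
        coefficients (used for counterfactual substitution).
        """
        if not self.phonemes_:
            raise RuntimeError("model is not fitted")
        bs = self.beta_synthetic_ if beta_synthetic is None else beta_synthetic
        m = len(self.phonemes_)
        ni = self._n_icpt
        beta = np.empty(ni + 2 * m)
        beta[0] = self.intercept_real_
        if ni == 2:
            beta[1] = self.intercept_synthetic_
        beta[ni : ni + m] = [self.beta_real_[p] for p in self.phonemes_]
        beta[ni + m :] = [bs[p] for p in self.phonemes_]
        eta = self._matrix(design) @ beta
        return 1.0 / (1.0 + np.exp(-eta))

    def counterfactual_accuracy(
        self, design: pd.DataFrame, improved: tuple[str, ...]
    ) -> tuple[float, float]:
        """Mean predicted synthetic-face accuracy before and after improvement.

        ``improved`` phonemes have their synthetic coefficients replaced by
        the real-face coefficients; both means are over synthetic-face trials.
        """
        unknown = set(improved) - set(self.phonemes_)
        if unknown:
            raise KeyError(f"improved phonemes not in model: {sorted(unknown)}")
        synth = design[design["face_class"] == "synthetic"]
        baseline = float(self.predict_proba(synth).mean())
        bs = dict(self.beta_synthetic_)
        for p in improved:
            bs[p] = self.beta_real_[p]
        counterfactual = float(self.predict_proba(synth, beta_synthetic=bs).mean())
        return baseline, counterfactual


def fit_model(design: pd.DataFrame, ridge: float = 1.0) -> PhonemePresenceModel:
    """Fit a :class:`PhonemePresenceModel` on a design table."""
    return PhonemePresenceModel(ridge=ridge).fit(design)


def counterfactual_accuracy(
    model: PhonemePresenceModel,
    design: pd.DataFrame,
    improved: tuple[str, ...],
) -> tuple[float, float]:
    """Functional form of :meth:`PhonemePresenceModel.counterfactual_accuracy`."""
    return model.counterfactual_accuracy(design, improved)


# ---------------------------------------------------------------------------
# prevalence-weighted corpus extrapolation


def load_prevalence(path: str | Path | None = None) -> pd.Series:
    """Load a phoneme -> relative frequency table (two-column delimited).

    With no path, the packaged SYNTHETIC placeholder table is loaded (it is
    for exercising the machinery, not a published English frequency count).
    """
    if path is None:
        path = Path(resources.files("avsin.data") / "prevalence_synthetic.tsv")
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     names=["phoneme", "weight"])
    w = pd.Series(df["weight"].to_numpy(float), index=df["phoneme"].str.upper())
    if (w < 0).any():
        raise ValueError("prevalence weights must be nonnegative")
    return w


def prevalence_extrapolation(
    pooled_rates: pd.DataFrame, prevalence: pd.Series
) -> pd.DataFrame:
    """Prevalence-weighted phoneme accuracy per condition.

    For each face type present in ``pooled_rates`` (one row per phoneme x
    face type with a ``rate`` column), predicts the phoneme accuracy of a
    corpus whose phoneme frequencies follow ``prevalence``:

        predicted(condition) = sum_p w_p * rate_p(condition)

    with weights renormalized over the phonemes present in both inputs.
    The output also reports each condition's unweighted ("actual stimulus
    set") pooled accuracy and, when Real and both synthetic face types are
    present, a ``Synthetic`` row (mean of DNN and FACS) so the
    real-synthetic difference can be read off directly.
    """
    table = pooled_rates.copy()
    if {"DNN", "FACS"} <= set(table["face_type"]):
        synth = (
            table[table["face_type"].isin(["DNN", "FACS"])]
            .groupby("phoneme")
            .agg(n_identified=("n_identified", "sum"), n_presented=("n_presented", "sum"),
                 rate=("rate", "mean"))
            .reset_index()
        )
        synth["face_type"] = "Synthetic"
        table = pd.concat([table, synth], ignore_index=True)
    out = []
    for face, sub in table.groupby("face_type"):
        common = sub[sub["phoneme"].isin(prevalence.index)]
        dropped = set(sub["phoneme"]) - set(common["phoneme"])
        if dropped:
            logger.warning(
                "face %s: phonemes missing from prevalence dropped: %s",
                face, sorted(dropped),
            )
        w = prevalence.loc[common["phoneme"]].to_numpy(float)
        if w.sum() <= 0:
            raise ValueError("no overlapping phonemes with positive weight")
        w = w / w.sum()
        predicted = float(np.dot(w, common["rate"].to_numpy(float)))
        actual = float(
            sub["n_identified"].sum() / sub["n_presented"].sum()
        )
        out.append(
            {"face_type": face, "predicted_accuracy": predicted,
             "actual_accuracy": actual, "n_phonemes": len(common)}
        )
    return pd.DataFrame(out).set_index("face_type")
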