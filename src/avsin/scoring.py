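"""Trial scoring: binary word accuracy and multiset-Jaccard phoneme accuracy.

A typed response is scored *correct* at the word level if it matches the
stimulus word after normalization, is a homophone of it, or appears in a
curated misspelling-equivalence table. Phoneme-level accuracy is the Jaccard
index of the stimulus and response phoneme multisets:

    J = |stim ∩ resp| / (|stim| + |resp| - |stim ∩ resp|)

where the intersection counts each repeated phoneme up to its minimum
multiplicity in the two sequences. When a word has several pronunciation
variants the maximum Jaccard over stimulus-variant x response-variant pairs
is taken (lenient, deterministic). Word-correct trials are assigned J = 1 so
that homophone/misspelling credit propagates to the phoneme measure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .phonemes import Lexicon, PhonemeSequence, normalize_text

#: Valid trial formats.
FORMATS = ("An", "AnV_Real", "AnV_FACS", "AnV_DNN", "AV_catch")
#: Format -> face type shown (An has no face; catch trials carry their own).
FORMAT_FACE = {"An": "An", "AnV_Real": "Real", "AnV_FACS": "FACS", "AnV_DNN": "DNN"}


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation."""

    participant: str
    batch: str
    word: str
    format: str
    response: str
    face_type_for_catch: str = "none"

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        if (self.format == "AV_catch") != (self.face_type_for_catch != "none"):
            raise ValueError("face_type_for_catch must be set iff format is AV_catch")
        if not self.response.strip():
            raise ValueError("response must be non-empty")

    @property
    def face_type(self) -> str:
        """Face type shown on this trial (Real/FACS/DNN/An)."""
        if self.format == "AV_catch":
            return self.face_type_for_catch
        return FORMAT_FACE[self.format]


@dataclass(frozen=True)
class ScoredTrial:
    """A trial plus its word-level and phoneme-level scores."""

    trial: TrialRecord
    word_correct: bool
    jaccard: float
    n_intersection: int
    n_union: int
    stimulus_phonemes: PhonemeSequence
    response_phonemes: PhonemeSequence
    oov_flag: bool = False


def jaccard_overlap(
    stim: PhonemeSequence, resp: PhonemeSequence
) -> tuple[float, int, int]:
    """Multiset Jaccard overlap between two phoneme sequences.

    Returns ``(jaccard, n_intersection, n_union)`` where the intersection
    counts each symbol at the minimum of its multiplicities in the two
    sequences and the union is ``|stim| + |resp| - n_intersection``.
    """
    if len(stim) == 0 or len(resp) == 0:
        raise ValueError("cannot compute Jaccard overlap of an empty sequence")
    cs, cr = Counter(stim), Counter(resp)
    n_int = sum(min(cs[p], cr[p]) for p in cs.keys() & cr.keys())
    n_union = len(stim) + len(resp) - n_int
    return n_int / n_union, n_int, n_union


def load_equivalences(path: str | Path | None = None) -> set[tuple[str, str]]:
    """Load the curated misspelling-equivalence table (stimulus,response pairs).

    Pairs are stored normalized and symmetrized. With no path, the packaged
    table (seeded with echos/echoes) is loaded.
    """
    if path is None:
        path = Path(resources.files("avsin.data") / "equivalences.csv")
    df = pd.read_csv(path)
    pairs: set[tuple[str, str]] = set()
    for stim, resp in zip(df["stimulus"], df["response"]):
        a, b = normalize_text(str(stim)), normalize_text(str(resp))
        pairs.add((a, b))
        pairs.add((b, a))
    return pairs


def score_word(
    stimulus: str,
    response: str,
    lexicon: Lexicon,
    equivalences: set[tuple[str, str]] | None = None,
) -> bool:
    """Binary word-level score.

    True iff the normalized response equals the normalized stimulus, the two
    are homophones, or the pair appears in the equivalence table.
    """
    stim_n, resp_n = normalize_text(stimulus), normalize_text(response)
    if stim_n == resp_n:
        return True
    if equivalences and (stim_n, resp_n) in equivalences:
        return True
    return lexicon.are_homophones(stim_n, resp_n)


def score_trial(
    trial: TrialRecord,
    lexicon: Lexicon,
    equivalences: set[tuple[str, str]] | None = None,
) -> ScoredTrial:
    """Score one trial at word and phoneme level.

    The phoneme score maximizes the multiset Jaccard over all stimulus-variant
    x response-variant pairs; a word-correct trial is forced to J = 1.
    """
    if trial.word not in lexicon:
        raise KeyError(f"stimulus word {trial.word!r} not in lexicon")
    word_correct = score_word(trial.word, trial.response, lexicon, equivalences)
    stim_variants = lexicon.variants(trial.word)
    resp_variants, oov = lexicon.phonemize(trial.response)
    best = (-1.0, 0, 0, stim_variants[0], resp_variants[0])
    for s in stim_variants:
        for r in resp_variants:
            j, n_int, n_union = jaccard_overlap(s, r)
            if j > best[0]:
                best = (j, n_int, n_union, s, r)
    j, n_int, n_union, stim_seq, resp_seq = best
    if word_correct and j < 1.0:
        # homophone / accepted-misspelling credit propagates to phoneme level
        stim_seq = resp_seq = stim_variants[0]
        n_int = n_union = len(stim_seq)
        j = 1.0
    return ScoredTrial(
        trial=trial,
        word_correct=word_correct,
        jaccard=j,
        n_intersection=n_int,
        n_union=n_union,
        stimulus_phonemes=stim_seq,
        response_phonemes=resp_seq,
        oov_flag=oov,
    )


def score_trials(
    trials: pd.DataFrame | list[TrialRecord],
    lexicon: Lexicon,
    equivalences: set[tuple[str, str]] | None = None,
) -> list[ScoredTrial]:
    """Score a trial table (DataFrame with the TrialRecord columns) or list."""
    if isinstance(trials, pd.DataFrame):
        trials = trials_from_frame(trials)
    return [score_trial(t, lexicon, equivalences) for t in trials]


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Build TrialRecords from a delimited trial table."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                participant=str(row.participant),
                batch=str(row.batch),
                word=str(row.word).lower(),
                format=str(row.format),
                response=str(row.response),
                face_type_for_catch=str(getattr(row, "face_type_for_catch", "none")),
            )
        )
    return records


def scored_to_frame(scored: list[ScoredTrial]) -> pd.DataFrame:
    """Tidy DataFrame of scored trials (one row per trial)."""
    rows = []
    for s in scored:
        t = s.trial
        rows.append(
            {
                "participant": t.participant,
                "batch": t.batch,
                "word": t.word,
                "format": t.format,
                "face_type": t.face_type,
                "response": t.response,
                "word_correct": s.word_correct,
                "jaccard": s.jaccard,
                "n_intersection": s.n_intersection,
                "n_union": s.n_union,
                "stimulus_phonemes": " ".join(s.stimulus_phonemes),
                "response_phonemes": " ".join(s.response_phonemes),
                "oov_flag": s.oov_flag,
            }
        )
    return pd.DataFrame(rows)
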