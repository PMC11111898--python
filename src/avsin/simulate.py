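"""Synthetic audiovisual speech-in-noise experiments.

The generator emulates the study design this package analyzes: each
participant identifies 64 noisy words, counterbalanced across four formats
(auditory-only plus real, FACS and DNN talking faces) so that every word
appears in every format across participants, plus 9 clear audiovisual catch
trials with disjoint words.

Responses come from a viseme-transmission generative model: each stimulus
phoneme survives into the perceived sequence independently with a
probability set by its viseme class and the trial format; untransmitted
phonemes are deleted or substituted by their voicing partner. The default
transmission probabilities are the phoneme identification rates observed in
the study (auditory-only 0.37; real faces 0.79; synthetic faces 0.61 except
the dental /th dh/ and labiodental /f v/ classes at 0.28; clear catch trials
0.99). With *lexical reconstruction* on, the simulated participant types the
lexicon word closest (by multiset Jaccard) to the perceived sequence,
mimicking whole-word typed responses; with it off, the perceived sequence is
emitted verbatim as a pseudo-word registered in the returned lexicon, which
makes per-phoneme transmission probabilities directly recoverable.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .phonemes import ARPABET, Lexicon, PhonemeSequence
from .scoring import FORMATS

logger = logging.getLogger(__name__)

NOISY_FORMATS = ("AnV_Real", "AnV_FACS", "AnV_DNN", "An")
CATCH_FACES = ("Real", "FACS", "DNN")

#: Acoustically confusable substitution partners (voicing pairs).
VOICING_PAIRS = {
    "P": "B", "B": "P", "T": "D", "D": "T", "K": "G", "G": "K",
    "F": "V", "V": "F", "TH": "DH", "DH": "TH", "S": "Z", "Z": "S",
    "SH": "ZH", "ZH": "SH", "CH": "JH", "JH": "CH",
}


def load_viseme_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the phoneme -> viseme-class map (total over the 39 phonemes)."""
    if path is None:
        path = Path(resources.files("avsin.data") / "visemes.tsv")
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["phoneme"].str.upper(), df["viseme_class"]))
    missing = ARPABET - set(mapping)
    if missing:
        raise ValueError(f"viseme map missing phonemes: {sorted(missing)}")
    return mapping


def default_transmission(
    viseme_map: dict[str, str],
    degraded_classes: tuple[str, ...] = ("dental", "labiodental"),
    p_an: float = 0.37,
    p_real: float = 0.79,
    p_synthetic: float = 0.61,
    p_synthetic_degraded: float = 0.28,
    p_catch: float = 0.99,
) -> dict[tuple[str, str], float]:
    """Default (viseme_class, format) -> transmission probability table."""
    classes = sorted(set(viseme_map.values()))
    table: dict[tuple[str, str], float] = {}
    for cls in classes:
        table[(cls, "An")] = p_an
        table[(cls, "AnV_Real")] = p_real
        p_syn = p_synthetic_degraded if cls in degraded_classes else p_synthetic
        table[(cls, "AnV_FACS")] = p_syn
        table[(cls, "AnV_DNN")] = p_syn
        table[(cls, "AV_catch")] = p_catch
    return table


@dataclass
class SimConfig:
    """Configuration of one simulated experiment.

    Defaults reproduce the study design: 61 participants, 64 noisy words in
    four counterbalanced formats (16 per format per participant), 9 clear
    catch trials, and viseme-class transmission probabilities matching the
    observed per-condition phoneme rates.
    """

    n_participants: int = 61
    n_words: int = 64
    formats: tuple[str, ...] = NOISY_FORMATS
    transmission: dict[tuple[str, str], float] | None = None
    slip_model: str = "substitute_within_auditory_set"  # or "delete"
    lexical_reconstruction: bool = True
    catch_trials_per_participant: int = 9
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_words % len(self.formats):
            raise ValueError("n_words must be divisible by the number of formats")
        if self.slip_model not in ("delete", "substitute_within_auditory_set"):
            raise ValueError(f"unknown slip model {self.slip_model!r}")
        if self.transmission is not None:
            bad = [p for p in self.transmission.values() if not 0 <= p <= 1]
            if bad:
                raise ValueError("transmission probabilities must lie in [0, 1]")


@dataclass
class SimResult:
    """Simulated trial table plus everything needed to analyze and audit it."""

    trials: pd.DataFrame
    lexicon: Lexicon  # includes pseudo-word entries when reconstruction is off
    stimuli: pd.DataFrame  # word, talker, is_catch, phonemes
    manifest: dict


def _eligible_words(lexicon: Lexicon, min_len: int = 3) -> list[str]:
    return [w for w in lexicon.words() if len(lexicon.variants(w)[0]) >= min_len]


def make_stimulus_set(
    config: SimConfig,
    lexicon: Lexicon,
    rng: np.random.Generator,
    viseme_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sample the noisy-word and catch-word stimulus sets.

    Words are unique, talker labels alternate female/male (half each), and
    the catch words are disjoint from the main words. Raises if the lexicon
    cannot cover every viseme class used by the transmission table.
    """
    viseme_map = viseme_map or load_viseme_map()
    pool = _eligible_words(lexicon)
    n_total = config.n_words + config.catch_trials_per_participant
    if len(pool) < n_total:
        raise ValueError(
            f"lexicon has {len(pool)} eligible words; need {n_total}"
        )
    chosen = list(rng.choice(pool, size=n_total, replace=False))
    main, catch = chosen[: config.n_words], chosen[config.n_words :]

    def classes_of(word):
        return {viseme_map[p] for p in lexicon.variants(word)[0]}

    # repair viseme coverage deterministically: swap in an unused word that
    # carries each missing class, replacing a word whose classes stay covered
    all_classes = set(viseme_map.values())
    for _ in range(len(all_classes)):
        covered = {c for w in main for c in classes_of(w)}
        missing = all_classes - covered
        if not missing:
            break
        target = sorted(missing)[0]
        unused = [w for w in pool if w not in main and w not in catch]
        donors = [w for w in unused if target in classes_of(w)]
        if not donors:
            raise ValueError(f"lexicon cannot cover viseme classes: {sorted(missing)}")
        class_counts = Counter(c for w in main for c in classes_of(w))
        redundant = [
            w for w in main if all(class_counts[c] > 1 for c in classes_of(w))
        ]
        victim = redundant[0] if redundant else main[-1]
        main[main.index(victim)] = donors[0]
    covered = {c for w in main for c in classes_of(w)}
    missing = all_classes - covered
    if missing:
        raise ValueError(f"stimulus set misses viseme classes: {sorted(missing)}")
    rows = []
    for i, w in enumerate(main):
        rows.append(
            {"word": w, "talker": "female" if i % 2 == 0 else "male",
             "is_catch": False, "phonemes": " ".join(lexicon.variants(w)[0])}
        )
    for i, w in enumerate(catch):
        rows.append(
            {"word": w, "talker": "female" if i % 2 == 0 else "male",
             "is_catch": True, "phonemes": " ".join(lexicon.variants(w)[0])}
        )
    return pd.DataFrame(rows)


def assign_formats(
    n_participants: int, words: list[str], formats: tuple[str, ...] = NOISY_FORMATS
) -> pd.DataFrame:
    """Cycled (Latin-square style) format assignment.

    Participant i sees word j in ``formats[(i + j) % len(formats)]``: within
    each participant every format occurs equally often, and across any
    ``len(formats)`` consecutive participants each word is seen in every
    format.
    """
    k = len(formats)
    if len(words) % k:
        raise ValueError("word count must be divisible by the number of formats")
    rows = [
        {"participant_index": i, "word": w, "format": formats[(i + j) % k]}
        for i in range(n_participants)
        for j, w in enumerate(words)
    ]
    return pd.DataFrame(rows)


def _perceive(
    phonemes: PhonemeSequence,
    fmt: str,
    transmission: dict[tuple[str, str], float],
    viseme_map: dict[str, str],
    slip_model: str,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Transmit each phoneme independently; slip the failures."""
    perceived = []
    for p in phonemes:
        if rng.random() < transmission[(viseme_map[p], fmt)]:
            perceived.append(p)
        elif slip_model == "substitute_within_auditory_set" and p in VOICING_PAIRS:
            perceived.append(VOICING_PAIRS[p])
        # else: deletion
    return tuple(perceived)


class _Reconstructor:
    """Nearest-lexicon-word lookup by multiset Jaccard (ties alphabetical)."""

    def __init__(self, lexicon: Lexicon):
        self.words = lexicon.words()  # sorted, so argmax breaks ties alphabetically
        self.symbols = sorted(ARPABET)
        sym_idx = {s: i for i, s in enumerate(self.symbols)}
        self.counts = np.zeros((len(self.words), len(self.symbols)))
        self.variant_of = []
        for i, w in enumerate(self.words):
            variant = lexicon.variants(w)[0]
            self.variant_of.append(variant)
            for p, c in Counter(variant).items():
                self.counts[i, sym_idx[p]] = c
        self.lengths = self.counts.sum(axis=1)
        self.sym_idx = sym_idx

    def nearest(self, perceived: tuple[str, ...]) -> str:
        v = np.zeros(len(self.symbols))
        for p, c in Counter(perceived).items():
            v[self.sym_idx[p]] = c
        inter = np.minimum(self.counts, v).sum(axis=1)
        union = self.lengths + len(perceived) - inter
        j = inter / union
        best = j.max()
        tied = np.flatnonzero(j == best)
        if len(tied) > 1:
            # Jaccard ignores order, so anagrams tie; prefer an exact ordered
            # match (the listener heard the order), then fall back to the
            # alphabetically first candidate
            for i in tied:
                if self.variant_of[i] == perceived:
                    return self.words[int(i)]
        return self.words[int(tied[0])]


def pseudo_word(perceived: tuple[str, ...]) -> str:
    """Collision-free textual encoding of a phoneme sequence.

    ``q`` never occurs inside an ARPAbet symbol, so joining lowercase symbols
    with ``q`` (and a ``qq`` prefix) encodes any sequence unambiguously; the
    pseudo-word is registered in the simulation's output lexicon so scoring
    phonemizes it back to exactly the perceived sequence.
    """
    return "qq" + "q".join(p.lower() for p in perceived)


def simulate_response(
    word_phonemes: PhonemeSequence,
    fmt: str,
    config: SimConfig,
    viseme_map: dict[str, str],
    lexicon: Lexicon,
    rng: np.random.Generator,
    transmission: dict[tuple[str, str], float],
    reconstructor: "_Reconstructor | None" = None,
    out_lexicon: Lexicon | None = None,
) -> str:
    """Generate one typed response for a stimulus.

    With reconstruction on, returns the lexicon word with maximal Jaccard to
    the perceived sequence; otherwise returns the perceived sequence encoded
    as a pseudo-word (registered in ``out_lexicon``). An empty perceived
    sequence falls back to a uniformly random eligible lexicon word.
    """
    perceived = _perceive(
        word_phonemes, fmt, transmission, viseme_map, config.slip_model, rng
    )
    if not perceived:
        fallback = str(rng.choice(lexicon.words()))
        logger.debug("empty perceived sequence; random fallback %r", fallback)
        return fallback
    if config.lexical_reconstruction:
        if reconstructor is None:
            reconstructor = _Reconstructor(lexicon)
        return reconstructor.nearest(perceived)
    word = pseudo_word(perceived)
    if out_lexicon is not None and word not in out_lexicon:
        out_lexicon.add(word, perceived)
    return word


def simulate_experiment(
    config: SimConfig,
    lexicon: Lexicon,
    viseme_map: dict[str, str] | None = None,
) -> SimResult:
    """Simulate a complete experiment.

    Returns the trial table (73 trials per participant under the default
    design, shuffled within participant), the lexicon to score it against
    (augmented with pseudo-words when reconstruction is off), the stimulus
    manifest, and a config manifest for parameter-recovery audits.
    """
    rng = np.random.default_rng(config.seed)
    viseme_map = viseme_map or load_viseme_map()
    transmission = (
        config.transmission
        if config.transmission is not None
        else default_transmission(viseme_map)
    )
    needed = {(viseme_map[p], f) for p in ARPABET for f in FORMATS}
    missing = needed - set(transmission)
    if missing:
        raise ValueError(f"transmission table missing entries: {sorted(missing)[:5]}")

    stimuli = make_stimulus_set(config, lexicon, rng, viseme_map)
    main = stimuli[~stimuli["is_catch"]].reset_index(drop=True)
    catch = stimuli[stimuli["is_catch"]].reset_index(drop=True)
    assignment = assign_formats(
        config.n_participants, list(main["word"]), config.formats
    )
    phonemes_of = dict(zip(stimuli["word"], stimuli["phonemes"]))

    out_lexicon = Lexicon()
    for w in lexicon.words():
        for v in lexicon.variants(w):
            out_lexicon.add(w, v)
    reconstructor = _Reconstructor(lexicon) if config.lexical_reconstruction else None

    rows = []
    for i in range(config.n_participants):
        pid = f"p{i + 1:03d}"
        batch = f"b{i // config.batch_size + 1}"
        sub = assignment[assignment["participant_index"] == i]
        trial_specs = [
            (w, f, "none") for w, f in zip(sub["word"], sub["format"])
        ]
        n_catch = min(config.catch_trials_per_participant, len(catch))
        for j in range(n_catch):
            trial_specs.append(
                (catch["word"].iloc[j], "AV_catch", CATCH_FACES[j % len(CATCH_FACES)])
            )
        order = rng.permutation(len(trial_specs))
        for idx in order:
            word, fmt, catch_face = trial_specs[idx]
            seq = tuple(phonemes_of[word].split())
            response = simulate_response(
                seq, fmt, config, viseme_map, lexicon, rng,
                transmission, reconstructor, out_lexicon,
            )
            rows.append(
                {"participant": pid, "batch": batch, "word": word,
                 "format": fmt, "face_type_for_catch": catch_face,
                 "response": response}
            )
    trials = pd.DataFrame(rows)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "transmission"
        },
        "transmission": {f"{cls}|{fmt}": p for (cls, fmt), p in transmission.items()},
        "n_trials": len(trials),
        "words": list(main["word"]),
        "catch_words": list(catch["word"]),
    }
    return SimResult(trials=trials, lexicon=out_lexicon, stimuli=stimuli, manifest=manifest)
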