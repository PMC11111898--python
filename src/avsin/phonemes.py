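"""ARPAbet phoneme sequences and CMU-dictionary-format pronouncing lexicons.

Words are represented as ordered sequences of stress-stripped ARPAbet symbols
(the 39-symbol set used by the CMU pronouncing dictionary once the 0-2 vowel
stress digits are removed). A :class:`Lexicon` maps lowercase words to one or
more pronunciation variants and supports homophone queries and phonemization
of free-text responses, including multi-word responses and a deterministic
letter-to-phoneme fallback for out-of-vocabulary tokens.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Sequence
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

#: The 39 stress-stripped ARPAbet phonemes.
ARPABET: frozenset[str] = frozenset(
    """AA AE AH AO AW AY B CH D DH EH ER EY F G HH IH IY JH K L M N NG
       OW OY P R S SH T TH UH UW V W Y Z ZH""".split()
)

#: ARPAbet vowels (the symbols that may carry a stress digit in CMU format).
VOWELS: frozenset[str] = frozenset(
    "AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW".split()
)

PhonemeSequence = tuple[str, ...]

_STRESS_RE = re.compile(r"^([A-Z]+)([0-2])?$")

# Deterministic letter-to-phoneme fallback for out-of-vocabulary tokens.
# Digraphs are consumed greedily left-to-right before single letters; a final
# silent "e" is dropped from tokens longer than two letters. This is a crude
# spelling-pronunciation rule, not a trained grapheme-to-phoneme model: its
# job is to keep scoring total and reproducible when a typed response is not
# in the lexicon.
_G2P_DIGRAPHS: dict[str, tuple[str, ...]] = {
    "th": ("TH",), "sh": ("SH",), "ch": ("CH",), "ph": ("F",), "wh": ("W",),
    "ck": ("K",), "ng": ("NG",), "qu": ("K", "W"), "ee": ("IY",),
    "oo": ("UW",), "ea": ("IY",), "ou": ("AW",), "ow": ("OW",),
    "ai": ("EY",), "ay": ("EY",), "oi": ("OY",), "oy": ("OY",),
    "au": ("AO",), "aw": ("AO",),
}
_G2P_LETTERS: dict[str, tuple[str, ...]] = {
    "a": ("AE",), "b": ("B",), "c": ("K",), "d": ("D",), "e": ("EH",),
    "f": ("F",), "g": ("G",), "h": ("HH",), "i": ("IH",), "j": ("JH",),
    "k": ("K",), "l": ("L",), "m": ("M",), "n": ("N",), "o": ("AA",),
    "p": ("P",), "q": ("K",), "r": ("R",), "s": ("S",), "t": ("T",),
    "u": ("AH",), "v": ("V",), "w": ("W",), "x": ("K", "S"), "y": ("Y",),
    "z": ("Z",),
}


def strip_stress(raw: Sequence[str]) -> PhonemeSequence:
    """Remove lexical stress digits from ARPAbet labels.

    Parameters
    ----------
    raw
        Labels such as ``["P", "AA1", "L", "IH0", "SH"]``. Each must be an
        ARPAbet symbol optionally followed by one digit 0-2.

    Returns
    -------
    tuple of str
        The same sequence with stress digits removed; order and repetitions
        are preserved.

    Raises
    ------
    ValueError
        If the input is empty or contains a label whose base symbol is not
        in the 39-symbol ARPAbet set.
    """
    if len(raw) == 0:
        raise ValueError("phoneme sequence must contain at least one symbol")
    out = []
    for label in raw:
        m = _STRESS_RE.match(label.strip().upper())
        base = m.group(1) if m else None
        if base is None or base not in ARPABET:
            raise ValueError(f"unknown ARPAbet symbol: {label!r}")
        out.append(base)
    return tuple(out)


def normalize_text(text: str) -> str:
    """Normalize a typed response: lowercase, keep [a-z ' -], hyphens as spaces."""
    text = text.lower().replace("-", " ")
    text = re.sub(r"[^a-z' ]", "", text)
    return re.sub(r"\s+", " ", text).strip()


def fallback_phonemes(token: str) -> PhonemeSequence:
    """Deterministic letter-to-phoneme conversion for an OOV token."""
    token = re.sub(r"[^a-z]", "", token.lower())
    if not token:
        raise ValueError("empty token after normalization")
    if len(token) > 2 and token.endswith("e"):
        token = token[:-1]
    out: list[str] = []
    i = 0
    while i < len(token):
        pair = token[i : i + 2]
        if pair in _G2P_DIGRAPHS:
            out.extend(_G2P_DIGRAPHS[pair])
            i += 2
        else:
            out.extend(_G2P_LETTERS[token[i]])
            i += 1
    return tuple(out)


class Lexicon:
    """A pronouncing lexicon: lowercase word -> ARPAbet pronunciation variants.

    All stored pronunciations are stress-stripped at load time. Lookup is
    case-insensitive.
    """

    def __init__(self, entries: dict[str, list[PhonemeSequence]] | None = None):
        self._entries: dict[str, list[PhonemeSequence]] = {}
        if entries:
            for word, variants in entries.items():
                for v in variants:
                    self.add(word, v)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def words(self) -> list[str]:
        return sorted(self._entries)

    def add(self, word: str, pronunciation: Sequence[str]) -> None:
        """Add a pronunciation variant (stress digits allowed; stripped here)."""
        seq = strip_stress(pronunciation)
        variants = self._entries.setdefault(word.lower(), [])
        if seq not in variants:
            variants.append(seq)

    def variants(self, word: str) -> list[PhonemeSequence]:
        """All pronunciation variants of ``word`` (empty list if OOV)."""
        return list(self._entries.get(word.lower(), []))

    def phonemize(
        self, text: str, allow_fallback: bool = True
    ) -> tuple[list[PhonemeSequence], bool]:
        """Phonemize free text, possibly spanning multiple words.

        The text is normalized, split on whitespace, and each token is looked
        up in the lexicon. For multi-word text the cross-product of per-token
        variants is concatenated in token order. OOV tokens are converted with
        the letter-to-phoneme fallback rule and flagged.

        Returns
        -------
        (variants, oov)
            ``variants`` is a list of candidate phoneme sequences for the
            whole text; ``oov`` is True if any token required the fallback.

        Raises
        ------
        ValueError
            If the text is empty after normalization, or if a token is OOV
            and ``allow_fallback`` is False.
        """
        norm = normalize_text(text)
        if not norm:
            raise ValueError("empty response")
        oov = False
        per_token: list[list[PhonemeSequence]] = []
        for token in norm.split():
            token_variants = self.variants(token)
            if not token_variants:
                if not allow_fallback:
                    raise KeyError(f"out-of-vocabulary token: {token!r}")
                token_variants = [fallback_phonemes(token)]
                oov = True
            per_token.append(token_variants)
        combined: list[PhonemeSequence] = [()]
        for token_variants in per_token:
            combined = [c + v for c in combined for v in token_variants]
        return combined, oov

    def are_homophones(self, a: str, b: str) -> bool:
        """True iff some stress-stripped variant of ``a`` equals one of ``b``.

        OOV words produce a warning and return False, never an exception.
        """
        va, vb = self.variants(a), self.variants(b)
        if not va or not vb:
            missing = a if not va else b
            logger.warning("homophone query with OOV word %r -> False", missing)
            return False
        return any(x == y for x in va for y in vb)

    def save(self, path: str | Path) -> None:
        """Write the lexicon in CMU-dictionary text format."""
        lines = []
        for word in sorted(self._entries):
            for i, seq in enumerate(self._entries[word]):
                suffix = f"({i + 1})" if i else ""
                lines.append(f"{word.upper()}{suffix}  {' '.join(seq)}")
        Path(path).write_text("\n".join(lines) + "\n")


_VARIANT_RE = re.compile(r"^(.*?)\((\d+)\)$")


def load_lexicon(path: str | Path) -> Lexicon:
    """Parse a CMU-dictionary-format text file into a :class:`Lexicon`.

    Lines are ``WORD  PH1 PH2 ...``; ``WORD(n)`` marks alternate variants,
    which are merged under the base word; lines starting with ``;;;`` (or
    ``#``) are comments. Stress digits are stripped at load time. Malformed
    lines are skipped with a logged warning and a reported count.
    """
    path = Path(path)
    try:
        raw = path.read_text(encoding="utf-8", errors="replace")
    except OSError as exc:
        raise FileNotFoundError(f"cannot read lexicon file {path}: {exc}") from exc
    lex = Lexicon()
    n_bad = 0
    for lineno, line in enumerate(raw.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(";;;") or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            logger.warning("%s:%d: malformed lexicon line skipped", path, lineno)
            n_bad += 1
            continue
        word = fields[0]
        m = _VARIANT_RE.match(word)
        if m:
            word = m.group(1)
        try:
            lex.add(word, fields[1:])
        except ValueError:
            logger.warning("%s:%d: bad phoneme labels, line skipped", path, lineno)
            n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d malformed lines", path, n_bad)
    if len(lex) == 0:
        raise ValueError(f"no lexicon entries parsed from {path}")
    return lex


def bundled_lexicon_path() -> Path:
    """Path to the packaged ~190-word mini-lexicon fixture."""
    return Path(resources.files("avsin.data") / "minilex.dict")


def load_bundled_lexicon() -> Lexicon:
    """Load the packaged mini-lexicon."""
    return load_lexicon(bundled_lexicon_path())


def are_homophones(a: str, b: str, lexicon: Lexicon) -> bool:
    """Functional form of :meth:`Lexicon.are_homophones`."""
    return lexicon.are_homophones(a, b)


def phonemize(
    text: str, lexicon: Lexicon, allow_fallback: bool = True
) -> tuple[list[PhonemeSequence], bool]:
    """Functional form of :meth:`Lexicon.phonemize`."""
    return lexicon.phonemize(text, allow_fallback=allow_fallback)
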