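"""German-aware stemming, compound splitting and OCR-aware spell correction.

Suffix stripping uses a small fixed inflectional suffix list rather than a
full morphological analyzer; compound nouns are decomposed by greedy
longest-match over a stem lexicon, allowing the usual German linking
morphemes (Fugenelemente: -s, -n, -en, -es, -e) between parts. Spell
correction minimizes a weighted edit distance in which substitutions from a
table of typical OCR confusions (h↔n, rn↔m, l↔1, O↔0) and dropped vowels
(the "prtone-pmp inhbtor" contraction pattern) cost half a generic edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .ontology import normalize_term

__all__ = [
    "GermanStemmer",
    "SpellCorrector",
    "split_compound",
    "weighted_edit_distance",
]

# longest-first so "-en" wins over "-n"
SUFFIXES = ("en", "es", "er", "e", "n", "s")
LINKERS = ("", "s", "n", "en", "es", "e")
_MIN_PART = 3


def _strip_suffix(word: str, lexicon: set[str] | None = None) -> str:
    """Strip one inflectional suffix; prefer a result found in the lexicon."""
    if lexicon:
        for suf in SUFFIXES:
            base = word[: -len(suf)]
            if word.endswith(suf) and len(base) >= _MIN_PART and base in lexicon:
                return base
    for suf in SUFFIXES:
        base = word[: -len(suf)]
        if word.endswith(suf) and len(base) >= _MIN_PART:
            return base
    return word


def split_compound(word: str, stem_lexicon: set[str]) -> list[str]:
    """Decompose a (normalized) German compound over a stem lexicon.

    Greedy longest-match from the left; linking morphemes may sit between
    parts. If no full decomposition exists the suffix-stripped whole word is
    returned as a single stem.
    """
    word = normalize_term(word)

    def decompose(s: str) -> list[str] | None:
        if not s:
            return []
        # final part may carry an inflectional suffix
        if s in stem_lexicon:
            return [s]
        stripped = _strip_suffix(s, stem_lexicon)
        if stripped in stem_lexicon:
            return [stripped]
        for plen in range(len(s) - 1, _MIN_PART - 1, -1):
            part = s[:plen]
            if part not in stem_lexicon:
                continue
            rest = s[plen:]
            for link in LINKERS:
                if link and not rest.startswith(link):
                    continue
                tail = decompose(rest[len(link):])
                if tail is not None and tail != []:
                    return [part] + tail
        return None

    parts = decompose(word)
    if parts:
        return parts
    return [_strip_suffix(word, stem_lexicon)]


@dataclass
class GermanStemmer:
    """Normalizes, suffix-strips and compound-splits single words.

    ``lexicon`` holds known stems (built from ontology description vocabulary
    plus a bundled supplement); words found in it — directly or after suffix
    stripping — are not decomposed further, so description words always stem
    identically on the indexing and the matching side.
    """

    lexicon: set[str] = field(default_factory=set)

    def stem_word(self, word: str) -> list[str]:
        """Stems of one word; hyphenated compounds are stemmed per part."""
        out: list[str] = []
        for part in word.split("-"):
            part = normalize_term(part)
            if not part:
                continue
            if not any(ch.isalpha() for ch in part):
                out.append(part)
                continue
            if part in self.lexicon:
                out.append(part)
                continue
            stripped = _strip_suffix(part, self.lexicon)
            if stripped in self.lexicon:
                out.append(stripped)
                continue
            out.extend(split_compound(part, self.lexicon))
        return out or [normalize_term(word)]

    def __call__(self, word: str) -> list[str]:
        return self.stem_word(word)


# ------------------------------------------------------------------ correction

VOWELS = set("aeiouy")

#: default OCR confusion pairs (symmetric) with reduced substitution cost
DEFAULT_CONFUSIONS: tuple[tuple[str, str, float], ...] = (
    ("h", "n", 0.5),
    ("rn", "m", 0.5),
    ("l", "1", 0.5),
    ("o", "0", 0.5),
)


def weighted_edit_distance(
    source: str,
    target: str,
    confusions: Iterable[tuple[str, str, float]] = DEFAULT_CONFUSIONS,
    vowel_insert_cost: float = 0.5,
    cutoff: float | None = None,
) -> float:
    """Edit distance with OCR-confusion and dropped-vowel discounts.

    Generic insert/delete/substitute cost 1; substituting a confusion pair
    (either direction, possibly multi-character like rn↔m) costs its table
    weight; inserting a vowel present in the target but dropped in the source
    costs ``vowel_insert_cost``. ``cutoff`` allows early exit (returns
    ``inf`` when the distance provably exceeds it).
    """
    subs: list[tuple[str, str, float]] = []
    for a, b, w in confusions:
        subs.append((a, b, w))
        subs.append((b, a, w))
    n, m = len(source), len(target)
    inf = float("inf")
    prevs: list[list[float]] = []
    row = [0.0] * (m + 1)
    for j in range(1, m + 1):
        row[j] = row[j - 1] + (vowel_insert_cost if target[j - 1] in VOWELS else 1.0)
    prevs.append(row)
    for i in range(1, n + 1):
        cur = [float(i)] + [inf] * m
        for j in range(1, m + 1):
            best = prevs[i - 1][j] + 1.0  # delete source char
            ins = cur[j - 1] + (vowel_insert_cost if target[j - 1] in VOWELS else 1.0)
            if ins < best:
                best = ins
            sub = prevs[i - 1][j - 1] + (
                0.0 if source[i - 1] == target[j - 1] else 1.0
            )
            if sub < best:
                best = sub
            for a, b, w in subs:
                la, lb = len(a), len(b)
                if i >= la and j >= lb and source[i - la : i] == a and target[j - lb : j] == b:
                    cand = prevs[i - la][j - lb] + w
                    if cand < best:
                        best = cand
            cur[j] = best
        prevs.append(cur)
        if cutoff is not None and min(cur) > cutoff:
            return inf
    return prevs[n][m]


@dataclass
class SpellCorrector:
    """Correct unknown words against a vocabulary of known word forms.

    The candidate with minimal weighted distance wins when it meets the
    length-dependent threshold (≤1 for words of up to 6 characters, ≤2
    otherwise); on a tie the word is left unchanged and the degenerate case
    recorded in ``ties``.
    """

    vocabulary: set[str]
    confusions: tuple[tuple[str, str, float], ...] = DEFAULT_CONFUSIONS
    ties: list[str] = field(default_factory=list)

    def threshold(self, word: str) -> float:
        return 1.0 if len(word) <= 6 else 2.0

    def _candidates(self, word: str) -> Iterable[str]:
        for cand in self.vocabulary:
            if abs(len(cand) - len(word)) > 3:
                continue
            yield cand

    def correct(self, word: str) -> str | None:
        """Best correction of ``word`` (normalized), or None if none qualifies."""
        norm = normalize_term(word)
        if norm in self.vocabulary:
            return None
        cutoff = self.threshold(norm)
        best: list[str] = []
        best_d = float("inf")
        for cand in self._candidates(norm):
            d = weighted_edit_distance(norm, cand, self.confusions, cutoff=cutoff)
            if d > cutoff:
                continue
            if d < best_d:
                best, best_d = [cand], d
            elif d == best_d and cand not in best:
                best.append(cand)
        if len(best) == 1:
            return best[0]
        if len(best) > 1:
            self.ties.append(word)
        return None
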