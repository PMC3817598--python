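"""String fingerprinting and longest-common-subsequence similarity.

Taxonomic databases store many spellings of the same name: accents come and
go ("Böhlke" vs "Bohlke"), commas and years appear or vanish ("Kaup 1829" vs
"Kaup, 1829").  Every comparison in this package therefore goes through two
primitives defined here:

* :func:`fingerprint` — a normal form (lowercase, de-accented,
  punctuation-free, whitespace-collapsed) that absorbs the cosmetic
  variation;
* :func:`similarity` — a score in [0, 1] based on the longest common
  *subsequence* (characters need not be consecutive), so single insertions
  and deletions degrade the score gracefully instead of breaking a match.

The scalar score is ``min(|LCS|/|a|, |LCS|/|b|)``: requiring the score to
clear a threshold is the same as requiring the LCS to be long relative to
*each* input, and identical non-empty strings score exactly 1.0.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

__all__ = ["Fingerprint", "SimilarityScore", "fingerprint", "lcs_length", "similarity"]

# Characters that survive NFKD decomposition with no combining mark to strip.
_SUBSTITUTIONS = {
    "ø": "o",
    "ß": "ss",
    "æ": "ae",
    "œ": "oe",
    "đ": "d",
    "ð": "d",
    "þ": "th",
    "ł": "l",
    "ı": "i",
}

_WS_RUN = re.compile(r"\s+")


@dataclass(frozen=True)
class Fingerprint:
    """Normalized form of a string: lowercase, unaccented, punctuation-free,
    single-spaced, stripped.  Fingerprinting is idempotent."""

    value: str

    def __len__(self) -> int:
        return len(self.value)

    def __str__(self) -> str:
        return self.value


def fingerprint(raw: str) -> Fingerprint:
    """Normalize ``raw`` to its comparison form.

    Lowercases (full casefold), decomposes accented characters and drops the
    combining marks, applies a small substitution table for letters that do
    not decompose (ø, ß, æ, ...), removes all Unicode punctuation, and
    collapses whitespace runs to a single ASCII space.

    Total function: any text (including empty) is accepted.

    >>> fingerprint("Böhlke").value
    'bohlke'
    >>> fingerprint("Gloger, 1827").value
    'gloger 1827'
    """
    s = unicodedata.normalize("NFKD", raw.casefold())
    out = []
    for ch in s:
        if ch in _SUBSTITUTIONS:
            out.append(_SUBSTITUTIONS[ch])
            continue
        cat = unicodedata.category(ch)
        if cat == "Mn":  # combining mark from the decomposition
            continue
        if cat.startswith("P"):  # any punctuation category
            continue
        out.append(ch)
    value = _WS_RUN.sub(" ", "".join(out)).strip()
    return Fingerprint(value)


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``.

    Subsequence, not substring: characters must appear in order but need not
    be consecutive.  Standard dynamic programme, two rolling rows.
    """
    if not a or not b:
        return 0
    if len(b) < len(a):
        a, b = b, a
    prev = [0] * (len(a) + 1)
    for ch in b:
        curr = [0] * (len(a) + 1)
        for i, ca in enumerate(a, start=1):
            if ca == ch:
                curr[i] = prev[i - 1] + 1
            else:
                curr[i] = curr[i - 1] if curr[i - 1] >= prev[i] else prev[i]
        prev = curr
    return prev[-1]


@dataclass(frozen=True)
class SimilarityScore:
    """LCS-based similarity between two (fingerprinted) strings.

    ``ratio_a`` and ``ratio_b`` are the LCS length relative to each input;
    ``score = min(ratio_a, ratio_b)`` is the scalar used for thresholding
    and for bipartite edge weights.
    """

    lcs: int
    ratio_a: float
    ratio_b: float
    score: float


def similarity(a: str, b: str, *, use_fingerprint: bool = True) -> SimilarityScore:
    """Similarity of ``a`` and ``b`` under the LCS min-ratio metric.

    Inputs are fingerprinted first (pass ``use_fingerprint=False`` to compare
    raw strings, for diagnostics).  Identical non-empty strings score 1.0;
    if either side is empty after fingerprinting the score is 0.0 — two
    empty/authorless strings are deliberately *not* similar here, the
    clustering layer handles authorless records by rule instead.
    """
    fa = fingerprint(a).value if use_fingerprint else a
    fb = fingerprint(b).value if use_fingerprint else b
    if not fa or not fb:
        return SimilarityScore(0, 0.0, 0.0, 0.0)
    n = lcs_length(fa, fb)
    ra = n / len(fa)
    rb = n / len(fb)
    return SimilarityScore(n, ra, rb, min(ra, rb))
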