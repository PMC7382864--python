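"""String and date comparators used throughout the linkage.

Three comparators cover the attribute types that occur in the registers:

* :func:`jaro_winkler` for person names — rewards shared characters and a
  common prefix, tolerant of transpositions and single-character typos;
* :func:`damerau_levenshtein` (restricted / optimal-string-alignment
  variant) for the fuzzy retrieval filter, normalized to [0, 1];
* :func:`hamming_date` for fixed-width compact dates (``YYYYMMDD``), where
  a positional substitution count is the natural error model for keyed
  digit fields.

All similarity values lie in [0, 1], are symmetric in their arguments and
equal 1 exactly for identical inputs.  The functions are pure and total
except where a precondition is stated (fixed width for Hamming).
"""

from __future__ import annotations

__all__ = [
    "jaro",
    "jaro_winkler",
    "damerau_levenshtein",
    "normalized_dl_similarity",
    "hamming_date",
    "normalized_date_similarity",
]


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity between two strings.

    Counts characters common to both strings within a sliding window of
    ``floor(max(|s1|, |s2|) / 2) - 1`` positions, and half-counts matched
    characters that appear in a different order (transpositions):

        J = (m/|s1| + m/|s2| + (m - t)/m) / 3

    Returns 0.0 when either string is empty or no characters match.
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    match1 = [False] * len1
    match2 = [False] * len2
    m = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not match2[j] and s2[j] == c:
                match1[i] = True
                match2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters compared in order; t = half the
    # number of positions where they disagree
    k = 0
    half_transposed = 0
    for i in range(len1):
        if match1[i]:
            while not match2[k]:
                k += 1
            if s1[i] != s2[k]:
                half_transposed += 1
            k += 1
    t = half_transposed / 2.0
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(
    s1: str,
    s2: str,
    prefix_scale: float = 0.1,
    max_prefix: int = 4,
) -> float:
    """Jaro-Winkler similarity: Jaro plus a bonus for a shared prefix.

        JW = J + ell * p * (1 - J)

    where ``ell`` is the length of the common prefix capped at
    ``max_prefix`` and ``p`` is ``prefix_scale``.  ``JW >= J`` always.

    Raises
    ------
    ValueError
        If ``prefix_scale`` is outside [0, 0.25] (values above 0.25 can
        push the similarity past 1).
    """
    if not 0.0 <= prefix_scale <= 0.25:
        raise ValueError(
            f"prefix_scale must be in [0, 0.25], got {prefix_scale}"
        )
    j = jaro(s1, s2)
    ell = 0
    for a, b in zip(s1, s2):
        if a != b or ell >= max_prefix:
            break
        ell += 1
    return j + ell * prefix_scale * (1.0 - j)


def damerau_levenshtein(s1: str, s2: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Minimum number of single-character insertions, deletions,
    substitutions and adjacent transpositions converting ``s1`` into
    ``s2``, with the restriction that no substring is edited more than
    once.  This is the variant standard in linkage tooling; it differs
    from the unrestricted distance only on rare inputs such as
    ("CA", "ABC").
    """
    len1, len2 = len(s1), len(s2)
    if len1 == 0:
        return len2
    if len2 == 0:
        return len1
    prev2: list[int] = []
    prev = list(range(len2 + 1))
    for i in range(1, len1 + 1):
        cur = [i] + [0] * len2
        for j in range(1, len2 + 1):
            cost = 0 if s1[i - 1] == s2[j - 1] else 1
            cur[j] = min(
                prev[j] + 1,        # deletion
                cur[j - 1] + 1,     # insertion
                prev[j - 1] + cost, # substitution / match
            )
            if (
                i > 1
                and j > 1
                and s1[i - 1] == s2[j - 2]
                and s1[i - 2] == s2[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)  # transposition
        prev2, prev = prev, cur
    return prev[len2]


def normalized_dl_similarity(s1: str, s2: str) -> float:
    """1 - DL(s1, s2) / max(|s1|, |s2|); defined as 1.0 for two empty strings."""
    longest = max(len(s1), len(s2))
    if longest == 0:
        return 1.0
    return 1.0 - damerau_levenshtein(s1, s2) / longest


def hamming_date(d1: str, d2: str) -> int:
    """Count of differing positions between two equal-width date strings.

    Inputs are compact 8-digit dates (``YYYYMMDD``); any equal widths are
    accepted.  A width mismatch is an error — truncating would silently
    turn a malformed date into a near-match.
    """
    if len(d1) != len(d2):
        raise ValueError(
            f"hamming_date requires equal widths, got {len(d1)} and {len(d2)}"
        )
    return sum(a != b for a, b in zip(d1, d2))


def normalized_date_similarity(d1: str, d2: str) -> float:
    """1 - hamming/width, in [0, 1]; 1.0 for two empty strings."""
    if len(d1) == 0 and len(d2) == 0:
        return 1.0
    width = len(d1)
    return 1.0 - hamming_date(d1, d2) / width
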