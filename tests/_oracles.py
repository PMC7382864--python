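"""Independent brute-force oracles shared across test modules."""


def brute_force_edit_distance(s1: str, s2: str) -> int:
    """Exhaustive recursion over left-to-right edit sequences.

    Enumerates every way of consuming the two strings with matches,
    substitutions, deletions, insertions and adjacent transpositions,
    where a transposed pair is consumed whole and never edited again
    (the optimal-string-alignment restriction).  No memoization, no DP
    matrix — an independent, exponential-time oracle for tiny strings.
    Note the unrestricted variant differs on inputs like BCA -> CABA
    (2 unrestricted, 3 restricted).
    """
    costs = [len(s1) + len(s2)] if not s1 or not s2 else []
    if s1 and s2:
        head_cost = 0 if s1[0] == s2[0] else 1
        costs.append(head_cost + brute_force_edit_distance(s1[1:], s2[1:]))
        costs.append(1 + brute_force_edit_distance(s1[1:], s2))  # delete
        costs.append(1 + brute_force_edit_distance(s1, s2[1:]))  # insert
        if (
            len(s1) >= 2
            and len(s2) >= 2
            and s1[0] == s2[1]
            and s1[1] == s2[0]
            and s1[0] != s1[1]
        ):
            costs.append(1 + brute_force_edit_distance(s1[2:], s2[2:]))
    return min(costs)


def mann_whitney_auc(scores, labels) -> float:
    """Brute-force pair enumeration: P(true > false) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
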