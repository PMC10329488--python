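"""Independent reference implementation of Jaro-Winkler, used only as a
test oracle.  Written from the textbook definition with a different
structure (explicit matched-index bookkeeping) than the package's
implementation, so agreement between the two is meaningful."""

from __future__ import annotations


def reference_jaro_winkler(
    s1: str,
    s2: str,
    prefix_scale: float = 0.1,
    max_prefix: int = 4,
    boost_threshold: float = 0.7,
) -> float:
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(max(len(s1), len(s2)) // 2 - 1, 0)
    taken: set[int] = set()
    matched_i: list[int] = []
    matched_j: list[int] = []
    for i, ch in enumerate(s1):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if j not in taken and s2[j] == ch:
                taken.add(j)
                matched_i.append(i)
                matched_j.append(j)
                break
    m = len(matched_i)
    if m == 0:
        return 0.0
    seq1 = [s1[i] for i in matched_i]
    seq2 = [s2[j] for j in sorted(matched_j)]
    transpositions = sum(a != b for a, b in zip(seq1, seq2)) / 2.0
    jaro = (m / len(s1) + m / len(s2) + (m - transpositions) / m) / 3.0
    if jaro < boost_threshold:
        return jaro
    prefix = 0
    for a, b in zip(s1[:max_prefix], s2[:max_prefix]):
        if a != b:
            break
        prefix += 1
    return jaro + prefix * prefix_scale * (1.0 - jaro)
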