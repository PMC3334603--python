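"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — dict lookups and explicit loops —
and shares no code with the scanning path it validates.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq.upper()))


def naive_log_odds(counts, pseudocount: float, background) -> list[dict[str, float]]:
    """Per-column {base: log2 odds} tables from raw counts."""
    width = len(counts[0])
    bases = "ACGT"
    table = []
    for j in range(width):
        n = sum(counts[i][j] for i in range(4))
        col = {}
        for i, b in enumerate(bases):
            f = (counts[i][j] + pseudocount) / (n + 4 * pseudocount)
            col[b] = math.log2(f / background[i]) if f > 0 else float("-inf")
        table.append(col)
    return table


def naive_score(table, word: str) -> float:
    total = 0.0
    for j, b in enumerate(word):
        if b not in "ACGT":
            return float("-inf")
        total += table[j][b]
    return total


def naive_scan(pwm, seq: str, threshold: float) -> list[tuple[int, str, float, str]]:
    """All-window, both-strand brute force scan.

    Returns (start, strand, score, word) tuples in (start, strand) order,
    with minus-strand coordinates mirrored onto the plus strand.
    """
    table = naive_log_odds(pwm.counts.tolist(), pwm.pseudocount, pwm.background.tolist())
    w = len(table)
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        s = naive_score(table, word)
        if s >= threshold:
            hits.append((i, "+", s, word))
        rc = naive_revcomp(word)
        s = naive_score(table, rc)
        if s >= threshold:
            hits.append((i, "-", s, rc))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
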