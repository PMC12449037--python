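"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checked against:
Fisher's exact test by exhaustive hypergeometric enumeration, AUC by
pairwise concordance counting, and 2x2 tables by a per-case
classification loop.
"""

from math import comb


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over the table support.

    With all margins fixed, sums the hypergeometric point probabilities of
    every table whose probability is at most that of the observed table
    (1e-7 relative slack for floating-point ties).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def auc_pair_count(scores, labels) -> float:
    """AUC by brute-force concordant-pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def table_by_case_loop(cases, event_ids, drug_ids):
    """(a, b, c, d) by classifying every case one at a time."""
    a = b = c = d = 0
    for cid in cases:
        ev, dr = cid in event_ids, cid in drug_ids
        if ev and dr:
            a += 1
        elif dr:
            b += 1
        elif ev:
            c += 1
        else:
            d += 1
    return a, b, c, d
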