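"""Independent brute-force oracles used to cross-check the statistics."""

from math import comb


def fisher_p_enumeration(tp: int, fn: int, fp: int, tn: int) -> float:
    """Two-sided Fisher exact p by exhaustive margin-fixed enumeration.

    Fixes both margins of the 2x2 table, walks every admissible table,
    computes each hypergeometric point probability from binomial
    coefficients, and sums those not exceeding the observed table's
    probability (point-probability two-sided rule). Independent of scipy.
    """
    row1 = tp + fp  # flagged drugs
    col1 = tp + fn  # AD-positive drugs
    n = tp + fn + fp + tn
    denom = comb(n, row1)

    def point_prob(a: int) -> float:
        # a = flagged AD-positive count; remaining cells follow from margins
        return comb(col1, a) * comb(n - col1, row1 - a) / denom

    observed = point_prob(tp)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    total = 0.0
    for a in range(lo, hi + 1):
        p = point_prob(a)
        if p <= observed * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def odds_ratio_direct(tp: float, fn: float, fp: float, tn: float) -> float:
    """Cross-product odds ratio with Haldane +0.5 on a zero cell."""
    if 0 in (tp, fn, fp, tn):
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
    return tp * tn / (fn * fp)
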