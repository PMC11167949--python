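"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from first principles (ANOVA sums
of squares, pairwise haplotype comparison, exhaustive window enumeration,
exact rational arithmetic) so they share no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def wc84_components_anova(geno_a: np.ndarray, geno_b: np.ndarray):
    """Weir-Cockerham (1984) variance components via the three-level ANOVA.

    ``geno_a``/``geno_b`` are (n_i, 2) arrays of 0/1 alleles (called genotypes
    only).  Populations / individuals-within-populations / gametes-within-
    individuals mean squares give sigma^2_a, sigma^2_b, sigma^2_w = (a, b, c).
    """
    pops = [np.asarray(geno_a, dtype=float), np.asarray(geno_b, dtype=float)]
    r = 2
    n = [len(g) for g in pops]
    N = sum(n)
    p_i = [g.sum() / (2 * len(g)) for g in pops]
    pbar = sum(g.sum() for g in pops) / (2 * N)
    ss_pop = sum(2 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i))
    ss_ind = sum(
        (2 * (g.mean(axis=1) - pi) ** 2).sum() for g, pi in zip(pops, p_i)
    )
    ss_gam = sum(((g[:, 0] != g[:, 1]).sum() / 2.0) for g in pops)
    ms_pop = ss_pop / (r - 1)
    ms_ind = ss_ind / (N - r)
    ms_gam = ss_gam / N
    nc = (N - sum(ni * ni for ni in n) / N) / (r - 1)
    c = ms_gam
    b = (ms_ind - ms_gam) / 2.0
    a = (ms_pop - ms_ind) / (2.0 * nc)
    return a, b, c


def pi_pairwise(alleles: np.ndarray) -> float:
    """Average pairwise difference at one site by enumerating haplotype pairs."""
    alleles = np.asarray(alleles)
    n = len(alleles)
    if n < 2:
        return 0.0
    diffs = sum(
        int(alleles[i] != alleles[j]) for i in range(n) for j in range(i + 1, n)
    )
    return diffs / (n * (n - 1) / 2)


def classify_rules(af_focal: float, af_other: float, threshold: float = 0.5) -> str:
    """Literal transcription of the screening rules for one focal population."""
    if af_focal < threshold:
        return "NONE"
    if af_other >= threshold:
        return "NONE"
    if af_other == 0:
        return "SPECIFIC"
    if abs(af_focal - af_other) >= threshold:
        return "PREDOMINANT"
    return "NONE"


def classify_pair_rules(af_a, af_b, threshold=0.5) -> str:
    cat = classify_rules(af_a, af_b, threshold)
    if cat != "NONE":
        return "A_" + cat
    cat = classify_rules(af_b, af_a, threshold)
    if cat != "NONE":
        return "B_" + cat
    return "NONE"


def classify_counts_exact(alt_a: int, tot_a: int, alt_b: int, tot_b: int) -> str:
    """Rule evaluation in exact rational arithmetic (ALT allele only)."""
    if tot_a == 0 or tot_b == 0:
        return "NONE"
    fa, fb = Fraction(alt_a, tot_a), Fraction(alt_b, tot_b)
    half = Fraction(1, 2)
    for focal, other, prefix in ((fa, fb, "A"), (fb, fa, "B")):
        if focal >= half and other < half:
            if other == 0:
                return f"{prefix}_SPECIFIC"
            if abs(focal - other) >= half:
                return f"{prefix}_PREDOMINANT"
    return "NONE"


def clustered_positions_bruteforce(positions, cluster_size=2, window_bp=5):
    """All SNPs inside any window of ``window_bp`` consecutive bases holding
    >= ``cluster_size`` SNPs, by enumerating every possible window start."""
    positions = sorted(positions)
    bad = set()
    if not positions:
        return bad
    for start in range(positions[0] - window_bp, positions[-1] + 1):
        inside = [p for p in positions if start <= p <= start + window_bp - 1]
        if len(inside) >= cluster_size:
            bad.update(inside)
    return bad


def nearest_rank_top_count(values, quantile):
    """Sort-based count of values in the top (1 - quantile) tail."""
    v = sorted(values)
    m = len(v)
    k = m - int(np.floor(quantile * m + 1e-9))
    return max(k, 1), v[m - max(k, 1)]
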