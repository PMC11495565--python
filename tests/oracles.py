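"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible -- python loops,
exact rational arithmetic, full enumeration -- and never calls the code paths
it is used to verify.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np


def pop_freqs_loop(derived, total, sample_pops, population):
    """Pooled per-site frequency by explicit looping; None where missing."""
    n_sites = derived.shape[1]
    rows = [u for u, p in enumerate(sample_pops) if p == population]
    out = []
    for s in range(n_sites):
        d = sum(int(derived[u, s]) for u in rows)
        t = sum(int(total[u, s]) for u in rows)
        out.append(None if t == 0 else d / t)
    return out


def brute_f3(derived, total, sample_pops, target, s1, s2):
    pt = pop_freqs_loop(derived, total, sample_pops, target)
    p1 = pop_freqs_loop(derived, total, sample_pops, s1)
    p2 = pop_freqs_loop(derived, total, sample_pops, s2)
    vals = [
        (t - a) * (t - b)
        for t, a, b in zip(pt, p1, p2)
        if t is not None and a is not None and b is not None
    ]
    return sum(vals) / len(vals)


def brute_f4(derived, total, sample_pops, a, b, c, d):
    ps = [pop_freqs_loop(derived, total, sample_pops, p) for p in (a, b, c, d)]
    vals = [
        (w - x) * (y - z)
        for w, x, y, z in zip(*ps)
        if None not in (w, x, y, z)
    ]
    return sum(vals) / len(vals)


def brute_d(derived, total, sample_pops, a, b, c, d):
    ps = [pop_freqs_loop(derived, total, sample_pops, p) for p in (a, b, c, d)]
    num = den = 0.0
    for w, x, y, z in zip(*ps):
        if None in (w, x, y, z):
            continue
        num += (w - x) * (y - z)
        den += (w + x - 2 * w * x) * (y + z - 2 * y * z)
    return num / den


def hwe_exact_enumeration(n_AA, n_Aa, n_aa):
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_Aa

    def prob(het):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        if het < 0 or hom_a < 0 or hom_A < 0 or (n_a - het) % 2:
            return Fraction(0)
        # multinomial configurations x 2^het genotype orderings, conditioned
        # on the allele counts: P = n! 2^h / (A!h!a!) * nA! na! / (2n)!
        return (
            Fraction(factorial(n) * 2**het,
                     factorial(hom_A) * factorial(het) * factorial(hom_a))
            * Fraction(factorial(n_a) * factorial(2 * n - n_a), factorial(2 * n))
        )

    p_obs = prob(n_Aa)
    total = Fraction(0)
    for het in range(0, min(n_a, 2 * n - n_a) + 1):
        p = prob(het)
        if p > 0 and p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    na = len(a)

    def u_of(group_a):
        rest = [x for x in pooled if x not in group_a]
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = u_of(a)
    mean_u = na * len(b) / 2
    extreme = 0
    configs = list(combinations(pooled, na))
    for ga in configs:
        if abs(u_of(list(ga)) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            extreme += 1
    return extreme / len(configs)


def brute_ascertain(derived, total, chrom, pos, maf_min=0.05, hwe_min=0.001,
                    min_spacing=5, site_missing_max=0.05, sample_missing_max=0.10):
    """Literal re-statement of the filter pipeline; returns kept site indices
    and kept sample indices."""
    n_units, n_sites = derived.shape
    keep_samples = [
        u for u in range(n_units)
        if sum(1 for s in range(n_sites) if total[u, s] == 0) / n_sites
        <= sample_missing_max
    ]
    kept = []
    for s in range(n_sites):
        miss = sum(1 for u in keep_samples if total[u, s] == 0) / len(keep_samples)
        if miss > site_missing_max:
            continue
        d = sum(int(derived[u, s]) for u in keep_samples)
        t = sum(int(total[u, s]) for u in keep_samples)
        if t == 0:
            continue
        maf = min(d / t, 1 - d / t)
        if maf < maf_min:
            continue
        n_dd = sum(1 for u in keep_samples if total[u, s] == 2 and derived[u, s] == 2)
        n_het = sum(1 for u in keep_samples if total[u, s] == 2 and derived[u, s] == 1)
        n_rr = sum(1 for u in keep_samples if total[u, s] == 2 and derived[u, s] == 0)
        if hwe_exact_enumeration(n_dd, n_het, n_rr) < hwe_min:
            continue
        kept.append(s)
    thinned = []
    last = {}
    for s in kept:
        c = chrom[s]
        if c in last and pos[s] - last[c] < min_spacing:
            continue
        last[c] = pos[s]
        thinned.append(s)
    return thinned, keep_samples


def hudson_fst(p1, p2, n1, n2):
    """Hudson's FST estimator from two frequency/count vectors (ratio of means)."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
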