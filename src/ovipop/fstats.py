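"""f3, f4, D statistics and f4-ratio estimation with weighted block jackknife.

All statistics work on pooled sample allele frequencies from an
:class:`~ovipop.geno_io.AlleleCountMatrix` and use the complete-case rule: a
site enters a statistic only if every population involved has at least one
called allele there.  Standard errors come from a weighted delete-one block
jackknife over contiguous genomic blocks (default 1 Mb), which is robust to
linkage between nearby sites.

Sign convention for D(p1, p2; p3, p4): the numerator is
``(p1 - p2)(p3 - p4)`` and the denominator the heterozygosity product
``(p1 + p2 - 2 p1 p2)(p3 + p4 - 2 p3 p4)``.  With p1 an outgroup, negative D
indicates excess affinity of p2 to p3 (relative to p4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import AlleleCountMatrix, SitePanel

__all__ = [
    "BlockIndex",
    "FStatResult",
    "allele_freq",
    "block_jackknife",
    "f3",
    "f4",
    "dstat",
    "f4_ratio",
]


@dataclass
class BlockIndex:
    """Maps each site to a contiguous genomic block (chrom, floor(pos/blocksize))."""

    block_ids: np.ndarray  # site-length integer labels, 0..n_blocks-1
    n_blocks: int
    blocksize: int

    @classmethod
    def from_panel(cls, panel: SitePanel, blocksize: int = 1_000_000) -> "BlockIndex":
        if blocksize < 1:
            raise ValueError("blocksize must be positive")
        ccodes, _ = pd.factorize(panel.chrom)  # panel is position-sorted
        key = (ccodes.astype(np.int64) << 32) | (panel.pos // blocksize)
        codes, _ = pd.factorize(key)
        return cls(codes.astype(np.int64), int(codes.max()) + 1, blocksize)

    def sums(self, values: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Per-block sums of ``values`` over sites where ``mask`` holds."""
        return np.bincount(
            self.block_ids[mask], weights=values[mask], minlength=self.n_blocks
        )

    def counts(self, mask: np.ndarray) -> np.ndarray:
        return np.bincount(self.block_ids[mask], minlength=self.n_blocks)


@dataclass
class FStatResult:
    """A ratio-of-sums statistic with jackknife uncertainty."""

    name: str
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    block_num: np.ndarray
    block_den: np.ndarray

    def __repr__(self) -> str:  # compact, table-friendly
        return (f"{self.name}: {self.estimate:+.6f} +/- {self.se:.6f} "
                f"(Z={self.z:+.2f}, sites={self.n_sites}, blocks={self.n_blocks})")


def allele_freq(matrix: AlleleCountMatrix, population: str, site=None):
    """Pooled derived-allele frequency; NaN marks missing."""
    p = matrix.pop_freq(population)
    return p if site is None else float(p[site])


def block_jackknife(block_num, block_den, weights=None):
    """Weighted delete-one block jackknife for a ratio-of-sums estimator.

    ``weights`` are the per-block site counts (defaults to ``block_den``,
    which is correct for plain means where the denominator is the count).
    Returns ``(estimate, se)`` using the Busing weighted-jackknife variance.
    """
    num = np.asarray(block_num, dtype=np.float64)
    den = np.asarray(block_den, dtype=np.float64)
    m = np.asarray(weights if weights is not None else block_den, dtype=np.float64)
    keep = m > 0
    num, den, m = num[keep], den[keep], m[keep]
    g = num.size
    if g < 2:
        raise ValueError(
            "block jackknife needs >= 2 non-empty blocks; use a smaller blocksize"
        )
    tot_num, tot_den, n = num.sum(), den.sum(), m.sum()
    if tot_den == 0:
        raise ValueError("zero denominator over all blocks")
    theta = tot_num / tot_den
    loo_den = tot_den - den
    if (loo_den == 0).any():
        raise ValueError("a leave-one-out denominator vanishes")
    theta_j = (tot_num - num) / loo_den
    h = n / m
    theta_dot = g * theta - ((1 - m / n) * theta_j).sum()
    tau = h * theta - (h - 1) * theta_j
    var = ((tau - theta_dot) ** 2 / (h - 1)).sum() / g
    return float(theta), float(np.sqrt(max(var, 0.0)))


def _freq_complete(matrix, populations, blocks, panel=None, transversions=False):
    freqs = matrix.freqs(populations)
    complete = np.isfinite(freqs).all(axis=0)
    if transversions:
        if panel is None:
            raise ValueError("transversions_only requires the SitePanel")
        complete &= panel.is_transversion
    if blocks is not None and blocks.block_ids.shape[0] != freqs.shape[1]:
        raise ValueError("BlockIndex not aligned with the matrix site axis")
    return freqs, complete


def _ratio_result(name, num_site, den_site, complete, blocks):
    if not complete.any():
        raise ValueError(f"{name}: zero complete sites")
    bn = blocks.sums(num_site, complete)
    bd = blocks.sums(den_site, complete) if den_site is not None else None
    counts = blocks.counts(complete)
    if bd is None:
        bd = counts.astype(np.float64)
    if bd.sum() == 0:
        raise ValueError(f"{name}: denominator is zero over all sites")
    est, se = block_jackknife(bn, bd, weights=counts)
    z = est / se if se > 0 else np.nan
    return FStatResult(
        name, est, se, float(z), int(complete.sum()),
        int((counts > 0).sum()), bn, bd,
    )


def f3(matrix, target, source1, source2, blocks, panel=None, transversions_only=False):
    """Vanilla f3(target; source1, source2) = mean (p_t - p_1)(p_t - p_2).

    No heterozygosity correction is applied, so single pseudohaploid genomes
    are valid inputs; with an outgroup as target this is the shared-drift
    "outgroup f3".
    """
    freqs, complete = _freq_complete(
        matrix, [target, source1, source2], blocks, panel, transversions_only
    )
    pt, p1, p2 = freqs
    num = (pt - p1) * (pt - p2)
    return _ratio_result(
        f"f3({target};{source1},{source2})", num, None, complete, blocks
    )


def f4(matrix, p1, p2, p3, p4, blocks, panel=None, transversions_only=False):
    """f4(p1, p2; p3, p4) = mean (p1 - p2)(p3 - p4)."""
    freqs, complete = _freq_complete(
        matrix, [p1, p2, p3, p4], blocks, panel, transversions_only
    )
    a, b, c, d = freqs
    num = (a - b) * (c - d)
    return _ratio_result(f"f4({p1},{p2};{p3},{p4})", num, None, complete, blocks)


def dstat(matrix, p1, p2, p3, p4, blocks, panel=None, transversions_only=False):
    """Patterson's D(p1, p2; p3, p4) with weighted block-jackknife SE and Z."""
    if len({p1, p2, p3, p4}) != 4:
        raise ValueError("D requires four distinct population labels")
    freqs, complete = _freq_complete(
        matrix, [p1, p2, p3, p4], blocks, panel, transversions_only
    )
    a, b, c, d = freqs
    num = (a - b) * (c - d)
    den = (a + b - 2 * a * b) * (c + d - 2 * c * d)
    return _ratio_result(f"D({p1},{p2};{p3},{p4})", num, den, complete, blocks)


def f4_ratio(matrix, a, o, x, b, c, blocks, panel=None, transversions_only=False):
    """Admixture proportion alpha = f4(A, O; X, C) / f4(A, O; B, C).

    X is modelled as a mixture of a B-related source (weight alpha) and a
    C-related source.  Both f4 values are computed on the same complete-case
    site set and the ratio itself is jackknifed over blocks (leave-one-block-
    out ratio with site-count weights), which is robust to the strong
    correlation between numerator and denominator.  Warns when the
    denominator f4 is not significantly non-zero (|Z| < 3).
    """
    freqs, complete = _freq_complete(
        matrix, [a, o, x, b, c], blocks, panel, transversions_only
    )
    if not complete.any():
        raise ValueError("f4_ratio: zero complete sites")
    pa, po, px, pb, pc = freqs
    num_site = (pa - po) * (px - pc)
    den_site = (pa - po) * (pb - pc)
    counts = blocks.counts(complete)
    bn = blocks.sums(num_site, complete)
    bd = blocks.sums(den_site, complete)
    if bd.sum() == 0:
        raise ValueError("f4_ratio: denominator f4 is exactly zero")
    den_est, den_se = block_jackknife(bd, counts.astype(float), weights=counts)
    if den_se > 0 and abs(den_est / den_se) < 3:
        warnings.warn(
            f"f4_ratio denominator f4({a},{o};{b},{c}) not significant "
            f"(|Z|={abs(den_est / den_se):.2f} < 3); alpha is unreliable"
        )
    est, se = block_jackknife(bn, bd, weights=counts)
    z = est / se if se > 0 else np.nan
    return FStatResult(
        f"alpha[f4({a},{o};{x},{c})/f4({a},{o};{b},{c})]",
        est, se, float(z), int(complete.sum()), int((counts > 0).sum()), bn, bd,
    )
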