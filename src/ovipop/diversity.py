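"""Within-group pairwise (1 - outgroup f3) dissimilarity and rank tests.

Each genome is treated as a single-unit "population"; for a pair (i, j) in
the same site/breed group, the dissimilarity is ``1 - f3(outgroup; g_i, g_j)``
where f3 is the vanilla (uncorrected) form, well-defined even for
pseudohaploid singletons whose per-site frequencies are 0 or 1.  Lower values
mean more shared drift, i.e. higher within-group relatedness and lower
diversity.  Group-level contrasts use the Kruskal-Wallis and Wilcoxon
rank-sum tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import AlleleCountMatrix, SitePanel

__all__ = ["pairwise_diversity", "kruskal_wallis", "wilcoxon_rank_sum"]


def pairwise_diversity(
    matrix: AlleleCountMatrix,
    groups,
    outgroup: str,
    panel: SitePanel | None = None,
    transversions_only: bool = True,
    min_sites: int = 5000,
) -> pd.DataFrame:
    """Pairwise 1 - f3(outgroup; g_i, g_j) within each group.

    ``groups`` maps sample id -> group label (dict or two-column DataFrame
    with columns id, group).  Groups with fewer than two genomes are
    excluded.  Pairs overlapping the outgroup on fewer than ``min_sites``
    sites are reported with NaN dissimilarity rather than an unstable
    estimate.  Returns a table sorted by group then pair.
    """
    if isinstance(groups, pd.DataFrame):
        groups = dict(zip(groups["id"], groups["group"]))
    if outgroup not in matrix.populations:
        raise KeyError(f"outgroup {outgroup!r} not in matrix")
    po = matrix.pop_freq(outgroup)
    ok_base = np.isfinite(po)
    if transversions_only:
        if panel is None:
            raise ValueError("transversions_only requires the SitePanel")
        ok_base &= panel.is_transversion

    by_group: dict[str, list[str]] = {}
    for sid, grp in groups.items():
        by_group.setdefault(grp, []).append(sid)
    eligible = {g: sorted(ids) for g, ids in by_group.items() if len(ids) >= 2}
    if not eligible:
        raise ValueError("no group has >= 2 genomes")

    sample_freq = {
        sid: matrix.sample_freq(sid)
        for ids in eligible.values() for sid in ids
    }
    rows = []
    for grp in sorted(eligible):
        for a, b in combinations(eligible[grp], 2):
            pa, pb = sample_freq[a], sample_freq[b]
            ok = ok_base & np.isfinite(pa) & np.isfinite(pb)
            n = int(ok.sum())
            if n < min_sites:
                diss = np.nan
            else:
                f3 = float(((po - pa) * (po - pb))[ok].mean())
                diss = 1.0 - f3
            rows.append((grp, a, b, diss, n))
    return pd.DataFrame(
        rows, columns=["group", "id1", "id2", "dissimilarity", "n_sites"]
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H with tie correction, chi-square reference.

    ``groups`` is a sequence of 1-D samples.  Degenerate input where every
    value is identical returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both samples have n <= 10 and there are no ties;
    otherwise the normal approximation with tie correction.  Returns (U, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
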