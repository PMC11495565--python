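"""Within-group (1 - outgroup f3) diversity contrasts.

Treats every genome as a single pseudohaploid or diploid unit, computes
pairwise 1 - f3(Goat; g_i, g_j) within each population (transversions only)
and tests whether groups differ in diversity with Kruskal-Wallis and
pairwise Wilcoxon rank-sum tests (raw p-values, Bonferroni column added).
"""

from itertools import combinations

import pandas as pd

import cohort_common as cc
from ovipop import geno_io
from ovipop.diversity import kruskal_wallis, pairwise_diversity, wilcoxon_rank_sum


def main() -> None:
    meta = pd.read_csv(cc.SCRATCH / "ascertained_samples.tsv", sep="\t")
    panel, matrix, _ = geno_io.read_eigenstrat(
        str(cc.SCRATCH / "ascertained"),
        roles=dict(zip(meta["id"], meta["role"])),
        ploidies=dict(zip(meta["id"], meta["ploidy"])),
    )
    matrix.samples["population"] = list(meta["population"])

    groups = {
        sid: pop for sid, pop in zip(meta["id"], meta["population"])
        if pop != "Goat"
    }
    table = pairwise_diversity(
        matrix, groups, "Goat", panel=panel,
        transversions_only=True, min_sites=1000,
    )
    cc.RESULTS.mkdir(exist_ok=True)
    table.to_csv(cc.RESULTS / "05_diversity.tsv", sep="\t", index=False)

    by_group = {
        g: sub["dissimilarity"].dropna().to_numpy()
        for g, sub in table.groupby("group")
        if sub["dissimilarity"].notna().sum() >= 2
    }
    h, p = kruskal_wallis(list(by_group.values()))
    print("mean pairwise (1 - outgroup f3) per group:")
    print(table.groupby("group")["dissimilarity"].mean().round(4).to_string())
    print(f"\nKruskal-Wallis H = {h:.2f}, p = {p:.3g}")

    rows = []
    names = sorted(by_group)
    for a, b in combinations(names, 2):
        u, pw = wilcoxon_rank_sum(by_group[a], by_group[b])
        rows.append({"group_a": a, "group_b": b, "U": u, "p": pw})
    tests = pd.DataFrame(rows)
    tests["p_bonferroni"] = (tests["p"] * len(tests)).clip(upper=1.0)
    tests.to_csv(cc.RESULTS / "05_group_tests.tsv", sep="\t", index=False)
    print("\npairwise Wilcoxon (raw p):")
    print(tests.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
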