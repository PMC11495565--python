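"""Simulate the synthetic study cohort.

Generates 40,000 biallelic sites on 26 short chromosomes under the study
demography (goat outgroup, wild mouflon panel, modern European/Asian breed
pools, damaged low-coverage ancients, 70% Asian-admixed Baltic genome),
writes the raw cohort to scratch/cohort/ and a summary table to results/.
"""


import cohort_common as cc


def main() -> None:
    freqs, matrix, pileups = cc.build_cohort()
    cc.write_cohort(freqs, matrix, pileups)

    tv_frac = freqs.panel.is_transversion.mean()
    summary = matrix.samples.groupby(["population", "role", "ploidy"]).size()
    summary = summary.rename("n_samples").reset_index()
    depth = {
        sid: pl["bases"].str.len().sum() / freqs.panel.n_sites
        for sid, pl in pileups.items()
    }
    summary["mean_depth"] = [
        round(
            sum(v for s, v in depth.items() if s.startswith(p)) /
            max(sum(1 for s in depth if s.startswith(p)), 1), 2
        ) if p in cc.ANCIENT_POPS else ""
        for p in summary["population"]
    ]
    cc.RESULTS.mkdir(exist_ok=True)
    summary.to_csv(cc.RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)

    print(f"simulated {freqs.panel.n_sites} sites "
          f"({tv_frac:.1%} transversions) on 26 chromosomes")
    print(f"{matrix.n_units} samples, {len(pileups)} ancient pileups "
          f"(deamination rate {cc.DAMAGE_DELTA}) -> {cc.SCRATCH}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
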