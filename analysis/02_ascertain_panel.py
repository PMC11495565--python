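"""Ascertain the SNP panel in the wild cohort and call the ancients.

Applies the filter pipeline (sample missingness, site missingness, MAF >=
0.05, HWE exact p >= 0.001, 5 bp spacing thin) to the wild mouflon diploid
cohort only -- discovering variants in an outgroup lineage avoids
ascertainment bias toward any modern breed -- then restricts every sample to
the surviving sites and pseudohaploidizes the damaged ancient pileups.
Writes the analysis-ready cohort to scratch/ and the filter report to
results/.
"""

import numpy as np
import pandas as pd

import cohort_common as cc
from ovipop import geno_io


def main() -> None:
    panel, matrix, pileups = cc.load_cohort()

    wild = (matrix.samples["population"] == "WildMouflon").to_numpy()
    fp, _, report = geno_io.ascertain_panel(matrix.take_samples(wild), panel)

    surviving = panel.site_key().get_indexer(fp.site_key())
    keep = np.zeros(panel.n_sites, dtype=bool)
    keep[surviving] = True
    filtered = matrix.take_sites(keep)
    filtered = cc.called_cohort(fp, filtered, pileups)

    geno_io.write_eigenstrat(str(cc.SCRATCH / "ascertained"), fp, filtered)
    filtered.samples.to_csv(cc.SCRATCH / "ascertained_samples.tsv",
                            sep="\t", index=False)
    cc.RESULTS.mkdir(exist_ok=True)
    rows = [(k, v if not isinstance(v, list) else ";".join(v) or "-")
            for k, v in report.items()]
    pd.DataFrame(rows, columns=["filter", "value"]).to_csv(
        cc.RESULTS / "02_filter_report.tsv", sep="\t", index=False
    )

    anc_called = {
        sid: int((filtered.total[filtered.unit_index(sid)] > 0).sum())
        for sid in pileups
    }
    print(f"panel: {panel.n_sites} -> {fp.n_sites} sites after ascertainment")
    print({k: v for k, v in report.items() if isinstance(v, int)})
    print("ancient pseudohaploid call counts:", anc_called)


if __name__ == "__main__":
    main()
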