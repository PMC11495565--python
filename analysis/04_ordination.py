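"""Projection PCA and D-PCA of the ascertained cohort.

Fits principal components on the modern diploid genomes only, projects the
low-coverage pseudohaploid ancients onto them by least squares (no
imputation), and runs the population-level D-PCA with the goat outgroup.
Coordinates and variance fractions go to results/.
"""

import pandas as pd

import cohort_common as cc
from ovipop import geno_io
from ovipop.ordination import dpca, pca_fit, project_samples


def main() -> None:
    meta = pd.read_csv(cc.SCRATCH / "ascertained_samples.tsv", sep="\t")
    panel, matrix, _ = geno_io.read_eigenstrat(
        str(cc.SCRATCH / "ascertained"),
        roles=dict(zip(meta["id"], meta["role"])),
        ploidies=dict(zip(meta["id"], meta["ploidy"])),
    )
    matrix.samples["population"] = list(meta["population"])

    modern = (
        (matrix.samples["role"] == "modern")
        & (matrix.samples["population"] != "WildMouflon")
    ).to_numpy()
    model = pca_fit(matrix.take_samples(modern), k=2)
    fitted = pd.DataFrame(model.coords, index=model.sample_ids,
                          columns=["PC1", "PC2"])
    fitted["kind"] = "fitted"
    ancients = meta.loc[meta["role"] == "ancient", "id"].tolist()
    projected = project_samples(model, matrix, ancients)
    projected["kind"] = "projected"
    coords = pd.concat([fitted, projected])
    coords.insert(0, "population", [
        meta.set_index("id").loc[i, "population"] for i in coords.index
    ])
    coords.index.name = "id"
    cc.RESULTS.mkdir(exist_ok=True)
    coords.reset_index().to_csv(cc.RESULTS / "04_pca.tsv", sep="\t",
                                index=False)
    print(f"PCA variance fractions: PC1 {model.var_frac[0]:.1%}, "
          f"PC2 {model.var_frac[1]:.1%}")
    centroids = coords.groupby("population")[["PC1", "PC2"]].mean()
    print(centroids.round(2).to_string())

    res = dpca(matrix, "Goat", panel=panel, transversions_only=True)
    ddf = pd.DataFrame(res.coords, index=res.populations,
                       columns=[f"PC{i+1}" for i in range(res.coords.shape[1])])
    ddf.index.name = "population"
    ddf.reset_index().to_csv(cc.RESULTS / "04_dpca.tsv", sep="\t", index=False)
    print(f"\nD-PCA variance fractions: {res.var_frac.round(3)}")
    print(ddf.round(3).to_string())


if __name__ == "__main__":
    main()
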