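import numpy as np
import pandas as pd
import pytest

from ovipop.geno_io import AlleleCountMatrix, SitePanel, make_sample_meta


def make_panel(n_sites=10, chrom="1", spacing=1000, alleles=("A", "C"), start=1):
    """A small single-chromosome panel with evenly spaced transversion sites."""
    return SitePanel(pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": [start + i * spacing for i in range(n_sites)],
        "ref": [alleles[0]] * n_sites,
        "derived": [alleles[1]] * n_sites,
    }))


def matrix_from_freqs(freq_rows, populations, n=1000):
    """Build an AlleleCountMatrix whose pooled frequencies equal ``freq_rows``.

    Each population gets a single unit with counts (round(p*N), N) for a large
    N, so pooled frequencies are exact for p on a fine grid.
    """
    freq_rows = np.asarray(freq_rows, dtype=float)
    derived = np.round(freq_rows * n).astype(np.int32)
    total = np.full_like(derived, n)
    total[np.isnan(freq_rows)] = 0
    derived[np.isnan(freq_rows)] = 0
    meta = make_sample_meta(
        [f"{p}_u" for p in populations], populations,
        ploidies=["pooled"] * len(populations),
    )
    return AlleleCountMatrix(derived, np.where(total > 0, n, 0), meta)


@pytest.fixture(scope="session")
def null_dstat_replicates():
    """200 seeded replicates of D under a symmetric demography (shared by the
    type-I and jackknife-calibration checks)."""
    from ovipop.workflows import symmetric_null_dstats

    ests, ses, zs = symmetric_null_dstats(seed=11, n_reps=200)
    return ests, ses, zs
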