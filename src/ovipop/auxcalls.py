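"""Rx-based molecular sexing and threshold-rule mitochondrial consensus.

The Rx metric compares X-chromosome read density to each autosome's: for a
female (XX) the normalised ratio is ~1, for a male (XY) ~0.5.  The call uses
a 95% confidence interval over the per-autosome ratios, so low-coverage
shotgun data yields "indeterminate" rather than an overconfident call.

The mitochondrial consensus applies fixed thresholds per position: minimum
read coverage, a base-quality floor (applied when the columns are built) and
a two-thirds majority; anything else becomes 'N'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RxResult", "rx_sex", "mito_consensus", "build_base_columns"]

_BASE_ORDER = "ACGT"


@dataclass
class RxResult:
    rx: float
    ci_low: float
    ci_high: float
    call: str            # 'XX' | 'XY' | 'indeterminate'
    n_autosomes: int


def rx_sex(
    coverage: pd.DataFrame,
    x_name: str = "X",
    thresholds: tuple[float, float] = (0.8, 0.6),
) -> RxResult:
    """Call genetic sex from per-chromosome aligned read counts.

    ``coverage`` needs columns name, length, reads (MAPQ-filtered counts).
    For each autosome i, ``ratio_i = (reads_X/len_X) / (reads_i/len_i)``;
    Rx is the mean ratio with a normal 95% CI over autosomes.  Call XX when
    the whole CI exceeds ``thresholds[0]``, XY when it lies below
    ``thresholds[1]``, otherwise indeterminate.  Chromosomes with zero reads
    are dropped with a warning.
    """
    df = coverage.copy()
    for col in ("name", "length", "reads"):
        if col not in df.columns:
            raise ValueError(f"coverage table missing column {col!r}")
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    if x_name not in set(df["name"]):
        raise ValueError(f"X chromosome {x_name!r} not in coverage table")
    zero = df["reads"] == 0
    if zero.any():
        warnings.warn(f"dropping zero-read chromosomes: {list(df.loc[zero, 'name'])}")
        df = df.loc[~zero]
    if x_name not in set(df["name"]):
        raise ValueError("X chromosome has zero reads; cannot compute Rx")
    x = df[df["name"] == x_name].iloc[0]
    aut = df[df["name"] != x_name]
    if len(aut) < 2:
        raise ValueError("need at least 2 usable autosomes")
    x_density = x["reads"] / x["length"]
    ratios = x_density / (aut["reads"] / aut["length"]).to_numpy()
    rx = float(ratios.mean())
    se = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
    lo, hi = rx - 1.96 * se, rx + 1.96 * se
    upper, lower = thresholds
    if lo > upper:
        call = "XX"
    elif hi < lower:
        call = "XY"
    else:
        call = "indeterminate"
    return RxResult(rx, lo, hi, call, int(ratios.size))


def build_base_columns(
    pileup: pd.DataFrame, length: int | None = None, min_qual: int = 40
) -> np.ndarray:
    """Per-position A/C/G/T counts from a pileup, applying the quality floor.

    Returns an (L, 4) integer array in A,C,G,T order; positions are 1-based
    in the pileup and map to rows 0..L-1.
    """
    length = int(length or (pileup["pos"].max() if len(pileup) else 0))
    counts = np.zeros((length, 4), dtype=np.int64)
    base_to_col = {ord(b): i for i, b in enumerate(_BASE_ORDER)}
    for row in pileup.itertuples(index=False):
        i = int(row.pos) - 1
        if not (0 <= i < length):
            continue
        for base, qual in zip(row.bases.encode(), row.quals.encode()):
            if qual - 33 >= min_qual and base in base_to_col:
                counts[i, base_to_col[base]] += 1
    return counts


def mito_consensus(
    columns: np.ndarray, min_cov: int = 10, min_agreement: float = 2 / 3
) -> str:
    """Threshold-rule consensus: coverage >= min_cov and a clear majority.

    Per position: if total count < ``min_cov`` the call is 'N'; otherwise the
    most frequent base is called when its share is >= ``min_agreement``
    (boundary included, so 8 of 12 passes a two-thirds rule); ties at the
    maximum are conservative 'N'.
    """
    columns = np.asarray(columns)
    if columns.ndim != 2 or columns.shape[1] != 4:
        raise ValueError("columns must be an (L, 4) count array in ACGT order")
    if (columns < 0).any():
        raise ValueError("negative base counts")
    total = columns.sum(axis=1)
    win_count = columns.max(axis=1)
    win_idx = columns.argmax(axis=1)
    tie = (columns == win_count[:, None]).sum(axis=1) > 1
    # boundary-safe share comparison: win/total >= min_agreement
    passes = (
        (total >= min_cov)
        & ~tie
        & (win_count + 1e-9 >= min_agreement * total)
    )
    out = np.full(len(columns), "N", dtype="<U1")
    bases = np.array(list(_BASE_ORDER))
    out[passes] = bases[win_idx[passes]]
    return "".join(out)
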