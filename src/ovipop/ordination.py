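"""Projection PCA and the D-statistic PCA (D-PCA).

``pca_fit`` computes a smartpca-style PCA of diploid genotypes (Patterson
normalisation with a pseudocount, mean imputation of missing calls) and
``pca_project`` places additional -- typically low-coverage pseudohaploid --
samples onto the fitted axes by least squares, using only their non-missing
sites (the "lsqproject" idea: missing sites are excluded from the normal
equations rather than imputed, which avoids shrinkage toward the origin).

``dpca`` ordinates whole populations by computing D(outgroup, focal; C, D)
for every focal population against all unordered pairs {C, D}, centering the
resulting matrix column-wise and taking an SVD.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geno_io import AlleleCountMatrix, SitePanel
from .fstats import BlockIndex

__all__ = ["PCAModel", "DPCAResult", "pca_fit", "pca_project",
           "project_samples", "dpca"]


@dataclass
class PCAModel:
    """Fitted PCA: per-site normalisation plus top-k orthonormal loadings."""

    site_index: np.ndarray     # indices into the input site axis
    mean: np.ndarray           # per-site mean dosage among called samples
    scale: np.ndarray          # sqrt(p~ (1 - p~)) with pseudocount
    loadings: np.ndarray       # k x m, rows orthonormal
    eigenvalues: np.ndarray
    var_frac: np.ndarray
    sample_ids: list
    coords: np.ndarray         # fitted sample coordinates, n x k


@dataclass
class DPCAResult:
    populations: list
    pair_labels: list
    dmatrix: np.ndarray        # rows = focal populations, uncentered D values
    coords: np.ndarray
    var_frac: np.ndarray


def _fix_signs(loadings: np.ndarray, *coupled: np.ndarray):
    """Make each component's largest-|loading| entry positive (reproducibility)."""
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            for arr in coupled:
                arr[:, i] *= -1


def _dosage(matrix: AlleleCountMatrix) -> np.ndarray:
    """Diploid-scale dosage in [0,2]; NaN where missing.  Pseudohaploid calls
    are doubled so they live on the same scale as diploid genotypes."""
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 2.0 * matrix.derived / np.where(matrix.total > 0, matrix.total, 1)
    return np.where(matrix.total > 0, d, np.nan)


def pca_fit(matrix: AlleleCountMatrix, k: int = 2) -> PCAModel:
    """Patterson-normalised PCA of a diploid cohort.

    Sites: missing calls are imputed with the site mean, each column is
    centered and divided by ``sqrt(p~(1-p~))`` where
    ``p~ = (1 + sum g) / (2 + 2 n_called)``; monomorphic columns are dropped.
    """
    dip = (matrix.samples["ploidy"] == "diploid").to_numpy()
    if not dip.all():
        matrix = matrix.take_samples(dip)
    if matrix.n_units < k + 1:
        raise ValueError(f"need at least {k + 1} diploid samples for k={k}")
    g = _dosage(matrix)
    called = np.isfinite(g)
    n_called = called.sum(axis=0)
    informative = np.zeros(matrix.n_sites, dtype=bool)
    ok = n_called > 0
    with np.errstate(invalid="ignore"):
        informative[ok] = np.nanvar(g[:, ok], axis=0) > 0
    if not informative.any():
        raise ValueError("all sites monomorphic or missing; nothing to fit")
    site_index = np.flatnonzero(informative)
    g = g[:, site_index]
    called = called[:, site_index]
    n_called = n_called[site_index]

    mean = np.nanmean(g, axis=0)
    p_tilde = (1.0 + np.nansum(g, axis=0)) / (2.0 + 2.0 * n_called)
    scale = np.sqrt(p_tilde * (1 - p_tilde))
    x = (np.where(called, g, mean) - mean) / scale

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    explained = s**2
    k = min(k, s.size)
    loadings = vt[:k].copy()
    coords = (u[:, :k] * s[:k]).copy()
    _fix_signs(loadings, coords)
    return PCAModel(
        site_index=site_index,
        mean=mean,
        scale=scale,
        loadings=loadings,
        eigenvalues=explained[:k] / max(matrix.n_units - 1, 1),
        var_frac=explained[:k] / explained.sum(),
        sample_ids=list(matrix.samples["id"]),
        coords=coords,
    )


def pca_project(
    model: PCAModel, derived: np.ndarray, total: np.ndarray, min_overlap: int = 10
) -> np.ndarray:
    """Least-squares projection of one sample onto the fitted axes.

    ``derived``/``total`` are site-length vectors on the *original* site axis
    the model was fitted from.  Only the sample's non-missing model sites
    enter the normal equations.
    """
    derived = np.asarray(derived, dtype=np.float64)
    total = np.asarray(total, dtype=np.float64)
    d = derived[model.site_index]
    t = total[model.site_index]
    obs = t > 0
    n_obs = int(obs.sum())
    if n_obs < min_overlap:
        raise ValueError(
            f"only {n_obs} sites overlap the PCA model (need >= {min_overlap})"
        )
    dosage = 2.0 * d[obs] / t[obs]
    x = (dosage - model.mean[obs]) / model.scale[obs]
    a = model.loadings[:, obs].T  # n_obs x k
    coef, *_ = np.linalg.lstsq(a, x, rcond=None)
    return coef


def project_samples(
    model: PCAModel, matrix: AlleleCountMatrix, ids=None, min_overlap: int = 10
) -> pd.DataFrame:
    """Project several samples; returns a coordinate table indexed by id."""
    ids = list(matrix.samples["id"]) if ids is None else list(ids)
    rows = []
    for sid in ids:
        u = matrix.unit_index(sid)
        rows.append(pca_project(model, matrix.derived[u], matrix.total[u],
                                min_overlap=min_overlap))
    k = model.loadings.shape[0]
    return pd.DataFrame(rows, index=ids, columns=[f"PC{i+1}" for i in range(k)])


def dpca(
    matrix: AlleleCountMatrix,
    outgroup: str,
    blocks: BlockIndex | None = None,
    panel: SitePanel | None = None,
    transversions_only: bool = True,
    k: int = 2,
) -> DPCAResult:
    """PCA over the matrix of D(outgroup, focal; C, D) statistics.

    Rows are focal populations (everything but the outgroup); columns are all
    unordered pairs {C, D} in canonical lexicographic orientation, including
    pairs that contain the focal population (still well-defined statistics).
    Columns are mean-centered before the SVD.  ``blocks`` is accepted for
    interface symmetry with the D-statistic caller but point estimates alone
    determine the ordination.
    """
    pops = [p for p in matrix.populations if p != outgroup]
    if outgroup not in matrix.populations:
        raise KeyError(f"outgroup {outgroup!r} not in matrix")
    if len(pops) < 4:
        raise ValueError("D-PCA needs at least 4 populations plus the outgroup")
    freqs = {p: matrix.pop_freq(p) for p in pops}
    freqs[outgroup] = matrix.pop_freq(outgroup)
    tv = None
    if transversions_only:
        if panel is None:
            raise ValueError("transversions_only requires the SitePanel")
        tv = panel.is_transversion

    pairs = list(combinations(sorted(pops), 2))
    dmat = np.zeros((len(pops), len(pairs)))
    po = freqs[outgroup]
    for j, (c, d) in enumerate(pairs):
        pc, pd_ = freqs[c], freqs[d]
        for i, focal in enumerate(pops):
            pf = freqs[focal]
            ok = np.isfinite(po) & np.isfinite(pf) & np.isfinite(pc) & np.isfinite(pd_)
            if tv is not None:
                ok &= tv
            if not ok.any():
                raise ValueError(f"population {focal!r} has zero complete sites")
            num = ((po - pf) * (pc - pd_))[ok].sum()
            den = ((po + pf - 2 * po * pf) * (pc + pd_ - 2 * pc * pd_))[ok].sum()
            if den == 0:
                raise ValueError(
                    f"zero D denominator for focal {focal!r} pair ({c},{d})"
                )
            dmat[i, j] = num / den

    centered = dmat - dmat.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    explained = s**2
    k = min(k, s.size)
    coords = (u[:, :k] * s[:k]).copy()
    loadings = vt[:k].copy()
    _fix_signs(loadings, coords)
    total = explained.sum()
    var_frac = explained[:k] / total if total > 0 else np.zeros(k)
    return DPCAResult(
        populations=pops,
        pair_labels=[f"{c}|{d}" for c, d in pairs],
        dmatrix=dmat,
        coords=coords,
        var_frac=var_frac,
    )
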