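"""Genotype data model, standard-format I/O, pseudohaploid calling and panel filters.

The in-memory model is deliberately simple: a :class:`SitePanel` describes an
ordered list of biallelic SNPs, and an :class:`AlleleCountMatrix` stores, per
unit (sample) and site, the number of derived alleles observed and the number
of alleles called.  Missing data is encoded as ``called_total == 0`` so that
every arithmetic path can pool counts without sentinel values.  Diploid calls
contribute totals of 2, pseudohaploid calls totals of 1; both flow through the
same statistics downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_TRANSITION_PAIRS = frozenset({frozenset("CT"), frozenset("AG")})

__all__ = [
    "FormatError",
    "SitePanel",
    "AlleleCountMatrix",
    "make_sample_meta",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_vcf",
    "write_vcf",
    "read_pileup",
    "write_pileup",
    "pseudohaploidize",
    "hwe_exact_test",
    "ascertain_panel",
    "transversions_only",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _chrom_order(chrom: pd.Series, pos: pd.Series) -> np.ndarray:
    """Sort order by (chrom, pos), numeric-aware ('2' < '10', names last)."""
    num = pd.to_numeric(chrom, errors="coerce")
    return np.lexsort((
        pos.to_numpy(),
        chrom.to_numpy(dtype=object),
        num.fillna(np.inf).to_numpy(),
    ))


@dataclass
class SitePanel:
    """Ordered biallelic SNP list: chrom, 1-based pos, ref and derived alleles."""

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites
        required = {"chrom", "pos", "ref", "derived"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"SitePanel missing columns: {sorted(missing)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        num = pd.to_numeric(df["chrom"], errors="coerce")
        pos = df["pos"].to_numpy()
        if not num.isna().any():
            # all-numeric chromosome names: fast integer sort path
            numv = num.to_numpy(dtype=np.int64)
            order = np.lexsort((pos, numv))
            if not (np.diff(order) == 1).all():
                df = df.iloc[order].reset_index(drop=True)
                numv, pos = numv[order], pos[order]
            dup = (np.diff(numv) == 0) & (np.diff(pos) == 0)
        else:
            df = df.iloc[_chrom_order(df["chrom"], df["pos"])].reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "pos"]).to_numpy()[1:]
        for col in ("ref", "derived"):
            seen = set(np.unique(df[col].to_numpy()))
            if not seen <= set(BASES):
                raise ValueError(f"non-ACGT allele in column {col!r}")
        if (df["ref"].to_numpy() == df["derived"].to_numpy()).any():
            raise ValueError("ref and derived alleles must differ")
        if dup.any():
            i = int(np.flatnonzero(dup)[0]) + 1
            raise ValueError(
                f"duplicate site {df['chrom'].iat[i]}:{df['pos'].iat[i]}"
            )
        self.sites = df
        self._is_tv: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chrom(self) -> np.ndarray:
        return self.sites["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    @property
    def ref(self) -> np.ndarray:
        return self.sites["ref"].to_numpy()

    @property
    def derived(self) -> np.ndarray:
        return self.sites["derived"].to_numpy()

    @property
    def is_transversion(self) -> np.ndarray:
        if self._is_tv is None:
            lo = np.minimum(self.ref, self.derived)
            hi = np.maximum(self.ref, self.derived)
            ts = ((lo == "C") & (hi == "T")) | ((lo == "A") & (hi == "G"))
            self._is_tv = ~ts
        return self._is_tv

    def take(self, index) -> "SitePanel":
        """Subset sites by boolean mask or integer index (order preserved)."""
        index = np.asarray(index)
        df = self.sites.loc[index] if index.dtype == bool else self.sites.iloc[index]
        return SitePanel(df.reset_index(drop=True))

    def site_key(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos])


def make_sample_meta(ids, populations, roles=None, ploidies=None) -> pd.DataFrame:
    """Build the per-sample metadata table (id, population, role, ploidy)."""
    ids = list(ids)
    if roles is None:
        roles = ["modern"] * len(ids)
    if ploidies is None:
        ploidies = ["diploid"] * len(ids)
    if isinstance(populations, str):
        populations = [populations] * len(ids)
    df = pd.DataFrame(
        {"id": ids, "population": list(populations), "role": list(roles),
         "ploidy": list(ploidies)}
    )
    if df["id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    bad = ~df["ploidy"].isin(["diploid", "pseudohaploid", "pooled"])
    if bad.any():
        raise ValueError("ploidy must be 'diploid', 'pseudohaploid' or 'pooled'")
    return df


@dataclass
class AlleleCountMatrix:
    """Per-unit, per-site derived-allele counts; ``total == 0`` encodes missing.

    ``derived[u, s]`` is the number of derived alleles called for unit ``u`` at
    site ``s`` and ``total[u, s]`` the number of called alleles (0, 1 for
    pseudohaploid units, 0, 2 for diploid individuals).
    """

    derived: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.derived = np.asarray(self.derived, dtype=np.int32)
        self.total = np.asarray(self.total, dtype=np.int32)
        if self.derived.shape != self.total.shape or self.derived.ndim != 2:
            raise ValueError("derived/total must be 2-D arrays of equal shape")
        if len(self.samples) != self.derived.shape[0]:
            raise ValueError("sample table does not match matrix rows")
        if (self.derived < 0).any() or (self.derived > self.total).any():
            raise ValueError("require 0 <= derived <= total")
        # 'pooled' units (population-level count columns) are unconstrained
        for ploidy, valid in (
            ("pseudohaploid", lambda t: (t <= 1).all()),
            ("diploid", lambda t: ((t == 0) | (t == 2)).all()),
        ):
            rows = np.flatnonzero((self.samples["ploidy"] == ploidy).to_numpy())
            if rows.size and not valid(self.total[rows]):
                limit = 1 if ploidy == "pseudohaploid" else 2
                raise ValueError(f"{ploidy} totals must be 0 or {limit}")

    @property
    def n_units(self) -> int:
        return self.derived.shape[0]

    @property
    def n_sites(self) -> int:
        return self.derived.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def unit_index(self, sample_id: str) -> int:
        hits = np.flatnonzero((self.samples["id"] == sample_id).to_numpy())
        if hits.size != 1:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return int(hits[0])

    def _pop_rows(self, population: str) -> np.ndarray:
        rows = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if rows.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return rows

    def pop_freq(self, population: str) -> np.ndarray:
        """Pooled derived-allele frequency per site; NaN where no allele called."""
        rows = self._pop_rows(population)
        der = self.derived[rows].sum(axis=0, dtype=np.float64)
        tot = self.total[rows].sum(axis=0, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, der / np.where(tot > 0, tot, 1), np.nan)

    def freqs(self, populations) -> np.ndarray:
        return np.vstack([self.pop_freq(p) for p in populations])

    def sample_freq(self, sample_id: str) -> np.ndarray:
        u = self.unit_index(sample_id)
        der = self.derived[u].astype(np.float64)
        tot = self.total[u].astype(np.float64)
        return np.where(tot > 0, der / np.where(tot > 0, tot, 1), np.nan)

    def take_sites(self, index) -> "AlleleCountMatrix":
        index = np.asarray(index)
        return AlleleCountMatrix(
            self.derived[:, index], self.total[:, index],
            self.samples.reset_index(drop=True),
        )

    def take_samples(self, mask) -> "AlleleCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("take_samples expects a boolean mask")
        return AlleleCountMatrix(
            self.derived[mask], self.total[mask],
            self.samples.loc[mask].reset_index(drop=True),
        )

    def set_unit(self, sample_id: str, derived: np.ndarray, total: np.ndarray) -> None:
        """Overwrite one unit's calls in place (e.g. after pseudohaploid calling)."""
        u = self.unit_index(sample_id)
        derived = np.asarray(derived, dtype=np.int32)
        total = np.asarray(total, dtype=np.int32)
        if derived.shape != (self.n_sites,) or total.shape != (self.n_sites,):
            raise ValueError("replacement arrays must be site-length vectors")
        self.derived[u] = derived
        self.total[u] = total
        self.__post_init__()

    @staticmethod
    def concat_units(parts: list["AlleleCountMatrix"]) -> "AlleleCountMatrix":
        n_sites = {p.n_sites for p in parts}
        if len(n_sites) != 1:
            raise ValueError("cannot concatenate matrices over different site sets")
        return AlleleCountMatrix(
            np.vstack([p.derived for p in parts]),
            np.vstack([p.total for p in parts]),
            pd.concat([p.samples for p in parts], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def write_eigenstrat(prefix: str, panel: SitePanel, matrix: AlleleCountMatrix) -> None:
    """Write geno/snp/ind files.

    The geno value counts copies of the derived allele (.snp column 6).
    Pseudohaploid calls are written homozygous (0 or 2), mirroring common
    pseudohaploid caller output; ploidy is restored at read time from the
    caller-supplied sample roles.
    """
    if matrix.n_sites != panel.n_sites:
        raise ValueError("matrix/panel site dimension mismatch")
    with open(f"{prefix}.snp", "w") as fh:
        for c, p, r, d in zip(panel.chrom, panel.pos, panel.ref, panel.derived):
            fh.write(f"{c}_{p}\t{c}\t0.0\t{p}\t{r}\t{d}\n")
    with open(f"{prefix}.ind", "w") as fh:
        for _, row in matrix.samples.iterrows():
            fh.write(f"{row['id']}\tU\t{row['population']}\n")
    ploidy = matrix.samples["ploidy"].to_numpy()
    codes = np.full(matrix.derived.shape, 9, dtype=np.int8)
    called = matrix.total > 0
    codes[called] = matrix.derived[called]
    pseudo = (ploidy == "pseudohaploid")[:, None] & called
    codes[pseudo] = matrix.derived[pseudo] * 2
    with open(f"{prefix}.geno", "w") as fh:
        for s in range(matrix.n_sites):
            fh.write("".join(map(str, codes[:, s])) + "\n")


def read_eigenstrat(prefix: str, roles=None, ploidies=None):
    """Read geno/snp/ind files into (SitePanel, AlleleCountMatrix, sample table).

    ``ploidies`` maps sample id to 'diploid' (default) or 'pseudohaploid'; a
    pseudohaploid sample's homozygous codes are folded back to haploid calls.
    """
    snp = pd.read_csv(
        f"{prefix}.snp", sep=r"\s+", header=None,
        names=["snpid", "chrom", "gpos", "pos", "ref", "derived"],
        dtype={"chrom": str},
    )
    panel = SitePanel(snp[["chrom", "pos", "ref", "derived"]])
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", header=None, names=["id", "sex", "population"]
    )
    n_ind = len(ind)
    ploidies = ploidies or {}
    roles = roles or {}
    meta = make_sample_meta(
        ind["id"], ind["population"],
        roles=[roles.get(i, "modern") for i in ind["id"]],
        ploidies=[ploidies.get(i, "diploid") for i in ind["id"]],
    )
    rows = []
    with open(f"{prefix}.geno") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if len(line) != n_ind:
                raise FormatError(
                    f"{prefix}.geno line {lineno}: {len(line)} genotypes for "
                    f"{n_ind} individuals"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    codes = np.array(rows, dtype=np.int8).T  # units x sites
    if codes.shape[1] != panel.n_sites:
        raise FormatError(
            f"{prefix}.geno has {codes.shape[1]} sites, .snp has {panel.n_sites}"
        )
    if not np.isin(codes, (0, 1, 2, 9)).all():
        raise FormatError(f"{prefix}.geno contains values outside {{0,1,2,9}}")
    derived = np.where(codes == 9, 0, codes).astype(np.int32)
    total = np.where(codes == 9, 0, 2).astype(np.int32)
    pseudo = (meta["ploidy"] == "pseudohaploid").to_numpy()
    if pseudo.any():
        sub = derived[pseudo]
        if np.isin(sub, (1,)).any():
            raise FormatError("pseudohaploid sample carries heterozygous code 1")
        derived[pseudo] = sub // 2
        total[pseudo] = np.where(total[pseudo] > 0, 1, 0)
    return panel, AlleleCountMatrix(derived, total, meta), meta


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path: str, panel: SitePanel, matrix: AlleleCountMatrix) -> None:
    """Write a plain-text VCFv4.2 with GT fields (haploid GT for pseudohaploids)."""
    if matrix.n_sites != panel.n_sites:
        raise ValueError("matrix/panel site dimension mismatch")
    ids = list(matrix.samples["id"])
    ploidy = matrix.samples["ploidy"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ovipop\n")
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for s in range(panel.n_sites):
            gts = []
            for u in range(matrix.n_units):
                t, d = matrix.total[u, s], matrix.derived[u, s]
                if ploidy[u] == "pseudohaploid":
                    gts.append(str(d) if t else ".")
                else:
                    gts.append(("0/0", "0/1", "1/1")[d] if t else "./.")
            fh.write(
                f"{panel.chrom[s]}\t{panel.pos[s]}\t.\t{panel.ref[s]}\t"
                f"{panel.derived[s]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str, panel: SitePanel | None = None, populations=None):
    """Read GT fields from a VCF into an AlleleCountMatrix.

    Only biallelic SNP records are ingested; multiallelic records and
    half-calls are skipped/set missing with a logged count.  When ``panel`` is
    given, only panel sites are kept and allele orientation is matched to the
    panel (records whose alleles cannot be matched are dropped and counted).
    Returns ``(panel_out, matrix, report)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    report = {"multiallelic": 0, "half_calls": 0, "unmatched_alleles": 0,
              "off_panel": 0, "records_used": 0}

    if panel is not None:
        lookup = {(c, p): i for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))}
        n_sites = panel.n_sites
        derived = np.zeros((len(ids), n_sites), dtype=np.int32)
        total = np.zeros((len(ids), n_sites), dtype=np.int32)
    else:
        recs = []
    rows_d, rows_t = [], []

    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in BASES or var.ALT[0] not in BASES:
            report["multiallelic"] += 1
            continue
        flip = False
        if panel is not None:
            idx = lookup.get((str(var.CHROM), int(var.POS)))
            if idx is None:
                report["off_panel"] += 1
                continue
            pr, pd_ = panel.ref[idx], panel.derived[idx]
            if (var.REF, var.ALT[0]) == (pr, pd_):
                flip = False
            elif (var.REF, var.ALT[0]) == (pd_, pr):
                flip = True
            else:
                report["unmatched_alleles"] += 1
                continue
        d_row = np.zeros(len(ids), dtype=np.int32)
        t_row = np.zeros(len(ids), dtype=np.int32)
        for u, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a != -1]
            n_missing = sum(1 for a in gt[:-1] if a == -1)
            if n_missing and alleles:
                report["half_calls"] += 1
                continue  # half-call -> fully missing
            if not alleles:
                continue
            t_row[u] = len(alleles)
            d_row[u] = sum(alleles)
        if flip:
            d_row = np.where(t_row > 0, t_row - d_row, 0)
        report["records_used"] += 1
        if panel is not None:
            derived[:, idx] = d_row
            total[:, idx] = t_row
        else:
            recs.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
            rows_d.append(d_row)
            rows_t.append(t_row)

    if panel is None:
        if not recs:
            raise FormatError(f"{path}: no usable biallelic records")
        site_df = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "derived"])
        panel_out = SitePanel(site_df)
        # reorder matrix columns to the panel's canonical sort
        key = pd.MultiIndex.from_frame(site_df[["chrom", "pos"]])
        target = panel_out.site_key()
        order = key.get_indexer(target)
        derived = np.array(rows_d, dtype=np.int32).T[:, order]
        total = np.array(rows_t, dtype=np.int32).T[:, order]
    else:
        panel_out = panel

    if populations is None:
        populations = ids
    # pseudohaploid if every called total is 1
    ploidies = []
    for u in range(len(ids)):
        t = total[u][total[u] > 0]
        ploidies.append("pseudohaploid" if t.size and (t == 1).all() else "diploid")
    meta = make_sample_meta(ids, populations, ploidies=ploidies)
    logger.info("read_vcf(%s): %s", path, report)
    return panel_out, AlleleCountMatrix(derived, total, meta), report


# ---------------------------------------------------------------------------
# Pileup text (samtools-mpileup column order: chrom pos ref depth bases quals)
# ---------------------------------------------------------------------------

def write_pileup(path: str, pileup: pd.DataFrame) -> None:
    cols = ["chrom", "pos", "ref", "bases", "quals"]
    with open(path, "w") as fh:
        for row in pileup[cols].itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{len(row.bases)}\t"
                     f"{row.bases}\t{row.quals}\n")


def read_pileup(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "ref", "depth", "bases", "quals"],
        dtype={"chrom": str, "bases": str, "quals": str},
        keep_default_na=False,
    )
    df["bases"] = df["bases"].fillna("")
    df["quals"] = df["quals"].fillna("")
    bad = df["bases"].str.len() != df["depth"]
    if bad.any():
        raise FormatError(f"{path}: depth/bases mismatch at line {bad.idxmax() + 1}")
    return df.drop(columns="depth")


def _explode_reads(pileup: pd.DataFrame):
    """Flatten per-site base/quality strings into read-level byte arrays."""
    bases = np.frombuffer("".join(pileup["bases"]).encode(), dtype=np.uint8)
    quals = np.frombuffer("".join(pileup["quals"]).encode(), dtype=np.uint8)
    depths = pileup["bases"].str.len().to_numpy()
    site_of_read = np.repeat(np.arange(len(pileup)), depths)
    return bases, quals, depths, site_of_read


def pseudohaploidize(
    pileup: pd.DataFrame,
    panel: SitePanel,
    min_base_quality: int = 30,
    seed: int = 0,
    sample_id: str = "sample",
    population: str | None = None,
    role: str = "ancient",
):
    """Random-draw haploid calling from a pileup, restricted to panel sites.

    At each panel site, reads below the base-quality floor or carrying a
    non-panel allele are discarded and one surviving read is chosen uniformly
    at random; its allele becomes the haploid call.  Sites with no surviving
    read are missing.  Mapping-quality filtering is assumed applied upstream
    when the pileup was produced (as ``samtools mpileup -q`` does).  Pileup
    sites absent from the panel are skipped and counted, not an error.
    Returns ``(AlleleCountMatrix with one unit, report)``.
    """
    rng = np.random.default_rng(seed)
    key = pd.MultiIndex.from_arrays(
        [pileup["chrom"].astype(str), pileup["pos"].astype(np.int64)]
    )
    site_idx = panel.site_key().get_indexer(key)
    on_panel = site_idx >= 0
    report = {"off_panel_sites": int((~on_panel).sum())}

    derived = np.zeros(panel.n_sites, dtype=np.int32)
    total = np.zeros(panel.n_sites, dtype=np.int32)
    sub = pileup.loc[on_panel]
    if len(sub):
        bases, quals, _, row_of_read = _explode_reads(sub)
        panel_site = site_idx[on_panel][row_of_read]
        ref_b = np.frombuffer("".join(panel.ref).encode(), dtype=np.uint8)
        der_b = np.frombuffer("".join(panel.derived).encode(), dtype=np.uint8)
        ok = (quals - 33 >= min_base_quality) & (
            (bases == ref_b[panel_site]) | (bases == der_b[panel_site])
        )
        idx = np.flatnonzero(ok)
        if idx.size:
            s = panel_site[idx]
            order = np.lexsort((rng.random(idx.size), s))
            s_sorted = s[order]
            first = np.ones(s_sorted.size, dtype=bool)
            first[1:] = s_sorted[1:] != s_sorted[:-1]
            chosen = idx[order][first]
            sites = s_sorted[first]
            total[sites] = 1
            derived[sites] = (bases[chosen] == der_b[sites]).astype(np.int32)
    report["sites_called"] = int(total.sum())
    meta = make_sample_meta(
        [sample_id], [population or sample_id], roles=[role],
        ploidies=["pseudohaploid"],
    )
    return AlleleCountMatrix(derived[None, :], total[None, :], meta), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts (same parity, same
    allele counts) that are no more probable than the observed one under the
    exact conditional distribution of heterozygote number given allele counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        warnings.warn("hwe_exact_test on zero genotypes; returning p=1")
        return 1.0
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Ascertainment / filter pipeline
# ---------------------------------------------------------------------------

def _genotype_counts(matrix: AlleleCountMatrix):
    """Per-site diploid genotype counts (hom-derived, het, hom-ref)."""
    dip = (matrix.samples["ploidy"] == "diploid").to_numpy()
    der = matrix.derived[dip]
    tot = matrix.total[dip]
    called = tot == 2
    n_dd = ((der == 2) & called).sum(axis=0)
    n_het = ((der == 1) & called).sum(axis=0)
    n_rr = ((der == 0) & called).sum(axis=0)
    return n_dd, n_het, n_rr


def ascertain_panel(
    matrix: AlleleCountMatrix,
    panel: SitePanel,
    maf_min: float = 0.05,
    hwe_min: float = 0.001,
    min_spacing_bp: int = 5,
    site_missing_max: float = 0.05,
    sample_missing_max: float = 0.10,
):
    """SNP ascertainment filters, applied in a fixed order.

    Order: sample-missingness, biallelic validity, site-missingness, minor
    allele frequency, Hardy-Weinberg exact test, then a keep-first greedy
    spacing thin (a site is kept only if >= ``min_spacing_bp`` from the
    previously kept site on the same chromosome).  Returns
    ``(filtered panel, filtered matrix, report)``.
    """
    if matrix.n_sites != panel.n_sites:
        raise ValueError("matrix/panel site dimension mismatch")
    report: dict[str, int | list] = {}

    # 1. sample missingness (PLINK --mind semantics: drop samples above max)
    miss_frac = (matrix.total == 0).mean(axis=1)
    keep_samples = miss_frac <= sample_missing_max
    report["samples_removed"] = [
        str(i) for i in matrix.samples.loc[~keep_samples, "id"]
    ]
    m = matrix.take_samples(keep_samples)
    if m.n_units == 0:
        raise ValueError("no samples survive the missingness filter")

    keep = np.ones(panel.n_sites, dtype=bool)

    # 2. biallelic validity (alleles distinct ACGT is enforced by SitePanel;
    #    here: drop sites where pooled counts are inconsistent -- none expected)
    report["non_biallelic_removed"] = 0

    # 3. site missingness (PLINK --geno)
    site_miss = (m.total == 0).mean(axis=0)
    drop = keep & (site_miss > site_missing_max)
    report["site_missingness_removed"] = int(drop.sum())
    keep &= ~drop

    # 4. minor allele frequency on non-missing alleles
    der = m.derived.sum(axis=0, dtype=np.float64)
    tot = m.total.sum(axis=0, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, der / np.where(tot > 0, tot, 1), np.nan)
    maf = np.fmin(p, 1 - p)
    drop = keep & (~np.isfinite(maf) | (maf < maf_min))
    report["maf_removed"] = int(drop.sum())
    keep &= ~drop

    # 5. HWE exact test on the ascertainment cohort's diploid genotypes
    n_dd, n_het, n_rr = _genotype_counts(m)
    hwe_p = np.ones(panel.n_sites)
    for s in np.flatnonzero(keep):
        hwe_p[s] = hwe_exact_test(int(n_dd[s]), int(n_het[s]), int(n_rr[s]))
    drop = keep & (hwe_p < hwe_min)
    report["hwe_removed"] = int(drop.sum())
    keep &= ~drop

    # 6. spacing thin: keep-first greedy within chromosome
    thin_drop = np.zeros(panel.n_sites, dtype=bool)
    chroms = panel.chrom
    pos = panel.pos
    last_kept: dict[str, int] = {}
    for s in np.flatnonzero(keep):
        c = chroms[s]
        if c in last_kept and pos[s] - last_kept[c] < min_spacing_bp:
            thin_drop[s] = True
        else:
            last_kept[c] = int(pos[s])
    report["spacing_removed"] = int(thin_drop.sum())
    keep &= ~thin_drop

    if not keep.any():
        raise ValueError("no sites survive the ascertainment filters")
    report["sites_kept"] = int(keep.sum())
    return panel.take(keep), m.take_sites(keep), report


def transversions_only(panel: SitePanel, matrix: AlleleCountMatrix):
    """Drop transition-class sites (ref/derived in {A,G} or {C,T})."""
    if matrix.n_sites != panel.n_sites:
        raise ValueError("matrix/panel site dimension mismatch")
    mask = panel.is_transversion
    return panel.take(mask), matrix.take_sites(mask)
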