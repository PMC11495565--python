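"""Synthetic allele-frequency, genotype and pileup generation.

Simulates derived-allele frequencies down a rooted population tree under the
Balding-Nichols drift model, with optional admixture pulses, then samples
diploid "modern" genotypes, pseudohaploid "ancient" calls, and read-level
pileups with post-mortem deamination-like damage.  The generator is the
stand-in for a real outgroup-ascertained SNP panel: every downstream analysis
(f-statistics, PCA, diversity) can be exercised against known truth.

Drift on an edge with parameter ``F`` draws the child frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that ``E[child] = p`` and
``Var[child] = F p (1-p)``; ``F = 0`` copies the parent exactly and
frequencies that fix at 0 or 1 stay fixed.  An admixed population's frequency
is ``alpha * p_A + (1 - alpha) * p_B`` before its own residual drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import AlleleCountMatrix, SitePanel, make_sample_meta

__all__ = [
    "ConfigurationError",
    "AdmixtureEvent",
    "DemographyConfig",
    "SampleConfig",
    "FrequencyTable",
    "simulate_frequencies",
    "sample_genotypes",
    "apply_damage",
]

_TRANSITION_ALLELES = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]
_TRANSVERSION_ALLELES = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]


class ConfigurationError(ValueError):
    """Raised for an inconsistent demography (cycles, bad rates, orphans)."""


@dataclass(frozen=True)
class AdmixtureEvent:
    """A two-way pulse: target = alpha * source_a + (1 - alpha) * source_b."""

    source_a: str
    source_b: str
    target: str
    alpha: float
    drift: float = 0.0  # residual drift applied to the target after mixing


@dataclass
class DemographyConfig:
    """Rooted tree with per-branch drift F plus admixture pulses.

    ``edges`` are (parent, child, F) with F in [0, 1); admixed nodes appear
    only as admixture targets, never as tree children.  ``populations`` lists
    the nodes that will be sampled; internal nodes need not be listed.
    """

    populations: list[str]
    edges: list[tuple[str, str, float]]
    admixtures: list[AdmixtureEvent] = field(default_factory=list)
    root_freq: tuple[float, float] = (0.05, 0.95)
    ts_fraction: float = 2 / 3
    n_chromosomes: int = 26
    chrom_length: int = 100_000_000

    def __post_init__(self) -> None:
        self.admixtures = [
            a if isinstance(a, AdmixtureEvent) else AdmixtureEvent(*a)
            for a in self.admixtures
        ]
        self.validate()

    def validate(self) -> None:
        parents: dict[str, str] = {}
        for parent, child, f in self.edges:
            if not (0 <= f < 1):
                raise ConfigurationError(f"drift F={f} outside [0,1) on {child}")
            if child in parents:
                raise ConfigurationError(f"node {child} has two parents")
            parents[child] = parent
        admix_targets = set()
        for ev in self.admixtures:
            if not (0 <= ev.alpha <= 1):
                raise ConfigurationError(f"alpha={ev.alpha} outside [0,1]")
            if not (0 <= ev.drift < 1):
                raise ConfigurationError("admixture residual drift outside [0,1)")
            if ev.target in parents or ev.target in admix_targets:
                raise ConfigurationError(
                    f"admixture target {ev.target} already has a parent"
                )
            admix_targets.add(ev.target)
        tree_nodes = set(parents) | {p for p, _, _ in self.edges}
        roots = tree_nodes - set(parents)
        if len(roots) != 1:
            raise ConfigurationError(f"expected one root, found {sorted(roots)}")
        # cycle check via walk-to-root
        for node in parents:
            seen = {node}
            cur = node
            while cur in parents:
                cur = parents[cur]
                if cur in seen:
                    raise ConfigurationError(f"cycle in tree at {cur}")
                seen.add(cur)
        if not (0 <= self.ts_fraction <= 1):
            raise ConfigurationError("ts_fraction outside [0,1]")
        lo, hi = self.root_freq
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("root_freq bounds must satisfy 0<=lo<=hi<=1")
        known = tree_nodes | admix_targets
        unknown = [p for p in self.populations if p not in known]
        if unknown:
            raise ConfigurationError(f"sampled populations not in demography: {unknown}")

    @property
    def root(self) -> str:
        children = {c for _, c, _ in self.edges}
        return next(p for p, _, _ in self.edges if p not in children)

    def topological_nodes(self):
        """Yield tree nodes root-first, then admixture targets in listed order."""
        children: dict[str, list[tuple[str, float]]] = {}
        for parent, child, f in self.edges:
            children.setdefault(parent, []).append((child, f))
        out = [(self.root, None, 0.0)]
        stack = [self.root]
        while stack:
            node = stack.pop(0)
            for child, f in children.get(node, []):
                out.append((child, node, f))
                stack.append(child)
        return out


@dataclass
class SampleConfig:
    """Per-population sampling spec for one simulated cohort."""

    population: str
    n_individuals: int
    mode: str = "diploid"  # 'diploid' | 'pseudohaploid' | 'pileup'
    missing_rate: float = 0.0
    mean_depth: float = 0.0  # reads/site for pileup emission
    damage_rate: float = 0.0  # deamination rate handed to apply_damage by drivers
    role: str | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        for rate in (self.missing_rate, self.damage_rate):
            if not (0 <= rate <= 1):
                raise ConfigurationError("rates must lie in [0,1]")
        if self.mode not in ("diploid", "pseudohaploid", "pileup"):
            raise ConfigurationError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "pileup" and self.mean_depth <= 0:
            raise ConfigurationError("pileup mode requires mean_depth > 0")


@dataclass
class FrequencyTable:
    """True derived-allele frequencies per node, aligned to a SitePanel."""

    panel: SitePanel
    node_names: list[str]
    freqs: np.ndarray  # nodes x sites, in [0,1]

    def __post_init__(self) -> None:
        if self.freqs.shape != (len(self.node_names), self.panel.n_sites):
            raise ValueError("frequency matrix shape mismatch")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies outside [0,1]")

    def freq(self, node: str) -> np.ndarray:
        try:
            return self.freqs[self.node_names.index(node)]
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    child = p.copy()
    seg = (p > 0) & (p < 1)  # fixed frequencies stay fixed
    ratio = (1 - f) / f
    child[seg] = rng.beta(p[seg] * ratio, (1 - p[seg]) * ratio)
    return child


def simulate_frequencies(
    config: DemographyConfig, n_sites: int, seed: int
) -> FrequencyTable:
    """Simulate per-node derived-allele frequencies and a synthetic SitePanel.

    Sites are placed uniformly on ``config.n_chromosomes`` synthetic
    chromosomes (so megabase jackknife blocks are meaningful); a
    ``ts_fraction`` share of sites gets transition-class alleles.
    Deterministic given (config, n_sites, seed).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)

    chrom_idx = rng.integers(0, config.n_chromosomes, size=n_sites)
    pos = rng.integers(1, config.chrom_length + 1, size=n_sites)
    # retry duplicate (chrom,pos) draws; collisions are vanishingly rare
    for _ in range(10):
        key = chrom_idx.astype(np.int64) * (config.chrom_length + 1) + pos
        _, first = np.unique(key, return_index=True)
        dup = np.ones(n_sites, dtype=bool)
        dup[first] = False
        if not dup.any():
            break
        pos[dup] = rng.integers(1, config.chrom_length + 1, size=int(dup.sum()))
    is_ts = rng.random(n_sites) < config.ts_fraction
    ts_arr = np.array(_TRANSITION_ALLELES)
    tv_arr = np.array(_TRANSVERSION_ALLELES)
    ts_pick = rng.integers(0, len(ts_arr), size=n_sites)
    tv_pick = rng.integers(0, len(tv_arr), size=n_sites)
    ref = np.where(is_ts, ts_arr[ts_pick, 0], tv_arr[tv_pick, 0])
    der = np.where(is_ts, ts_arr[ts_pick, 1], tv_arr[tv_pick, 1])
    # pre-sort into the panel's canonical (chrom, pos) order so the simulated
    # frequencies line up with the SitePanel without a reindexing pass
    order = np.lexsort((pos, chrom_idx))
    panel = SitePanel(pd.DataFrame({
        "chrom": (chrom_idx[order] + 1).astype(str),
        "pos": pos[order],
        "ref": ref[order],
        "derived": der[order],
    }))

    lo, hi = config.root_freq
    node_freq: dict[str, np.ndarray] = {}
    for node, parent, f in config.topological_nodes():
        if parent is None:
            node_freq[node] = rng.uniform(lo, hi, size=n_sites)
        else:
            node_freq[node] = _balding_nichols(rng, node_freq[parent], f)
    for ev in config.admixtures:
        for src in (ev.source_a, ev.source_b):
            if src not in node_freq:
                raise ConfigurationError(f"admixture source {src!r} not simulated")
        mixed = ev.alpha * node_freq[ev.source_a] + (1 - ev.alpha) * node_freq[ev.source_b]
        node_freq[ev.target] = _balding_nichols(rng, mixed, ev.drift)

    names = list(node_freq)
    freqs = np.vstack([node_freq[n][order] for n in names])
    return FrequencyTable(panel, names, freqs)


def _quality_string(rng, n, q_high=37, q_low=20, low_fraction=0.1) -> np.ndarray:
    q = np.full(n, q_high + 33, dtype=np.uint8)
    q[rng.random(n) < low_fraction] = q_low + 33
    return q


def sample_genotypes(
    freqs: FrequencyTable,
    samples: list[SampleConfig],
    seed: int,
    q_high: int = 37,
    q_low: int = 20,
    low_quality_fraction: float = 0.1,
):
    """Draw individuals from the true frequencies.

    Diploid genotypes are Binomial(2, p); pseudohaploid calls Bernoulli(p);
    sites are dropped independently at each sample's ``missing_rate``.  For
    ``mode='pileup'`` samples, per-site depth is Poisson(``mean_depth``), each
    read's base is drawn from the individual's two alleles, and per-read
    quality strings are emitted (Q37 baseline with a low-quality fraction at
    Q20 to exercise quality filters); their matrix rows are left all-missing
    until a pseudohaploid caller fills them in.

    Returns ``(AlleleCountMatrix, {sample_id: pileup DataFrame})``.
    """
    rng = np.random.default_rng(seed)
    panel = freqs.panel
    n_sites = panel.n_sites
    rows_d, rows_t, meta_rows = [], [], []
    pileups: dict[str, pd.DataFrame] = {}

    for spec in samples:
        p = freqs.freq(spec.population)
        role = spec.role or ("ancient" if spec.mode != "diploid" else "modern")
        for i in range(spec.n_individuals):
            sid = f"{spec.population}_{i + 1}"
            present = rng.random(n_sites) >= spec.missing_rate
            if spec.mode == "diploid":
                g = rng.binomial(2, p)
                rows_d.append(np.where(present, g, 0))
                rows_t.append(np.where(present, 2, 0))
                meta_rows.append((sid, spec.population, role, "diploid"))
            elif spec.mode == "pseudohaploid":
                g = rng.binomial(1, p)
                rows_d.append(np.where(present, g, 0))
                rows_t.append(np.where(present, 1, 0))
                meta_rows.append((sid, spec.population, role, "pseudohaploid"))
            else:  # pileup
                geno = rng.binomial(2, p)
                depth = np.where(present, rng.poisson(spec.mean_depth, n_sites), 0)
                n_der = rng.binomial(depth, geno / 2.0)
                pileups[sid] = _build_pileup(
                    rng, panel, depth, n_der, q_high, q_low, low_quality_fraction
                )
                rows_d.append(np.zeros(n_sites, dtype=np.int32))
                rows_t.append(np.zeros(n_sites, dtype=np.int32))
                meta_rows.append((sid, spec.population, role, "pseudohaploid"))

    meta = make_sample_meta(
        [m[0] for m in meta_rows], [m[1] for m in meta_rows],
        roles=[m[2] for m in meta_rows], ploidies=[m[3] for m in meta_rows],
    )
    matrix = AlleleCountMatrix(np.array(rows_d), np.array(rows_t), meta)
    return matrix, pileups


def _build_pileup(rng, panel, depth, n_der, q_high, q_low, low_fraction):
    covered = depth > 0
    idx = np.flatnonzero(covered)
    total_reads = int(depth[idx].sum())
    # read bases: derived copies first within a site; the caller draws uniformly
    site_of_read = np.repeat(idx, depth[idx])
    offsets = np.zeros(len(idx) + 1, dtype=np.int64)
    np.cumsum(depth[idx], out=offsets[1:])
    within = np.arange(total_reads) - np.repeat(offsets[:-1], depth[idx])
    der_b = np.frombuffer("".join(panel.derived).encode(), dtype=np.uint8)
    ref_b = np.frombuffer("".join(panel.ref).encode(), dtype=np.uint8)
    bases = np.where(
        within < np.repeat(n_der[idx], depth[idx]),
        der_b[site_of_read], ref_b[site_of_read],
    ).astype(np.uint8)
    quals = _quality_string(rng, total_reads, q_high, q_low, low_fraction)
    base_strs, qual_strs = _split_strings(bases, quals, offsets)
    return pd.DataFrame({
        "chrom": panel.chrom[idx],
        "pos": panel.pos[idx],
        "ref": panel.ref[idx],
        "bases": base_strs,
        "quals": qual_strs,
    })


def _split_strings(bases: np.ndarray, quals: np.ndarray, offsets: np.ndarray):
    b = bases.tobytes().decode()
    q = quals.tobytes().decode()
    return (
        [b[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)],
        [q[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)],
    )


def apply_damage(
    pileup: pd.DataFrame, panel: SitePanel, delta: float, seed: int
) -> pd.DataFrame:
    """Deamination-like damage: flip read C->T and G->A at transition sites.

    Each read base at a transition-class panel site is flipped with
    probability ``delta``; transversion-class sites (and sites absent from the
    panel) are untouched.  Returns a new pileup; the input is not modified.
    """
    if not (0 <= delta <= 1):
        raise ValueError("delta must lie in [0,1]")
    if delta == 0 or len(pileup) == 0:
        return pileup.copy()
    rng = np.random.default_rng(seed)
    key = pd.MultiIndex.from_arrays(
        [pileup["chrom"].astype(str), pileup["pos"].astype(np.int64)]
    )
    site_idx = panel.site_key().get_indexer(key)
    is_tv = panel.is_transversion
    eligible_row = (site_idx >= 0) & ~np.where(site_idx >= 0, is_tv[site_idx], True)

    depths = pileup["bases"].str.len().to_numpy()
    bases = np.frombuffer("".join(pileup["bases"]).encode(), dtype=np.uint8).copy()
    row_of_read = np.repeat(np.arange(len(pileup)), depths)
    hit = (
        eligible_row[row_of_read]
        & np.isin(bases, (ord("C"), ord("G")))
        & (rng.random(bases.size) < delta)
    )
    bases[hit & (bases == ord("C"))] = ord("T")
    bases[hit & (bases == ord("G"))] = ord("A")
    offsets = np.zeros(len(pileup) + 1, dtype=np.int64)
    np.cumsum(depths, out=offsets[1:])
    joined = bases.tobytes().decode()
    out = pileup.copy()
    out["bases"] = [joined[offsets[i]:offsets[i + 1]] for i in range(len(pileup))]
    return out
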