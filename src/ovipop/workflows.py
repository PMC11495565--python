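"""Canned synthetic-study workflows.

These routines bundle the demographies and sampling designs that the
analysis drivers, the test suite and the acceptance script all share:
the five-population Baltic admixture model and its f4-ratio estimate,
null and calibration replicates for the D statistic, the damage-robustness
contrast, and the sexing replicates.  Each takes an explicit seed and is
fully deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simdata
from .auxcalls import rx_sex
from .fstats import BlockIndex, dstat, f4_ratio
from .geno_io import AlleleCountMatrix, pseudohaploidize
from .simdata import AdmixtureEvent, DemographyConfig, SampleConfig

__all__ = [
    "baltic_demography",
    "baltic_f4_ratio",
    "symmetric_null_dstats",
    "jackknife_calibration",
    "damage_robustness",
    "sexing_replicates",
    "sheep_like_chromosomes",
]

# The Baltic Neolithic genome's admixture proportion from a Kyrgyzstan
# Neolithic-related source, relative to a European Neolithic background.
BALTIC_ALPHA = 0.70


def baltic_demography(alpha: float = BALTIC_ALPHA, **kwargs) -> DemographyConfig:
    """Five sampled populations mirroring the Baltic admixture model.

    Goat is the outgroup; Iran_N and Kyrgyzstan_N descend from a shared
    Asian branch, Iberia_N from a European branch, and Baltic_N is an
    ``alpha`` : ``1 - alpha`` mixture of a Kyrgyzstan-related and a
    European source with residual drift of its own.  Per-branch drift values
    lie in [0.01, 0.05].
    """
    return DemographyConfig(
        populations=["Goat", "Iran_N", "Kyrgyzstan_N", "Iberia_N", "Baltic_N"],
        edges=[
            ("root", "Goat", 0.05),
            ("root", "Dom", 0.01),
            ("Dom", "Asian", 0.05),
            ("Asian", "Iran_N", 0.02),
            ("Asian", "KyrgyzAnc", 0.01),
            ("KyrgyzAnc", "Kyrgyzstan_N", 0.02),
            ("Dom", "Euro", 0.03),
            ("Euro", "EuroSrc", 0.01),
            ("Euro", "Iberia_N", 0.02),
        ],
        admixtures=[AdmixtureEvent("KyrgyzAnc", "EuroSrc", "Baltic_N", alpha, 0.02)],
        **kwargs,
    )


def baltic_f4_ratio(
    seed: int,
    n_sites: int = 200_000,
    alpha: float = BALTIC_ALPHA,
    missing_rate: float = 0.2,
    n_ancient: int = 8,
    n_outgroup: int = 4,
    blocksize: int = 1_000_000,
):
    """Simulate the Baltic model and estimate alpha by f4-ratio.

    Ancients are pseudohaploid with ``missing_rate`` missingness, the goat
    outgroup diploid.  Returns the FStatResult for
    alpha = f4(Iran_N, Goat; Baltic_N, Iberia_N) /
            f4(Iran_N, Goat; Kyrgyzstan_N, Iberia_N).
    """
    ss = np.random.SeedSequence(seed)
    s_freq, s_geno = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    config = baltic_demography(alpha)
    freqs = simdata.simulate_frequencies(config, n_sites, s_freq)
    samples = [
        SampleConfig("Goat", n_outgroup, mode="diploid", role="outgroup"),
        SampleConfig("Iran_N", n_ancient, "pseudohaploid", missing_rate),
        SampleConfig("Kyrgyzstan_N", n_ancient, "pseudohaploid", missing_rate),
        SampleConfig("Iberia_N", n_ancient, "pseudohaploid", missing_rate),
        SampleConfig("Baltic_N", n_ancient, "pseudohaploid", missing_rate),
    ]
    matrix, _ = simdata.sample_genotypes(freqs, samples, s_geno)
    blocks = BlockIndex.from_panel(freqs.panel, blocksize)
    return f4_ratio(
        matrix, "Iran_N", "Goat", "Baltic_N", "Kyrgyzstan_N", "Iberia_N", blocks
    )


def _null_demography(**kwargs) -> DemographyConfig:
    """Outgroup + X + a symmetric (P3, P4) sister pair: E[D(O, X; P3, P4)] = 0."""
    return DemographyConfig(
        populations=["O", "X", "P3", "P4"],
        edges=[
            ("root", "O", 0.05),
            ("root", "A", 0.02),
            ("A", "X", 0.03),
            ("A", "B", 0.03),
            ("B", "P3", 0.02),
            ("B", "P4", 0.02),
        ],
        **kwargs,
    )


def _replicate_dstats(seed, n_reps, n_sites, n_per_pop, missing_rate, config_fn):
    zs, ests, ses = [], [], []
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for child in children:
        s_freq, s_geno = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        config = config_fn()
        freqs = simdata.simulate_frequencies(config, n_sites, s_freq)
        samples = [
            SampleConfig(p, n_per_pop, "pseudohaploid", missing_rate)
            for p in config.populations
        ]
        matrix, _ = simdata.sample_genotypes(freqs, samples, s_geno)
        blocks = BlockIndex.from_panel(freqs.panel)
        res = dstat(matrix, *config.populations, blocks)
        zs.append(res.z)
        ests.append(res.estimate)
        ses.append(res.se)
    return np.array(ests), np.array(ses), np.array(zs)


def symmetric_null_dstats(
    seed: int, n_reps: int = 200, n_sites: int = 100_000,
    n_per_pop: int = 4, missing_rate: float = 0.1,
):
    """Replicate D(O, X; P3, P4) under a symmetric topology (true D = 0).

    Returns (estimates, jackknife SEs, Z scores); the fraction with
    |Z| >= 3 measures type-I calibration.  Sites sit on 50 one-megabase
    chromosomes so the default blocksize yields 50 jackknife blocks.
    """
    cfg = dict(n_chromosomes=50, chrom_length=1_000_000)
    return _replicate_dstats(
        seed, n_reps, n_sites, n_per_pop, missing_rate,
        lambda: _null_demography(**cfg),
    )


def jackknife_calibration(
    seed: int, n_reps: int = 200, n_sites: int = 100_000,
    n_per_pop: int = 4, missing_rate: float = 0.1,
):
    """Jackknife-SE calibration: mean reported SE over empirical SD of D.

    Returns ``(ratio, estimates, ses)`` across independent replicates of the
    symmetric demography (50 blocks of 1 Mb, pseudohaploid sampling).
    """
    ests, ses, _ = symmetric_null_dstats(
        seed, n_reps, n_sites, n_per_pop, missing_rate
    )
    return float(ses.mean() / ests.std(ddof=1)), ests, ses


def _damage_demography() -> DemographyConfig:
    # X shares the deep (A -> anc1) branch with the damaged population P3,
    # so a C->T/G->A shift in P3 leaks into D through that covariance.
    return DemographyConfig(
        populations=["O", "X", "P3", "P4"],
        edges=[
            ("root", "O", 0.05),
            ("root", "A", 0.02),
            ("A", "anc1", 0.10),
            ("anc1", "X", 0.02),
            ("anc1", "P3", 0.02),
            ("A", "P4", 0.02),
        ],
    )


def damage_robustness(
    seed: int,
    n_sites: int = 150_000,
    delta: float = 0.15,
    n_modern: int = 4,
    n_ancient: int = 6,
    mean_depth: float = 2.0,
):
    """Contrast D on clean vs deamination-damaged data.

    P3 is sequenced as damaged low-coverage pileups and pseudohaploidized;
    O, X, P4 are clean diploids.  Returns a dict with three FStatResults:
    ``all_clean``, ``all_damaged`` (biased at transition sites) and
    ``tv_damaged`` (transversions only, damage-immune).
    """
    ss = np.random.SeedSequence(seed)
    s_freq, s_geno, s_dmg, s_call = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    )
    config = _damage_demography()
    freqs = simdata.simulate_frequencies(config, n_sites, s_freq)
    panel = freqs.panel
    samples = [
        SampleConfig("O", n_modern, "diploid", role="outgroup"),
        SampleConfig("X", n_modern, "diploid"),
        SampleConfig("P4", n_modern, "diploid"),
        SampleConfig("P3", n_ancient, "pileup", mean_depth=mean_depth),
    ]
    matrix, pileups = simdata.sample_genotypes(freqs, samples, s_geno)
    blocks = BlockIndex.from_panel(panel)

    def called(pileup_set, call_seed):
        m = AlleleCountMatrix(
            matrix.derived.copy(), matrix.total.copy(), matrix.samples.copy()
        )
        rng = np.random.default_rng(call_seed)
        for sid, pl in pileup_set.items():
            unit, _ = pseudohaploidize(
                pl, panel, seed=int(rng.integers(2**31)), sample_id=sid
            )
            m.set_unit(sid, unit.derived[0], unit.total[0])
        return m

    clean = called(pileups, s_call)
    dmg_pileups = {
        sid: simdata.apply_damage(pl, panel, delta, s_dmg + i)
        for i, (sid, pl) in enumerate(pileups.items())
    }
    damaged = called(dmg_pileups, s_call)  # same caller seed isolates damage

    return {
        "all_clean": dstat(clean, "O", "X", "P3", "P4", blocks),
        "all_damaged": dstat(damaged, "O", "X", "P3", "P4", blocks),
        "tv_damaged": dstat(
            damaged, "O", "X", "P3", "P4", blocks, panel=panel,
            transversions_only=True,
        ),
    }


def sheep_like_chromosomes() -> pd.DataFrame:
    """26 autosomes spanning ~42-280 Mb plus a 135 Mb X, sheep-like sizes."""
    lengths = np.linspace(280e6, 42e6, 26).astype(np.int64)
    names = [str(i + 1) for i in range(26)] + ["X"]
    return pd.DataFrame(
        {"name": names, "length": list(lengths) + [135_000_000]}
    )


def sexing_replicates(
    seed: int,
    n_reps: int = 200,
    coverage: float = 0.02,
    read_length: int = 70,
    sex: str = "XY",
):
    """Simulate shotgun sexing at low coverage; returns the list of calls.

    Autosomal read counts are Poisson with density coverage/read_length; the
    X density is halved for XY individuals.
    """
    chroms = sheep_like_chromosomes()
    density = coverage / read_length
    x_factor = 0.5 if sex == "XY" else 1.0
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(n_reps):
        lam = chroms["length"].to_numpy() * density
        lam = np.where(chroms["name"] == "X", lam * x_factor, lam)
        cov = chroms.assign(reads=rng.poisson(lam))
        calls.append(rx_sex(cov, x_name="X").call)
    return calls
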