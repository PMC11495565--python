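"""Shared synthetic study cohort for the numbered analysis drivers.

One demography stands in for the real study design: a goat outgroup, a wild
mouflon ascertainment cohort, modern European and Asian breed pools, ancient
Anatolian and Iranian genomes sequenced as damaged low-coverage pileups, and
a Baltic ancient genome admixed 70:30 between the Asian and European
backgrounds.  The cohort is simulated once into scratch/ and reused by the
later drivers; delete scratch/cohort to regenerate.
"""

from pathlib import Path

import numpy as np

from ovipop import simdata, geno_io
from ovipop.simdata import AdmixtureEvent, DemographyConfig, SampleConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

STUDY_SEED = 20_260_929
N_SITES = 40_000
BALTIC_ALPHA = 0.70
DAMAGE_DELTA = 0.30          # per-read C->T/G->A rate at transition sites
ANCIENT_DEPTH = 2.0
ANCIENT_POPS = ("Anatolia_N", "Iran_N", "Baltic_N")


def study_demography() -> DemographyConfig:
    return DemographyConfig(
        populations=[
            "Goat", "WildMouflon", "Modern_EU", "Modern_AS",
            "Anatolia_N", "Iran_N", "Baltic_N",
        ],
        edges=[
            ("root", "Goat", 0.08),
            ("root", "Ovis", 0.02),
            ("Ovis", "WildMouflon", 0.04),
            ("Ovis", "Dom", 0.04),
            ("Dom", "West", 0.03),
            ("West", "Anatolia_N", 0.01),
            ("West", "EuroBg", 0.01),
            ("EuroBg", "Modern_EU", 0.03),
            ("Dom", "East", 0.03),
            ("East", "Iran_N", 0.01),
            ("East", "AsiaBg", 0.01),
            ("AsiaBg", "Modern_AS", 0.03),
        ],
        admixtures=[
            AdmixtureEvent("AsiaBg", "EuroBg", "Baltic_N", BALTIC_ALPHA, 0.02)
        ],
        n_chromosomes=26,
        chrom_length=2_000_000,
    )


def sample_plan() -> list[SampleConfig]:
    return [
        SampleConfig("Goat", 4, "diploid", role="outgroup"),
        SampleConfig("WildMouflon", 6, "diploid", role="modern"),
        SampleConfig("Modern_EU", 8, "diploid"),
        SampleConfig("Modern_AS", 8, "diploid"),
        SampleConfig("Anatolia_N", 5, "pileup", mean_depth=ANCIENT_DEPTH,
                     damage_rate=DAMAGE_DELTA),
        SampleConfig("Iran_N", 4, "pileup", mean_depth=ANCIENT_DEPTH,
                     damage_rate=DAMAGE_DELTA),
        SampleConfig("Baltic_N", 2, "pileup", mean_depth=ANCIENT_DEPTH,
                     damage_rate=DAMAGE_DELTA),
    ]


def build_cohort(seed: int = STUDY_SEED):
    """Simulate the cohort; returns (freqs, matrix, pileups)."""
    config = study_demography()
    freqs = simdata.simulate_frequencies(config, N_SITES, seed)
    matrix, pileups = simdata.sample_genotypes(freqs, sample_plan(), seed + 1)
    # ancient reads acquire post-mortem deamination before any calling
    for i, (sid, pl) in enumerate(sorted(pileups.items())):
        pileups[sid] = simdata.apply_damage(
            pl, freqs.panel, DAMAGE_DELTA, seed + 100 + i
        )
    return freqs, matrix, pileups


def write_cohort(freqs, matrix, pileups) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    geno_io.write_eigenstrat(str(SCRATCH / "raw"), freqs.panel, matrix)
    for sid, pl in pileups.items():
        geno_io.write_pileup(str(SCRATCH / f"{sid}.pileup"), pl)
    matrix.samples.to_csv(SCRATCH / "samples.tsv", sep="\t", index=False)


def load_cohort():
    """Read the simulated cohort back from scratch (building it if absent)."""
    import pandas as pd

    if not (SCRATCH / "raw.geno").exists():
        freqs, matrix, pileups = build_cohort()
        write_cohort(freqs, matrix, pileups)
    meta = pd.read_csv(SCRATCH / "samples.tsv", sep="\t")
    ploidies = dict(zip(meta["id"], meta["ploidy"]))
    roles = dict(zip(meta["id"], meta["role"]))
    panel, matrix, _ = geno_io.read_eigenstrat(
        str(SCRATCH / "raw"), roles=roles, ploidies=ploidies
    )
    matrix.samples["population"] = list(meta["population"])
    pileups = {
        sid: geno_io.read_pileup(str(SCRATCH / f"{sid}.pileup"))
        for sid, pl in ploidies.items()
        if (SCRATCH / f"{sid}.pileup").exists()
    }
    return panel, matrix, pileups


def called_cohort(panel, matrix, pileups, seed: int = STUDY_SEED + 500):
    """Pseudohaploidize the ancient pileups into the cohort matrix."""
    rng = np.random.default_rng(seed)
    for sid, pl in sorted(pileups.items()):
        unit, _ = geno_io.pseudohaploidize(
            pl, panel, seed=int(rng.integers(2**31)), sample_id=sid
        )
        matrix.set_unit(sid, unit.derived[0], unit.total[0])
    return matrix
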