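import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ovipop.geno_io import (
    AlleleCountMatrix,
    FormatError,
    SitePanel,
    ascertain_panel,
    hwe_exact_test,
    make_sample_meta,
    pseudohaploidize,
    read_eigenstrat,
    read_vcf,
    transversions_only,
    write_eigenstrat,
    write_vcf,
)

import oracles
from conftest import make_panel


def random_diploid_matrix(rng, n_units=5, n_sites=20, missing=0.1):
    codes = rng.integers(0, 3, size=(n_units, n_sites))
    miss = rng.random((n_units, n_sites)) < missing
    derived = np.where(miss, 0, codes).astype(np.int32)
    total = np.where(miss, 0, 2).astype(np.int32)
    meta = make_sample_meta(
        [f"s{i}" for i in range(n_units)], ["pop1"] * n_units
    )
    return AlleleCountMatrix(derived, total, meta)


class TestSitePanel:
    def test_sites_are_sorted_and_unique(self):
        df = pd.DataFrame({
            "chrom": ["2", "1", "1", "10"],
            "pos": [5, 9, 3, 1],
            "ref": list("ACGT"),
            "derived": list("CAAA"),
        })
        p = SitePanel(df)
        assert list(p.chrom) == ["1", "1", "2", "10"]  # numeric chrom order
        assert list(p.pos) == [3, 9, 5, 1]

    def test_duplicate_position_rejected(self):
        df = pd.DataFrame({
            "chrom": ["1", "1"], "pos": [7, 7], "ref": ["A", "C"],
            "derived": ["C", "G"],
        })
        with pytest.raises(ValueError, match="duplicate"):
            SitePanel(df)

    def test_transversion_classification(self):
        df = pd.DataFrame({
            "chrom": ["1"] * 4, "pos": [1, 2, 3, 4],
            "ref": ["C", "G", "A", "A"], "derived": ["T", "A", "T", "C"],
        })
        assert list(SitePanel(df).is_transversion) == [False, False, True, True]


class TestEigenstrat:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        panel = make_panel(20)
        matrix = random_diploid_matrix(rng)
        prefix = str(tmp_path / "ds")
        write_eigenstrat(prefix, panel, matrix)
        panel2, matrix2, _ = read_eigenstrat(prefix)
        assert np.array_equal(matrix.derived, matrix2.derived)
        assert np.array_equal(matrix.total, matrix2.total)
        assert panel2.sites.equals(panel.sites)

    def test_pseudohaploid_round_trip(self, tmp_path):
        panel = make_panel(6)
        meta = make_sample_meta(["a1"], ["anc"], ploidies=["pseudohaploid"])
        derived = np.array([[0, 1, 0, 1, 0, 0]], dtype=np.int32)
        total = np.array([[1, 1, 0, 1, 1, 0]], dtype=np.int32)
        matrix = AlleleCountMatrix(derived, total, meta)
        prefix = str(tmp_path / "ph")
        write_eigenstrat(prefix, panel, matrix)
        _, back, _ = read_eigenstrat(prefix, ploidies={"a1": "pseudohaploid"})
        assert np.array_equal(back.derived, derived)
        assert np.array_equal(back.total, total)

    def test_missing_code_maps_to_total_zero(self, tmp_path):
        panel = make_panel(1)
        prefix = str(tmp_path / "m")
        with open(f"{prefix}.snp", "w") as fh:
            fh.write("1_1\t1\t0.0\t1\tA\tC\n")
        with open(f"{prefix}.ind", "w") as fh:
            fh.write("s0\tU\tp\n")
        with open(f"{prefix}.geno", "w") as fh:
            fh.write("9\n")
        _, matrix, _ = read_eigenstrat(prefix)
        assert matrix.total[0, 0] == 0

    def test_bad_row_length_reports_line(self, tmp_path):
        prefix = str(tmp_path / "bad")
        with open(f"{prefix}.snp", "w") as fh:
            fh.write("1_1\t1\t0.0\t1\tA\tC\n1_2\t1\t0.0\t2\tA\tC\n")
        with open(f"{prefix}.ind", "w") as fh:
            fh.write("s0\tU\tp\ns1\tU\tp\n")
        with open(f"{prefix}.geno", "w") as fh:
            fh.write("02\n012\n")
        with pytest.raises(FormatError, match="line 2"):
            read_eigenstrat(prefix)


class TestVcf:
    def test_round_trip_with_panel(self, tmp_path):
        rng = np.random.default_rng(1)
        panel = make_panel(15)
        matrix = random_diploid_matrix(rng, n_units=4, n_sites=15)
        path = str(tmp_path / "a.vcf")
        write_vcf(path, panel, matrix)
        _, back, report = read_vcf(path, panel=panel)
        assert np.array_equal(back.derived, matrix.derived)
        assert np.array_equal(back.total, matrix.total)
        assert report["unmatched_alleles"] == 0

    def test_het_and_missing_genotypes(self, tmp_path):
        path = str(tmp_path / "b.vcf")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n")
            fh.write("1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t./.\n")
        panel = SitePanel(pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "derived": ["C"]}
        ))
        _, m, _ = read_vcf(path, panel=panel)
        assert (m.derived[0, 0], m.total[0, 0]) == (1, 2)
        assert m.total[1, 0] == 0

    def test_swapped_alleles_flip_to_panel_orientation(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        panel = SitePanel(pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "derived": ["C"]}
        ))
        straight = str(tmp_path / "s.vcf")
        flipped = str(tmp_path / "f.vcf")
        with open(straight, "w") as fh:
            fh.write(header + "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\n")
        with open(flipped, "w") as fh:
            fh.write(header + "1\t100\t.\tC\tA\t.\tPASS\t.\tGT\t0/0\n")
        _, m1, _ = read_vcf(straight, panel=panel)
        _, m2, _ = read_vcf(flipped, panel=panel)
        assert m1.derived[0, 0] == m2.derived[0, 0] == 2

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        path = str(tmp_path / "c.vcf")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
            fh.write("1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT\t1/2\n")
            fh.write("1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\n")
        _, m, report = read_vcf(path)
        assert report["multiallelic"] == 1
        assert m.n_sites == 1


def _pileup_df(records):
    return pd.DataFrame(records, columns=["chrom", "pos", "ref", "bases", "quals"])


class TestPseudohaploidize:
    def test_single_derived_read_called(self):
        panel = make_panel(1)
        pl = _pileup_df([("1", 1, "A", "C", "F")])  # Q37
        m, _ = pseudohaploidize(pl, panel, seed=0)
        assert (m.derived[0, 0], m.total[0, 0]) == (1, 1)

    def test_low_quality_reads_ignored(self):
        panel = make_panel(1)
        pl = _pileup_df([("1", 1, "A", "CC", "55")])  # Q20 < 30
        m, _ = pseudohaploidize(pl, panel, seed=0)
        assert m.total[0, 0] == 0

    def test_non_panel_alleles_discarded(self):
        panel = make_panel(1)  # A/C site
        pl = _pileup_df([("1", 1, "A", "GT", "FF")])
        m, _ = pseudohaploidize(pl, panel, seed=0)
        assert m.total[0, 0] == 0

    def test_off_panel_sites_counted_not_fatal(self):
        panel = make_panel(1)
        pl = _pileup_df([("1", 1, "A", "A", "F"), ("1", 999999, "A", "A", "F")])
        m, report = pseudohaploidize(pl, panel, seed=0)
        assert report["off_panel_sites"] == 1
        assert m.total.sum() == 1

    def test_draw_is_unbiased(self):
        # 10,000 sites, each with 7 derived / 3 ancestral reads at Q37:
        # the haploid call should be derived ~70% of the time
        n = 10_000
        panel = make_panel(n)
        pl = _pileup_df([
            ("1", 1 + i * 1000, "A", "CCCCCCCAAA", "FFFFFFFFFF") for i in range(n)
        ])
        m, _ = pseudohaploidize(pl, panel, seed=1)
        frac = m.derived[0].sum() / m.total[0].sum()
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 3 * se

    def test_deterministic_given_seed(self):
        n = 200
        panel = make_panel(n)
        pl = _pileup_df([
            ("1", 1 + i * 1000, "A", "CA", "FF") for i in range(n)
        ])
        a, _ = pseudohaploidize(pl, panel, seed=9)
        b, _ = pseudohaploidize(pl, panel, seed=9)
        assert np.array_equal(a.derived, b.derived)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [
        (0, 2, 0), (25, 50, 25), (5, 1, 5), (3, 0, 3), (10, 5, 1), (0, 9, 1),
    ])
    def test_matches_full_enumeration(self, counts):
        expected = oracles.hwe_exact_enumeration(*counts)
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_agrees_with_oracle_everywhere(self, naa, nab, nbb):
        if naa + nab + nbb == 0:
            return
        assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
            oracles.hwe_exact_enumeration(naa, nab, nbb), abs=1e-10
        )

    def test_zero_genotypes_warns(self):
        with pytest.warns(UserWarning):
            assert hwe_exact_test(0, 0, 0) == 1.0


class TestAscertainPanel:
    @pytest.fixture()
    def toy(self):
        # 10 sites x 6 diploid samples with structure exercising every filter
        rng = np.random.default_rng(7)
        panel = SitePanel(pd.DataFrame({
            "chrom": ["1"] * 10,
            "pos": [100, 103, 200, 300, 400, 500, 600, 700, 800, 802],
            "ref": ["A"] * 10,
            "derived": ["C"] * 10,
        }))
        codes = rng.integers(0, 3, size=(6, 10))
        codes[:, 2] = [0, 0, 0, 0, 0, 1]      # MAF 1/12 < 0.05? = 0.083 (kept)
        codes[:, 3] = [0, 0, 0, 0, 0, 0]      # monomorphic -> MAF 0
        codes[:, 4] = [2, 2, 2, 0, 0, 0]      # heterozygote deficit -> HWE
        total = np.full((6, 10), 2, dtype=np.int32)
        total[0, 5:] = 0                       # sample 0: 50% missing -> dropped
        total[1:, 6] = 0                       # site 6 missing in cohort
        meta = make_sample_meta([f"s{i}" for i in range(6)], ["wild"] * 6)
        return panel, AlleleCountMatrix(np.where(total > 0, codes, 0), total, meta)

    def test_matches_bruteforce_oracle(self, toy):
        panel, matrix = toy
        fp, fm, report = ascertain_panel(matrix, panel)
        kept, samples = oracles.brute_ascertain(
            matrix.derived, matrix.total, panel.chrom, panel.pos
        )
        assert list(fp.pos) == [int(panel.pos[s]) for s in kept]
        assert list(fm.samples["id"]) == [f"s{u}" for u in samples]

    def test_idempotent(self, toy):
        panel, matrix = toy
        fp, fm, _ = ascertain_panel(matrix, panel)
        fp2, fm2, report2 = ascertain_panel(fm, fp)
        assert fp2.sites.equals(fp.sites)
        assert np.array_equal(fm2.derived, fm.derived)
        assert report2["spacing_removed"] == 0

    def test_low_maf_site_removed(self):
        panel = make_panel(2)
        # site 0: MAF 1/50 = 0.02 -> removed; site 1: MAF 0.5 -> kept
        derived = np.tile([0, 1], (25, 1)).astype(np.int32)
        derived[0, 0] = 1
        total = np.full((25, 2), 2, dtype=np.int32)
        meta = make_sample_meta([f"s{i}" for i in range(25)], ["w"] * 25)
        m = AlleleCountMatrix(derived, total, meta)
        fp, _, report = ascertain_panel(m, panel, hwe_min=0.0)
        assert report["maf_removed"] == 1
        assert list(fp.pos) == [1001]  # only the second site survives

    def test_close_pair_thinned_keep_first(self):
        panel = SitePanel(pd.DataFrame({
            "chrom": ["1", "1"], "pos": [100, 103],
            "ref": ["A", "A"], "derived": ["C", "C"],
        }))
        derived = np.tile([1, 1], (6, 1)).astype(np.int32)
        total = np.full((6, 2), 2, dtype=np.int32)
        meta = make_sample_meta([f"s{i}" for i in range(6)], ["w"] * 6)
        fp, _, report = ascertain_panel(
            AlleleCountMatrix(derived, total, meta), panel
        )
        assert list(fp.pos) == [100]
        assert report["spacing_removed"] == 1

    def test_no_survivors_is_error(self):
        panel = make_panel(1)
        derived = np.zeros((6, 1), dtype=np.int32)
        total = np.full((6, 1), 2, dtype=np.int32)
        meta = make_sample_meta([f"s{i}" for i in range(6)], ["w"] * 6)
        with pytest.raises(ValueError, match="no sites survive"):
            ascertain_panel(AlleleCountMatrix(derived, total, meta), panel)


class TestTransversionsOnly:
    def test_transition_site_removed_transversion_kept(self):
        panel = SitePanel(pd.DataFrame({
            "chrom": ["1", "1"], "pos": [1, 2],
            "ref": ["C", "A"], "derived": ["T", "T"],
        }))
        m = random_diploid_matrix(np.random.default_rng(3), n_units=2, n_sites=2)
        fp, fm = transversions_only(panel, m)
        assert list(fp.pos) == [2]
        assert fm.n_sites == 1

    def test_survivor_count_matches_set_oracle(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        ref = bases[rng.integers(0, 4, 50)]
        der = np.array([
            rng.choice([b for b in "ACGT" if b != r]) for r in ref
        ])
        panel = SitePanel(pd.DataFrame({
            "chrom": ["1"] * 50, "pos": np.arange(1, 51) * 10,
            "ref": ref, "derived": der,
        }))
        m = random_diploid_matrix(rng, n_units=2, n_sites=50)
        fp, _ = transversions_only(panel, m)
        expected = sum(
            1 for r, d in zip(panel.ref, panel.derived)
            if {r, d} not in ({"C", "T"}, {"A", "G"})
        )
        assert fp.n_sites == expected
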