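"""PLINK/VCF reading, allele harmonization and the no-imputation contract."""

import numpy as np
import pandas as pd
import pytest

from barypop.genotype_io import (
    EmptyCohortError,
    GenotypeSet,
    harmonize_to_panel,
    load_plink_cohort,
    mask_high_missingness_snps,
    read_vcf,
    write_plink_cohort,
)
from barypop.plink import PlinkFormatError, read_plink, write_plink
from barypop.simulate import apply_missingness, simulate_panel, simulate_subjects

from conftest import make_panel


def three_snp_panel():
    panel = make_panel([[0.5] * 5] * 3, [[0.5] * 3] * 3)
    panel.table["ref"] = ["A", "A", "A"]
    panel.table["alt"] = ["G", "G", "T"]  # rs2 is strand-ambiguous (A/T)
    return panel


def variants_df(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2"])


class TestPlinkCodec:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        n, s = 7, 13  # n not a multiple of 4 exercises byte padding
        g = rng.integers(-1, 3, size=(n, s)).astype(np.int8)
        variants = variants_df(
            [(f"v{k}", "1", 100 + k, "A", "G") for k in range(s)]
        )
        write_plink(tmp_path / "x", [f"s{i}" for i in range(n)], variants, g)
        var2, samples, g2 = read_plink(tmp_path / "x")
        np.testing.assert_array_equal(g2, g)
        assert list(var2["snp_id"]) == list(variants["snp_id"])
        assert list(samples["iid"]) == [f"s{i}" for i in range(n)]

    def test_missing_call_preserved_and_s_prime(self, tmp_path):
        panel = three_snp_panel()
        g = np.array([[0, 1, 2], [2, -1, 0]], dtype=np.int8)
        gs = GenotypeSet(["a", "b"], panel.snp_ids, g)
        write_plink_cohort(gs, panel, tmp_path / "c")
        gs2, report = load_plink_cohort(tmp_path / "c", panel, drop_ambiguous=False)
        np.testing.assert_array_equal(gs2.genotypes, g)
        np.testing.assert_array_equal(gs2.s_prime, [3, 2])
        assert report.n_dropped_unmatched == 0

    def test_bad_magic_rejected(self, tmp_path):
        panel = three_snp_panel()
        gs = GenotypeSet(["a"], panel.snp_ids, np.zeros((1, 3), dtype=np.int8))
        write_plink_cohort(gs, panel, tmp_path / "c")
        bed = tmp_path / "c.bed"
        bed.write_bytes(b"\x00\x00" + bed.read_bytes()[2:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(tmp_path / "c")

    def test_size_mismatch_rejected(self, tmp_path):
        panel = three_snp_panel()
        gs = GenotypeSet(["a", "b"], panel.snp_ids, np.zeros((2, 3), dtype=np.int8))
        write_plink_cohort(gs, panel, tmp_path / "c")
        bed = tmp_path / "c.bed"
        bed.write_bytes(bed.read_bytes() + b"\x00")
        with pytest.raises(PlinkFormatError, match="size"):
            read_plink(tmp_path / "c")

    def test_empty_fam_rejected(self, tmp_path):
        panel = three_snp_panel()
        gs = GenotypeSet(["a"], panel.snp_ids, np.zeros((1, 3), dtype=np.int8))
        write_plink_cohort(gs, panel, tmp_path / "c")
        (tmp_path / "c.fam").write_text("")
        with pytest.raises((PlinkFormatError, EmptyCohortError, pd.errors.EmptyDataError)):
            read_plink(tmp_path / "c")


class TestHarmonization:
    def test_exact_match_kept(self):
        panel = three_snp_panel()
        variants = variants_df([("rs0", "1", 1000, "A", "G")])
        g = np.array([[2], [1]], dtype=np.int8)
        gs, rep = harmonize_to_panel(variants, g, ["a", "b"], panel)
        assert rep.n_matched == 1
        np.testing.assert_array_equal(gs.genotypes[:, 0], [2, 1])
        # panel SNPs absent from the input stay missing for everyone
        assert (gs.genotypes[:, 1:] == -1).all()

    def test_allele_order_swap_complements(self):
        panel = three_snp_panel()
        variants = variants_df([("rs0", "1", 1000, "G", "A")])
        g = np.array([[0], [2], [-1]], dtype=np.int8)
        gs, rep = harmonize_to_panel(variants, g, ["a", "b", "c"], panel)
        assert rep.n_flipped == 1
        np.testing.assert_array_equal(gs.genotypes[:, 0], [2, 0, -1])

    def test_strand_flip_resolved(self):
        panel = three_snp_panel()  # rs1: ref=A alt=G
        variants = variants_df([("rs1", "1", 2000, "T", "C")])  # complement of A, G
        g = np.array([[1]], dtype=np.int8)
        gs, rep = harmonize_to_panel(variants, g, ["a"], panel)
        assert rep.n_strand_flipped == 1
        assert gs.genotypes[0, 1] == 1

    def test_ambiguous_dropped_by_default(self):
        panel = three_snp_panel()  # rs2: ref=A alt=T
        variants = variants_df([("rs2", "1", 3000, "A", "T")])
        g = np.array([[2]], dtype=np.int8)
        gs, rep = harmonize_to_panel(variants, g, ["a"], panel)
        assert rep.n_dropped_ambiguous == 1
        assert gs.genotypes[0, 2] == -1
        gs2, rep2 = harmonize_to_panel(variants, g, ["a"], panel, drop_ambiguous=False)
        assert rep2.n_matched == 1
        assert gs2.genotypes[0, 2] == 2

    def test_unmatched_counted(self):
        panel = three_snp_panel()
        variants = variants_df(
            [("rsX", "1", 9000, "A", "G"), ("rs0", "1", 1000, "A", "C")]
        )
        g = np.zeros((1, 2), dtype=np.int8)
        _, rep = harmonize_to_panel(variants, g, ["a"], panel)
        assert rep.n_dropped_unmatched == 2  # unknown id + irreconcilable alleles

    def test_position_fallback(self):
        panel = three_snp_panel()
        variants = variants_df([("othername", "1", 2000, "A", "G")])
        g = np.array([[1]], dtype=np.int8)
        gs, rep = harmonize_to_panel(
            variants, g, ["a"], panel, position_fallback=True
        )
        assert rep.n_matched == 1
        assert gs.genotypes[0, 1] == 1

    def test_never_imputes(self):
        """Harmonization may drop variants but never turns missing into a call."""
        panel = simulate_panel(n_snps=100, seed=3)
        gs = simulate_subjects(panel, [(10, (1.0, 0.0, 0.0))], seed=4)
        gs = apply_missingness(gs, mode="mcar", rate=0.4, seed=5)
        variants = variants_df(
            list(
                zip(
                    panel.snp_ids,
                    panel.table["chrom"],
                    panel.table["pos"],
                    panel.table["ref"],
                    panel.table["alt"],
                )
            )
        )
        out, _ = harmonize_to_panel(variants, gs.genotypes, gs.subject_ids, panel)
        np.testing.assert_array_equal(out.genotypes == -1, gs.genotypes == -1)


class TestVcf:
    def _write_vcf(self, path, records, samples=("s1", "s2")):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        body = "".join(
            "\t".join(map(str, rec)) + "\n" for rec in records
        )
        path.write_text(header + body)

    def test_gt_parsing(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        self._write_vcf(
            vcf,
            [
                ("1", 1000, "rs0", "A", "G", ".", ".", ".", "GT", "0/1", "./."),
                ("1", 2000, "rs1", "A", "G", ".", ".", ".", "GT", "1/1", "0|0"),
            ],
        )
        variants, g, _ = read_vcf(vcf)
        assert list(variants["snp_id"]) == ["rs0", "rs1"]
        # REF-allele counts: 0/1 -> 1; ./. -> missing; 1/1 -> 0; 0|0 -> 2
        np.testing.assert_array_equal(g, [[1, 0], [-1, 2]])

    def test_vcf_ref_equals_panel_alt_flips(self, tmp_path):
        panel = three_snp_panel()  # rs0: ref=A alt=G
        vcf = tmp_path / "t.vcf"
        self._write_vcf(
            vcf, [("1", 1000, "rs0", "G", "A", ".", ".", ".", "GT", "1/1", "0/0")]
        )
        variants, g, _ = read_vcf(vcf)
        gs, rep = harmonize_to_panel(variants, g, variants.attrs["subject_ids"], panel)
        assert rep.n_flipped == 1
        # 1/1 means two A alleles = two panel refs -> g = 2
        np.testing.assert_array_equal(gs.genotypes[:, 0], [2, 0])

    def test_multiallelic_skipped(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        self._write_vcf(
            vcf, [("1", 1000, "rs0", "A", "G,T", ".", ".", ".", "GT", "0/1", "0/2")]
        )
        variants, g, _ = read_vcf(vcf)
        assert len(variants) == 0


class TestMissingnessFilter:
    def test_high_missingness_snps_masked(self):
        panel = three_snp_panel()
        g = np.array([[0, -1, 2], [1, -1, -1], [2, -1, 0]], dtype=np.int8)
        gs = GenotypeSet(["a", "b", "c"], panel.snp_ids, g)
        out = mask_high_missingness_snps(gs, max_rate=0.5)
        assert (out.genotypes[:, 1] == -1).all()  # 100% missing -> masked
        np.testing.assert_array_equal(out.genotypes[:, 0], g[:, 0])
        np.testing.assert_array_equal(out.genotypes[:, 2], g[:, 2])  # 1/3 <= 0.5 kept
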