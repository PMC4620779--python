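"""Panel, genotype and phenotype IO: validation, round-trips, allele bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from grstrata.errors import (
    AlleleMismatchError,
    PanelFormatError,
    PanelValidationError,
    PhenotypeValidationError,
)
from grstrata.io import (
    read_genotypes_csv,
    read_genotypes_vcf,
    read_phenotypes,
    write_genotypes_csv,
    write_genotypes_vcf,
    write_phenotypes,
)
from grstrata.panel import SnpPanel, SnpWeight, bundled_panel, read_panel, write_panel


def _panel_csv(tmp_path, rows, name="panel.csv"):
    header = "rsid,chrom,pos,risk_allele,other_allele,allelic_or,risk_allele_freq"
    path = tmp_path / name
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestPanelIO:
    def test_read_valid_panel_preserves_rows(self, tmp_path):
        rows = [f"rs{i},1,{1000+i},A,G,1.2,0.4" for i in range(7)]
        panel = read_panel(_panel_csv(tmp_path, rows), name="east-asian-7")
        assert panel.name == "east-asian-7"
        assert len(panel) == 7

    @pytest.mark.parametrize(
        "row,err_match",
        [
            ("rsBAD,1,100,A,G,0.0,0.4", "rsBAD"),  # OR <= 0
            ("rsBAD,1,100,A,G,1.2,1.4", "rsBAD"),  # freq outside (0,1)
            ("rsBAD,1,100,A,A,1.2,0.4", "rsBAD"),  # identical alleles
        ],
    )
    def test_invalid_rows_name_the_rsid(self, tmp_path, row, err_match):
        with pytest.raises(PanelValidationError, match=err_match):
            read_panel(_panel_csv(tmp_path, ["rs1,1,100,A,G,1.2,0.4", row]))

    def test_duplicate_rsid_rejected(self, tmp_path):
        rows = ["rs1,1,100,A,G,1.2,0.4", "rs1,2,200,C,T,1.3,0.5"]
        with pytest.raises(PanelValidationError, match="rs1"):
            read_panel(_panel_csv(tmp_path, rows))

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("rsid,chrom,pos,risk_allele,other_allele,allelic_or\nrs1,1,1,A,G,1.2\n")
        with pytest.raises(PanelFormatError, match="risk_allele_freq"):
            read_panel(path)

    def test_strand_ambiguous_snp_warned(self, tmp_path):
        with pytest.warns(UserWarning, match="strand-ambiguous"):
            read_panel(_panel_csv(tmp_path, ["rs1,1,100,A,T,1.2,0.4"]))

    def test_round_trip(self, tmp_path, tiny_panel):
        write_panel(tiny_panel, tmp_path / "out.csv")
        back = read_panel(tmp_path / "out.csv", name=tiny_panel.name)
        assert back == tiny_panel

    def test_bundled_panels(self):
        overall = bundled_panel("overall")
        ea = bundled_panel("east-asian")
        assert len(overall) == 24
        assert len(ea) == 7
        assert set(ea.rsids) <= set(overall.rsids)


class TestGenotypeCsv:
    def test_round_trip_with_missing(self, tmp_path, tiny_panel):
        g = pd.DataFrame(
            {"S1": [0.0, 1.0, 2.0], "S2": [np.nan, 2.0, 0.0]},
            index=pd.Index(tiny_panel.rsids, name="rsid"),
        )
        write_genotypes_csv(g, tmp_path / "g.csv")
        back = read_genotypes_csv(tmp_path / "g.csv")
        pd.testing.assert_frame_equal(back, g)

    def test_counts_outside_range_rejected(self, tmp_path):
        (tmp_path / "g.csv").write_text("rsid,S1\nrs1,3\n")
        with pytest.raises(PanelFormatError, match="rs1"):
            read_genotypes_csv(tmp_path / "g.csv")


class TestGenotypeVcf:
    def test_vcf_round_trip_recovers_matrix(self, tmp_path, tiny_panel):
        rng = np.random.default_rng(5)
        g = pd.DataFrame(
            rng.integers(0, 3, size=(3, 8)).astype(float),
            index=pd.Index(tiny_panel.rsids, name="rsid"),
            columns=[f"S{i}" for i in range(8)],
        )
        g.iloc[0, 0] = np.nan
        write_genotypes_vcf(g, tiny_panel, tmp_path / "g.vcf")
        back = read_genotypes_vcf(tmp_path / "g.vcf", tiny_panel)
        pd.testing.assert_frame_equal(back, g)

    def test_ref_risk_orientation_complemented(self, tmp_path, one_snp_panel):
        # REF = risk allele A, ALT = other allele G: GT 1/1 means 0 risk copies
        vcf = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\n"
        )
        (tmp_path / "g.vcf").write_text(vcf)
        back = read_genotypes_vcf(tmp_path / "g.vcf", one_snp_panel)
        assert back.loc["rs1", "S1"] == 0.0
        assert back.loc["rs1", "S2"] == 1.0

    def test_allele_orientation_invariance(self, tmp_path, tiny_panel):
        """Swapping REF/ALT and complementing the genotypes in the VCF leaves
        the returned risk-allele counts unchanged."""
        rng = np.random.default_rng(6)
        g = pd.DataFrame(
            rng.integers(0, 3, size=(3, 5)).astype(float),
            index=pd.Index(tiny_panel.rsids, name="rsid"),
            columns=[f"S{i}" for i in range(5)],
        )
        write_genotypes_vcf(g, tiny_panel, tmp_path / "a.vcf")
        flipped = SnpPanel(
            "flip",
            tuple(
                SnpWeight(s.rsid, s.chrom, s.pos, s.other_allele, s.risk_allele,
                          s.allelic_or, s.risk_allele_freq)
                for s in tiny_panel
            ),
        )
        write_genotypes_vcf(2.0 - g, flipped, tmp_path / "b.vcf")
        a = read_genotypes_vcf(tmp_path / "a.vcf", tiny_panel)
        b = read_genotypes_vcf(tmp_path / "b.vcf", tiny_panel)
        pd.testing.assert_frame_equal(a, b)

    def test_allele_mismatch_raises(self, tmp_path, one_snp_panel):
        vcf = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        (tmp_path / "g.vcf").write_text(vcf)
        with pytest.raises(AlleleMismatchError, match="rs1"):
            read_genotypes_vcf(tmp_path / "g.vcf", one_snp_panel)

    def test_absent_site_missing_for_all(self, tmp_path, tiny_panel, caplog):
        sub = SnpPanel("sub", tiny_panel.snps[:2])
        g = pd.DataFrame(
            {"S1": [1.0, 2.0]}, index=pd.Index(sub.rsids, name="rsid")
        )
        write_genotypes_vcf(g, sub, tmp_path / "g.vcf")
        back = read_genotypes_vcf(tmp_path / "g.vcf", tiny_panel)
        assert back.loc["rs3"].isna().all()
        assert any("rs3" in r.getMessage() for r in caplog.records)

    def test_located_by_position_when_id_differs(self, tmp_path, one_snp_panel):
        vcf = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
        )
        (tmp_path / "g.vcf").write_text(vcf)
        back = read_genotypes_vcf(tmp_path / "g.vcf", one_snp_panel)
        assert back.loc["rs1", "S1"] == 1.0


def _pheno_frame(n=10):
    rng = np.random.default_rng(1)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.normal(67, 8, n).round(1),
            "bmi": rng.normal(24, 3, n).round(2),
            "psa": np.exp(rng.normal(2.3, 0.9, n)).round(3),
            "prostate_volume": rng.normal(45, 18, n).clip(10).round(1),
            "dre_abnormal": pd.array(rng.random(n) < 0.25, dtype="boolean"),
            "family_history": pd.array(rng.random(n) < 0.03, dtype="boolean"),
            "smoking": pd.array(rng.random(n) < 0.45, dtype="boolean"),
            "drinking": pd.array(rng.random(n) < 0.3, dtype="boolean"),
            "hypertension": pd.array(rng.random(n) < 0.3, dtype="boolean"),
            "diabetes": pd.array(rng.random(n) < 0.12, dtype="boolean"),
            "pca": pd.array(rng.random(n) < 0.43, dtype="boolean"),
            "high_grade": pd.array([False] * n, dtype="boolean"),
        }
    )


class TestPhenotypes:
    def test_well_formed_round_trip(self, tmp_path):
        ph = _pheno_frame(10)
        ph.loc[~ph["pca"].astype(bool), "high_grade"] = pd.NA
        write_phenotypes(ph, tmp_path / "ph.csv")
        back = read_phenotypes(tmp_path / "ph.csv")
        assert len(back) == 10
        pd.testing.assert_frame_equal(back, ph)

    def test_boolean_spellings_accepted(self, tmp_path):
        ph = _pheno_frame(2)
        write_phenotypes(ph, tmp_path / "ph.csv")
        text = (tmp_path / "ph.csv").read_text()
        text = text.replace("S0,", "S0,", 1)
        lines = text.splitlines()
        # rewrite the boolean block of row S0 with mixed spellings
        parts = lines[1].split(",")
        parts[5:13] = ["Yes", "NO", "true", "False", "1", "0", "YES", ""]
        lines[1] = ",".join(parts)
        (tmp_path / "ph2.csv").write_text("\n".join(lines) + "\n")
        back = read_phenotypes(tmp_path / "ph2.csv")
        assert back.loc[0, "dre_abnormal"] == True  # noqa: E712
        assert back.loc[0, "family_history"] == False  # noqa: E712
        assert back.loc[0, "pca"] == True  # noqa: E712
        assert pd.isna(back.loc[0, "high_grade"])

    def test_nonpositive_psa_names_subject(self, tmp_path):
        ph = _pheno_frame(3)
        ph.loc[1, "psa"] = -1.0
        write_phenotypes(ph, tmp_path / "ph.csv")
        with pytest.raises(PhenotypeValidationError, match="S1"):
            read_phenotypes(tmp_path / "ph.csv")

    def test_high_grade_without_pca_inconsistent(self, tmp_path):
        ph = _pheno_frame(3)
        ph.loc[2, "pca"] = False
        ph.loc[2, "high_grade"] = True
        write_phenotypes(ph, tmp_path / "ph.csv")
        with pytest.raises(PhenotypeValidationError, match="S2"):
            read_phenotypes(tmp_path / "ph.csv")

    def test_missing_column_named(self, tmp_path):
        ph = _pheno_frame(3).drop(columns=["bmi"])
        ph.to_csv(tmp_path / "ph.csv", index=False)
        with pytest.raises(PanelFormatError, match="bmi"):
            read_phenotypes(tmp_path / "ph.csv")
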