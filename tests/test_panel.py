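"""Panel definition, genotype normalization, and file I/O tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eightplex.panel import (
    EYE_SNPS,
    SKIN_SNPS,
    GenotypeCall,
    PanelValidationError,
    PhenotypeRecord,
    SampleGenotypes,
    StrandFlipWarning,
    VcfParseError,
    get_snp,
    normalize_genotype,
    panel,
    panel_rsids,
    read_genotype_table,
    read_phenotype_table,
    read_vcf,
    write_genotype_table,
)

from conftest import make_sample


class TestPanelDefinition:
    def test_eight_snps(self):
        assert len(panel()) == 8
        assert len({s.rsid for s in panel()}) == 8

    def test_trait_assignment_sets(self):
        assert set(EYE_SNPS) == {
            "rs12913832", "rs16891982", "rs6119471", "rs12203592", "rs12896399",
        }
        assert set(SKIN_SNPS) == {
            "rs12913832", "rs16891982", "rs6119471", "rs1426654", "rs885479",
            "rs1545397",
        }
        assert set(EYE_SNPS) & set(SKIN_SNPS) == {
            "rs12913832", "rs16891982", "rs6119471",
        }
        assert set(EYE_SNPS) | set(SKIN_SNPS) == set(panel_rsids())

    def test_specific_assignments(self):
        assert get_snp("rs12896399").used_for_eye
        assert not get_snp("rs12896399").used_for_skin
        assert get_snp("rs1426654").used_for_skin
        assert not get_snp("rs1426654").used_for_eye

    def test_strand_ambiguity_flags(self):
        ambiguous = {s.rsid for s in panel() if s.strand_ambiguous}
        assert ambiguous == {"rs16891982", "rs1545397", "rs6119471"}

    def test_allele_pairs_valid(self):
        for s in panel():
            a, b = s.alleles
            assert a != b
            assert {a, b} <= set("ACGT")

    def test_unknown_rsid(self):
        with pytest.raises(PanelValidationError):
            get_snp("rs0")


class TestNormalizeGenotype:
    def test_accept_in_panel(self):
        call = normalize_genotype(("G", "A"), get_snp("rs12913832"))
        assert call.alleles == ("A", "G")

    def test_complement_flip_with_warning(self):
        with pytest.warns(StrandFlipWarning):
            call = normalize_genotype(("T", "C"), get_snp("rs12913832"))
        assert call.alleles == ("A", "G")

    def test_ambiguous_never_flipped(self):
        call = normalize_genotype(("C", "G"), get_snp("rs16891982"))
        assert call.alleles == ("C", "G")

    def test_irreconcilable(self):
        with pytest.raises(PanelValidationError, match="rs12913832"):
            normalize_genotype(("A", "C"), get_snp("rs12913832"))

    def test_invalid_token(self):
        with pytest.raises(PanelValidationError):
            normalize_genotype(("A", "N"), get_snp("rs12913832"))

    @given(st.sampled_from(panel_rsids()), st.data())
    def test_idempotent(self, rsid, data):
        snp = get_snp(rsid)
        raw = (
            data.draw(st.sampled_from(snp.alleles)),
            data.draw(st.sampled_from(snp.alleles)),
        )
        once = normalize_genotype(raw, snp)
        twice = normalize_genotype(once.alleles, snp)
        assert once == twice


def _random_cohort_strategy():
    def genotype_for(rsid):
        a, b = get_snp(rsid).alleles
        return st.sampled_from([None, (a, a), (a, b), (b, b)])

    def build(draw_values):
        samples = []
        for i, calls in enumerate(draw_values):
            s = SampleGenotypes(sample_id=f"H{i}")
            for rsid, gt in zip(panel_rsids(), calls):
                s.calls[rsid] = GenotypeCall(rsid, gt)
            samples.append(s)
        return samples

    row = st.tuples(*[genotype_for(r) for r in panel_rsids()])
    return st.lists(row, min_size=1, max_size=8).map(build)


class TestGenotypeTable:
    def test_round_trip_simple(self, tmp_path):
        samples = [
            make_sample({"rs12913832": "AG", "rs16891982": "CC"}, "A"),
            make_sample({}, "B"),
        ]
        path = tmp_path / "g.tsv"
        write_genotype_table(samples, path)
        back = read_genotype_table(path)
        assert [s.sample_id for s in back] == ["A", "B"]
        assert back[0].genotype("rs12913832") == ("A", "G")
        assert back[1].genotype("rs12913832") is None

    @settings(max_examples=25, deadline=None)
    @given(cohort=_random_cohort_strategy())
    def test_round_trip_property(self, tmp_path_factory, cohort):
        path = tmp_path_factory.mktemp("rt") / "g.tsv"
        write_genotype_table(cohort, path)
        back = read_genotype_table(path)
        assert len(back) == len(cohort)
        for orig, new in zip(cohort, back):
            assert orig.sample_id == new.sample_id
            for rsid in panel_rsids():
                assert orig.genotype(rsid) == new.genotype(rsid)

    def test_unordered_cells_equal(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs12913832\nS1\tG/A\nS2\tA/G\n")
        s1, s2 = read_genotype_table(path)
        assert s1.calls["rs12913832"].alleles == s2.calls["rs12913832"].alleles

    def test_na_and_dot_missing(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs12913832\trs12203592\nS1\tNA\t./.\n")
        (s,) = read_genotype_table(path)
        assert s.genotype("rs12913832") is None
        assert s.genotype("rs12203592") is None

    def test_unknown_column(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs9999\nS1\tA/G\n")
        with pytest.raises(PanelValidationError, match="rs9999"):
            read_genotype_table(path)

    def test_bad_cell_names_location(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs12913832\nS1\tA+G\n")
        with pytest.raises(PanelValidationError, match="S1"):
            read_genotype_table(path)


def _write_vcf_text(path, records, samples=("S1", "S2")):
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        header,
    ]
    lines += records
    path.write_text("\n".join(lines) + "\n")


class TestVcf:
    def test_full_panel_two_samples(self, tmp_path):
        records = []
        for i, snp in enumerate(panel()):
            a, b = snp.alleles
            records.append(
                f"1\t{1000 + i}\t{snp.rsid}\t{a}\t{b}\t.\t.\t.\tGT\t0/1\t1/1"
            )
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, records)
        s1, s2 = read_vcf(path)
        assert all(not c.is_missing for c in s1.calls.values())
        assert all(not c.is_missing for c in s2.calls.values())
        assert len(s1.calls) == 8

    def test_gt_index_semantics(self, tmp_path):
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, ["1\t1\trs12913832\tA\tG\t.\t.\t.\tGT\t0/1\t0/0"])
        s1, s2 = read_vcf(path)
        assert s1.genotype("rs12913832") == ("A", "G")
        assert s2.genotype("rs12913832") == ("A", "A")

    def test_absent_site_missing(self, tmp_path):
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, ["1\t1\trs12913832\tA\tG\t.\t.\t.\tGT\t0/1\t0/0"])
        for s in read_vcf(path):
            assert s.genotype("rs12896399") is None

    def test_half_call_and_missing(self, tmp_path):
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, ["1\t1\trs12913832\tA\tG\t.\t.\t.\tGT\t./.\t./1"])
        s1, s2 = read_vcf(path)
        assert s1.genotype("rs12913832") is None
        assert s2.genotype("rs12913832") is None

    def test_positional_fallback(self, tmp_path):
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, ["9\t42\t.\tA\tG\t.\t.\t.\tGT\t1/1\t0/0"])
        out = read_vcf(path, positions={("9", 42): "rs12913832"})
        assert out[0].genotype("rs12913832") == ("G", "G")

    def test_invalid_allele_names_sample_and_rsid(self, tmp_path):
        path = tmp_path / "t.vcf"
        # A/C is irreconcilable with the A/G panel pair even after
        # complementation (G/T)
        _write_vcf_text(path, ["1\t1\trs12913832\tA\tC\t.\t.\t.\tGT\t0/0\t0/1"])
        with pytest.raises(PanelValidationError, match="rs12913832") as exc:
            read_vcf(path)
        assert "S2" in str(exc.value)

    def test_malformed_vcf(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(VcfParseError):
            read_vcf(path)

    def test_no_samples(self, tmp_path):
        path = tmp_path / "t.vcf"
        _write_vcf_text(path, [], samples=())
        with pytest.raises(VcfParseError, match="no sample"):
            read_vcf(path)


class TestPhenotypeTable:
    def test_parse(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tpopulation\teye_bin\tskin_bin\n"
            "S1\tE\tblue\tlight\n"
            "S2\tmix\tbrown\t\n"
        )
        r1, r2 = read_phenotype_table(path)
        assert r1 == PhenotypeRecord("S1", "E", "blue", "light")
        assert r2.skin_bin is None
        assert r2.eye_bin == "brown"

    def test_unknown_population(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tpopulation\teye_bin\tskin_bin\nS3\tX\tblue\tlight\n"
        )
        with pytest.raises(PanelValidationError, match="population"):
            read_phenotype_table(path)

    def test_unknown_bin(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tpopulation\teye_bin\tskin_bin\nS3\tE\thazel\tlight\n"
        )
        with pytest.raises(PanelValidationError, match="hazel"):
            read_phenotype_table(path)
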