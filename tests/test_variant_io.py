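"""Variant-table I/O: HGVS parsing, invariant enforcement, round-tripping."""

import pytest

from sarcosig.variant_io import (ConfigurationError, VariantRecord,
                                 normalize_consequence, parse_hgvs_p,
                                 read_sample_meta, read_variant_table,
                                 validate_record, write_sample_meta,
                                 write_variant_table)

HEADER = "sample\tchrom\tpos\tref\talt\tcontext\tconsequence\tprotein_change\n"


def _write(tmp_path, body, name="v.tsv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


@pytest.mark.parametrize("text,expected", [
    ("p.G12D", ("G", 12, "D")),
    ("G12D", ("G", 12, "D")),
    ("p.Ala123Val", ("A", 123, "V")),
    ("p.Tyr55=", ("Y", 55, "Y")),
    ("p.A123A", ("A", 123, "A")),
    ("p.A123=", ("A", 123, "A")),
    ("p.Q61*", ("Q", 61, "*")),
    ("p.Gln61Ter", ("Q", 61, "*")),
    ("p.(R97C)", ("R", 97, "C")),
    ("p.A123fs", None),
    ("p.Met1ext-5", None),
    ("p.L100_P101del", None),
    ("", None),
    ("not hgvs", None),
])
def test_parse_hgvs_p(text, expected):
    assert parse_hgvs_p(text) == expected


def test_invariant_enforcement_rejects_bad_rows(tmp_path):
    """ref==alt rows are rejected with a reason; valid rows survive."""
    path = _write(tmp_path,
                  "S1\tchr1\t100\tC\tT\tACG\tmissense\tp.A10V\n"
                  "S1\tchr1\t200\tG\tA\t\tsilent\tp.L5=\n"
                  "S1\tchr1\t300\tT\tT\t\tsilent\t\n")
    res = read_variant_table(path)
    assert res.n_accepted == 2
    assert res.n_rejected == 1
    assert res.rejected[0][1] == "ref equals alt"


def test_empty_file_with_header(tmp_path):
    res = read_variant_table(_write(tmp_path, ""))
    assert res.records == [] and res.n_rejected == 0


def test_accounting_partition(tmp_path):
    """accepted + rejected always equals the number of data rows."""
    body = ("S1\tchr1\t1\tC\tA\t\tmissense\tp.A1V\n"
            "S1\tchr1\t2\tC\tC\t\t\t\n"          # ref == alt
            "S1\tchr1\t3\tCC\tA\t\t\t\n"         # unparseable allele
            "S1\tchr1\t4\tG\tT\t\tmissense\t\n"  # missense without aa change
            "S2\tchr2\t5\t-\tA\t\tother\t\n")
    res = read_variant_table(_write(tmp_path, body))
    assert res.n_accepted + res.n_rejected == 5
    assert res.n_accepted == 2


def test_round_trip_identity(tmp_path, default_cohort):
    """write -> read reproduces the record list exactly (first 200 records)."""
    records = default_cohort[0][:200]
    p1 = tmp_path / "a.tsv"
    write_variant_table(records, p1)
    res = read_variant_table(p1)
    assert res.records == records and res.n_rejected == 0
    p2 = tmp_path / "b.tsv"
    write_variant_table(res.records, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_missing_mandatory_column_names_it(tmp_path):
    p = tmp_path / "v.tsv"
    p.write_text("sample\tchrom\tpos\tref\n")
    with pytest.raises(ConfigurationError, match="alt"):
        read_variant_table(p)


def test_maf_like_dialect(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("Tumor_Sample_Barcode\tChromosome\tStart_Position\t"
                 "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
                 "HGVSp_Short\n"
                 "S1\t7\t140453136\ta\tt\tMissense_Mutation\tp.V600E\n")
    res = read_variant_table(p, dialect="maf_like")
    (rec,) = res.records
    assert (rec.ref, rec.alt) == ("A", "T")  # upper-cased
    assert rec.consequence == "missense" and rec.ref_aa == "V" and rec.alt_aa == "E"


def test_unknown_consequence_maps_to_other():
    assert normalize_consequence("De_novo_Start_InFrame") == "other"
    assert normalize_consequence(None) == "unknown"
    assert normalize_consequence("Missense_Mutation") == "missense"


def test_frameshift_notation_demotes_to_other(tmp_path):
    path = _write(tmp_path, "S1\tchr1\t1\tC\tA\t\tmissense\tp.A123fs\n")
    res = read_variant_table(path)
    assert res.n_accepted == 1
    assert res.records[0].consequence == "other"


def test_malformed_context_drops_context_not_row(tmp_path):
    path = _write(tmp_path, "S1\tchr1\t1\tC\tA\tAGG\tsilent\tp.L5=\n")
    res = read_variant_table(path)
    assert res.n_accepted == 1
    assert res.records[0].context is None
    assert res.n_context_dropped == 1


def test_validate_record_consequence_invariants():
    base = dict(sample_id="S", chrom="1", pos=1, ref="C", alt="T")
    assert validate_record(VariantRecord(**base, consequence="missense",
                                         ref_aa="A", alt_aa="A", aa_pos=1))
    assert validate_record(VariantRecord(**base, consequence="silent",
                                         ref_aa="A", alt_aa="V", aa_pos=1))
    assert validate_record(VariantRecord(**base, consequence="missense",
                                         ref_aa="A", alt_aa="V", aa_pos=1)) is None


def test_sample_meta_round_trip_and_validation(tmp_path, default_cohort):
    meta = default_cohort[1]
    p = tmp_path / "meta.tsv"
    write_sample_meta(meta, p)
    assert read_sample_meta(p) == meta

    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tpatient_id\tsite_group\tcapture_size_bp\n"
                   "S1\tP1\tface_scalp\t100\nS1\tP2\tother\t100\n")
    with pytest.raises(ConfigurationError, match="duplicate"):
        read_sample_meta(bad)
    bad.write_text("sample_id\tpatient_id\tsite_group\tcapture_size_bp\n"
                   "S1\tP1\tlung\t100\n")
    with pytest.raises(ConfigurationError, match="site_group"):
        read_sample_meta(bad)
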