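import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopepscan import (
    MassSpec,
    SchemaError,
    ValidationError,
    compute_peptide_mass,
    load_expression,
    load_library,
    load_proteome,
    validate_library_masses,
    write_library,
)
from biopepscan._masses import STANDARD_RESIDUES
from biopepscan.library_io import BiopeptideLibrary, BiopeptideRecord

AA = st.text(alphabet=sorted(STANDARD_RESIDUES), min_size=1, max_size=30)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


LIB_HEADER = "biopeptide_ID\tbiopeptid_name (biological role)\tpeptide sequence\tchemical mass\tbiological activity category\n"


class TestLoadLibrary:
    def test_header_only_gives_empty_library(self, tmp_path):
        path = write(tmp_path, "lib.tsv", LIB_HEADER)
        assert len(load_library(path)) == 0

    def test_five_field_rows_fully_populated(self, tmp_path):
        """The published header spelling (including 'biopeptid_name') loads."""
        rows = "".join(
            f"BP{i}\trole {i}\t{seq}\t{mass}\t{act}\n"
            for i, (seq, mass, act) in enumerate(
                [
                    ("GG", "132.12", "ACE inhibitor"),
                    ("AKK", "346.43", "ACE inhibitor;DPP-4 inhibitor"),
                    ("VPP", "311.38", "hypotensive"),
                    ("IPP", "325.41", "ACE inhibitor"),
                    ("YP", "278.31", "antioxidative"),
                ]
            )
        )
        lib = load_library(write(tmp_path, "lib.tsv", LIB_HEADER + rows))
        assert len(lib) == 5
        rec = lib.get("BP1")
        assert rec.sequence == "AKK"
        assert rec.mass == pytest.approx(346.43)
        assert rec.activities == ("ACE inhibitor", "DPP-4 inhibitor")
        assert rec.name == "role 1"

    def test_nonstandard_residue_strict_names_offender(self, tmp_path):
        path = write(tmp_path, "lib.tsv", LIB_HEADER + "BP1\tx\tAZQ\t\tbinding\n")
        with pytest.raises(ValidationError, match="'Z'"):
            load_library(path, strict=True)

    def test_lenient_mode_skips_invalid_rows(self, tmp_path):
        path = write(
            tmp_path,
            "lib.tsv",
            LIB_HEADER + "BP1\tx\tAZQ\t\tbinding\nBP2\ty\tGG\t\tbinding\n",
        )
        lib = load_library(path, strict=False)
        assert [r.peptide_id for r in lib] == ["BP2"]

    def test_duplicate_id_rejected_either_mode(self, tmp_path):
        body = "BP1\tx\tGG\t\ta\nBP1\ty\tAA\t\ta\n"
        path = write(tmp_path, "lib.tsv", LIB_HEADER + body)
        for strict in (True, False):
            with pytest.raises(ValidationError, match="duplicate"):
                load_library(path, strict=strict)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "lib.tsv", "id\tname\tmass\tactivity\nBP1\tx\t1.0\ta\n")
        with pytest.raises(SchemaError, match="sequence"):
            load_library(path)

    def test_length_gate_and_override(self, tmp_path):
        long_seq = "A" * 61
        path = write(
            tmp_path, "lib.tsv", LIB_HEADER + f"BP1\tx\t{long_seq}\t\ta\nBP2\ty\tG\t\ta\n"
        )
        with pytest.raises(ValidationError, match="length"):
            load_library(path, strict=True)
        lib = load_library(path, allow_out_of_range=True)
        assert all(r.out_of_range for r in lib)
        assert len(lib) == 2

    def test_csv_extension_switches_delimiter(self, tmp_path):
        path = write(tmp_path, "lib.csv", "id,name,sequence,mass,activity\nBP1,x,GG,,a\n")
        assert load_library(path).get("BP1").sequence == "GG"

    def test_round_trip_is_field_identical(self, tmp_path):
        lib = BiopeptideLibrary(
            [
                BiopeptideRecord("BP1", "alpha", "GGAK", 361.44, ("a", "b")),
                BiopeptideRecord("BP2", "beta", "WW", None, ("c",)),
            ]
        )
        out = tmp_path / "out.tsv"
        write_library(lib, out)
        reloaded = load_library(out)
        for a, b in zip(lib, reloaded):
            assert (a.peptide_id, a.name, a.sequence, a.mass, a.activities) == (
                b.peptide_id, b.name, b.sequence, b.mass, b.activities
            )


class TestLoadProteome:
    def test_direct_parse(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">p1 desc here\nMKV\n>p2\nGG\n")
        recs = load_proteome(path)
        assert [(r.protein_id, r.length) for r in recs] == [("p1", 3), ("p2", 2)]
        assert recs[0].description == "desc here"

    def test_uppercase_and_stop_strip(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">p1\nmkvr*\n")
        (rec,) = load_proteome(path)
        assert rec.sequence == "MKVR"
        assert rec.length == 4

    def test_internal_stop_kept_verbatim(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">p1\nMK*VR\n")
        (rec,) = load_proteome(path)
        assert rec.sequence == "MK*VR"

    def test_duplicate_id_error(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">p1\nMKV\n>p1\nGG\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_proteome(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = write(tmp_path, "p.fasta", "")
        with caplog.at_level("WARNING"):
            assert load_proteome(path) == []
        assert any("no FASTA records" in m for m in caplog.messages)

    def test_nucleotide_looking_content_warns(self, tmp_path, caplog):
        path = write(tmp_path, "p.fasta", ">p1\nACGTACGTACGTACGTACGT\n")
        with caplog.at_level("WARNING"):
            load_proteome(path)
        assert any("nucleotide" in m for m in caplog.messages)

    def test_loaded_sequences_normalised(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">a\nmKv*\n>b\ngGg\n")
        for rec in load_proteome(path):
            assert rec.sequence == rec.sequence.upper()
            assert not rec.sequence.endswith("*")


class TestLoadExpression:
    def test_direct_parse(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene_id\tlog2fc\ngA\t1.5\ngB\t-2.0\n")
        recs = load_expression(path)
        assert [(r.gene_id, r.log2fc) for r in recs] == [("gA", 1.5), ("gB", -2.0)]

    def test_non_numeric_row_rejected_with_index(self, tmp_path, caplog):
        path = write(tmp_path, "e.tsv", "gene_id\tlog2fc\ngA\t1.5\ngC\tNA\n")
        with caplog.at_level("WARNING"):
            recs = load_expression(path)
        assert [r.gene_id for r in recs] == ["gA"]
        assert any("row 3" in m for m in caplog.messages)

    def test_empty_file_with_header(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene_id\tlog2fc\n")
        assert load_expression(path) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene_id\tfold\ngA\t1.5\n")
        with pytest.raises(SchemaError):
            load_expression(path)

    def test_infinite_value_rejected(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene_id\tlog2fc\ngA\tinf\ngB\t0.2\n")
        assert [r.gene_id for r in load_expression(path)] == ["gB"]


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 75.07), ("GG", 132.12), ("AG", 146.15), ("W", 204.23)],
    )
    def test_average_masses(self, seq, expected):
        assert compute_peptide_mass(seq, MassSpec("average", 0.5)) == pytest.approx(
            expected, abs=0.01
        )

    def test_empty_sequence_errors(self):
        with pytest.raises(ValidationError):
            compute_peptide_mass("")

    def test_nonstandard_residue_errors(self):
        with pytest.raises(ValidationError, match="'X'"):
            compute_peptide_mass("GXG")

    def test_monoisotopic_agrees_with_pyteomics(self):
        """Independent cross-check of the embedded monoisotopic table."""
        from pyteomics import mass as pmass

        for seq in ("G", "PEPTIDE", "WWKR", "ACDEFGHIKLMNPQRSTVWY"):
            ours = compute_peptide_mass(seq, MassSpec("monoisotopic", 0.01))
            theirs = pmass.calculate_mass(sequence=seq)
            assert ours == pytest.approx(theirs, abs=0.01)

    @settings(max_examples=50, deadline=None)
    @given(s1=AA, s2=AA)
    def test_additivity(self, s1, s2):
        """mass(s1 + s2) = mass(s1) + mass(s2) - water."""
        spec = MassSpec("average", 0.5)
        water = compute_peptide_mass("G", spec) - 57.0519
        total = compute_peptide_mass(s1 + s2, spec)
        assert math.isclose(
            total,
            compute_peptide_mass(s1, spec) + compute_peptide_mass(s2, spec) - water,
            abs_tol=1e-6,
        )


class TestValidateMasses:
    def test_within_tolerance_passes(self):
        lib = BiopeptideLibrary([BiopeptideRecord("P1", "x", "GG", 132.12, ("a",))])
        report = validate_library_masses(lib, MassSpec("average", 0.5))
        assert report.ok and report.missing == []

    def test_discrepancy_reported_with_delta(self):
        lib = BiopeptideLibrary([BiopeptideRecord("P1", "x", "GG", 500.0, ("a",))])
        report = validate_library_masses(lib, MassSpec("average", 0.5))
        (d,) = report.discrepancies
        assert d.peptide_id == "P1"
        assert d.delta == pytest.approx(367.88, abs=0.01)

    def test_missing_mass_listed_separately(self):
        lib = BiopeptideLibrary([BiopeptideRecord("P1", "x", "GG", None, ("a",))])
        report = validate_library_masses(lib)
        assert report.ok
        assert report.missing == ["P1"]
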