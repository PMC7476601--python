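"""Identification-export parsing: accessions, filters, scans, peptides."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoquant.byonic_reader import (
    PeptideParseError,
    ScanParseError,
    TableFormatError,
    extract_accession,
    extract_scan,
    is_excluded,
    parse_peptide,
    read_ident_file,
)
from glycoquant.glycan_model import ModifiedPeptide


class TestExtractAccession:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("sp|P01857|IGHG1_HUMAN Immunoglobulin heavy constant gamma 1", "P01857"),
            (">Reverse sp|P01011|AACT_HUMAN", "P01011"),
            ("tr|A0A024R6I7|A0A024R6I7_HUMAN", "A0A024R6I7"),
            ("MyCustomConstruct_v2", "MyCustomConstruct_v2"),  # total fallback
            ("Common contaminant protein Trypsin", "Common contaminant protein Trypsin"),
        ],
    )
    def test_accession_or_fallback(self, name, expected):
        assert extract_accession(name) == expected

    def test_idempotent(self):
        for name in ("sp|P01857|IGHG1_HUMAN", "NotAnAccession"):
            once = extract_accession(name)
            assert extract_accession(once) == once

    def test_entry_names_do_not_fire_the_pattern(self):
        # the bounded pattern must not match inside IGHG1_HUMAN-style tokens
        assert extract_accession("IGHG1_HUMAN") == "IGHG1_HUMAN"


class TestExclusionFilter:
    @pytest.mark.parametrize(
        "name,excluded",
        [
            (">Reverse sp|P01857|IGHG1_HUMAN", True),
            (">REVERSE sp|P01857|IGHG1_HUMAN", True),
            ("Reverse sp|P01011|AACT_HUMAN", True),
            ("Common contaminant protein Trypsin", True),
            ("common CONTAMINANT keratin", True),
            ("sp|P01857|IGHG1_HUMAN", False),
            ("sp|Q9REV5|SOME_PROTEIN", False),  # 'rev' inside an accession is fine
        ],
    )
    def test_decoy_and_contaminant_markers(self, name, excluded):
        assert is_excluded(name) is excluded

    def test_configurable_marker_list(self):
        assert is_excluded("CON__TRYP_PIG", contaminant_markers=("con__",))
        assert not is_excluded("CON__TRYP_PIG")


class TestExtractScan:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("8341", 8341),
            ("Scan 8341", 8341),
            ("ctrl_rep1.10288.10288.2", 10288),
            (12345, 12345),
        ],
    )
    def test_dialects(self, text, expected):
        assert extract_scan(text) == expected

    def test_no_number_raises(self):
        with pytest.raises(ScanParseError):
            extract_scan("n/a")


class TestParsePeptide:
    def test_glycopeptide_with_delta(self):
        p = parse_peptide("R.EEQYN[+1444.5339]STYR.V")
        assert p.sequence == "EEQYNSTYR"
        assert p.mods == ((5, 1444.5339),)
        assert (p.flank_n, p.flank_c) == ("R", "V")

    def test_terminal_flanks(self):
        p = parse_peptide("-.M[+15.9949]K.- ")
        assert p.sequence == "MK"
        assert p.mods == ((1, 15.9949),)

    def test_unmodified_peptide(self):
        p = parse_peptide("K.VAATVISK.-")
        assert p.sequence == "VAATVISK"
        assert p.mods == ()

    def test_negative_delta_sign_preserved(self):
        p = parse_peptide("K.Q[-17.0265]NVSK.A")
        assert p.mods == ((1, -17.0265),)

    @pytest.mark.parametrize("text", ["K.PEP[TIDE.K", "K.PE[+abc]P.K", "K..K"])
    def test_malformed_raises(self, text):
        with pytest.raises(PeptideParseError):
            parse_peptide(text)

    deltas = st.integers(min_value=-200000, max_value=30000000).map(
        lambda n: n / 1e4
    ).filter(lambda d: d != 0)

    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
        st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_render_parse_round_trip(self, sequence, data):
        n_mods = data.draw(st.integers(0, min(4, len(sequence))))
        positions = data.draw(
            st.lists(
                st.integers(1, len(sequence)),
                min_size=n_mods,
                max_size=n_mods,
                unique=True,
            )
        )
        mods = tuple(sorted((p, data.draw(self.deltas)) for p in positions))
        pep = ModifiedPeptide(sequence=sequence, mods=mods, flank_n="K", flank_c="A")
        parsed = parse_peptide(pep.render())
        assert parsed.sequence == pep.sequence
        assert tuple(sorted(parsed.mods)) == mods
        assert (parsed.flank_n, parsed.flank_c) == ("K", "A")


class TestReadIdentFile:
    HEADER = (
        "Protein Name,Scan #,Peptide,Glycans,Modification Type(s),"
        "Score,Calc. m/z,Starting position"
    )

    def _write(self, tmp_path, lines):
        f = tmp_path / "ident.csv"
        f.write_text("\n".join([self.HEADER] + lines) + "\n")
        return f

    def test_synonym_headers_and_filtering(self, tmp_path):
        f = self._write(
            tmp_path,
            [
                'sp|P01857|IGHG1_HUMAN IgG1,s.10.10.2,R.EEQYN[+1444.5339]STYR.V,HexNAc(4)Hex(3)Fuc(1),Glycan,350.0,1000.5,176',
                '>Reverse sp|P01857|IGHG1_HUMAN,s.11.11.2,R.EEQYN[+1444.5339]STYR.V,HexNAc(4)Hex(3)Fuc(1),Glycan,350.0,1000.5,176',
                'Common contaminant protein Trypsin,s.12.12.2,K.VAATVISK.-,,,300.0,400.2,45',
            ],
        )
        rows, stats, names = read_ident_file(f)
        assert stats.total == 3
        assert stats.decoy_or_contaminant == 2
        assert [r.master_id for r in rows] == ["P01857"]
        assert names["P01857"].startswith("sp|P01857|")
        assert rows[0].scan == 10
        assert rows[0].peptide.start == 176

    def test_filter_happens_before_grouping_and_shrinks(self, tmp_path):
        f = self._write(
            tmp_path,
            [
                '>Reverse sp|P01011|AACT_HUMAN,s.1.1.2,K.VAATVISK.-,,,300.0,400.2,45',
            ],
        )
        rows, stats, names = read_ident_file(f)
        assert rows == [] and names == {}
        assert stats.kept <= stats.total

    def test_inconsistent_glycan_rows_skipped(self, tmp_path):
        f = self._write(
            tmp_path,
            ['sp|P01857|X,s.1.1.2,K.VAATVISK.-,,Glycan,300.0,400.2,45'],
        )
        rows, stats, _ = read_ident_file(f)
        assert rows == []
        assert stats.inconsistent_glycan == 1

    def test_isoform_rows_share_master_id(self, tmp_path):
        f = self._write(
            tmp_path,
            [
                'sp|P01857|IGHG1_HUMAN isoform 1,s.1.1.2,K.VAATVISK.-,,,300.0,400.2,45',
                'sp|P01857-2|IGHG1_HUMAN isoform 2,s.2.2.2,K.VAATVISK.-,,,300.0,400.2,45',
            ],
        )
        rows, _, names = read_ident_file(f)
        assert {r.master_id for r in rows} == {"P01857"}
        assert names["P01857"].endswith("isoform 1")  # first-seen display name

    def test_tsv_dialect_accepted(self, tmp_path):
        f = tmp_path / "ident.tsv"
        f.write_text(
            self.HEADER.replace(",", "\t")
            + "\n"
            + "sp|P01857|IGHG1_HUMAN\ts.1.1.2\tK.VAATVISK.-\t\t\t300.0\t400.2\t45\n"
        )
        rows, _, _ = read_ident_file(f)
        assert len(rows) == 1

    def test_missing_column_is_config_error(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("Protein Name,Peptide\nX,K.AK.-\n")
        with pytest.raises(TableFormatError, match="bad.csv"):
            read_ident_file(f)
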