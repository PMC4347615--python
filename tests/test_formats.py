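"""I/O layer: FASTA, ASCII PSSM, attribute scales, manifests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pssmloc as pl
from pssmloc.formats import FormatError, DegenerateScaleError


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">p1\nACDE\n")
        recs = pl.read_fasta(p)
        assert recs == [pl.ProteinRecord(id="p1", sequence="ACDE")]

    def test_wrapped_lines_and_multiple_records(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">p1\nAC\nDE\n>p2\nKLM\n")
        recs = pl.read_fasta(p)
        assert [r.sequence for r in recs] == ["ACDE", "KLM"]

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            pl.read_fasta(p)

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("\nACDE\n>p1\nKLM\n")
        with pytest.raises(FormatError, match="line 2"):
            pl.read_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [
            pl.ProteinRecord(id="p1", sequence="ACDEFGHIKLMNPQRSTVWY" * 5),
            pl.ProteinRecord(id="p2", sequence="MKLXBZU"),
        ]
        p = tmp_path / "out.fa"
        pl.write_fasta(recs, p)
        assert pl.read_fasta(p) == recs


def _pssm_text(pct_rows, residues):
    """Minimal PSI-BLAST ASCII dialect: index, residue, 20 log-odds, 20 pcts."""
    lines = ["", "Last position-specific scoring matrix computed", "   header"]
    for i, (res, pct) in enumerate(zip(residues, pct_rows), start=1):
        logodds = " ".join("0" for _ in range(20))
        pcts = " ".join(str(int(v)) for v in pct)
        lines.append(f"{i} {res} {logodds} {pcts} 0.5 1.0")
    return "\n".join(lines) + "\n"


class TestParsePssm:
    def test_percentage_rows_become_probabilities(self, tmp_path):
        rows = [[0] * 20 for _ in range(3)]
        rows[0][0] = 100
        rows[1][1] = 100
        rows[2][0] = rows[2][1] = 50
        p = tmp_path / "x.pssm"
        p.write_text(_pssm_text(rows, "MKL"))
        pssm = pl.parse_pssm(p)
        assert pssm.length == 3 and pssm.residues == "MKL"
        np.testing.assert_allclose(pssm.probs[0], np.eye(20)[0])
        np.testing.assert_allclose(pssm.probs[2][:2], [0.5, 0.5])

    def test_all_zero_row_becomes_uniform(self, tmp_path):
        rows = [[0] * 20, [100] + [0] * 19]
        p = tmp_path / "x.pssm"
        p.write_text(_pssm_text(rows, "MK"))
        pssm = pl.parse_pssm(p)
        np.testing.assert_allclose(pssm.probs[0], np.full(20, 1 / 20))

    def test_rows_are_stochastic_for_both_sources(self, tmp_path, random_pssm):
        p = tmp_path / "x.pssm"
        pl.write_pssm_ascii(random_pssm, p)
        for source in ("percentages", "sigmoid_logodds"):
            parsed = pl.parse_pssm(p, prob_source=source)
            np.testing.assert_allclose(parsed.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_ascii_round_trip_approximates_probs(self, tmp_path, random_pssm):
        p = tmp_path / "x.pssm"
        pl.write_pssm_ascii(random_pssm, p)
        parsed = pl.parse_pssm(p)
        assert parsed.residues == random_pssm.residues
        # percentages are integer-rounded, so agreement is to ~1%
        np.testing.assert_allclose(parsed.probs, random_pssm.probs, atol=0.02)

    def test_short_row_is_format_error_with_row_index(self, tmp_path):
        text = _pssm_text([[100] + [0] * 19], "M")
        text += "2 K 1 2 3\n"
        p = tmp_path / "x.pssm"
        p.write_text(text)
        with pytest.raises(FormatError, match="row 2"):
            pl.parse_pssm(p)

    def test_empty_matrix_is_format_error(self, tmp_path):
        p = tmp_path / "x.pssm"
        p.write_text("no data rows here\n")
        with pytest.raises(FormatError):
            pl.parse_pssm(p)


class TestAttributeScale:
    def test_tsv_read(self, tmp_path):
        p = tmp_path / "s.tsv"
        lines = [f"{aa}\t{1.0 if aa != 'C' else 2.0}" for aa in pl.CANONICAL_AA]
        p.write_text("# comment\n" + "\n".join(lines) + "\n")
        scale = pl.read_attribute_scale(p, "toy")
        assert len(scale.values) == 20 and scale.values["C"] == 2.0

    def test_missing_residue_named(self, tmp_path):
        p = tmp_path / "s.tsv"
        lines = [f"{aa}\t{i}" for i, aa in enumerate(pl.CANONICAL_AA) if aa != "W"]
        p.write_text("\n".join(lines))
        with pytest.raises(FormatError, match="W"):
            pl.read_attribute_scale(p)

    def test_duplicate_residue_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        lines = [f"{aa}\t{i}" for i, aa in enumerate(pl.CANONICAL_AA)] + ["A\t99"]
        p.write_text("\n".join(lines))
        with pytest.raises(FormatError):
            pl.read_attribute_scale(p)

    def test_degenerate_scale_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("\n".join(f"{aa}\t1.0" for aa in pl.CANONICAL_AA))
        with pytest.raises(DegenerateScaleError):
            pl.read_attribute_scale(p)

    def test_aaindex_entry(self, tmp_path):
        p = tmp_path / "s.aaindex"
        p.write_text(
            "H FAKE000001\n"
            "D synthetic test entry\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/V     H/W     I/Y\n"
            "   1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
            "  11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
            "//\n"
        )
        scale = pl.read_attribute_scale(p)
        assert scale.attribute_id == "FAKE000001"
        assert scale.values["A"] == 1.0 and scale.values["L"] == 11.0 and scale.values["Y"] == 20.0

    def test_tsv_round_trip(self, tmp_path, random_scale):
        p = tmp_path / "s.tsv"
        pl.write_attribute_scale(random_scale, p)
        back = pl.read_attribute_scale(p, random_scale.attribute_id)
        assert back.values == random_scale.values


class TestManifest:
    def test_expansion_examples_from_benchmark_counts(self):
        labels = ("a", "b", "c", "d")
        rng = np.random.default_rng(0)
        m = pl.synth_manifest(515, 4, labels, rng)
        assert len(pl.expand_manifest(m)) == 523
        m = pl.synth_manifest(1328, 64, tuple("abcdefgh"), rng)
        assert len(pl.expand_manifest(m)) == 1456

    def test_single_protein_identity(self):
        m = pl.DatasetManifest(entries=[("p1", frozenset(["x"]))])
        table = pl.expand_manifest(m)
        assert table.samples == [("p1", "x")]

    def test_round_trip(self, tmp_path):
        m = pl.DatasetManifest(
            entries=[("p1", frozenset(["x"])), ("p2", frozenset(["x", "y"]))]
        )
        p = tmp_path / "m.tsv"
        pl.write_manifest(m, p)
        back = pl.read_manifest(p)
        assert sorted(back.entries) == sorted(m.entries)

    @given(
        st.lists(
            st.tuples(st.integers(0, 10**6), st.sets(st.sampled_from("abcde"), min_size=1)),
            min_size=1,
            max_size=60,
            unique_by=lambda t: t[0],
        )
    )
    def test_expansion_count_is_sum_of_label_set_sizes(self, raw):
        entries = [(f"p{i}", frozenset(labs)) for i, labs in raw]
        m = pl.DatasetManifest(entries=entries)
        assert len(pl.expand_manifest(m)) == sum(len(labs) for _, labs in entries)

    def test_duplicate_protein_rejected(self):
        with pytest.raises(ValueError):
            pl.DatasetManifest(
                entries=[("p1", frozenset(["x"])), ("p1", frozenset(["y"]))]
            )
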