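"""FASTA reading, PSSM parsing, softmax standardization, one-hot fallback."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspcp import (
    RESIDUE_ORDER,
    ProteinRecord,
    PSSMMatrix,
    one_hot_profile,
    parse_ascii_pssm,
    read_fasta,
    standardize_pssm,
    write_ascii_pssm,
)
from pspcp.profiles import PSSMFormatError, SequenceError, load_profile


class TestReadFasta:
    def test_minimal_record(self):
        recs = read_fasta(io.StringIO(">p1 some description\nACDEF\n"))
        assert len(recs) == 1
        assert recs[0].identifier == "p1"
        assert recs[0].length == 5

    def test_lower_case_folded(self):
        recs = read_fasta(io.StringIO(">p1\nacdef\n"))
        assert recs[0].sequence == "ACDEF"

    def test_illegal_characters_name_the_record(self):
        with pytest.raises(SequenceError, match="p1"):
            read_fasta(io.StringIO(">p1\nAC1EF\n"))

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(SequenceError, match="duplicate"):
            read_fasta(io.StringIO(">p1\nACD\n>p1\nEFG\n"))

    def test_empty_input_rejected(self):
        with pytest.raises(SequenceError, match="no FASTA records"):
            read_fasta(io.StringIO(""))

    def test_file_order_preserved(self):
        recs = read_fasta(io.StringIO(">b\nAC\n>a\nDE\n"))
        assert [r.identifier for r in recs] == ["b", "a"]


def _pssm_text(rows, residues):
    header = "".join(f"{aa:>4}" for aa in RESIDUE_ORDER)
    lines = ["", "Last position-specific scoring matrix computed",
             "          " + header + " " + header]
    for i, (aa, row) in enumerate(zip(residues, rows)):
        scores = "".join(f"{v:>4d}" for v in row)
        pcts = "".join(f"{0:>4d}" for _ in row)
        lines.append(f"{i + 1:>5d} {aa} {scores} {pcts}  0.36 0.12")
    lines += ["", "footer stats"]
    return "\n".join(lines) + "\n"


class TestParseAsciiPssm:
    def test_zero_row(self):
        pssm = parse_ascii_pssm(io.StringIO(_pssm_text([[0] * 20], "A")))
        assert pssm.E.shape == (1, 20)
        assert np.all(pssm.E == 0)

    def test_literal_integers_recovered(self):
        rows = [list(range(-10, 10)), [3] * 20]
        pssm = parse_ascii_pssm(io.StringIO(_pssm_text(rows, "AC")))
        assert pssm.E.tolist() == rows
        assert pssm.residue_column == "AC"

    def test_expected_sequence_mismatch_reports_position(self):
        text = _pssm_text([[0] * 20, [0] * 20], "AD")
        with pytest.raises(PSSMFormatError, match="position 2"):
            parse_ascii_pssm(io.StringIO(text), expected_sequence="AC")

    def test_truncated_row_reports_line_number(self):
        text = _pssm_text([[0] * 20], "A")
        truncated = "\n".join(
            ln if not ln.lstrip().startswith("1 ") else " ".join(ln.split()[:10])
            for ln in text.splitlines()
        )
        with pytest.raises(PSSMFormatError, match="line 4"):
            parse_ascii_pssm(io.StringIO(truncated))

    def test_non_integer_score_rejected(self):
        text = _pssm_text([[0] * 20], "A").replace("   0", " 0.5", 1)
        with pytest.raises(PSSMFormatError, match="non-integer"):
            parse_ascii_pssm(io.StringIO(text))

    def test_round_trip_through_writer(self, tmp_path):
        rng = np.random.default_rng(5)
        E = rng.integers(-10, 11, size=(7, 20))
        seq = "".join(rng.choice(list(RESIDUE_ORDER), 7))
        path = tmp_path / "x.pssm"
        write_ascii_pssm(PSSMMatrix("x", E, seq), path)
        back = parse_ascii_pssm(path, expected_sequence=seq)
        assert np.array_equal(back.E, E)


class TestStandardizePssm:
    def test_constant_row_is_uniform(self):
        pssm = PSSMMatrix("p", np.full((1, 20), 7), "A")
        A = standardize_pssm(pssm).A
        assert np.allclose(A, 0.05, atol=1e-12)

    def test_single_unit_score_matches_closed_form(self):
        row = np.zeros((1, 20), dtype=int)
        row[0, 0] = 1
        A = standardize_pssm(PSSMMatrix("p", row, "A")).A[0]
        e = math.e
        assert A[0] == pytest.approx(e / (e + 19), abs=1e-12)
        assert A[5] == pytest.approx(1 / (e + 19), abs=1e-12)

    def test_huge_score_stays_finite(self):
        row = np.zeros((1, 20), dtype=int)
        row[0, 3] = 10000
        A = standardize_pssm(PSSMMatrix("p", row, "A")).A[0]
        assert np.all(np.isfinite(A))
        assert A[3] == pytest.approx(1.0)
        assert A.sum() == pytest.approx(1.0)

    def test_agrees_with_naive_softmax_when_finite(self):
        rng = np.random.default_rng(0)
        E = rng.integers(-30, 31, size=(40, 20))
        A = standardize_pssm(PSSMMatrix("p", E, "A" * 40)).A
        naive = np.exp(E.astype(float))
        naive /= naive.sum(axis=1, keepdims=True)
        assert np.allclose(A, naive, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_rows_sum_to_one_for_random_integer_matrices(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.integers(-1000, 1001, size=(rng.integers(1, 30), 20))
        A = standardize_pssm(PSSMMatrix("p", E, "")).A
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((A >= 0) & (A <= 1))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(-500, 500))
    def test_row_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        E = rng.integers(-100, 101, size=(5, 20))
        A1 = standardize_pssm(PSSMMatrix("p", E, "")).A
        E2 = E.copy()
        E2[2] += shift
        A2 = standardize_pssm(PSSMMatrix("p", E2, "")).A
        assert np.allclose(A1[2], A2[2], atol=1e-10)


class TestOneHotProfile:
    def test_single_standard_residue(self):
        A = one_hot_profile(ProteinRecord("p", "A")).A
        assert A[0, 0] == 1.0 and A[0, 1:].sum() == 0.0

    def test_degenerate_residue_uniform(self):
        A = one_hot_profile(ProteinRecord("p", "X")).A
        assert np.allclose(A[0], 0.05)

    def test_rows_sum_to_one_and_argmax_recovers_sequence(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        prof = one_hot_profile(ProteinRecord("p", seq))
        assert np.allclose(prof.A.sum(axis=1), 1.0)
        recovered = "".join(RESIDUE_ORDER[j] for j in prof.A.argmax(axis=1))
        assert recovered == seq


class TestProfileLookup:
    def test_missing_pssm_falls_back_to_one_hot(self, tmp_path):
        rec = ProteinRecord("nope", "ACDEF")
        prof = load_profile(rec, tmp_path)
        assert prof.origin == "one_hot"

    def test_present_pssm_is_used_and_validated(self, tmp_path):
        rec = ProteinRecord("yes", "AC")
        E = np.array([[1] * 20, [-2] * 20])
        write_ascii_pssm(PSSMMatrix("yes", E, "AC"), tmp_path / "yes.pssm")
        prof = load_profile(rec, tmp_path)
        assert prof.origin == "pssm"
        assert np.allclose(prof.A, 0.05, atol=1e-12)  # constant rows
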