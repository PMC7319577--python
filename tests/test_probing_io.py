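"""Sequence canonicalization, QuShape parsing, reactivity files, ROI trims."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probekit.errors import (
    EmptyRoiError,
    FormatError,
    InvalidSequenceError,
    ReconciliationError,
    StateError,
)
from probekit.probing_io import (
    RegionOfInterest,
    RNASequence,
    apply_roi,
    canonicalize_sequence,
    parse_qushape,
    read_reactivity_file,
    reconcile,
    write_reactivity_file,
)

from .conftest import make_profile


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("acgu", "ACGU"),
            ("ACGT", "ACGU"),  # DNA-style T is read as U
            ("  a c\ng u\n", "ACGU"),
            (">hdr\nACGU\nACGU", "ACGUACGU"),
        ],
    )
    def test_canonical_forms(self, raw, expected):
        assert canonicalize_sequence(raw).residues == expected

    def test_invalid_letter_reports_position(self):
        with pytest.raises(InvalidSequenceError) as exc:
            canonicalize_sequence("ACGX")
        assert exc.value.position == 4

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidSequenceError):
            canonicalize_sequence(">only a header\n")


QUSHAPE_3ROW = (
    "seqNum\tseqRNA\tareaDiff\n"
    "1\tA\t0.1\n"
    "2\tC\t0.2\n"
    "3\tG\t0.3\n"
)


class TestQuShape:
    def test_direct_read(self):
        p = parse_qushape(QUSHAPE_3ROW)
        assert len(p) == 3
        assert p.sequence.residues == "ACG"
        assert p.measured.all()
        assert not p.normalized
        np.testing.assert_allclose(p.values, [0.1, 0.2, 0.3])

    def test_blank_cell_is_missing(self):
        text = QUSHAPE_3ROW.replace("2\tC\t0.2", "2\tC\t")
        p = parse_qushape(text)
        assert list(p.measured) == [True, False, True]

    def test_non_numeric_cell_is_missing(self):
        text = QUSHAPE_3ROW.replace("0.2", "n/a")
        p = parse_qushape(text)
        assert list(p.measured) == [True, False, True]

    def test_missing_seqrna_column(self):
        with pytest.raises(FormatError, match="seqRNA"):
            parse_qushape("seqNum\tareaDiff\n1\t0.1\n")

    def test_missing_reactivity_column(self):
        with pytest.raises(FormatError, match="areaDiff"):
            parse_qushape("seqNum\tseqRNA\n1\tA\n")

    def test_non_monotonic_positions_rejected(self):
        text = QUSHAPE_3ROW.replace("2\tC", "9\tC")
        with pytest.raises(FormatError, match="monotonic"):
            parse_qushape(text)

    def test_extra_columns_ignored_and_length_matches_rows(self):
        text = (
            "seqNum\tseqRNA\tareaDiff\tjunk\n"
            "1\tt\t1.0\tx\n"
            "2\ta\t2.0\ty\n"
        )
        p = parse_qushape(text)
        assert len(p) == 2
        assert p.sequence.residues == "UA"  # lower-case t canonicalized


class TestReconcile:
    def test_identical_sequences_empty_report(self):
        p = make_profile([0.1] * 4, sequence="ACGU")
        assert reconcile(p, RNASequence("r", "ACGU")).empty

    def test_single_substitution(self):
        p = make_profile([0.1] * 4, sequence="ACGU")
        report = reconcile(p, RNASequence("r", "ACGA"))
        assert report.mismatches == [(4, "U", "A")]

    def test_strict_length_mismatch_raises(self):
        p = make_profile([0.1] * 10, sequence="ACGU" * 2 + "AC")
        with pytest.raises(ReconciliationError):
            reconcile(p, RNASequence("r", "ACGU" * 3), strict=True)


class TestRoi:
    def test_noop(self):
        p = make_profile(range(10))
        q = apply_roi(p, RegionOfInterest(0, 0))
        assert q.sequence.residues == p.sequence.residues
        np.testing.assert_array_equal(q.values, p.values)

    def test_trim_window(self):
        p = make_profile(range(10))
        q = apply_roi(p, RegionOfInterest(2, 3))
        assert len(q) == 5
        np.testing.assert_array_equal(q.values, [2, 3, 4, 5, 6])
        assert q.sequence.residues == p.sequence.residues[2:7]
        assert "roi" in q.origin

    def test_degenerate_trims(self):
        p = make_profile(range(5))
        with pytest.raises(EmptyRoiError):
            apply_roi(p, RegionOfInterest(3, 2))

    def test_successive_trims_compose(self, rng):
        p = make_profile(rng.random(30))
        once = apply_roi(p, RegionOfInterest(5, 7))
        twice = apply_roi(apply_roi(p, RegionOfInterest(2, 3)), RegionOfInterest(3, 4))
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.sequence.residues == twice.sequence.residues


class TestReactivityFile:
    def test_sentinel_maps_to_missing(self):
        seq = RNASequence("r", "ACG")
        p = read_reactivity_file("1 0.5\n2 -999\n3 1.0\n", seq)
        assert list(p.measured) == [True, False, True]
        assert p.normalized
        np.testing.assert_allclose(p.values[[0, 2]], [0.5, 1.0])

    def test_empty_text_all_missing(self):
        p = read_reactivity_file("", RNASequence("r", "ACGU"))
        assert not p.measured.any()

    def test_absent_positions_missing(self):
        p = read_reactivity_file("2 0.25\n", RNASequence("r", "ACGU"))
        assert list(p.measured) == [False, True, False, False]

    def test_non_numeric_field(self):
        with pytest.raises(FormatError) as exc:
            read_reactivity_file("1 abc\n", RNASequence("r", "ACG"))
        assert exc.value.line == 1

    def test_duplicate_position(self):
        with pytest.raises(FormatError, match="duplicate"):
            read_reactivity_file("1 0.5\n1 0.6\n", RNASequence("r", "ACG"))

    def test_write_format(self):
        p = make_profile([0.5, None, 1.0], normalized=True)
        assert write_reactivity_file(p) == "1 0.500\n2 -999\n3 1.000\n"

    def test_write_requires_normalized(self):
        with pytest.raises(StateError):
            write_reactivity_file(make_profile([1.0, 2.0]))

    def test_line_count_equals_length(self, rng):
        p = make_profile(rng.random(37), normalized=True)
        assert len(write_reactivity_file(p).splitlines()) == 37

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        min_size=1, max_size=80,
    ))
    def test_round_trip_identity(self, values):
        """write -> read reproduces values (to 3 decimals) and states."""
        p = make_profile(values, normalized=True)
        q = read_reactivity_file(write_reactivity_file(p), p.sequence)
        assert list(q.measured) == list(p.measured)
        np.testing.assert_allclose(
            q.values[q.measured], p.values[p.measured], atol=5.1e-4
        )
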