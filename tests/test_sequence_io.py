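"""Encoding, labeling, layout and gene-usage behaviour of the sequence reader."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrmatrix.sequence_io import (
    LABEL_EXCLUDED,
    LABEL_NONPOLY,
    LABEL_POLY,
    RESIDUE_ORDER,
    EncodingLayout,
    LayoutError,
    SchemaError,
    SequenceRecord,
    assign_polyreactivity_labels,
    center_align_segment,
    decode_code,
    decode_row,
    encode_repertoire,
    encode_residue,
    gene_usage_table,
    read_repertoire,
    write_repertoire,
)
from tests.conftest import make_records


class TestResidueCodes:
    def test_published_anchor_codes(self):
        # the three printed assignments of the 1..21 encoding
        assert encode_residue("L") == 3
        assert encode_residue("H") == 16
        assert encode_residue("R") == 17

    def test_bijective_on_standard_residues(self):
        codes = {encode_residue(aa) for aa in RESIDUE_ORDER}
        assert codes == set(range(1, 21))
        for aa in RESIDUE_ORDER:
            assert decode_code(encode_residue(aa)) == aa

    def test_nonstandard_maps_to_21(self):
        assert encode_residue("X") == 21
        assert encode_residue("B") == 21  # ambiguity code

    @pytest.mark.parametrize("bad", ["", "AB", "-", "1"])
    def test_rejects_non_letters(self, bad):
        with pytest.raises(ValueError):
            encode_residue(bad)


class TestCenterAlignment:
    def test_symmetric_pad(self):
        vec = center_align_segment("CAR", 5)
        assert vec[0] == 0 and vec[4] == 0
        assert [decode_code(c) for c in vec[1:4]] == ["C", "A", "R"]

    def test_odd_slack_goes_right(self):
        vec = center_align_segment("CARD", 5)
        assert vec[4] == 0 and vec[0] != 0

    def test_empty_sequence_all_zeros(self):
        assert np.all(center_align_segment("", 3) == 0)

    def test_overlong_sequence_names_record(self):
        with pytest.raises(LayoutError, match="rec7"):
            center_align_segment("CARDAT", 3, record_id="rec7")


class TestLabeling:
    @pytest.mark.parametrize("count,scheme,expected", [
        (2, "full", LABEL_POLY),
        (1, "full", LABEL_NONPOLY),
        (0, "full", LABEL_NONPOLY),
        (7, "parsed", LABEL_POLY),
        (4, "parsed", LABEL_POLY),
        (3, "parsed", LABEL_EXCLUDED),
        (1, "parsed", LABEL_EXCLUDED),
        (0, "parsed", LABEL_NONPOLY),
    ])
    def test_labeling_schemes(self, count, scheme, expected):
        recs = make_records([("A",) * 6], ["unknown"], counts=[count])
        assert assign_polyreactivity_labels(recs, scheme)[0].label == expected

    def test_count_out_of_panel_rejected(self):
        recs = make_records([("A",) * 6], ["unknown"], counts=[8])
        with pytest.raises(ValueError, match="0..7"):
            assign_polyreactivity_labels(recs, "full")

    def test_parsed_partition_covers_everyone(self):
        recs = make_records(
            [("A",) * 6] * 8, ["unknown"] * 8, counts=list(range(8))
        )
        labeled = assign_polyreactivity_labels(recs, "parsed")
        counts = {lbl: sum(r.label == lbl for r in labeled)
                  for lbl in (LABEL_POLY, LABEL_NONPOLY, LABEL_EXCLUDED)}
        assert sum(counts.values()) == 8
        assert counts == {LABEL_POLY: 4, LABEL_NONPOLY: 1, LABEL_EXCLUDED: 3}


class TestLayoutAndEncoding:
    def test_total_length_arithmetic(self):
        layout = EncodingLayout(loop_widths=(3,) * 6, buffer_width=1)
        assert layout.total_length == 6 * 3 + 5 * 1

    def test_auto_width_uses_max_over_both_classes(self):
        recs = make_records(
            [("A", "A", "A", "A", "A", "CARDATTTTT"),
             ("A", "A", "A", "A", "A", "CARDATTTTTGGGG")],
            [LABEL_POLY, LABEL_NONPOLY],
        )
        matrix = encode_repertoire(recs)
        start, end = matrix.layout.loop_spans["cdr3h"]
        assert end - start == 14

    def test_class_blocks_are_contiguous(self, tiny_matrix):
        labels = tiny_matrix.row_labels
        first_non = labels.index(LABEL_NONPOLY)
        assert all(lbl == LABEL_POLY for lbl in labels[:first_non])
        assert all(lbl == LABEL_NONPOLY for lbl in labels[first_non:])

    def test_buffer_conservation(self, tiny_matrix):
        # zeros per row == L minus the residue count of that record
        L = tiny_matrix.n_columns
        for row in tiny_matrix.values:
            assert int((row == 0).sum()) == L - 18  # six loops of length 3

    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(*[st.text(alphabet=RESIDUE_ORDER, min_size=0, max_size=8)] * 6),
        min_size=1, max_size=6,
    ))
    def test_encode_decode_round_trip(self, loop_tuples):
        recs = make_records(loop_tuples, [LABEL_POLY] * len(loop_tuples))
        matrix = encode_repertoire(recs, drop_excluded=False)
        # rows may be reordered into class blocks; match by id
        by_id = {rid: row for rid, row in zip(matrix.row_ids, matrix.values)}
        for rec in recs:
            decoded = decode_row(by_id[rec.id], matrix.layout)
            assert decoded == rec.loops


class TestReadWrite:
    def test_csv_round_trip(self, tmp_path):
        recs = make_records(
            [("CAR", "LH", "A", "GG", "WW", "CARDAT")],
            [LABEL_POLY], counts=[5],
        )
        path = tmp_path / "rep.csv"
        write_repertoire(recs, path)
        back = read_repertoire(path)
        assert back[0].loops == recs[0].loops
        assert back[0].reactivity_count == 5

    def test_lowercase_normalized_and_unknown_letter_mapped(self, tmp_path):
        path = tmp_path / "rep.csv"
        path.write_text(
            "id,cdr1l,cdr2l,cdr3l,cdr1h,cdr2h,cdr3h\n"
            "s1,cars,A,A,A,A,ABA\n"
        )
        rec = read_repertoire(path)[0]
        assert rec.loops["cdr1l"] == "CARS"
        assert rec.loops["cdr3h"] == "AXA"

    def test_missing_loop_column_is_schema_error(self, tmp_path):
        path = tmp_path / "rep.csv"
        path.write_text("id,cdr1l,cdr2l,cdr3l,cdr1h,cdr2h\ns1,A,A,A,A,A\n")
        with pytest.raises(SchemaError, match="cdr3h"):
            read_repertoire(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "rep.csv"
        path.write_text("id,cdr1l,cdr2l,cdr3l,cdr1h,cdr2h,cdr3h\n")
        with pytest.raises(ValueError, match="empty"):
            read_repertoire(path)


class TestGeneUsage:
    def _records_with_genes(self, genes_a, genes_b):
        recs = []
        for i, g in enumerate(genes_a):
            recs.append(SequenceRecord(
                id=f"a{i}", loops={}, label=LABEL_POLY, v_gene_h=g))
        for i, g in enumerate(genes_b):
            recs.append(SequenceRecord(
                id=f"b{i}", loops={}, label=LABEL_NONPOLY, v_gene_h=g))
        return recs

    def test_counts_and_frequencies(self):
        recs = self._records_with_genes(
            ["VH1-69", "VH1-69", "VH3-23", "VH4-59"], ["VH3-23"])
        tab = gene_usage_table(recs)
        assert tab.counts[LABEL_POLY]["VH1-69"] == 2
        assert tab.frequencies[LABEL_POLY]["VH1-69"] == pytest.approx(0.5)
        for cls in tab.frequencies:
            assert sum(tab.frequencies[cls].values()) == pytest.approx(1.0, abs=1e-9)

    def test_gene_absent_in_other_class_flagged(self):
        recs = self._records_with_genes(
            ["VH1-69"] + ["VH3-23"] * 9, ["VH3-23"] * 10)
        tab = gene_usage_table(recs, threshold=0.02)
        assert "below threshold" in tab.below_threshold_flags["VH1-69"]

    def test_identical_classes_zero_difference(self):
        recs = self._records_with_genes(["VH1-69", "VH3-23"], ["VH1-69", "VH3-23"])
        tab = gene_usage_table(recs)
        assert all(abs(d) < 1e-12 for d in tab.difference.values())

    def test_no_gene_calls_raises_helpful_error(self):
        recs = make_records([("A",) * 6], [LABEL_POLY])
        with pytest.raises(ValueError, match="AIRR"):
            gene_usage_table(recs)
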