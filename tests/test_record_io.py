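"""Record/annotation round trips, format-212 packing and the AAMI
symbol mapping."""

import numpy as np
import pytest

from ecgresnet.record_io import (
    AamiClass,
    BeatAnnotation,
    EcgRecord,
    FormatError,
    MIT_TO_AAMI,
    map_to_aami,
    pack_212,
    read_annotations,
    read_record,
    unpack_212,
    write_record,
)


class TestFormat212:
    def test_pair_round_trip(self):
        data = pack_212([1, -1])
        assert len(data) == 3
        assert unpack_212(data, 2).tolist() == [1, -1]

    def test_all_12bit_values_round_trip(self):
        # brute force over the full 12-bit range, paired with a shifted copy
        vals = np.arange(-2048, 2048)
        partner = np.roll(vals, 1)
        flat = np.empty(2 * vals.size, dtype=np.int64)
        flat[0::2], flat[1::2] = vals, partner
        assert np.array_equal(unpack_212(pack_212(flat), flat.size), flat)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pack_212([5000, 0])

    def test_odd_sample_count(self):
        assert unpack_212(pack_212([7, -9, 13]), 3).tolist() == [7, -9, 13]


class TestAamiMapping:
    @pytest.mark.parametrize(
        "symbol,expected",
        [
            ("N", AamiClass.N), ("L", AamiClass.N), ("R", AamiClass.N),
            ("e", AamiClass.N), ("j", AamiClass.N),
            ("V", AamiClass.V), ("E", AamiClass.V),
            ("A", AamiClass.S), ("a", AamiClass.S), ("J", AamiClass.S),
            ("S", AamiClass.S),
            ("F", AamiClass.F),
            ("/", AamiClass.Q), ("f", AamiClass.Q), ("Q", AamiClass.Q),
        ],
    )
    def test_fifteen_beat_types(self, symbol, expected):
        assert map_to_aami(symbol) is expected

    def test_mapping_is_total_onto_five_classes(self):
        assert len(MIT_TO_AAMI) == 15
        assert {map_to_aami(s) for s in MIT_TO_AAMI} == set(AamiClass)

    def test_unknown_beat_symbol_goes_to_q_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert map_to_aami("B") is AamiClass.Q
        assert "unknown beat symbol" in caplog.text

    @pytest.mark.parametrize("symbol", ["+", "~", "|", "["])
    def test_non_beat_symbols_rejected(self, symbol):
        with pytest.raises(ValueError, match="not a heartbeat"):
            map_to_aami(symbol)


class TestEcgRecord:
    def test_invalid_fs_rejected(self):
        with pytest.raises(ValueError):
            EcgRecord("x", 0.0, np.zeros((1, 10)))

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            EcgRecord("x", 360.0, np.zeros((1, 0)))

    def test_single_channel_promoted_to_2d(self):
        rec = EcgRecord("x", 360.0, np.zeros(100))
        assert rec.n_channels == 1 and rec.n_samples == 100


@pytest.mark.parametrize("fmt", ["212", "txt"])
class TestRoundTrip:
    def test_record_round_trip(self, small_record, tmp_path, fmt):
        record, annotations = small_record
        paths = write_record(record, annotations, tmp_path, fmt=fmt)
        back = read_record(paths["header"])
        assert back.record_id == record.record_id
        assert back.fs == 360.0
        assert back.n_channels == 2
        assert back.n_samples == 3600
        # one quantization step: 1/gain mV for 212, 1e-6 for text
        tol = 1.0 / 200.0 if fmt == "212" else 1e-6
        assert np.abs(back.signal - record.signal).max() <= tol + 1e-12

    def test_annotation_round_trip(self, small_record, tmp_path, fmt):
        record, annotations = small_record
        paths = write_record(record, annotations, tmp_path, fmt=fmt)
        back = read_annotations(paths["annotations"])
        assert len(back) == 5
        assert [a.sample_index for a in back] == [300, 900, 1500, 2400, 3300]
        assert [a.mit_symbol for a in back] == ["N", "V", "N", "A", "N"]
        assert [a.aami_class for a in back] == [
            AamiClass.N, AamiClass.V, AamiClass.N, AamiClass.S, AamiClass.N,
        ]

    def test_empty_annotations(self, small_record, tmp_path, fmt):
        record, _ = small_record
        paths = write_record(record, [], tmp_path, fmt=fmt)
        assert read_annotations(paths["annotations"]) == []


class TestReadAnnotationsText:
    def test_parse_and_sort(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("250,V\n100,N\n")
        anns = read_annotations(p)
        assert [(a.sample_index, a.aami_class) for a in anns] == [
            (100, AamiClass.N), (250, AamiClass.V),
        ]

    def test_non_beat_rows_dropped(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("50,+\n100,N\n150,~\n")
        assert len(read_annotations(p)) == 1

    def test_paced_beat_is_q(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("10,/\n")
        assert read_annotations(p)[0].aami_class is AamiClass.Q


class TestBinaryAnnotations:
    def test_long_gap_uses_skip_words(self, small_record, tmp_path):
        record, _ = small_record
        anns = [
            BeatAnnotation.from_symbol(5, "N"),
            BeatAnnotation.from_symbol(3000, "V"),  # delta > 1023
        ]
        paths = write_record(record, anns, tmp_path, fmt="212")
        back = read_annotations(paths["annotations"])
        assert [(a.sample_index, a.mit_symbol) for a in back] == [
            (5, "N"), (3000, "V"),
        ]


class TestErrors:
    def test_missing_header(self, tmp_path):
        with pytest.raises(FormatError):
            read_record(tmp_path / "nope.hea")

    def test_corrupt_header(self, tmp_path):
        p = tmp_path / "bad.hea"
        p.write_text("bad\n")
        with pytest.raises(FormatError):
            read_record(p)

    def test_truncated_signal_detected(self, small_record, tmp_path):
        record, _ = small_record
        paths = write_record(record, [], tmp_path, fmt="212")
        data = paths["signal"].read_bytes()
        paths["signal"].write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError):
            read_record(paths["header"])

    def test_annotation_outside_record_rejected(self, small_record, tmp_path):
        record, _ = small_record
        bad = [BeatAnnotation.from_symbol(5000, "N")]
        with pytest.raises(ValueError):
            write_record(record, bad, tmp_path)
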