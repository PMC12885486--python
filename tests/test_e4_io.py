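"""Device CSV reading, calibration, round-trips and stitching."""

import numpy as np
import pytest

from tremorindex.e4_io import (
    RawAccelRecording,
    count_samples_in,
    read_e4_acc,
    slice_recording,
    stitch,
    write_e4_acc,
)
from tremorindex.errors import (
    EmptyRecordingError,
    FormatError,
    IncompatibilityError,
    OverlapError,
)


def write_file(path, header=("1700000000", "32"), rows=((0, 0, 64),)):
    lines = list(header) + [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestRead:
    def test_counts_calibrated_to_g(self, tmp_path):
        f = write_file(tmp_path / "acc.csv", rows=[(0, 0, 64), (0, 0, 64)])
        rec = read_e4_acc(f)
        assert rec.start_epoch == 1700000000
        assert rec.fs == 32
        np.testing.assert_array_equal(rec.az, [1.0, 1.0])
        assert rec.n_samples == 2

    def test_sign_preserved(self, tmp_path):
        f = write_file(tmp_path / "acc.csv", rows=[(64, -64, 0)])
        rec = read_e4_acc(f)
        assert (rec.ax[0], rec.ay[0], rec.az[0]) == (1.0, -1.0, 0.0)

    @pytest.mark.parametrize(
        "header,rows,err",
        [
            (("not-a-number", "32"), [(0, 0, 0)], FormatError),
            (("1700000000", "zero"), [(0, 0, 0)], FormatError),
            (("1700000000", "32"), [(0, 0)], FormatError),
            (("1700000000", "32"), [(0, 0, 0, 0)], FormatError),
            (("1700000000", "32"), [], EmptyRecordingError),
        ],
    )
    def test_malformed_files_raise(self, tmp_path, header, rows, err):
        f = write_file(tmp_path / "bad.csv", header=header, rows=rows)
        with pytest.raises(err):
            read_e4_acc(f)

    def test_error_names_offending_row(self, tmp_path):
        f = write_file(tmp_path / "bad.csv", rows=[(0, 0, 0), (1, 2)])
        with pytest.raises(FormatError, match="row 4"):
            read_e4_acc(f)

    def test_round_trip_bit_exact(self, tmp_path, rng):
        counts = rng.integers(-128, 128, size=(100, 3))
        f = write_file(tmp_path / "acc.csv", rows=[tuple(r) for r in counts])
        rec = read_e4_acc(f)
        out = tmp_path / "out.csv"
        write_e4_acc(rec, out)
        rec2 = read_e4_acc(out)
        np.testing.assert_array_equal(rec.az, rec2.az)
        np.testing.assert_array_equal(rec.ax, rec2.ax)
        assert rec2.start_epoch == rec.start_epoch

    def test_calibration_linearity(self, tmp_path, rng):
        counts = rng.integers(-20, 20, size=(50, 3))
        f1 = write_file(tmp_path / "a.csv", rows=[tuple(r) for r in counts])
        f2 = write_file(tmp_path / "b.csv", rows=[tuple(3 * r) for r in counts])
        np.testing.assert_allclose(
            3 * read_e4_acc(f1).az, read_e4_acc(f2).az, rtol=0, atol=0
        )


class TestStitch:
    def make(self, start, dur, fs=32.0, hand="T"):
        n = int(dur * fs)
        z = np.arange(n, dtype=float)
        return RawAccelRecording(start, fs, np.zeros(n), np.zeros(n), z, hand)

    def test_abutting_files_have_no_gap(self):
        out = stitch([self.make(0, 3600), self.make(3600, 3600)])
        assert out.gaps == []
        assert out.n_samples == 2 * 3600 * 32

    def test_interval_recorded_as_gap(self):
        out = stitch([self.make(0, 3600), self.make(4200, 3600)])
        assert out.gaps == [(3600.0, 4200.0)]
        assert out.n_samples == 2 * 3600 * 32

    def test_order_invariance(self):
        parts = [self.make(0, 60), self.make(200, 60), self.make(100, 60)]
        a = stitch(parts)
        b = stitch(sorted(parts, key=lambda r: r.start_epoch))
        np.testing.assert_array_equal(a.az, b.az)
        assert a.gaps == b.gaps

    def test_never_fabricates_samples(self):
        parts = [self.make(0, 10), self.make(500, 20), self.make(1000, 30)]
        assert stitch(parts).n_samples == sum(p.n_samples for p in parts)

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            stitch([self.make(0, 3600), self.make(1800, 3600)])

    def test_mixed_rates_rejected(self):
        with pytest.raises(IncompatibilityError):
            stitch([self.make(0, 60), self.make(100, 60, fs=64.0)])


class TestSliceAndCount:
    def test_slice_respects_half_open_interval(self, make_recording):
        rec = make_recording(10.0, fs=4.0, start_epoch=100.0)
        part = slice_recording(rec, 102.0, 104.0)
        assert part.n_samples == 8
        assert part.start_epoch == 102.0

    def test_count_closed_interval(self, make_recording):
        rec = make_recording(10.0, fs=4.0, start_epoch=0.0)
        # samples at 2.0, 2.25, ..., 4.0 inclusive
        assert count_samples_in(rec, 2.0, 4.0) == 9

    def test_gap_chunks(self):
        n = 32 * 20
        rec = RawAccelRecording(
            0.0, 32.0, np.zeros(2 * n), np.zeros(2 * n), np.zeros(2 * n),
            "T", gaps=[(20.0, 50.0)],
        )
        chunks = rec.chunks()
        assert [(c[0], c[2] - c[1]) for c in chunks] == [(0.0, n), (50.0, n)]
        assert rec.end_epoch == 70.0
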