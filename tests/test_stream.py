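"""List-mode stream parsing, slicing, z reduction, rate maps and containers."""

import numpy as np
import pytest

from fastflim.decay import DecayModel, ParameterError
from fastflim.pileup import DetectionConfig
from fastflim.stream import (
    FRAME_TRIGGER,
    LINE_TRIGGER,
    PHOTON,
    PIXEL_TRIGGER,
    RECORD_DTYPE,
    DiscardReport,
    FLIMStack,
    ImagingLayout,
    StreamFormatError,
    StreamStructureError,
    check_stream_header,
    count_rate_map,
    make_records,
    parse_stream,
    read_stack,
    read_stream,
    reduce_z,
    slice_frames,
    write_stack,
    write_stream,
)
from fastflim.synth import generate_stream, make_scene


def _open_config():
    return DetectionConfig(td=0.0, mode="multi_hit", max_hits=10**9, window_pulses=1)


def _tiny_stream(n=4, **layout_kwargs):
    layout = ImagingLayout(n_pixels=n, T=12.5, k_bins=32, **layout_kwargs)
    scene = make_scene(
        {
            "shape": [n, n],
            "background": {"intensity": 20.0, "tau": 2.5},
        }
    )
    model = DecayModel(tau=2.5, T=12.5, k=32, p_pulse=1.0, irf_center=1.0, irf_sigma=0.1)
    records, truth = generate_stream(
        scene, layout, model, _open_config(), layout.active_frames, seed=17, dwell_periods=50
    )
    return records, truth, layout


class TestParseStream:
    def test_reconstruction_matches_ground_truth_exactly(self):
        records, truth, layout = _tiny_stream(4)
        stack, report = parse_stream(records, layout)
        assert np.array_equal(stack.intensity()[0, 0, 0], truth.detected)
        assert np.array_equal(stack.decay_plane(), truth.detected_hist[0])
        assert report.total == 0

    def test_offsets_are_skipped_and_reported(self):
        records, truth, layout = _tiny_stream(4, pixel_offset=1, line_offset=2, frame_offset=1)
        stack, report = parse_stream(records, layout)
        assert np.array_equal(stack.intensity()[0, 0, 0], truth.detected)
        n_photons = int(np.sum(records["kind"] == PHOTON))
        assert stack.total + report.total == n_photons

    def test_empty_stream_gives_zero_stack(self):
        layout = ImagingLayout(n_pixels=2, k_bins=16)
        rec = make_records(
            [0.0] + [10.0 * i for i in range(1, 7)],
            [FRAME_TRIGGER, LINE_TRIGGER, PIXEL_TRIGGER, PIXEL_TRIGGER,
             LINE_TRIGGER, PIXEL_TRIGGER, PIXEL_TRIGGER],
        )
        stack, report = parse_stream(rec, layout)
        assert stack.total == 0
        assert stack.counts.shape == (1, 1, 1, 1, 2, 2, 16)

    def test_photon_conservation_with_stray_photons(self):
        """Photons before the first frame and during retrace are counted, not lost."""
        layout = ImagingLayout(n_pixels=1, k_bins=16)
        rec = make_records(
            [0.5, 1.0, 2.0, 3.0, 3.5, 4.0],
            [PHOTON, FRAME_TRIGGER, LINE_TRIGGER, PIXEL_TRIGGER, PHOTON, PHOTON],
        )
        stack, report = parse_stream(rec, layout)
        assert report.before_first_frame == 1
        assert stack.total == 2
        assert stack.total + report.total == 3

    def test_trigger_surplus_raises_with_record_index(self):
        layout = ImagingLayout(n_pixels=1, k_bins=16)
        rec = make_records([0.0, 1.0, 2.0, 3.0], [FRAME_TRIGGER] * 4)
        with pytest.raises(StreamStructureError, match="record 1"):
            parse_stream(rec, layout)

    def test_trigger_deficit_raises(self):
        layout = ImagingLayout(n_pixels=1, k_bins=16, timepoints=3)
        rec = make_records([0.0, 1.0, 2.0], [FRAME_TRIGGER, LINE_TRIGGER, PIXEL_TRIGGER])
        with pytest.raises(StreamStructureError, match="deficit"):
            parse_stream(rec, layout)

    def test_non_monotone_timestamps_rejected(self):
        rec = make_records([1.0, 0.5], [FRAME_TRIGGER, PHOTON])
        with pytest.raises(StreamStructureError, match="non-monotone"):
            parse_stream(rec, ImagingLayout(n_pixels=1, k_bins=16))

    def test_out_of_range_channel_rejected(self):
        rec = make_records(
            [0.0, 1.0, 2.0, 2.5], [FRAME_TRIGGER, LINE_TRIGGER, PIXEL_TRIGGER, PHOTON],
            channels=[0, 0, 0, 3],
        )
        with pytest.raises(StreamStructureError, match="channel 3"):
            parse_stream(rec, ImagingLayout(n_pixels=1, k_bins=16, channels=1))

    def test_reparsing_is_idempotent(self):
        records, _, layout = _tiny_stream(3)
        stack1, _ = parse_stream(records, layout)
        stack2, _ = parse_stream(records, layout)
        assert np.array_equal(stack1.counts, stack2.counts)


class TestSliceFrames:
    def _three_frame_records(self):
        rows = []
        t = 0.0
        for _ in range(3):
            rows.append((t, FRAME_TRIGGER, 0))
            for _ in range(4):
                t += 1.0
                rows.append((t, PHOTON, 0))
            t += 1.0
        rec = np.array(rows, dtype=RECORD_DTYPE)
        return rec

    def test_partition_preserves_photons(self):
        rec = self._three_frame_records()
        slices = slice_frames(rec)
        assert len(slices) == 3
        total = sum(int(np.sum(b["kind"] == PHOTON)) for b in slices.buffers)
        assert total == int(np.sum(rec["kind"] == PHOTON))
        assert np.array_equal(np.concatenate(slices.buffers), rec)

    def test_duplicate_trigger_coalesced(self):
        rec = self._three_frame_records()
        dup = np.array([(rec["time"][0] + 0.01, FRAME_TRIGGER, 0)], dtype=RECORD_DTYPE)
        noisy = np.sort(np.concatenate([rec, dup]), order="time")
        slices = slice_frames(noisy, coalesce_tol=0.1)
        assert len(slices) == 3
        assert slices.coalesced_triggers == 1

    def test_missing_final_trigger_flags_partial_frame(self):
        layout = ImagingLayout(n_pixels=2, k_bins=16)
        rows = [(0.0, FRAME_TRIGGER, 0), (1.0, LINE_TRIGGER, 0), (2.0, LINE_TRIGGER, 0),
                (10.0, FRAME_TRIGGER, 0), (11.0, LINE_TRIGGER, 0)]  # second frame truncated
        rec = np.array(rows, dtype=RECORD_DTYPE)
        slices = slice_frames(rec, layout)
        assert slices.partial_last


class TestReduceZ:
    def _z_stack(self, nz=28):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, size=(1, 1, nz, 1, 2, 2, 8))
        return FLIMStack(counts, 12.5)

    def test_identity(self):
        stack = self._z_stack(4)
        out = reduce_z(stack, "stack", 1)
        assert np.array_equal(out.counts, stack.counts)

    def test_accumulate_conserves_photons(self):
        stack = self._z_stack(7)
        out = reduce_z(stack, "accumulate")
        assert out.counts.shape[2] == 1
        assert out.total == stack.total

    def test_downsample_group_sums(self):
        stack = self._z_stack(28)
        out = reduce_z(stack, "stack", 4)
        assert out.counts.shape[2] == 7
        for g in range(7):
            expected = stack.counts[:, :, 4 * g : 4 * g + 4].sum(axis=2)
            assert np.array_equal(out.counts[:, :, g], expected)


class TestCountRateMap:
    def test_uniform_rates(self):
        layout = ImagingLayout(n_pixels=4, duty_cycle=1.0, k_bins=8)
        counts = np.full((1, 1, 1, 1, 4, 4, 8), 5)
        stack = FLIMStack(counts, 12.5)
        rates = count_rate_map(stack, layout, frame_time=2.0)
        assert np.allclose(rates, 40 * 16 / 2.0)

    def test_duty_cycle_scaling(self):
        counts = np.full((1, 1, 1, 1, 4, 4, 8), 5)
        stack = FLIMStack(counts, 12.5)
        full = count_rate_map(stack, ImagingLayout(n_pixels=4, duty_cycle=1.0, k_bins=8), 2.0)
        partial = count_rate_map(stack, ImagingLayout(n_pixels=4, duty_cycle=0.65, k_bins=8), 2.0)
        assert np.allclose(partial, full / 0.65)

    def test_relative_dwell_map(self):
        counts = np.full((1, 1, 1, 1, 2, 2, 8), 5)
        stack = FLIMStack(counts, 12.5)
        layout = ImagingLayout(n_pixels=2, duty_cycle=1.0, k_bins=8)
        rel = np.ones((1, 1, 1, 1, 2, 2))
        rel[..., 0, 0] = 2.0
        rates = count_rate_map(stack, layout, 1.0, relative_dwell=rel)
        base = count_rate_map(stack, layout, 1.0)
        assert rates[0, 0, 0, 0, 0, 0] == pytest.approx(base[0, 0, 0, 0, 0, 0] / 2)


class TestContainers:
    def test_text_round_trip(self, tmp_path):
        records, _, layout = _tiny_stream(3)
        path = tmp_path / "stream.tsv"
        write_stream(path, records, T=layout.T, k=layout.k_bins, channels=1)
        back, header = read_stream(path)
        assert np.array_equal(back, records)
        assert header["T"] == layout.T and header["k"] == layout.k_bins

    def test_hdf5_round_trip_large(self, tmp_path):
        rng = np.random.default_rng(5)
        rec = np.zeros(10**6, dtype=RECORD_DTYPE)
        rec["time"] = np.sort(rng.random(10**6) * 1e6)
        rec["kind"] = PHOTON
        path = tmp_path / "stream.h5"
        write_stream(path, rec, T=12.5, k=128)
        back, header = read_stream(path)
        assert np.array_equal(back, rec)

    def test_empty_stream_file_round_trips(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_stream(path, np.zeros(0, dtype=RECORD_DTYPE), T=12.5, k=128)
        back, header = read_stream(path)
        assert back.size == 0
        assert header["channels"] == 1

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# fastflim-stream v1\n# T = 12.5\n# k = 8\n# channels = 1\n"
                        "1.0\tphoton\t0\nnot-a-row\n")
        with pytest.raises(StreamFormatError, match="line 6"):
            read_stream(path)

    def test_header_layout_mismatch_rejected(self):
        layout = ImagingLayout(n_pixels=2, k_bins=64)
        with pytest.raises(StreamFormatError):
            check_stream_header({"T": 12.5, "k": 128, "channels": 1}, layout)

    def test_stack_round_trip(self, tmp_path):
        records, _, layout = _tiny_stream(3)
        stack, _ = parse_stream(records, layout)
        path = tmp_path / "stack.h5"
        write_stack(path, stack)
        back = read_stack(path)
        assert np.array_equal(back.counts, stack.counts)
        assert back.T == stack.T
        assert back.dims == stack.dims
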