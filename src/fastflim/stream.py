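"""Time-tagged photon-stream data model and FLIM stack reconstruction.

A list-mode stream is a time-ordered sequence of records: photon detections
(with a detector channel) interleaved with pixel, line and frame trigger
records from the scan head.  Reconstruction slices the stream into frames,
assigns each photon to (timepoint, field of view, z, channel, y, x) via the
most recent enclosing triggers — after discarding the configured number of
offset (empty) pixels, lines and frames — and histograms its delay modulo
the laser period into a decay bin.  Photons arriving before the first valid
pixel or during scanner retrace are dropped and itemised in a discard
report; photon conservation (stream total = stack total + discards) holds
at every stage.

Scan convention: 0-based coordinates, x fastest.  A pixel trigger advances
x; a line trigger resets x and advances y; a frame trigger resets both and
advances the frame counter.  Frames map to dimensions z-fastest, then
timepoint, then field of view.  Scanning is unidirectional.

Streams round-trip through a columnar text container (one record per row:
time_ns, kind, channel, with ``# key = value`` header lines) or an HDF5
twin; stacks live in HDF5 with named axes and can be exported to TIFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import h5py
import numpy as np

from fastflim.decay import ParameterError

__all__ = [
    "PHOTON",
    "PIXEL_TRIGGER",
    "LINE_TRIGGER",
    "FRAME_TRIGGER",
    "RECORD_DTYPE",
    "make_records",
    "ImagingLayout",
    "FLIMStack",
    "DiscardReport",
    "StreamStructureError",
    "StreamFormatError",
    "parse_stream",
    "slice_frames",
    "FrameSlices",
    "reduce_z",
    "count_rate_map",
    "read_stream",
    "write_stream",
    "read_stack",
    "write_stack",
    "export_tiff",
]

# record kinds
PHOTON = 0
PIXEL_TRIGGER = 1
LINE_TRIGGER = 2
FRAME_TRIGGER = 3

_KIND_NAMES = {PHOTON: "photon", PIXEL_TRIGGER: "pixel", LINE_TRIGGER: "line", FRAME_TRIGGER: "frame"}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}

RECORD_DTYPE = np.dtype([("time", "f8"), ("kind", "i1"), ("channel", "i2")])

STACK_DIMS = ("timepoint", "fov", "z", "channel", "y", "x", "bin")


class StreamStructureError(ValueError):
    """Trigger sequence inconsistent with the imaging layout."""


class StreamFormatError(ValueError):
    """Malformed stream container (bad row, missing header, version mismatch)."""


def make_records(times, kinds, channels=None) -> np.ndarray:
    """Assemble a structured record array (not sorted; caller's order kept)."""
    times = np.asarray(times, dtype=float)
    rec = np.zeros(times.size, dtype=RECORD_DTYPE)
    rec["time"] = times
    rec["kind"] = kinds
    if channels is not None:
        rec["channel"] = channels
    return rec


@dataclass(frozen=True)
class ImagingLayout:
    """Geometry and histogramming parameters of a scanned acquisition.

    ``n_pixels`` is the image side (square images); the ``*_offset`` fields
    give the number of empty pixels/lines/frames emitted by the scan
    hardware before valid data, which are discarded on parsing.  ``T`` and
    ``k_bins`` set the decay histogramming; ``phase_offset`` (ns) shifts
    the reconstructed laser-pulse epoch for imported streams whose t = 0 is
    not pulse-aligned.
    """

    n_pixels: int = 256
    pixel_offset: int = 0
    line_offset: int = 0
    frame_offset: int = 0
    channels: int = 1
    z_sections: int = 1
    timepoints: int = 1
    fovs: int = 1
    z_mode: str = "stack"  # "stack" | "accumulate"
    z_downsample: int = 1
    duty_cycle: float = 1.0
    T: float = 12.5
    k_bins: int = 128
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ParameterError(f"n_pixels must be >= 1, got {self.n_pixels}")
        for name in ("pixel_offset", "line_offset", "frame_offset"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("channels", "z_sections", "timepoints", "fovs", "z_downsample"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ParameterError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if self.z_mode not in ("stack", "accumulate"):
            raise ParameterError(f"z_mode must be 'stack' or 'accumulate', got {self.z_mode!r}")
        if self.T <= 0 or self.k_bins < 2:
            raise ParameterError("require T > 0 and k_bins >= 2")

    @property
    def active_frames(self) -> int:
        """Number of data-bearing frames: z * timepoints * fovs."""
        return self.z_sections * self.timepoints * self.fovs

    @property
    def total_frames(self) -> int:
        return self.frame_offset + self.active_frames

    @property
    def lines_per_frame(self) -> int:
        return self.line_offset + self.n_pixels

    @property
    def pixels_per_line(self) -> int:
        return self.pixel_offset + self.n_pixels

    def frame_to_index(self, active_frame: int) -> Tuple[int, int, int]:
        """Map an active-frame counter to (timepoint, fov, z); z fastest."""
        z = active_frame % self.z_sections
        rest = active_frame // self.z_sections
        tp = rest % self.timepoints
        fov = rest // self.timepoints
        return tp, fov, z


@dataclass
class FLIMStack:
    """Multi-dimensional photon-count histogram.

    Axes (in order): timepoint, fov, z, channel, y, x, decay bin.
    """

    counts: np.ndarray
    T: float
    dims: Tuple[str, ...] = STACK_DIMS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != len(self.dims):
            raise ParameterError(
                f"counts has {self.counts.ndim} axes but dims names {len(self.dims)}"
            )
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[-1]

    @property
    def bin_width(self) -> float:
        return self.T / self.k

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def intensity(self) -> np.ndarray:
        """Photon totals with the decay axis summed out."""
        return self.counts.sum(axis=-1)

    def decay_plane(self, timepoint=0, fov=0, z=0, channel=0) -> np.ndarray:
        """A (y, x, bin) slice ready for phasor analysis."""
        return self.counts[timepoint, fov, z, channel]


@dataclass
class DiscardReport:
    """Photons dropped during parsing, itemised by cause."""

    before_first_frame: int = 0
    offset_frames: int = 0
    offset_lines: int = 0
    offset_pixels: int = 0
    retrace: int = 0
    after_last_frame: int = 0

    @property
    def total(self) -> int:
        return (
            self.before_first_frame
            + self.offset_frames
            + self.offset_lines
            + self.offset_pixels
            + self.retrace
            + self.after_last_frame
        )


def parse_stream(records: np.ndarray, layout: ImagingLayout) -> Tuple[FLIMStack, DiscardReport]:
    """Reconstruct a FLIM stack from a sorted record stream.

    Every photon is assigned by the most recent enclosing frame/line/pixel
    triggers; its decay bin is ``floor(((t - phase_offset) mod T) / (T/k))``.
    Raises :class:`StreamStructureError` on non-monotone timestamps or a
    trigger count inconsistent with the layout, naming the first offending
    record.
    """
    records = np.asarray(records)
    times = records["time"]
    if times.size > 1 and np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 1
        raise StreamStructureError(f"non-monotone timestamp at record {bad}")

    shape = (
        layout.timepoints,
        layout.fovs,
        layout.z_sections,
        layout.channels,
        layout.n_pixels,
        layout.n_pixels,
        layout.k_bins,
    )
    counts = np.zeros(shape, dtype=np.int64)
    report = DiscardReport()
    bw = layout.T / layout.k_bins

    frame_count = -1  # triggers seen - 1
    line_count = -1
    pixel_count = -1

    for idx in range(records.size):
        kind = records["kind"][idx]
        if kind == FRAME_TRIGGER:
            frame_count += 1
            if frame_count >= layout.total_frames:
                raise StreamStructureError(
                    f"frame trigger surplus at record {idx}: layout expects "
                    f"{layout.total_frames} frames"
                )
            line_count = -1
            pixel_count = -1
        elif kind == LINE_TRIGGER:
            if frame_count < 0:
                raise StreamStructureError(f"line trigger before any frame trigger at record {idx}")
            line_count += 1
            if line_count >= layout.lines_per_frame:
                raise StreamStructureError(
                    f"line trigger surplus at record {idx}: layout expects "
                    f"{layout.lines_per_frame} lines/frame"
                )
            pixel_count = -1
        elif kind == PIXEL_TRIGGER:
            if line_count < 0:
                raise StreamStructureError(f"pixel trigger before any line trigger at record {idx}")
            pixel_count += 1
            if pixel_count >= layout.pixels_per_line:
                raise StreamStructureError(
                    f"pixel trigger surplus at record {idx}: layout expects "
                    f"{layout.pixels_per_line} pixels/line"
                )
        elif kind == PHOTON:
            if frame_count < 0:
                report.before_first_frame += 1
                continue
            af = frame_count - layout.frame_offset
            if af < 0:
                report.offset_frames += 1
                continue
            y = line_count - layout.line_offset
            if y < 0:
                report.offset_lines += 1
                continue
            x = pixel_count - layout.pixel_offset
            if x < 0:
                report.offset_pixels += 1
                continue
            if x >= layout.n_pixels or y >= layout.n_pixels:
                report.retrace += 1
                continue
            ch = int(records["channel"][idx])
            if not 0 <= ch < layout.channels:
                raise StreamStructureError(
                    f"photon channel {ch} outside layout channels at record {idx}"
                )
            tp, fov, z = layout.frame_to_index(af)
            b = int(((times[idx] - layout.phase_offset) % layout.T) / bw)
            if b >= layout.k_bins:
                b = layout.k_bins - 1
            counts[tp, fov, z, ch, y, x, b] += 1
        else:
            raise StreamFormatError(f"unknown record kind {kind} at record {idx}")

    if frame_count + 1 < layout.total_frames:
        raise StreamStructureError(
            f"frame trigger deficit: saw {frame_count + 1}, layout expects {layout.total_frames}"
        )
    stack = FLIMStack(counts, layout.T, metadata={"layout": layout})
    return stack, report


@dataclass
class FrameSlices:
    """Per-frame record buffers produced by :func:`slice_frames`."""

    buffers: List[np.ndarray]
    partial_last: bool = False
    coalesced_triggers: int = 0

    def __len__(self) -> int:
        return len(self.buffers)


def slice_frames(
    records: np.ndarray,
    layout: Optional[ImagingLayout] = None,
    coalesce_tol: float = 0.0,
) -> FrameSlices:
    """Partition a stream into per-frame record buffers.

    Each buffer starts at a frame trigger and runs to the next one; the
    concatenation of the buffers reproduces the record subsequence from the
    first frame trigger onward exactly.  Frame triggers duplicated within
    ``coalesce_tol`` ns (e.g. the hardware's spare-channel copy) are merged
    into a single boundary rather than opening an empty phantom frame.  If a
    layout is given, the last frame is flagged partial when it contains
    fewer line triggers than the layout requires (missing final trigger).
    """
    records = np.asarray(records)
    is_frame = records["kind"] == FRAME_TRIGGER
    boundaries = np.nonzero(is_frame)[0]
    coalesced = 0
    if boundaries.size and coalesce_tol > 0:
        keep = [boundaries[0]]
        for b in boundaries[1:]:
            if records["time"][b] - records["time"][keep[-1]] <= coalesce_tol:
                coalesced += 1
            else:
                keep.append(b)
        boundaries = np.asarray(keep)
    buffers = [
        records[start:stop]
        for start, stop in zip(boundaries, list(boundaries[1:]) + [records.size])
    ]
    partial = False
    if layout is not None and buffers:
        n_lines = int(np.sum(buffers[-1]["kind"] == LINE_TRIGGER))
        partial = n_lines < layout.lines_per_frame
    return FrameSlices(buffers=buffers, partial_last=partial, coalesced_triggers=coalesced)


def reduce_z(stack: FLIMStack, mode: str, downsample: int = 1) -> FLIMStack:
    """Collapse or downsample the z axis.

    ``mode="accumulate"`` sums all sections into one (extended focus);
    ``mode="stack"`` sums consecutive groups of ``downsample`` sections
    (group anchored at index 0; a trailing partial group is kept).
    """
    z_axis = stack.dims.index("z")
    if mode == "accumulate":
        counts = stack.counts.sum(axis=z_axis, keepdims=True)
    elif mode == "stack":
        if downsample < 1:
            raise ParameterError(f"downsample must be >= 1, got {downsample}")
        if downsample == 1:
            counts = stack.counts
        else:
            nz = stack.counts.shape[z_axis]
            groups = [
                stack.counts.take(range(i, min(i + downsample, nz)), axis=z_axis).sum(
                    axis=z_axis, keepdims=True
                )
                for i in range(0, nz, downsample)
            ]
            counts = np.concatenate(groups, axis=z_axis)
    else:
        raise ParameterError(f"mode must be 'accumulate' or 'stack', got {mode!r}")
    return FLIMStack(counts, stack.T, stack.dims, dict(stack.metadata))


def count_rate_map(
    stack: FLIMStack,
    layout: ImagingLayout,
    frame_time: float,
    relative_dwell: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-pixel count-rate map in Hz.

    The effective pixel dwell time is ``frame_time * duty_cycle /
    n_pixels**2`` seconds, optionally scaled by a per-pixel relative-dwell
    map for scanners with inhomogeneous dwell across the field.
    """
    if frame_time <= 0:
        raise ParameterError(f"frame_time must be > 0, got {frame_time}")
    dwell = frame_time * layout.duty_cycle / layout.n_pixels**2
    rates = stack.intensity() / dwell
    if relative_dwell is not None:
        relative_dwell = np.asarray(relative_dwell, dtype=float)
        if np.any(relative_dwell <= 0):
            raise ParameterError("relative_dwell must be positive everywhere")
        rates = rates / relative_dwell
    return rates


# ---------------------------------------------------------------------------
# Containers

_STREAM_VERSION = "1"


def write_stream(path, records: np.ndarray, T: float, k: int, channels: int = 1, **meta) -> None:
    """Write a record stream; HDF5 when the suffix is .h5/.hdf5, else text."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("records", data=np.asarray(records))
            ds.attrs["version"] = _STREAM_VERSION
            ds.attrs["T"] = T
            ds.attrs["k"] = k
            ds.attrs["channels"] = channels
            for key, value in meta.items():
                ds.attrs[key] = value
        return
    with path.open("w") as fh:
        fh.write(f"# fastflim-stream v{_STREAM_VERSION}\n")
        fh.write(f"# T = {T!r}\n# k = {k}\n# channels = {channels}\n")
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        fh.write("# time_ns\tkind\tchannel\n")
        for rec in np.asarray(records):
            fh.write(f"{float(rec['time'])!r}\t{_KIND_NAMES[int(rec['kind'])]}\t{int(rec['channel'])}\n")


def read_stream(path) -> Tuple[np.ndarray, dict]:
    """Read a stream container; returns (records, header dict with T/k/channels)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["records"]
            if str(ds.attrs.get("version")) != _STREAM_VERSION:
                raise StreamFormatError(
                    f"{path}: unsupported stream version {ds.attrs.get('version')!r}"
                )
            header = {key: ds.attrs[key] for key in ds.attrs if key != "version"}
            header["T"] = float(header["T"])
            header["k"] = int(header["k"])
            header["channels"] = int(header.get("channels", 1))
            return ds[()].astype(RECORD_DTYPE), header
    header: dict = {}
    rows: List[Tuple[float, int, int]] = []
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# fastflim-stream"):
            raise StreamFormatError(f"{path}: not a fastflim stream (missing magic line)")
        if not first.endswith(f"v{_STREAM_VERSION}"):
            raise StreamFormatError(f"{path}: unsupported stream version in {first!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[1] not in _KIND_CODES:
                raise StreamFormatError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                rows.append((float(parts[0]), _KIND_CODES[parts[1]], int(parts[2])))
            except ValueError as exc:
                raise StreamFormatError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
    for key in ("T", "k", "channels"):
        if key not in header:
            raise StreamFormatError(f"{path}: missing '{key}' header")
    header["T"] = float(header["T"])
    header["k"] = int(header["k"])
    header["channels"] = int(header["channels"])
    rec = np.zeros(len(rows), dtype=RECORD_DTYPE)
    for i, (t, kd, ch) in enumerate(rows):
        rec[i] = (t, kd, ch)
    return rec, header


def check_stream_header(header: dict, layout: ImagingLayout) -> None:
    """Raise when a stream's histogramming header disagrees with the layout."""
    if not math.isclose(header["T"], layout.T, rel_tol=1e-12):
        raise StreamFormatError(f"stream T={header['T']} != layout T={layout.T}")
    if header["k"] != layout.k_bins:
        raise StreamFormatError(f"stream k={header['k']} != layout k_bins={layout.k_bins}")


def write_stack(path, stack: FLIMStack) -> None:
    """Write a FLIM stack to HDF5 with named axes."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("counts", data=stack.counts, compression="gzip")
        ds.attrs["dims"] = ",".join(stack.dims)
        ds.attrs["T"] = stack.T
        ds.attrs["bin_width"] = stack.bin_width


def read_stack(path) -> FLIMStack:
    with h5py.File(path, "r") as fh:
        ds = fh["counts"]
        dims = tuple(str(ds.attrs["dims"]).split(","))
        return FLIMStack(ds[()], float(ds.attrs["T"]), dims)


def export_tiff(path, image: np.ndarray) -> None:
    """Export an intensity or lifetime map as single-precision TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
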