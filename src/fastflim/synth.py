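"""Synthetic scenes and time-tagged streams standing in for the microscope.

Scenes assign each pixel (per detector channel) an expected photon yield
per frame and a mono- or bi-exponential decay; a FRET-pair scene carries
complementary amplitude fractions on the donor and acceptor channels.
``generate_stream`` renders a scene into a list-mode record stream: per
pixel dwell the photon count is Poisson, arrival phases are drawn from the
pixel's IRF-convolved decay on the T/k grid (so reconstruction is exact on
the same grid), detection rules (dead-time, single- or multi-hit) are
applied per pixel, and pixel/line/frame triggers with the configured
offsets are emitted around the photons.  Ground-truth bookkeeping (emitted
and detected photons per pixel, per frame, and the folded decay histograms)
accompanies every stream so conservation is checkable at every stage.

Pixel dwell is an integer number of laser periods and the retrace gap is
rounded to whole periods, keeping the pulse phase of every photon exact.
Motion (linear drift or a Brownian walk of whole-pixel steps) is applied
between frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from fastflim.decay import (
    DecayHistogram,
    DecayModel,
    ParameterError,
    convolve_irf,
    decay_pdf,
    fold_times,
)
from fastflim.pileup import DetectionConfig, apply_detection
from fastflim.stream import (
    FRAME_TRIGGER,
    LINE_TRIGGER,
    PHOTON,
    PIXEL_TRIGGER,
    RECORD_DTYPE,
    ImagingLayout,
)

__all__ = [
    "Motion",
    "Scene",
    "GroundTruth",
    "make_scene",
    "generate_stream",
    "dwell_periods_from_frame_time",
    "emulate_retrigger_irf",
]


@dataclass(frozen=True)
class Motion:
    """Inter-frame object motion: linear drift or a Brownian pixel walk."""

    kind: str = "linear"  # "linear" | "brownian"
    dx_per_frame: float = 0.0
    dy_per_frame: float = 0.0
    step_px: float = 0.0  # Brownian step std dev, pixels/frame

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "brownian"):
            raise ParameterError(f"motion kind must be 'linear' or 'brownian', got {self.kind!r}")


@dataclass
class Scene:
    """Per-pixel photon yields and decay parameters, per channel.

    All arrays have shape (channels, ny, nx).  ``frac_a`` is the amplitude
    fraction of the ``tau_a`` component; the ``tau_b`` component carries
    ``1 - frac_a`` (set ``frac_a = 1`` for mono-exponential pixels).
    """

    intensity: np.ndarray  # expected photons per pixel per frame
    tau_a: np.ndarray
    tau_b: np.ndarray
    frac_a: np.ndarray
    motion: Optional[Motion] = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.intensity, self.tau_a, self.tau_b, self.frac_a)}
        if len(shapes) != 1 or self.intensity.ndim != 3:
            raise ParameterError("scene arrays must share one (channels, ny, nx) shape")
        if np.any(self.intensity < 0):
            raise ParameterError("intensities must be >= 0")
        if np.any((self.frac_a < 0) | (self.frac_a > 1)):
            raise ParameterError("amplitude fractions must be in [0, 1]")
        if np.any(self.tau_a <= 0) or np.any(self.tau_b <= 0):
            raise ParameterError("lifetimes must be > 0")

    @property
    def channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape[1:]

    def shifted(self, dx: int, dy: int) -> "Scene":
        """Scene with all maps rolled by whole pixels (periodic boundary)."""
        roll = lambda a: np.roll(np.roll(a, dy, axis=1), dx, axis=2)
        return Scene(
            intensity=roll(self.intensity),
            tau_a=roll(self.tau_a),
            tau_b=roll(self.tau_b),
            frac_a=roll(self.frac_a),
            motion=self.motion,
        )


def make_scene(spec: Dict) -> Scene:
    """Build a scene from a declarative specification.

    Schema (all lifetimes in ns, intensities in expected photons per pixel
    per frame)::

        {"shape": [ny, nx], "channels": 1,
         "background": {"intensity": 0.0, "tau": 2.5},
         "regions": [
            {"kind": "rect", "y0": 0, "y1": 8, "x0": 0, "x1": 8,
             "intensity": 40, "tau": 3.0},
            {"kind": "disk", "cy": 12, "cx": 12, "r": 3,
             "intensity": 40, "tau_a": 1.0, "tau_b": 3.0, "frac_a": 0.6},
         ],
         "fret": false,
         "motion": {"kind": "linear", "dx_per_frame": 1.0}}

    Regions are painted in order (later regions overwrite).  A region may
    give a single ``tau`` or a (``tau_a``, ``tau_b``, ``frac_a``) mixture
    and may restrict itself to one ``channel``.  With ``"fret": true`` and
    two channels, a region's ``frac_a`` applies to channel 0 and the
    complementary fraction ``1 - frac_a`` to channel 1 (donor/acceptor
    bookkeeping of a FRET pair).
    """
    ny, nx = spec["shape"]
    channels = int(spec.get("channels", 1))
    bg = spec.get("background", {})
    fret = bool(spec.get("fret", False))
    if fret and channels != 2:
        raise ParameterError("fret scenes require exactly 2 channels")

    def _tau_triplet(d: Dict, default_tau: float = 2.5):
        if "tau" in d:
            return float(d["tau"]), float(d["tau"]), 1.0
        if "tau_a" in d:
            return float(d["tau_a"]), float(d["tau_b"]), float(d.get("frac_a", 0.5))
        return default_tau, default_tau, 1.0

    ta0, tb0, fa0 = _tau_triplet(bg)
    intensity = np.full((channels, ny, nx), float(bg.get("intensity", 0.0)))
    tau_a = np.full((channels, ny, nx), ta0)
    tau_b = np.full((channels, ny, nx), tb0)
    frac_a = np.full((channels, ny, nx), fa0)
    if fret:
        frac_a[1] = 1.0 - fa0

    yy, xx = np.mgrid[0:ny, 0:nx]
    for region in spec.get("regions", []):
        kind = region.get("kind", "rect")
        if kind == "rect":
            mask = (
                (yy >= region["y0"]) & (yy < region["y1"])
                & (xx >= region["x0"]) & (xx < region["x1"])
            )
        elif kind == "disk":
            mask = (yy - region["cy"]) ** 2 + (xx - region["cx"]) ** 2 <= region["r"] ** 2
        else:
            raise ParameterError(f"unknown region kind {kind!r}")
        ta, tb, fa = _tau_triplet(region)
        chans = [int(region["channel"])] if "channel" in region else list(range(channels))
        for ch in chans:
            intensity[ch][mask] = float(region.get("intensity", 0.0))
            tau_a[ch][mask] = ta
            tau_b[ch][mask] = tb
            frac_a[ch][mask] = (1.0 - fa) if (fret and ch == 1) else fa

    motion = None
    if "motion" in spec:
        motion = Motion(**spec["motion"])
    return Scene(intensity=intensity, tau_a=tau_a, tau_b=tau_b, frac_a=frac_a, motion=motion)


@dataclass
class GroundTruth:
    """Exact per-pixel bookkeeping for a generated stream.

    ``emitted``/``detected``: photon counts per (channel, y, x) summed over
    frames; ``per_frame_detected``: counts per (frame, channel, y, x);
    ``detected_hist``: folded decay histograms per (channel, y, x, bin) on
    the same T/k grid the reconstruction uses.
    """

    emitted: np.ndarray
    detected: np.ndarray
    per_frame_detected: np.ndarray
    detected_hist: np.ndarray
    dwell_periods: int
    seed: int

    @property
    def suppressed(self) -> np.ndarray:
        """Photons lost to the detection rules, per pixel."""
        return self.emitted - self.detected


def dwell_periods_from_frame_time(frame_time_s: float, layout: ImagingLayout) -> int:
    """Pixel dwell in laser periods nearest to frame_time*duty/n_pixels**2."""
    dwell_s = frame_time_s * layout.duty_cycle / layout.n_pixels**2
    return max(1, int(round(dwell_s / (layout.T * 1e-9))))


def _mixture_probs(
    tau_a: float, tau_b: float, frac_a: float, model: DecayModel
) -> np.ndarray:
    """Unit-mass binned mixture decay with the model's IRF applied."""
    pdf_a = decay_pdf(model.with_(tau=tau_a, p_pulse=1.0)).counts
    if frac_a >= 1.0:
        mix = pdf_a
    else:
        pdf_b = decay_pdf(model.with_(tau=tau_b, p_pulse=1.0)).counts
        mix = frac_a * pdf_a + (1.0 - frac_a) * pdf_b
    hist = DecayHistogram(mix, model.T)
    if model.has_irf:
        hist = convolve_irf(hist, model.irf_center, model.irf_sigma)
    return hist.counts / hist.counts.sum()


def generate_stream(
    scene: Scene,
    layout: ImagingLayout,
    model: DecayModel,
    config: DetectionConfig,
    n_frames: int,
    seed: int,
    dwell_periods: int = 200,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render a scene into a time-tagged record stream with ground truth.

    ``model`` supplies the laser period, bin count and IRF (its ``tau`` and
    ``p_pulse`` are ignored; the scene sets per-pixel decays and yields).
    Offsets declared in the layout are emitted as empty pixels/lines/frames
    so the stream exercises the parser's discard logic.  Dead-time is
    applied within each pixel dwell (dwells are separated by retrace gaps
    much longer than any realistic dead-time).
    """
    ny, nx = scene.shape
    if (ny, nx) != (layout.n_pixels, layout.n_pixels):
        raise ParameterError(
            f"scene shape {scene.shape} != layout image {layout.n_pixels}x{layout.n_pixels}"
        )
    if scene.channels != layout.channels:
        raise ParameterError("scene channels != layout channels")
    if n_frames != layout.active_frames:
        raise ParameterError(
            f"n_frames={n_frames} must equal layout.active_frames={layout.active_frames}"
        )
    rng = np.random.default_rng(seed)
    T = layout.T
    k = layout.k_bins
    bw = T / k
    base = model.with_(T=T, k=k)

    # retrace after each line, rounded to whole periods to keep pulse phase exact
    line_active_periods = layout.pixels_per_line * dwell_periods
    retrace_periods = int(round(line_active_periods * (1.0 / layout.duty_cycle - 1.0)))

    pdf_cache: Dict[Tuple[float, float, float], np.ndarray] = {}

    times: List[np.ndarray] = []
    kinds: List[np.ndarray] = []
    chans: List[np.ndarray] = []

    emitted = np.zeros((scene.channels, ny, nx), dtype=np.int64)
    detected = np.zeros_like(emitted)
    per_frame = np.zeros((n_frames, scene.channels, ny, nx), dtype=np.int64)
    det_hist = np.zeros((scene.channels, ny, nx, k), dtype=np.int64)

    def _emit(t, kind, ch=0):
        times.append(np.atleast_1d(np.asarray(t, dtype=float)))
        n = times[-1].size
        kinds.append(np.full(n, kind, dtype=np.int8))
        chans.append(np.full(n, ch, dtype=np.int16) if np.isscalar(ch) else np.asarray(ch, dtype=np.int16))

    period = 0  # global clock in laser periods
    frame_scene = scene
    offset_x = offset_y = 0.0
    for f in range(layout.total_frames):
        _emit(period * T, FRAME_TRIGGER)
        af = f - layout.frame_offset
        active = af >= 0
        if active and af > 0 and scene.motion is not None:
            m = scene.motion
            if m.kind == "linear":
                offset_x += m.dx_per_frame
                offset_y += m.dy_per_frame
            else:
                offset_x += rng.normal(0.0, m.step_px)
                offset_y += rng.normal(0.0, m.step_px)
            frame_scene = scene.shifted(int(round(offset_x)), int(round(offset_y)))
        for line in range(layout.lines_per_frame):
            _emit(period * T, LINE_TRIGGER)
            y = line - layout.line_offset
            for px in range(layout.pixels_per_line):
                t0 = period * T
                _emit(t0, PIXEL_TRIGGER)
                x = px - layout.pixel_offset
                if active and 0 <= y < ny and 0 <= x < nx:
                    for ch in range(scene.channels):
                        mean = frame_scene.intensity[ch, y, x]
                        if mean <= 0:
                            continue
                        n_phot = int(rng.poisson(mean))
                        if n_phot == 0:
                            continue
                        key = (
                            float(frame_scene.tau_a[ch, y, x]),
                            float(frame_scene.tau_b[ch, y, x]),
                            float(frame_scene.frac_a[ch, y, x]),
                        )
                        probs = pdf_cache.get(key)
                        if probs is None:
                            probs = _mixture_probs(*key, base)
                            pdf_cache[key] = probs
                        bins = rng.choice(k, size=n_phot, p=probs)
                        pulses = rng.integers(0, dwell_periods, size=n_phot)
                        t_phot = np.sort(t0 + pulses * T + bins * bw)
                        kept = apply_detection(t_phot, config, T)
                        emitted[ch, y, x] += n_phot
                        detected[ch, y, x] += kept.size
                        per_frame[af, ch, y, x] += kept.size
                        kept_bins = np.floor((kept % T) / bw).astype(np.int64)
                        np.clip(kept_bins, 0, k - 1, out=kept_bins)
                        det_hist[ch, y, x] += np.bincount(kept_bins, minlength=k)
                        if kept.size:
                            _emit(kept, PHOTON, np.full(kept.size, ch, dtype=np.int16))
                period += dwell_periods
            period += retrace_periods

    all_times = np.concatenate(times)
    all_kinds = np.concatenate(kinds)
    all_chans = np.concatenate(chans)
    # stable order: at equal times triggers precede photons (frame<line<pixel<photon)
    order = np.lexsort((np.where(all_kinds == PHOTON, 4, 4 - all_kinds), all_times))
    records = np.zeros(all_times.size, dtype=RECORD_DTYPE)
    records["time"] = all_times[order]
    records["kind"] = all_kinds[order]
    records["channel"] = all_chans[order]
    truth = GroundTruth(
        emitted=emitted,
        detected=detected,
        per_frame_detected=per_frame,
        detected_hist=det_hist,
        dwell_periods=dwell_periods,
        seed=seed,
    )
    return records, truth


def emulate_retrigger_irf(
    model: DecayModel, divider: int, n_pulses: int, seed: int
) -> DecayHistogram:
    """IRF trace of a retriggered TDC: one peak per pulse of the window.

    A frequency divider restarts the timer only every ``divider`` laser
    periods, so histogramming a near-zero-lifetime emitter against the
    retrigger epoch shows ``divider`` equally spaced copies of the IRF,
    one per laser pulse in the window.  Returns a histogram spanning
    ``divider * T`` with ``divider * k`` bins.
    """
    if divider < 1:
        raise ParameterError(f"divider must be >= 1, got {divider}")
    from fastflim.decay import sample_arrival_times

    times = sample_arrival_times(model, n_pulses, seed)
    return fold_times(times, divider * model.T, divider * model.k)
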