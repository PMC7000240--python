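"""Analytic fluorescence-decay model under periodic pulsed excitation.

A mode-locked laser excites the sample every ``T`` nanoseconds and the decay
is histogrammed into ``k`` uniform bins spanning one period.  For a
mono-exponential emitter with lifetime ``tau`` the per-bin detection
probability follows the Köllner–Wolfrum form of the wrapped exponential,
scaled by ``p_pulse``, the probability of detecting one photon per laser
period::

    pdf(t_i) = p_pulse * exp(-i*T/(k*tau)) * (exp(T/(k*tau)) - 1) / (1 - exp(-T/tau))

with bins indexed ``i = 1..k``; bin ``i`` covers ``[(i-1)*T/k, i*T/k)`` and
times are reported at bin left edges.  The per-bin masses sum exactly to
``p_pulse``.  A Gaussian instrument response function (IRF) is applied by
circular convolution over the period: under periodic excitation the
pre-pulse tail of the response wraps around.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ParameterError",
    "DecayModel",
    "DecayHistogram",
    "decay_pdf",
    "convolve_irf",
    "sample_arrival_times",
    "fold_times",
    "gaussian_fwhm",
    "read_histogram",
    "write_histogram",
]

#: FWHM of a Gaussian with unit standard deviation.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class ParameterError(ValueError):
    """A model or instrument parameter is non-finite or out of range."""


def gaussian_fwhm(sigma: float) -> float:
    """Full width at half maximum of a Gaussian, ``2*sqrt(2*ln 2)*sigma``."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    return _FWHM_PER_SIGMA * sigma


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class DecayModel:
    """Mono-exponential decay under periodic excitation.

    Parameters
    ----------
    tau
        Fluorescence lifetime in nanoseconds.
    T
        Laser period in nanoseconds (12.5 ns for an 80 MHz source).
    k
        Number of histogram bins spanning one period.
    p_pulse
        Probability of detecting one photon per laser period (``P_N``),
        in ``[0, 1]``.
    irf_center, irf_sigma
        Center and standard deviation (ns) of the Gaussian instrument
        response function, or ``None`` for an ideal delta response.
    """

    tau: float
    T: float
    k: int
    p_pulse: float = 1.0
    irf_center: Optional[float] = None
    irf_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tau", "T", "p_pulse"):
            _require_finite(name, getattr(self, name))
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if self.T <= 0:
            raise ParameterError(f"T must be > 0, got {self.T}")
        if int(self.k) != self.k or self.k < 2:
            raise ParameterError(f"k must be an integer >= 2, got {self.k}")
        if not 0.0 <= self.p_pulse <= 1.0:
            raise ParameterError(f"p_pulse must be in [0, 1], got {self.p_pulse}")
        if (self.irf_center is None) != (self.irf_sigma is None):
            raise ParameterError("irf_center and irf_sigma must be set together")
        if self.irf_sigma is not None:
            _require_finite("irf_center", self.irf_center)  # type: ignore[arg-type]
            _require_finite("irf_sigma", self.irf_sigma)
            if self.irf_sigma < 0:
                raise ParameterError(f"irf_sigma must be >= 0, got {self.irf_sigma}")

    @property
    def bin_width(self) -> float:
        """Bin width ``T/k`` in nanoseconds."""
        return self.T / self.k

    @property
    def has_irf(self) -> bool:
        return self.irf_sigma is not None

    def with_(self, **changes) -> "DecayModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Paper-style instrument defaults: 80 MHz excitation, 128 bins, 3 ns dye,
#: Gaussian IRF centred at 1 ns with 0.1 ns standard deviation.
DEFAULT_MODEL = DecayModel(tau=3.0, T=12.5, k=128, p_pulse=0.01, irf_center=1.0, irf_sigma=0.1)


@dataclass
class DecayHistogram:
    """Binned photon counts (or probability mass) over one laser period."""

    counts: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ParameterError("counts must be a 1-D array of length >= 2")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ParameterError("counts must be finite and non-negative")
        if self.T <= 0:
            raise ParameterError(f"T must be > 0, got {self.T}")

    @property
    def k(self) -> int:
        return self.counts.size

    @property
    def bin_width(self) -> float:
        return self.T / self.k

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_left_edges(self) -> np.ndarray:
        return np.arange(self.k) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.k) + 0.5) * self.bin_width


def decay_pdf(model: DecayModel) -> DecayHistogram:
    """Per-bin detection probability of the wrapped exponential decay.

    Returns a histogram whose ``k`` masses sum to ``model.p_pulse``.  IRF
    fields of the model are ignored here; apply :func:`convolve_irf` to the
    result for a realistic response.
    """
    x = model.T / (model.k * model.tau)  # bin width in lifetime units
    i = np.arange(1, model.k + 1, dtype=float)
    with np.errstate(over="raise"):
        mass = model.p_pulse * np.exp(-i * x) * math.expm1(x) / (-math.expm1(-model.T / model.tau))
    return DecayHistogram(mass, model.T)


def _gaussian_kernel(k: int, bin_width: float, center: float, sigma: float) -> np.ndarray:
    """Periodic Gaussian kernel sampled on the bin grid, normalised to 1."""
    T = k * bin_width
    offsets = np.arange(k) * bin_width - center
    # wrap enough periods to capture the tails of wide kernels
    n_wrap = max(1, int(math.ceil(4.0 * sigma / T)) + 1)
    m = np.arange(-n_wrap, n_wrap + 1)[:, None]
    kernel = np.exp(-0.5 * ((offsets[None, :] + m * T) / sigma) ** 2).sum(axis=0)
    return kernel / kernel.sum()


def convolve_irf(pdf: DecayHistogram, irf_center: float, irf_sigma: float) -> DecayHistogram:
    """Circularly convolve a decay histogram with a Gaussian IRF.

    The convolution is circular over the laser period (periodic excitation
    wraps the pre-pulse tail).  Total mass is preserved.  With
    ``irf_sigma == 0`` the kernel degenerates to a delta and the histogram is
    circularly shifted by ``round(irf_center / bin_width)`` bins.
    """
    if irf_sigma < 0:
        raise ParameterError(f"irf_sigma must be >= 0, got {irf_sigma}")
    if irf_sigma == 0:
        shift = int(round(irf_center / pdf.bin_width)) % pdf.k
        return DecayHistogram(np.roll(pdf.counts, shift), pdf.T)
    kernel = _gaussian_kernel(pdf.k, pdf.bin_width, irf_center, irf_sigma)
    out = np.real(np.fft.ifft(np.fft.fft(pdf.counts) * np.fft.fft(kernel)))
    out = np.clip(out, 0.0, None)  # FFT round-off can leave tiny negatives
    out *= pdf.counts.sum() / out.sum()
    return DecayHistogram(out, pdf.T)


def model_pdf(model: DecayModel) -> DecayHistogram:
    """Decay pdf with the model's IRF applied (if any)."""
    pdf = decay_pdf(model)
    if model.has_irf:
        pdf = convolve_irf(pdf, model.irf_center, model.irf_sigma)  # type: ignore[arg-type]
    return pdf


def sample_arrival_times(
    model: DecayModel,
    n_pulses: int,
    seed: int,
    *,
    chunk_pulses: int = 100_000,
) -> np.ndarray:
    """Monte Carlo photon arrival times over a train of laser pulses.

    Per time step of width ``T/k`` an independent uniform draw in (0, 1)
    decides whether a photon arrives: a photon is triggered in bin ``i`` of
    pulse ``p`` when ``pdf_i >= u``.  Arrival times are reported at bin left
    edges, ``p*T + (i-1)*T/k``.  The expected photon count is
    ``n_pulses * p_pulse`` as long as every bin mass is <= 1; any bin mass
    above 1 is clipped to 1 with a warning (the draw rule cannot produce
    more than one photon per time step).

    Deterministic for a given ``seed``; returns a sorted float64 array of
    absolute times in nanoseconds.
    """
    if n_pulses < 1:
        raise ParameterError(f"n_pulses must be >= 1, got {n_pulses}")
    probs = model_pdf(model).counts
    if np.any(probs > 1.0):
        warnings.warn(
            "per-bin probability exceeds 1; clipping (the one-photon-per-step "
            "draw rule saturates)",
            RuntimeWarning,
            stacklevel=2,
        )
        probs = np.clip(probs, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    bw = model.bin_width
    out = []
    for start in range(0, n_pulses, chunk_pulses):
        n = min(chunk_pulses, n_pulses - start)
        hits = rng.random((n, model.k)) < probs
        pulse, binidx = np.nonzero(hits)
        out.append((start + pulse) * model.T + binidx * bw)
    times = np.concatenate(out) if out else np.empty(0)
    return times  # already sorted: chunks are ordered, rows ordered, bins ordered


def fold_times(times: np.ndarray, T: float, k: int, phase_offset: float = 0.0) -> DecayHistogram:
    """Histogram absolute photon times modulo the laser period.

    Bin ``i`` (0-based) collects times with ``(t - phase_offset) mod T`` in
    ``[i*T/k, (i+1)*T/k)``.
    """
    times = np.asarray(times, dtype=float)
    idx = np.floor(((times - phase_offset) % T) / (T / k)).astype(np.int64)
    np.clip(idx, 0, k - 1, out=idx)
    return DecayHistogram(np.bincount(idx, minlength=k).astype(float), T)


# ---------------------------------------------------------------------------
# Columnar text I/O: two columns (bin_index, counts) with '# key = value'
# header lines carrying T and free-form metadata.

def write_histogram(path, hist: DecayHistogram, **metadata) -> None:
    """Write a decay histogram as two-column delimited text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# fastflim-histogram v1\n")
        fh.write(f"# T = {hist.T!r}\n")
        fh.write(f"# k = {hist.k}\n")
        for key, value in metadata.items():
            fh.write(f"# {key} = {value}\n")
        fh.write("# bin_index\tcounts\n")
        for i, c in enumerate(hist.counts, start=1):
            fh.write(f"{i}\t{float(c)!r}\n")


def read_histogram(path) -> tuple[DecayHistogram, dict]:
    """Read a histogram written by :func:`write_histogram`.

    Returns the histogram and a dict of header metadata (string-valued,
    except ``T`` and ``k`` which are parsed).
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParameterError(f"{path}: malformed row at line {lineno}: {line!r}")
            rows.append(float(parts[1]))
    if "T" not in meta:
        raise ParameterError(f"{path}: missing 'T' header")
    T = float(meta.pop("T"))
    k = int(meta.pop("k", len(rows)))
    if k != len(rows):
        raise ParameterError(f"{path}: header k={k} but {len(rows)} rows present")
    return DecayHistogram(np.asarray(rows), T), meta
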