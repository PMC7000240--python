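"""Closed-form figure-of-merit calculus for single-photon-counting FLIM design.

Collects the small algebra that relates photon economy, dead-time, count
rate, imaging speed, dynamic range and motion blur for a TCSPC system:

* photon economy ``F = (sigma_tau/tau) * sqrt(N)`` sets the photon budget
  ``N = F**2 * SNR0**2`` needed for a target signal-to-noise ratio;
* pile-up loss ``Delta = k0*td / (1 + k0*td)`` for arrival rate ``k0`` and
  non-paralyzable dead-time ``td``;
* relative throughput ``A = F**-2 * (tau/n) * k0/(1 + k0*td)
  = F**-2 * (tau/n) * Delta/td`` against the shot-noise-limited maximum
  ``n/tau``;
* frame rate ``FR = Delta / (N_pixels**2 * F**2 * SNR0**2 * td)``;
* dynamic range ``D = 20*log10(k_detected/sqrt(DCR))``, decomposed as
  ``D = D_ref - 20*log10(td)`` with ``D_ref = 20*log10(Delta/sqrt(DCR))``;
* motion blur ``B = 20*log10(R/b)`` for resolution ``R`` and Brownian
  displacement ``b = sqrt(2*D_diff*t)`` over the exposure.

Unit conventions: rates in Hz, dead-times and exposures in seconds (the
``td`` inside the dB log terms is in seconds), lifetimes here in seconds,
distances in nanometres, diffusion coefficients in nm^2/s.  Decay-histogram
mathematics elsewhere in the package uses nanoseconds; the CLI converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from fastflim.decay import ParameterError

__all__ = [
    "PrecisionSpec",
    "InstrumentSpec",
    "SampleSpec",
    "pileup_loss",
    "rate_for_loss",
    "required_exposure",
    "throughput",
    "throughput_from_loss",
    "frame_rate",
    "dynamic_range_ref",
    "dynamic_range",
    "dynamic_range_from_rate",
    "diffraction_resolution",
    "brownian_displacement",
    "blur_figure",
    "blur_reference",
    "blur_from_params",
    "safe_count_rate",
    "multi_hit_capacity",
    "burst_rate",
]


@dataclass(frozen=True)
class PrecisionSpec:
    """Photon-economy target: figure-of-merit ``F`` and target ``SNR0``.

    ``F`` is the ratio of the estimator's relative lifetime error to the
    shot-noise limit ``N**-0.5``; ``F = 1`` is photon-efficient.
    """

    F: float = 1.0
    snr0: float = 100.0

    def __post_init__(self) -> None:
        if not (self.F > 0 and math.isfinite(self.F)):
            raise ParameterError(f"F must be > 0, got {self.F}")
        if not (self.snr0 > 0 and math.isfinite(self.snr0)):
            raise ParameterError(f"snr0 must be > 0, got {self.snr0}")

    @property
    def required_photons(self) -> float:
        """Photon count ``N = F**2 * SNR0**2`` reaching the target SNR."""
        return self.F**2 * self.snr0**2


@dataclass(frozen=True)
class InstrumentSpec:
    """Detection-chain description.

    td : system dead-time (s); k0 : photon arrival rate in the absence of
    pile-up (Hz); dcr : dark count rate (Hz); rep_rate : laser repetition
    rate (Hz); pulse_pair_resolution : minimum resolvable photon spacing (s).
    """

    td: float = 0.0
    k0: float = 0.0
    dcr: float = 0.0
    rep_rate: float = 80e6
    pulse_pair_resolution: float = 0.0

    def __post_init__(self) -> None:
        for name in ("td", "k0", "dcr", "rep_rate", "pulse_pair_resolution"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ParameterError(f"{name} must be >= 0 and finite, got {v}")


@dataclass(frozen=True)
class SampleSpec:
    """Specimen description for throughput and blur estimates.

    n : effective number of emitting fluorophores in the probed volume;
    tau : lifetime (s); d_diff : diffusion coefficient (nm^2/s);
    wavelength : emission wavelength (nm); na : numerical aperture.
    """

    n: float = 1.0
    tau: float = 3e-9
    d_diff: float = 1e5
    wavelength: float = 500.0
    na: float = 1.2

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError(f"n must be > 0, got {self.n}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if self.d_diff < 0:
            raise ParameterError(f"d_diff must be >= 0, got {self.d_diff}")
        if self.na <= 0:
            raise ParameterError(f"na must be > 0, got {self.na}")

    @property
    def saturation_rate(self) -> float:
        """Maximum theoretical count rate ``k_sat = n / tau`` (Hz)."""
        return self.n / self.tau


def pileup_loss(k0: float, td: float) -> float:
    """Pile-up loss fraction ``Delta = k0*td / (1 + k0*td)``.

    Monotone increasing in both arguments; in ``[0, 1)``.
    """
    if k0 < 0 or td < 0:
        raise ParameterError("k0 and td must be >= 0")
    x = k0 * td
    return x / (1.0 + x)


def rate_for_loss(delta: float, td: float) -> float:
    """Arrival rate ``k0`` (Hz) producing pile-up loss ``delta`` at dead-time ``td``."""
    if not 0.0 <= delta < 1.0:
        raise ParameterError(f"delta must be in [0, 1), got {delta}")
    if td <= 0:
        raise ParameterError(f"td must be > 0, got {td}")
    return delta / ((1.0 - delta) * td)


def required_exposure(spec: PrecisionSpec, inst: InstrumentSpec) -> float:
    """Exposure time (s) to reach the target SNR under pile-up.

    ``T = F**2 * SNR0**2 / k0 * (1 + k0*td)``; reduces to the shot-noise
    value ``N/k0`` at zero dead-time.
    """
    if inst.k0 == 0:
        raise ParameterError("k0 = 0: no signal, exposure time is unbounded")
    return spec.required_photons / inst.k0 * (1.0 + inst.k0 * inst.td)


def throughput(spec: PrecisionSpec, inst: InstrumentSpec, sample: SampleSpec) -> float:
    """Relative acquisition throughput ``A = F**-2 * (tau/n) * k0/(1+k0*td)``.

    ``A`` compares the achievable acquisition rate with the theoretical
    maximum set by the fluorophores' saturation rate ``n/tau``; it is
    bounded by ``F**-2 * (tau/n) / td`` however high the excitation.
    """
    return (sample.tau / sample.n) / spec.F**2 * inst.k0 / (1.0 + inst.k0 * inst.td)


def throughput_from_loss(
    spec: PrecisionSpec, sample: SampleSpec, delta: float, td: float
) -> float:
    """Throughput in the accepted-loss form ``A = F**-2 * (tau/n) * Delta/td``.

    Algebraically identical to :func:`throughput` when
    ``delta = pileup_loss(k0, td)``; undefined (0/0) at ``td = 0``, where the
    rate form must be used.
    """
    if td <= 0:
        raise ParameterError("td must be > 0 for the loss form; use throughput() at td=0")
    return (sample.tau / sample.n) / spec.F**2 * delta / td


def frame_rate(n_pixels: int, spec: PrecisionSpec, delta: float, td: float) -> float:
    """FLIM frame rate ``FR = Delta / (N_pixels**2 * F**2 * SNR0**2 * td)`` (Hz).

    Square ``n_pixels x n_pixels`` images; net of scan overheads.
    """
    if n_pixels < 1:
        raise ParameterError(f"n_pixels must be >= 1, got {n_pixels}")
    if not 0.0 < delta < 1.0:
        raise ParameterError(f"delta must be in (0, 1), got {delta}")
    if td <= 0:
        raise ParameterError("td must be > 0; at td=0 use 1/(n_pixels**2 * required_exposure)")
    return delta / (n_pixels**2 * spec.required_photons * td)


def dynamic_range_ref(delta: float, dcr: float) -> float:
    """Reference dynamic-range term ``D_ref = 20*log10(Delta/sqrt(DCR))`` (dB)."""
    if dcr <= 0:
        raise ParameterError("dcr must be > 0 (dynamic range unbounded otherwise)")
    if delta <= 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    return 20.0 * math.log10(delta / math.sqrt(dcr))


def dynamic_range(delta: float, dcr: float, td: float) -> float:
    """Dynamic range ``D = D_ref - 20*log10(td)`` in dB, ``td`` in seconds.

    Equivalent to ``20*log10(k_detected/sqrt(DCR))`` with the detected rate
    ``k_detected = Delta/td`` implied by the accepted loss.
    """
    if td <= 0:
        raise ParameterError(f"td must be > 0, got {td}")
    return dynamic_range_ref(delta, dcr) - 20.0 * math.log10(td)


def dynamic_range_from_rate(k_detected: float, dcr: float) -> float:
    """Direct form ``D = 20*log10(k_detected/sqrt(DCR))`` (dB)."""
    if dcr <= 0 or k_detected <= 0:
        raise ParameterError("k_detected and dcr must be > 0")
    return 20.0 * math.log10(k_detected / math.sqrt(dcr))


def diffraction_resolution(wavelength: float, na: float) -> float:
    """Confocal diffraction-limited resolution ``R0 = 0.6 * lambda / NA`` (nm)."""
    if na <= 0:
        raise ParameterError(f"na must be > 0, got {na}")
    if wavelength <= 0:
        raise ParameterError(f"wavelength must be > 0, got {wavelength}")
    return 0.6 * wavelength / na


def brownian_displacement(d_diff: float, t: float, *, factor_two: bool = True) -> float:
    """Root-mean-square Brownian displacement over time ``t`` (nm).

    Default convention ``b**2 = 2*D_diff*t``.  With ``factor_two=False`` the
    alternative ``b**2 = D_diff*t`` is used; both appear in the literature
    and the package exposes the choice explicitly.
    """
    if d_diff < 0 or t < 0:
        raise ParameterError("d_diff and t must be >= 0")
    return math.sqrt((2.0 if factor_two else 1.0) * d_diff * t)


def blur_figure(R: float, b: float) -> float:
    """Motion-blur figure ``B = 20*log10(R/b)`` in dB, capped at 0.

    Negative values mean the displacement ``b`` over the exposure exceeds
    the optical resolution ``R``; immobility cannot *gain* resolution, so
    ``b <= R`` reports 0 dB ("no loss").
    """
    if R <= 0 or b <= 0:
        raise ParameterError("R and b must be > 0")
    return min(0.0, 20.0 * math.log10(R / b))


def blur_reference(
    R: float, spec: PrecisionSpec, delta: float, d_diff: float
) -> float:
    """Dead-time-independent blur term ``B_ref`` (dB).

    ``B_ref = 20*log10( (R/(F*SNR0)) * sqrt(Delta/(2*D_diff)) )`` so that
    ``B = B_ref - 10*log10(td)`` equals ``blur_figure`` evaluated at the
    exposure time implied by (``F``, ``SNR0``, ``Delta``, ``td``).
    """
    if R <= 0 or d_diff <= 0 or not 0.0 < delta < 1.0:
        raise ParameterError("require R > 0, d_diff > 0, 0 < delta < 1")
    return 20.0 * math.log10(R / (spec.F * spec.snr0) * math.sqrt(delta / (2.0 * d_diff)))


def blur_from_params(
    R: float, spec: PrecisionSpec, delta: float, d_diff: float, td: float
) -> float:
    """Blur figure (dB, capped at 0) from instrument parameters.

    Composes ``B_ref - 10*log10(td)``; identical to the pipeline
    exposure -> Brownian displacement -> ``blur_figure``.
    """
    if td <= 0:
        raise ParameterError(f"td must be > 0, got {td}")
    return min(0.0, blur_reference(R, spec, delta, d_diff) - 10.0 * math.log10(td))


def safe_count_rate(rep_rate: float, divisor: float = 100.0) -> float:
    """Classic pile-up-safe arrival rate: repetition rate over ``divisor``.

    The one-photon-per-pulse constraint of single-stop TCSPC is usually
    managed by keeping the count rate one to two orders of magnitude below
    the laser repetition rate; 80 MHz / 100 = 800 kHz with the default.
    """
    if rep_rate < 0 or divisor <= 0:
        raise ParameterError("rep_rate must be >= 0 and divisor > 0")
    return rep_rate / divisor


def multi_hit_capacity(max_hits: int, window_pulses: int) -> float:
    """Average stop events per laser pulse a multi-hit TDC can record.

    ``M`` hits shared over a retrigger window of ``W`` pulses gives ``M/W``
    (3.2 events/pulse for the 32-hit, 10-pulse configuration).
    """
    if max_hits < 1 or window_pulses < 1:
        raise ParameterError("max_hits and window_pulses must be >= 1")
    return max_hits / window_pulses


def burst_rate(pulse_pair_resolution: float) -> float:
    """Burst count rate ``1 / pulse_pair_resolution`` (Hz).

    The inverse of the minimum resolvable photon spacing: ~180 MHz for a
    5.5 ns pulse-pair resolution.
    """
    if pulse_pair_resolution <= 0:
        raise ParameterError("pulse_pair_resolution must be > 0")
    return 1.0 / pulse_pair_resolution
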