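# Methods

This note records the models implemented in `fastflim`, the conventions and
numerical choices behind them, what the synthetic data generator does and
does not emulate, and the known limitations. Units: decay mathematics
(lifetimes, laser period, dead-times inside the simulator) is in
nanoseconds; the `merit` calculus (exposures, dead-times inside dB terms,
rates) is in seconds and hertz; distances in nanometres; diffusion
coefficients in nm²/s.

## Decay model and sampling

The per-bin detection probability of a mono-exponential emitter under
periodic excitation is the Köllner–Wolfrum wrapped exponential scaled by the
per-pulse detection probability `p_pulse`:

    pdf(t_i) = p_pulse · e^(−iT/(kτ)) · (e^(T/(kτ)) − 1) / (1 − e^(−T/τ))

with bins indexed 1…k, bin *i* covering [(i−1)·T/k, i·T/k). The masses sum
to `p_pulse` exactly (telescoping geometric sum); this is asserted to 1e-9
relative in tests. Sampled and evaluated times are reported at **bin left
edges**; the phasor module evaluates histograms at **bin centers**. Both
conventions are fixed and documented; where they meet (lifetime recovery
from sampled streams) the reference calibration absorbs the half-bin offset
(see below).

The Gaussian instrument response (default: centred at 1 ns, σ = 0.1 ns,
i.e. ≈235 ps FWHM) is applied by **circular** convolution over the period:
under periodic excitation the pre-pulse tail wraps around. The kernel is
the Gaussian sampled on the bin grid, wrapped over enough periods to
capture its tails, renormalised to unit sum, applied by FFT; tiny negative
FFT residues are clipped and the total renormalised, so mass conservation
is exact to rounding. With σ = 0 the kernel degenerates to a delta and the
histogram is circularly shifted by `round(center/bin_width)` bins. A
zero-padded linear convolution is deliberately not offered; periodicity is
part of the model.

Monte Carlo sampling follows the per-time-step Bernoulli rule: each of the
`n_pulses·k` steps of width T/k draws one uniform number and triggers a
photon when the bin's mass exceeds it. Expected yield is
`n_pulses·p_pulse`. Because the bin masses are non-negative and sum to
`p_pulse` ≤ 1, no single bin can exceed probability 1; the clipping guard
in the sampler is defensive and unreachable for valid models. Sampling is
vectorised in chunks of 10⁵ pulses; a fixed chunk size keeps draws
reproducible for a given seed. One `numpy.random.Generator` per simulation
run, seeded explicitly; every stochastic entry point takes a seed.

## Figure-of-merit calculus

The photon economy F is the ratio of an estimator's relative lifetime error
to the shot-noise floor N^(−1/2); N = F²·SNR₀² photons reach a target
signal-to-noise ratio SNR₀. With a non-paralyzable dead-time t_d the
exposure needed at arrival rate k₀ grows by (1 + k₀t_d), the pile-up loss is
Δ = k₀t_d/(1+k₀t_d), and the derived quantities follow as closed forms
(throughput in its rate and accepted-loss forms, frame rate, dynamic range,
blur). Two forms of the same quantity are implemented separately and tested
for algebraic identity rather than aliased, because their domains differ
(the loss form is 0/0 at t_d = 0).

Conventions that are easy to get wrong and are therefore fixed here:

* the t_d inside the dB log terms of dynamic range (D = D_ref −
  20·log₁₀ t_d) and blur (B = B_ref − 10·log₁₀ t_d) is in **seconds**;
* the blur figure B = 20·log₁₀(R/b) is **capped at 0 dB**: immobility
  cannot gain resolution beyond the diffraction limit;
* the Brownian displacement defaults to b² = 2·D_diff·t, with a
  `factor_two=False` option for the b² = D_diff·t convention that also
  circulates in the literature;
* B_ref = 20·log₁₀((R/(F·SNR₀))·√(Δ/(2·D_diff))) is the unique grouping
  that makes the parametric form equal the compositional pipeline
  exposure → displacement → dB; this identity is property-tested over 1000
  random parameter sets at 1e-9 absolute tolerance.

Convenience helpers expose the classic instrument numbers: the safe count
rate (repetition rate divided by a configurable factor, default 100), the
multi-hit capacity M/W events per pulse, and the burst rate as the inverse
pulse-pair resolution.

## Dead-time Monte Carlo

Detection rules operate on the sorted arrival list. A detected photon opens
a dead window of t_d; photons inside any window are discarded
(non-paralyzable default; a paralyzable option lets discarded arrivals
extend the window). Single-stop mode additionally discards every photon
whose laser period already contains a detection — both constraints are
active simultaneously, as in classic TCSPC electronics. Multi-hit mode
instead enforces a budget of `max_hits` detections per retrigger window of
`window_pulses` consecutive periods (windows are blocks anchored at pulse
0, emulating a start-frequency divider; counters reset at block
boundaries) and a minimum spacing of one pulse-pair resolution between
detections (default 0 in simulation; 5.5 ns reproduces the reference TDC
hardware). All event logic runs on the T/k sampling grid (~100 ps at
defaults).

The loss fraction is validated against Δ = k₀t_d/(1+k₀t_d) with
k₀ = p_pulse/T at low rates (within 3 binomial standard errors,
σ = √(Δ(1−Δ)/N_ref)). Decay distortion is read out from the per-bin
measured/reference ratio. Because single bins are noise-dominated at
feasible pulse counts, the distortion classifier coarse-grains the
post-peak ratio into 8-bin blocks and reports the maximum rise above the
running minimum in units of its standard error: dead-times that are integer
multiples of the period give flat-to-monotone suppression (score ≈ 2,
consistent with pure noise), fractional multiples give a dip-and-recovery
"wobble" that scores ≈ 4–17 depending on count rate. The classifier
thresholds used in tests (3.5 / 6) sit between the two populations observed
across seeds at the tested conditions.

Simulated conditions follow the instrument defaults throughout: τ = 3 ns,
T = 12.5 ns (80 MHz), k = 128, IRF 1 ± 0.1 ns; p_pulse ∈ {0.01, 0.1, 1}
for safe/high/extreme count rates; dead-times 100, 80 and 2.5 ns;
multi-hit budget 32 hits per 10 periods. Tests and the distortion checks
run 10⁵–10⁶ pulses per experiment — enough for the statistics asserted
while keeping the default suite under a minute per module.

## Phasor analysis

The phasor is the counts-normalised Fourier coefficient at an integer
harmonic of the repetition frequency, evaluated at bin centers. For the
wrapped mono-exponential the continuous-time phasor is exactly
(1, iωτ)/(1+(ωτ)²) at every harmonic, so phase and modulation lifetimes
are consistent estimators; discretisation bias is O((T/k)²). Lifetime maps
smooth the decay stack spatially with a box kernel first (borders
renormalised by the kernel mass actually inside the image, so uniform
images stay uniform), threshold on the smoothed totals, then transform —
in that order. Phases outside (−π/2, π/2) or modulations above 1 are
flagged invalid; small negative phase lifetimes from noise are clipped to
zero in maps.

Calibration: a measured phasor is multiplied by the complex ratio
(true reference)/(measured reference). The reference can be the analytic
Gaussian-IRF phasor e^(iωc−ω²σ²/2) or, preferably, the phasor of a
noiseless model histogram of known lifetime — the numerical analogue of
imaging a reference dye — which cancels the IRF phase and the
left-edge/center convention offset in one step. Calibration is **off by
default** (simulated streams define t = 0 exactly); recovery tests use the
reference-dye route with a 2.5 ns reference.

The empirical photon economy `estimate_F` draws repeated multinomial
histograms of N photons and measures the spread of lifetime estimates.
Lifetimes are obtained by inverting the binned-model phase–lifetime curve
(600-point geometric grid spanning ×30 around the model lifetime) rather
than by a linear calibration: a linear factor maps the mean correctly but
hides the sensitivity loss of coarse histograms and can report F < 1 — an
artefact, since F < 1 would beat the Cramér–Rao bound. The inversion
reduces to tan(φ)/ω at fine binning. At k = 2 both bin centers sit at phase
±π/2, the phase carries no lifetime information at the fundamental, and
`estimate_F` returns infinity. The phase estimator is photon-efficient
only at small ωτ: the delta-method value is F ≈ 1.01 at ωτ = 0.25, 1.08 at
ωτ = 0.5 (τ = 1 ns at 80 MHz), and 2.4 at ωτ = 1.5 (τ = 3 ns) — the
near-unity claim for histogramming electronics with ~10² bins belongs to
the maximum-likelihood bound, which phase estimation attains only in the
favorable range. Efficiency tests therefore run at τ = 1 ns.

## List-mode engine

Records are (time ns, kind, channel) rows, time-sorted; kinds are photon
and pixel/line/frame triggers. Parsing is a single pass: frame triggers
advance the frame counter and reset lines; line triggers advance y and
reset x; pixel triggers advance x; photons are assigned to the most recent
enclosing triggers. The configured numbers of offset frames, lines and
pixels are discarded first; photons before the first frame, in offset
units, or beyond the last active pixel of a line (retrace) are itemised in
a discard report, and stream total = stack total + discards holds exactly
and is asserted end to end. Trigger surpluses and deficits against the
layout, non-monotone timestamps, out-of-range channels and malformed
container rows raise structured errors naming the first offending record
or line. Frames map to dimensions z-fastest, then timepoint, then field of
view; scanning is unidirectional. Duplicated frame triggers (hardware
double-reporting) are coalesced within a configurable time tolerance when
slicing streams into frames; a final frame with fewer line triggers than
the layout demands is flagged partial rather than silently kept.

The decay bin is floor(((t − phase_offset) mod T)/(T/k)). Synthetic streams
embed the pulse phase exactly (all trigger and dwell times are integer
multiples of T, which is why pixel dwells are an integer number of laser
periods and retrace gaps are rounded to whole periods); for imported
streams the constant `phase_offset` stands in for sync-record parsing,
which is not modelled.

Count-rate maps divide per-pixel totals by the effective dwell
`frame_time · duty_cycle / n_pixels²`, optionally scaled by a per-pixel
relative-dwell map for scanners with inhomogeneous dwell.

## Synthetic scenes

`make_scene` paints rectangles and disks with per-pixel intensity
(expected photons per frame) and mono- or bi-exponential decay parameters
over a background; a FRET flag gives two channels complementary amplitude
fractions, the statistical skeleton of a donor/acceptor biosensor pair.
`generate_stream` draws Poisson photon counts per pixel dwell, assigns
arrival phases by multinomial sampling of the pixel's IRF-convolved mixture
decay on the T/k grid, spreads photons uniformly over the dwell's laser
periods, applies the detection rules within the dwell, and emits triggers
with the layout's offsets. Ground truth carries emitted/detected counts per
pixel and per frame plus folded decay histograms on the same grid, so
reconstruction can be checked for exact equality, not just statistically.

What the generator does **not** emulate: optics (no PSF — photons land in
exactly one pixel), photobleaching, triplet states, background/dark counts
in the image (dark counts enter only the analytic dynamic-range
calculus), dead-time carry-over between pixel dwells (retrace gaps are
long compared with any realistic dead-time), bidirectional scanning, and
intra-frame motion (scenes move between frames, by whole pixels with
periodic boundaries). Passing the end-to-end suites therefore demonstrates
the correctness of the bookkeeping, the estimators and the detection
logic under the stated statistical model — not robustness to optical
blur, background or drift within a frame.

Motion supports linear drift and a Brownian whole-pixel walk, applied
between frames — sufficient for blur-metric phenomenology (a drifting
object's accumulated footprint spreads with exposure), not for modelling
within-line shear.

`emulate_retrigger_irf` histograms a near-zero-lifetime emitter against a
divided retrigger epoch, reproducing the multi-peak IRF trace of a
frequency-divided TDC start channel (one IRF copy per laser period in the
window).

## Numerical and interface choices

* All dataclasses validate on construction and raise `ParameterError` on
  non-finite or out-of-range values; stochastic operations require an
  explicit seed.
* Histograms and streams round-trip through plain-text containers with
  `# key = value` headers (floats written with `repr`, hence bit-exact)
  and HDF5 twins; stacks are HDF5 with named axes and optional TIFF
  export.
* The detection loop is plain Python over numpy arrays; at the 10⁵–10⁶
  photons per experiment used throughout, runtime is seconds and the
  clarity of the rule set was preferred over compiled acceleration.
* The CLI is a thin `click` layer over the library; each subcommand writes
  a JSON manifest (full parameters, seeds, package version, outputs,
  timestamp) sufficient to reproduce the run.

## Known limitations

* Analytic pile-up correction/deconvolution of distorted decays is out of
  scope; the simulator quantifies distortions, it does not undo them.
* Multi-exponential *analysis* (unmixing on the phasor plot, global
  fitting) is not provided; bi-exponential decays exist only as generative
  mixtures.
* The hardware-facing layers of a real instrument (FIFO management,
  transfer-rate saturation, vendor list-mode dialects, sync-record
  parsing) are not modelled; the engine consumes the package's own
  documented stream format.
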