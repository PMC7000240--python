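# fastflim

Quantitative tooling for **fast time-correlated single-photon counting (TCSPC)
fluorescence lifetime imaging (FLIM)**: the closed-form design calculus that
relates dead-time to acquisition speed, dynamic range and motion blur; a Monte
Carlo simulator of detector/electronics dead-time and multi-hit
time-to-digital-converter (TDC) operation; phasor-based lifetime estimation;
and reconstruction of multi-dimensional FLIM stacks from time-tagged photon
streams. A synthetic-scene generator stands in for the microscope, so the
whole pipeline runs and is tested without any external data.

It is aimed at instrument builders and microscopists who want to reason
quantitatively about single-photon-counting FLIM designs — how much a 100 ns
counting chain costs in photons, dynamic range and blur compared with a
2.5 ns multi-hit TDC — and at analysts who want a reference implementation of
list-mode reconstruction and phasor FLIM they can verify photon by photon.

## The model

Under pulsed excitation with period *T* histogrammed into *k* bins, a
mono-exponential emitter of lifetime τ detected with probability *P_N* per
pulse follows the Köllner–Wolfrum wrapped-exponential mass function

    pdf(t_i) = P_N · e^(−iT/(kτ)) · (e^(T/(kτ)) − 1) / (1 − e^(−T/τ)),  i = 1…k,

which sums exactly to *P_N* and is convolved circularly with a Gaussian
instrument response. Around it the package implements:

* **Pile-up loss** Δ = k₀t_d / (1 + k₀t_d) for arrival rate k₀ and
  non-paralyzable dead-time t_d, and the photon-economy calculus
  N = F²·SNR₀², T_exp = F²·SNR₀²·k₀⁻¹·(1 + k₀t_d);
* **Throughput** A = F⁻²·(τ/n)·k₀/(1+k₀t_d) = F⁻²·(τ/n)·Δ/t_d and frame rate
  FR = Δ/(N²_pixels·F²·SNR₀²·t_d);
* **Dynamic range** D = 20·log₁₀(k_detected/√DCR) = D_ref − 20·log₁₀(t_d)
  with D_ref = 20·log₁₀(Δ/√DCR);
* **Motion blur** B = 20·log₁₀(R/b) against the Brownian displacement
  b = √(2·D_diff·t) over the exposure;
* **Detection Monte Carlo**: single-stop TCSPC (one photon per period plus a
  dead window) versus a multi-hit TDC (M stops per W-period retrigger
  window, pulse-pair resolution), reproducing the characteristic decay
  distortions — uniform/monotone suppression when t_d is an integer number
  of laser periods, transient "wobbles" when it is not;
* **Phasor analysis**: g + i·s Fourier coordinates at harmonics of the
  repetition rate, phase and modulation lifetimes, reference calibration,
  smoothed and count-thresholded lifetime maps, and an empirical
  photon-economy estimator F = (σ_τ/τ)·√N;
* **List-mode engine**: pixel/line/frame trigger parsing with offset and
  retrace handling into (timepoint, FOV, z, channel, y, x, decay-bin)
  stacks, z accumulation/downsampling, dwell-time-normalised count-rate
  maps, text and HDF5 containers, TIFF export.

## Worked example

```python
from fastflim import merit
from fastflim.decay import DecayModel
from fastflim.pileup import DetectionConfig, run_pileup_experiment
from fastflim.merit import pileup_loss

# dynamic range of a hybrid-PMT chain (DCR 600 Hz, 5% accepted pile-up loss)
print(f"D_ref = {merit.dynamic_range_ref(0.05, 600.0):.1f} dB")
for td in (100e-9, 10e-9, 1e-9):
    print(f"D(td={td*1e9:.0f} ns) = {merit.dynamic_range(0.05, 600.0, td):.1f} dB")

# Monte Carlo pile-up at a classically 'safe' count rate (P_N = 0.01)
model = DecayModel(tau=3.0, T=12.5, k=128, p_pulse=0.01, irf_center=1.0, irf_sigma=0.1)
res = run_pileup_experiment(model, DetectionConfig(td=100.0, mode="single_hit"),
                            n_pulses=10**6, seed=1)
k0 = model.p_pulse / (model.T * 1e-9)   # 0.8 MHz
print(f"simulated loss = {res.loss_fraction:.4f}, analytic = {pileup_loss(k0, 100e-9):.4f}")
```

prints

```
D_ref = -53.8 dB
D(td=100 ns) = 86.2 dB
D(td=10 ns) = 106.2 dB
D(td=1 ns) = 126.2 dB
simulated loss = 0.0728, analytic = 0.0741
```

Reading: accepting 5% pile-up losses against a 600 Hz dark count rate, a
100 ns counting chain reaches ~86 dB of dynamic range; every tenfold
reduction of dead-time buys 20 dB. Even at the "safe" 800 kHz count rate a
100 ns dead-time already discards ~7% of photons, and the simulated loss
agrees with Δ = k₀t_d/(1+k₀t_d) to within Monte Carlo error.

The same functionality is scriptable from the shell:

```sh
fastflim merit --delta 0.05 --dcr 600 --td 1e-9:1e-7:13 --out merit.tsv
fastflim simulate --pn 0.01 --deadtime 100 --pulses 1000000 --seed 1 --out sim/
fastflim synth --scene scene.json --layout layout.cfg --seed 1 --out stream.tsv
fastflim reconstruct --stream stream.tsv --layout layout.cfg --out stack.h5
fastflim phasor --input stack.h5 --kernel 2 --min-counts 80 --out maps
```

Every invocation writes a JSON manifest alongside its outputs from which the
run can be reproduced exactly.

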