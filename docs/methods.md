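# Methods

## The problem

Respiratory and cardiac pulsations modulate intracranial pressure; because
the skull fixes total intracranial volume (the Monro–Kellie doctrine), an
oscillatory inflow of blood or CSF in one compartment must be compensated by
an opposite flow elsewhere. On rapidly repeated gradient-echo MR images
these oscillatory flows appear as flow-related enhancement: each pixel's
signal-time curve carries small periodic fluctuations at the breathing
frequency (~0.3–0.5 Hz) and the heart rate (~1–1.4 Hz). `pulsemap`
quantifies, pixel by pixel, the strength of those pulsations and their
temporal delay relative to a reference waveform.

## Processing model

The pixel time course `y(t)` is treated as the output of a linear
time-invariant system driven by a reference pulsation `x(t)`. In the
frequency domain `Y(f) = X(f) H(f)`, and the transfer function

    H(f) = |H(f)| exp{i φ(f)} = Y(f) / X(f)

carries the amplitude gain `|H|` and phase shift `φ` of the pixel's
pulsation relative to the reference at each frequency. The phase converts
to a temporal phase delay

    τ_p(f) = −φ(f) / (2π f),

the offset of the pixel's periodic waveform relative to the reference,
bounded by half a period (`|τ_p| ≤ T/2`, `T = 1/f`). Two intrinsic
ambiguities follow and are not resolvable from the data: (1) a delay of
`τ_p + kT` is indistinguishable from `τ_p` (phase wraps), so an inverted
waveform cannot be distinguished from a half-period delay; (2) spectral
content above the Nyquist frequency `1/(2·TR)` aliases — at TR = 0.2 s the
Nyquist frequency is 2.5 Hz, so the second cardiac harmonic is observable
only for heart rates up to 1.25 Hz (75 bpm). The impulse response `h(t)` is
never materialized; only `H(f)` is used.

## Pipeline stages

1. **Analysis mask.** Pixels above a percentile (default 75) of the
   temporal-standard-deviation image. Oscillatory flow concentrates
   temporal variance, so the std image highlights vessels and CSF spaces;
   the default is configurable because no principled rule exists for
   arbitrary anatomy.

2. **Stationary-segment selection.** Physiological frequencies wander over
   a several-minute scan. A sliding-window periodogram is computed: for
   every window start, the amplitude spectra (plain DFT, no taper; leakage
   accepted) of all masked pixels' windowed courses are summed after
   per-window mean removal (which suppresses an otherwise dominant DC row).
   A window of 300 frames over 512 yields 213 columns. Each window is
   scored for stationarity: over a centered neighborhood of 25 windows, the
   variance of the in-band peak frequency (in bin units) plus the variance
   of the relative peak amplitude, summed over the respiratory and cardiac
   bands; the minimizing start (earliest on ties) is selected. The
   neighborhood size trades smoothness of the ranking against localization
   of drift. All scores are exported for audit, and the selection can be
   overridden manually.

3. **Reference extraction (spatial FastICA).** The selected segment is made
   zero-temporal-mean per pixel and decomposed with FastICA (tanh contrast,
   symmetric decorrelation, tolerance 1e−6, at most 500 iterations, seeded
   random start — the most reproducible standard variant), pixels as
   samples and frames as variables, so each frame is modelled as a mixture
   of a few spatially independent source images; 4 components by default.
   The mixing time courses are normalized to zero mean and unit variance
   (maps absorb the scale). Sign indeterminacy is fixed by making each
   map's skewness non-negative (pulsation foci are sparse bright pixels),
   flipping map and course together. Each course is labelled by its
   dominant in-band spectral energy fraction (threshold 0.25): the default
   classification bands, respiratory 0.2–0.5 Hz and cardiac 0.9–1.4 Hz,
   are deliberately narrow enough that a white-noise course's expected
   fraction (bandwidth/Nyquist: 0.12 and 0.20 at TR = 0.2 s) cannot reach
   the threshold, so pure noise yields no reference and the run fails
   cleanly for that band.

4. **Transfer maps.** With the chosen reference course `x(t)`, per pixel
   and per band: `H = Y·conj(X) / (|X|² + ε)` with `ε = 1e−12·max|X|²` —
   the regularization matters because `X(f)` is near zero outside the
   pulsation bands, where a raw ratio explodes; in-band values are
   unaffected. The band magnitude is the arithmetic mean of `|H|` over
   in-band bins. The band phase is a circular mean (argument of a sum of
   unit phasors `H/|H|`; naive averaging is wrong at the ±π wrap) with the
   phasors weighted by reference power `|X(f)|²`: bins where the reference
   is silent carry only noise phase, and unweighted they would swamp the
   signal bins (the standalone `band_average` keeps the unweighted mean).
   Bins with `|H|` below 1e−9 of the in-band maximum are dropped entirely —
   they are regularization residue. The delay image converts the band
   phase at the band peak frequency of `|X|` (a single delay per band). A
   coherence image, `|Σ H·|X|²| / Σ |H|·|X|²` over in-band bins, scores
   magnitude-weighted phase consistency in [0, 1]; bands where the
   reference has no power (peak ≤ 10× the median out-of-band amplitude)
   additionally carry an explicit warning. Analysis bands default to the
   reference component's in-band peak ± 0.05 Hz.

5. **Rendering.** Phase images use a cyclic four-anchor colormap — 0 white
   (no delay), +π/2 green (lagging), −π/2 red (leading), ±π yellow (the
   half-period/inversion ambiguity) — with low-coherence pixels gray and
   the colorbar labelled in both radians and seconds.

## The phantom generator

No public acquisitions of this kind exist, so validation uses synthetic
phantoms: compartments (disks, boxes or pixel lists) oscillating as
`A·cos(2π f_inst (t − delay))` with the delay applied as a time shift —
which makes recovered phase delays directly comparable to the specified
delay — plus optional integer harmonics, optional linear frequency drift
(`f_inst = f + drift·(t − delay)`, phase integrated accordingly; used to
exercise segment selection), a constant baseline and additive Gaussian
noise. Defaults mirror the targeted acquisition: 128 × 128 single slice,
512 frames, TR = 0.2 s, baseline 100, amplitude 2 (2 % of baseline — in
the low-percent range plausible for flow-related signal fluctuation; the
true in-vivo ratio is not established), noise SD 0.2 (SNR 10 against the
default amplitude). Tests use smaller grids and frame counts chosen so the
full suite runs in seconds; the geometry-dependent claims (window counts,
frequency grids) are always exercised at the full 512-frame / 300-window
configuration.

What the phantom does *not* emulate: Rician noise statistics (Gaussian is
adequate for the zero-mean fluctuations the analysis operates on, but
magnitude-image noise is Rician at low SNR), T2* decay, inflow saturation,
k-space sampling or EPI artifacts, spatially varying baselines, or motion.
Passing phantom tests therefore demonstrates correctness of the signal
processing, not robustness to every property of real acquisitions.

## Numerical conventions

- Frame `k` occurs at `t = k·TR` (0-based) everywhere.
- Spectra are one-sided with amplitude normalization 2/N for interior bins
  (1/N for DC and the even-N Nyquist bin), so an exact-bin cosine of
  amplitude A reads A at its bin. Peaks are reported at grid bins, never
  interpolated; ties break to the lowest frequency.
- Standard deviations use the population formula (divide by N).
- Phases live in (−π, π]; delays consequently span ±T/2 with the sign
  fixed by τ_p = −φ/(2πf): a positive delay means the pixel lags the
  reference.
- Everything downstream of a seed (phantom noise, ICA start) is
  deterministic; reruns with the same configuration and seed reproduce
  reports byte-identically.

## Known limitations

- The coherence statistic flags *bands* where the reference lacks power
  (noise-vs-noise phases are uniform → coherence low). A pixel with strong
  in-band power of its own against a nearly silent reference can still
  score high, because a single dominant bin is trivially self-consistent;
  the band-level warning covers that case.
- Course-pairwise decorrelation holds exactly only when the true spatial
  sources are uncorrelated over pixels; disjoint compact compartments are
  slightly correlated after centering, leaving residual course correlation
  of order 0.1 even on noise-free data.
- Band edges have no universal values; the defaults assume normal adult
  breathing and heart rates at TR ≈ 0.2 s and must be adapted for other
  sampling rates or populations.
- No model-order selection: the component count is fixed (default 4), and
  no sub-bin frequency refinement or multitaper/Welch estimation is
  performed.
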