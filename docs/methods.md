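# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `thetagamma`.

## Analysis timeline and segmentation

The tetanus protocol is 10 trains of 15 biphasic pulses at 200 Hz with 10 s
between trains; the first-to-last-pulse span is
`10·(14/200) + 9·10 = 90.7 s`. The analysis timeline places a 100 s
baseline immediately before HFS onset, an HFS window equal to the protocol
span rounded **up** to whole 10 s inter-stimulus slots (100 s for the
default protocol), and three 100 s post windows — five contiguous,
non-overlapping windows.

One epoch is extracted per 10 s slot. The nominal 4.1 s epoch is realized
as exactly 4.096 s so that one epoch equals one FFT block at every
analysis rate (512 samples at 125 Hz, 1024 at 250 Hz, 2048 at 500 Hz,
4096 at the 1 kHz acquisition rate). Artifact samples are flagged by a
robust amplitude rule (|z| > 6 in median/MAD units) **or** proximity to
any stimulus event, with a 0.25 s guard margin dilated around both; the
epoch is centered in the longest clean run of its slot (ties resolved
toward the slot start) and dropped if no run can host it. Contaminated
spans are excluded, never interpolated or template-subtracted. A window
that yields no epoch is marked invalid and produces missing normalized
values rather than silently vanishing.

## Band power

Band filters are linear-phase FIR (Hamming windowed sinc) with −3 dB
edges at δ 2–4, θ 4.5–10, α 10–12, β 12.5–28, γ 29.5–99.5 Hz and a
48.5–55 Hz band-stop for mains. Transition widths are 1 Hz (δ, α),
1.5 Hz (θ, β) and 2.5 Hz (γ, notch) — narrower bands get narrower
transitions. Because the windowed-sinc method places −6 dB at its cutoff,
cutoffs are calibrated numerically (measured on the frequency response)
until the −3 dB points land on the stated edges within 0.25 Hz. Filters
are applied with compensated delay (odd symmetric taps, centered
convolution), not forward–backward, so the single-pass −3 dB contract
holds. The mains notch is applied before band filtering only for β and γ
(the bands overlapping 50 Hz); it is a no-op below 28 Hz.

Epochs are down-sampled (anti-alias FIR at 0.45× the target rate, integer
decimation) to 125 Hz (δ, θ, α), 250 Hz (β) or 500 Hz (γ) before
filtering. Per-epoch power is the mean over bins of the mean square
spectrum — the squared magnitude of the Hamming-windowed FFT. The mean is
taken over the **full** spectrum by default (the filtered epoch carries
essentially no out-of-band energy, so this differs from a
passband-restricted mean only by a constant bin-count factor that cancels
under baseline normalization); a `spectrum="passband"` switch restricts
it. Power is normalized per subject and band to the mean over the ten
baseline epochs (= 100 %); the absolute scale is arbitrary (µV²) by
design, since no amplitude calibration is modeled.

## Cycle analysis

Band-filtered epochs are converted to analytic signals via the Hilbert
transform; phase uses the cosine convention (zero at the waveform
maximum). Cycles are excised between successive upward crossings of phase
−π (trough to trough); partial edge cycles are discarded, so cycle lengths
plus edge partials exactly tile the epoch. Per cycle, frequency is
recalculated as `rate / length` and the "maximum elongation" is the
trough-to-peak amplitude (max − min within the cycle); an alternative
reading (maximum analytic amplitude) is available behind
`amplitude_mode="analytic_peak"`. "Trough-to-peak" and "peak-to-slope"
amplitude are treated as the same quantity.

Nested gamma: gamma cycles are excised at the gamma analysis rate and each
is attributed to the theta cycle containing its **start**; a theta cycle's
nested amplitude is the mean gamma trough-to-peak amplitude of its gamma
cycles (missing when none fall inside). Frequency-binned maps round cycle
frequency to the nearest integer Hz, keep 5–10 Hz, normalize per subject
and bin to the bin's baseline mean, and average over epochs and subjects.

## Envelope-to-signal correlation (ESC)

ESC is the Pearson correlation between the slow rhythm's band-filtered
signal and the fast rhythm's amplitude envelope, computed on raw epochs at
500 Hz over 20 center frequencies (3–98 Hz in 5 Hz steps, each ± 2 Hz).
The fast envelope is the modulus of a complex Morlet response with width 7
(σ_t = 7 / 2πf), unit passband gain; convolution runs as overlap-add with
a 200-sample block (the stated processing setting) and is block-size
invariant, which the tests verify. The slow signal is FIR band-passed at
center ± 2 Hz — a plain band filter, not a wavelet, consistent with the
± 2 Hz binning. Cells with signal frequency ≥ envelope frequency are
undefined (the envelope of a slower rhythm against a faster signal is not
meaningful) and reported missing.

The surrogate null cuts the envelope into 200 contiguous equal segments,
permutes their order (envelope only — both marginal spectra are
preserved), and recomputes ESC; 200 seeded permutations give a per-cell
null mean/SD. The permuted correlations are computed exactly via the
decomposition of the correlation numerator into per-(slot, segment) dot
products, which the tests check against a literal shuffle-and-correlate
oracle. Trailing samples beyond `200·⌊n/200⌋` are excluded from the
surrogate statistic. On white-noise epochs the fraction of cells outside
the ±1.96 SD bound measures ~4 %, slightly conservative because 20 ms
segments still break some envelope autocorrelation.

The theta-gamma score pools cells whose **center** frequency lies inside
the band (signal center in 4–10 Hz → the 8 Hz row; envelope centers in
30–100 Hz → 33–98 Hz, 14 columns) and normalizes each window's pooled
mean to the baseline window. Per-envelope-center series are also emitted
so bin-resolved baseline differences remain visible.

One structural property worth knowing: because the Morlet bandwidth grows
with center frequency, an amplitude-modulated carrier midway between two
bins produces nearly equal ESC in both flanking envelope bins, with the
upper neighbor often marginally higher (asymmetric sideband capture). The
comodulogram maximum for an injected pair is therefore guaranteed only to
within one bin of the carrier; tests assert exactly that.

## Evoked potentials

Sweeps are millisecond-resolved (0.1 ms) with the stimulus at t = 0; five
sweeps per scheduled time point are averaged before measurement.

* **fEPSP slope**: the maximum least-squares slope over five consecutive
  samples, searched on the rising phase within 1–10 ms post-stimulus and
  stopped at the first prominent local maximum so the steep recovery edge
  of the population spike is never mistaken for the synaptic rising
  phase. Flat sweeps gate to missing.
* **PS amplitude**: the first prominent local minimum after the fEPSP
  peak (prominence ≥ 5 % of the sweep range) is the spike trough; the
  falling edge must contain a descending five-point window. The default
  `"tangent"` convention measures the trough's depth below the fEPSP
  envelope interpolated across the spike — a local quadratic fit through
  short support windows outside the flanking maxima (second-order
  accurate; it recovers an injected spike depth to < 1 % on the default
  sweep shape, where a straight-line interpolation is biased by fEPSP
  curvature). `"peak_to_trough"` (preceding maximum minus trough) is the
  documented alternative; both are DC-invariant and scale linearly.
* **I/O intensity**: the tested intensity whose response is nearest 40 %
  of the maximum, ties to the lower intensity.
* **Plasticity**: each time point as percent of the mean of the first six
  baseline points; phase summaries for baseline, post-injection, the 4 h
  follow-up and the 24–25 h block; group curves as mean ± SEM over
  subjects with counts.

## Statistics

An Anderson-Darling gate (5 % critical value; n < 8 or degenerate samples
default to nonparametric with a warning) routes comparisons to a t-test or
to rank statistics. The between-group test is the Wilcoxon rank-sum
(Mann-Whitney) with tie-corrected normal approximation, continuity
correction, two-sided p and effect size `r = Z/√N`. Kruskal-Wallis serves
within-group window comparisons; its Tukey-type post hoc is Nemenyi
(studentized-range on mean ranks; Conover's t-on-ranks is the switchable
alternative) with Bonferroni-corrected flags, and the post hoc table
carries a `vs_baseline` marker for map-style significance dots. The
Friedman test quantifies relationships among aligned series over the ten
HFS epochs; the default orientation treats the epochs as treatments
(df = 9 over 10 epochs), with the textbook orientation
(series as treatments) available. Bonferroni thresholds are `α/m`
(0.05/70 ≈ 0.00071).

## Synthetic data generator

The generator is phenomenological, not biophysical: five cosine
oscillators (δ 3 Hz, θ 8 Hz, α 11 Hz, β 20 Hz, γ 60 Hz) with slow
Ornstein-Uhlenbeck frequency jitter (τ = 1 s; SD 0.3–3 Hz per band, so
theta cycles spread over roughly 6–9 Hz), additive white noise
(SD 10 µV), and base amplitudes 15/30/10/10/20 µV — theta dominant, as in
hippocampal LFP. Gamma amplitude is multiplicatively modulated by the
*generated* theta phase, `A_γ(t)·(1 + m(t)·cos φ_θ)`, giving an exact
analytic envelope for oracle tests. Band gain curves are stated in percent
of baseline **power** (amplitude scales with the square root) so injected
curves read directly against the normalized spectral output.

Condition profiles (step curves over the ten HFS slots and three post
windows):

* **control** — all bands suppressed during HFS; theta (and gamma) at
  50 % of baseline power in the first five slots, ramping back in the
  second half; gamma peaking at 150 % in the first post window; coupling
  multiplier rising to 1.5× (m: 0.4 → 0.6) during HFS. Evoked factors:
  ~1.9 immediately after HFS decaying to a sustained ~1.55 at 24 h.
* **abeta** — elevated power in all five bands during HFS (theta 140 %,
  alpha 160 %, beta 150 %, unstable delta alternating 130–170 %, gamma
  ramping 120→180 %), no early theta suppression, power drifting upward
  after HFS; coupling multiplier collapsing to 0.4× during HFS. Evoked:
  0.85 after injection (depressed transmission), transient potentiation
  decaying to ~0.9 by 4 h and 24 h.

Cohorts derive per-subject seeds from one master seed
(`numpy.random.SeedSequence.spawn`) and jitter band amplitudes ± 10 %
uniformly per animal — realistic between-animal variance that leaves the
group ordering intact. Stimulus artifacts are 5 ms biphasic spikes of
20× the signal SD at every test pulse (0.025 Hz, suspended during the
tetanus) and every HFS pulse; events beyond the trace are truncated with
a warning. Default sessions are 610 s at 1 kHz with HFS onset at 100 s.

What the generator does **not** emulate: 1/f background spectra, movement
and chewing artifacts, non-sinusoidal cycle shapes, behavioral-state
changes, electrode drift, or any biophysical network mechanism. Passing
tests therefore demonstrate that the estimators recover known injected
structure through the full pipeline — not that the biological effects
themselves are reproduced from first principles.

## Problem sizes and numerical choices

* The pipeline's default cohort is 6 control + 5 treated subjects (the
  study-condition sizes); parameter-recovery checks run 20 independent
  master seeds, and the acceptance script 6, with coupling restricted to
  the pooled theta-signal × gamma-envelope cells (the full 20 × 20
  comodulogram path is exercised on smaller cohorts).
* Null calibrations use 2000 rank-test replicates (1000 in the script)
  and 500 white-noise comodulogram epochs (150 in the script).
* Filter lengths follow `3.3·rate/transition` (odd); epochs are long
  relative to filter edge effects, and the Hamming analysis window
  down-weights epoch edges.
* Degenerate inputs are explicit: constant signals reject phase
  estimation; zero-variance inputs yield missing ESC; windows without
  epochs, theta cycles without nested gamma, and missing baselines all
  propagate as NaN with warnings rather than being dropped.

## Known limitations

* ESC is a correlation, hence bounded and already near ceiling for strong
  noise-free coupling; the injected coupling multipliers are recovered as
  ordering and direction, not as exact ratios (a 1.5× multiplier does not
  produce exactly 150 % relative ESC except in the noise-dominated
  regime).
* The surrogate's 20 ms segments leave some envelope autocorrelation
  intact at low envelope frequencies, making the null slightly
  conservative there.
* Cycle trough-to-peak amplitudes on coarsely sampled fast rhythms
  (e.g. 60 Hz at 500 Hz) are biased low by up to ~4 % from peak sampling;
  frequencies are unaffected.
* The post hoc after Kruskal-Wallis applies a Bonferroni correction on
  top of the studentized-range familywise control, i.e. it is
  deliberately conservative, mirroring the described battery.
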