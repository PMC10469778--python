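# Methods

## The analysis in one paragraph

Sensorimotor electrocorticography (ECoG) during consonant-vowel (CV)
speech shows opposite modulation of beta-band activity (BBA, 12–35 Hz)
and gamma/high-gamma activity (GBA, 35–140 Hz): beta is high while the
vocal tract holds its inter-utterance speech posture (ISP), declines
several hundred milliseconds before movement onset, reaches its minimum
during the vowel, and rebounds after movement terminates, while gamma
does roughly the reverse.  This package implements the full analysis
chain that quantifies that structure — sub-band Hilbert bandpower over
ISP1-CV-ISP2 trials, interval correlation grids, change-point
segmentation, and mixed-effects inference — together with a synthetic
session generator whose ground-truth envelopes make every stage
verifiable by parameter recovery.

## Signal model and preprocessing

A session is a channels × samples matrix of cortical surface electrical
potentials with annotated speech start, CV-transition, and end times.
Valid sensorimotor (SMC) channels are the session's SMC index list minus
its bad-channel list; the surviving channels are common-average
referenced (CAR) by subtracting their cross-channel mean — exclusion
happens first, so artifactual channels never contaminate the reference.

Per trial, the padded window is notch filtered at 60/120/180 Hz
(second-order IIR notch, quality factor 30, forward-backward; the design
is a package choice — it gives >40 dB rejection in a ~2 Hz band with
zero phase) and band-passed into six log-spaced sub-bands (β_ℓ 12–21,
β_h 21–35, γ_ℓ 35–50, γ_h 50–70, Γ_ℓ 70–99, Γ_h 99–140 Hz) with a
3rd-order Butterworth in second-order sections run forward-backward.
Instantaneous bandpower is the squared modulus of the analytic signal
x + i·H[x]; it is averaged over the N valid channels, and low/high
sub-band pairs are additionally averaged into merged β, γ, Γ bands.
The Hilbert transform is computed per trial window with 500 ms pads
attached on each side; the pads absorb convolution edge effects
(conservatively, the first/last 100 ms of any analytic series) and are
discarded before any statistic is computed.

## Trials and the canonical grid

A trial is ISP1–consonant–vowel–ISP2.  Inclusion rules, applied in
order with every exclusion tallied to its first failing rule:
boundary (first/last utterance, where an ISP is undefined), invalid
(overlap with a marked artifact interval, tested against the clipped
trial span), vowel (syllable must end in /i/), and short-ISP (either
flanking gap < 500 ms).  Only the 500 ms of each ISP nearest the CV
movement is kept.  Variable consonant and vowel intervals are resampled
by band-limited (frequency-domain, periodic-sinc) interpolation to the
across-trial average lengths of 107 ms and 388 ms; segment lengths are
round(duration × fs) with ties to even, giving e.g. lengths
(1526, 327, 1184, 1526) and boundaries (1526, 1853, 3037) at 3052 Hz.
Resampling happens after pad truncation so filter edge effects never
enter the canonical window.

Per session and band, trials are z-scored with pooled-sample moments
(mean and SD over every time sample of every included trial; a config
switch to trial-mean moments exists).  Sessions are the averaging unit:
the grand timecourse is the pointwise mean of per-session mean
timecourses with dispersion σ/√N (an σ/N option is provided because
both conventions appear in the literature for this kind of figure).

## Statistics

*Correlations.*  Pearson r with two-tailed p between all C(6,2) = 15
sub-band pairs over each interval's samples of the grand timecourse
(grand-average is the default unit; pooled trials is the documented
alternative), thresholded at α/m = 0.05/15 ≈ 0.003.  A separate window
of one consonant length centered on the CV transition reproduces the
known positive β_h–Γ coupling at the transition: the beta inhibition
transient and the high-gamma activation peak sit adjacent there, so a
window straddling both picks up positive co-variation even though the
interval-wise correlations are negative.

*Extrema and wavelet maps.*  Strict interior local extrema per interval,
and a continuous map of inner products between the series and zero-mean,
unit-energy Gaussian templates of width σ = 1–42 canonical samples
(support truncated at ±4σ; reflection padding at the edges keeps the
zero-mean property, so a constant series maps to exactly zero).
Positive coefficients mark peak-like features, negative ones troughs.

*Change points.*  PELT with a mean-shift (L2) cost and the modified BIC
of Zhang & Siegmund: minimize Σ_i [RSS_i/σ² + log(l_i/n)] + 3 m log n.
The noise scale defaults to σ = 1 — the conventional known-variance
normal cost for z-scored input (a robust first-difference MAD estimator
is available for non-z-scaled series).  Minimum segment length is 10
canonical samples.  Pruning is provably exact for this cost (RSS is
superadditive and the log-length term's defect is bounded by zero), and
the implementation is tested for cost equality against an exhaustive
dynamic program on short series.  The change point marking
pre-movement ERD onset is defined as the last detected change point at
or before consonant movement onset; with a 400 ms ground-truth decline
lead the pipeline recovers it to within a few tens of milliseconds.

*Mixed-effects inference.*  For each sub-band, the mean z-scored power
per change-point interval per session (one observation per session ×
interval) is modelled with a fixed interval effect and random session
intercepts.  Full and null (intercept-only) models are fitted by
maximum likelihood — REML likelihoods are not comparable across fixed
effects — and compared by χ² = 2(ℓ_full − ℓ_null) on K−1 degrees of
freedom.  Boundary variance estimates are flagged, and the optimizer
falls back to gradient-free methods when the default fit's Hessian is
singular at the boundary.  Pairwise interval contrasts use the fitted
model's fixed-effect covariance with Tukey HSD adjustment (studentized
range with residual df ≈ n_obs − K − (n_sessions − 1)); "Bonferroni-
corrected pairwise Tukey" is read as a second Bonferroni stage across
the six band-wise families, and both stages are reported separately.
Under a simulated null (31 sessions, 5 intervals, intercept SD 0.5,
residual SD 1) the LRT's type-I rate is calibrated to ~5%.

## The synthetic generator

Each channel is a sum over the six sub-bands of an envelope-modulated,
unit-RMS band-limited Gaussian-noise carrier (narrowband noise, not a
tone, so its Hilbert envelope behaves like cortical bandpower), plus
1/f broadband noise (unit spectrum slope by default, flattened below
1 Hz), plus common-phase 60/120/180 Hz line interference.  Bad channels
are replaced with large low-frequency drift that only exclusion — not
CAR — can remove.  Envelopes are piecewise linear between named event
nodes anchored to each utterance's timing: beta declines from its
baseline starting 400 ms before consonant onset (β_h faster than β_ℓ,
with a brief inhibition transient during the consonant), bottoms out
early in the vowel, peaks briefly before vowel termination, dips, and
rebounds; gamma/high-gamma rise starting 300 ms before onset, peak late
in the consonant (mid-vowel for γ_ℓ, which also shows a return-to-
posture bump), and decay through ISP2.  Per-utterance templates merge
into one session envelope by elementwise min (beta) or max (gamma), so
closely spaced utterances overlap gracefully.  All randomness flows
from one integer seed through a seed sequence, making sessions
bit-reproducible.

Default study conditions: 80 utterances/session, consonants
U(50, 165) ms (mean 107.5), vowels U(250, 525) ms (mean 387.5),
inter-speech gaps U(400, 1200) ms (median 800 ms), 80% of syllables
ending in /i/, 16 channels, 10% bad, two 1 s invalid intervals.  After
the exclusion rules this leaves roughly 50 trials per session.
SimConfig defaults to the deposited-recording rate of 3052 Hz; the
test collection runs at 1000 Hz (all bands sit far below Nyquist
either way), which keeps the default suite and the acceptance script
fast.  Noise amplitudes are chosen for testability — the real
recordings publish no SNR — and carrier/noise scales are irrelevant
after z-scoring.

What the generator does **not** emulate: cortical biophysics, spatial
(somatotopic) structure across the array, cross-channel envelope
correlation, non-stationary artifacts other than the bad-channel
drift, or any acoustic signal.  Passing tests therefore demonstrate
that the pipeline recovers known ERD/ERS structure from realistic
noise and timing variability — not that the real recordings contain
that structure.

## Numerical choices and degenerate inputs

- Analytic series shorter than 16 samples, bandpass edges at or above
  Nyquist, single-channel CAR, zero-variance z-scoring or correlation
  windows, and empty valid-channel sets are all rejected with errors,
  never silently patched.
- Sinc resampling returns constants exactly and is the identity when
  lengths already match.
- Envelope nodes that would violate strict time ordering (degenerate
  timings) are dropped in favour of earlier nodes.
- The wavelet grid-search peak for a Gaussian bump does not sit exactly
  at the bump's σ (mean subtraction shifts the optimum upward); the
  implementation is therefore tested against a direct inner-product
  oracle rather than against σ itself.

## Known limitations

- The LRT's χ² reference is asymptotic; with very few sessions the
  type-I rate drifts above nominal.
- Tukey contrasts use a containment-style residual df approximation
  rather than Satterthwaite/Kenward-Roger.
- Change-point locations on smooth ramps are staircase approximations;
  only well-separated mean shifts have sharply identified locations.
- The deposited 256-channel/3052 Hz recordings are not analysed here;
  all quantitative results in `results/` describe the synthetic study
  conditions above.
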