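# Methods

## Overview

`somnipeak` re-implements, as a tested pipeline, a slow-oscillation (SO)
referenced analysis of transient oscillatory events in sleep EEG. The chain
is: staged polysomnography → preprocessing → time-frequency peak (TF-peak)
detection by watershed segmentation of a baseline-flattened multitaper
spectrogram (4–25 Hz) → annotation of each event with the concurrent SO
(0.3–1.5 Hz) power percentile and phase → per-subject 2-D coupling
histograms (density by frequency × SO-power bin; proportion by frequency ×
SO-phase bin) → column-standardized PCA/ICA across subjects → nonparametric
five-group statistics with FDR control → split-half eigenvector reliability
and permutation-tested one-vs-all classification. A seeded synthetic
staged-PSG generator supplies cohorts with known coupling structure so every
stage can be validated without clinical recordings.

## Preprocessing

Recordings are down-sampled to 100 Hz (polyphase FIR, anti-aliased) and
band-passed 0.1–40 Hz. The band-pass is a zero-phase Butterworth cascade —
4th-order high-pass at 0.1 Hz plus 6th-order low-pass at 40 Hz, each run
forward–backward. Separate sections are used because a single band-pass SOS
with a 0.1 Hz edge at a 100–256 Hz rate is numerically ill-conditioned and
loses stop-band attenuation; the chosen orders give > 20 dB one octave
outside the band after the forward–backward doubling. Zero-phase filtering
matters because group delay would bias downstream SO-phase estimates.

Re-referencing supports common-average and constant (mastoid-like) schemes.
Channel rejection removes at most one channel per recording: flat-line
(per-epoch SD < 0.1 µV in > 5 % of epochs) or amplitude outlier (robust SD
more than 8 times the *other* channels' median robust SD — a leave-one-out
reference, so one degenerate channel cannot poison the scale).

Condition masks select per-sample membership in NREM (N1∪N2∪N3), REM, or
their union; wake is never analysed. Epochs are 30 s, half-open sample
ranges, 0-based.

## TF-peak detection

The substrate is a sliding multitaper spectrogram (1 s window, 0.05 s step,
3 DPSS tapers, time-half-bandwidth 2 → ≈ 2 Hz resolution, enough to resolve
0.8 s sigma bursts at 100 Hz). Power is converted to dB and a per-frequency
baseline (2nd percentile over time) is subtracted, so a stationary 1/f
background maps to ≈ 0 dB and transients stand out.

Segmentation is watershed flooding (8-connected) from marker maxima; every
above-0 dB cell belongs to exactly one catchment region. Three marker
policies exist:

- *strict maxima* (every cell greater than its 8 neighbours) — the exact
  configuration mirrored by the exhaustive `brute_force_peaks` oracle;
- *h-maxima* (morphological reconstruction) — suppresses maxima with
  prominence below a threshold before flooding;
- *footprint maxima* (default in the detector): maxima within a
  0.5 s × 1 Hz neighbourhood that also exceed a flattened height of 14 dB.
  This policy resolves events that are close in time but separated by a
  shallow saddle (which h-maxima-style merging would fuse) and is much
  cheaper on long recordings.

Adjacent regions are then merged while the lower peak rises less than
`prominence_min_db` (default 3 dB) above the connecting saddle, shallowest
saddles first (order-independent). Each surviving region yields one event at
its arg-max cell. Duration and bandwidth are measured on the *near-peak*
subregion (cells within ~6 dB of the peak): with a low-percentile baseline
nearly the whole plane is above threshold, so full catchment basins tile the
plane and their extent reflects background topography rather than the event.
Filters keep events with arg-max frequency in 4–25 Hz, duration 0.1–5 s and
bandwidth 0.5–15 Hz. Long recordings are processed in overlapping 6-min
chunks (5 s overlap) to bound memory and keep cost linear.

With these defaults, on the simulator's 1/f + SO background the detector
recovers ≥ 90 % of injected bursts at ≥ 3 background SD (±0.5 s, ±1.5 Hz)
with < 2 false peaks/min on burst-free signal; both numbers are recomputed
by the test suite and the acceptance script. The detector's practical
resolution limit is ~1 s between same-band events; event rates above
~20/min in one band begin to merge (see "Simulator calibration" below).

## SO annotation and histograms

The SO state is measured with two operators sharing one 0.3–1.5 Hz
zero-phase 4th-order Butterworth filter:

- *power*: 30-s moving average of the squared narrowband signal, evaluated
  every 0.1 s (by Parseval this equals per-window integrated band power),
  then rank-transformed to percentiles ((rank − 0.5)/n × 100) within the
  condition's valid samples, per subject and channel — the within-subject
  normalization implied by percentage axes;
- *phase*: analytic-signal angle minus π, wrapped to [−π, π), so the
  filtered trough maps to 0 rad and the positive peak to ±π.

Events are annotated at their detected times by interpolation between the
two bracketing series samples (complex interpolation for the phase). Plain
nearest-sample lookup is available but adds up to ±0.24 rad quantization
noise per event — an SO cycle at 0.75 Hz advances ~27° per 0.1 s grid step —
and a small systematic bias from the detector's time grid; interpolation
removes both. Events at invalid samples (outside the condition mask) are
dropped and counted. In REM-only analyses only events in the 25–75 %
SO-power interquartile range are kept.

Histograms use 1-Hz frequency bins over 4–25 Hz (configurable), SO-power
quartiles, and 18 phase bins of 20°. The power histogram stores density
(peaks/min in bin) together with the minutes spent per power column, so
density × minutes always reproduces raw counts exactly; the phase histogram
stores proportions summing to 1 (global normalization across the whole map,
matching a single proportion colour scale). Internal layout is fixed as
frequency rows × coupling columns. Group means and patient-minus-control
difference maps follow the convention that positive cells mean more events
in patients.

## Decomposition and statistics

Per channel × condition × histogram kind, subjects' maps are vectorized
(row-major), column-standardized (constant cells set to 0 and flagged, never
dropped, so grids stay aligned across subjects and splits), and decomposed
with PCA (10 components; fewer with a warning when subjects − 1 < 10) and
FastICA (deflation on PCA-whitened data, seeded; 5 components for power
maps, 4 falling back to 3 for phase maps on non-convergence; rank-deficient
matrices are fitted at their effective rank and flagged). Component signs
are arbitrary, so each component is oriented so the majority of patient
groups score at or above the control median; two-sided tests are invariant
to this. Components recurring across channels/conditions are grouped into a
pattern catalogue by greedy centroid clustering on |Pearson r| of loading
maps (threshold 0.7), iterated so every member keeps |r| ≥ threshold with
its centroid; patterns are named by descending member count (Pow1…, Pha1…).
The grouping rule is a design choice — the analysis it mirrors never states
one.

Group comparisons per component: five-group Kruskal–Wallis (tie-corrected;
all-equal data returns H = 0, p = 1), Benjamini–Yekutieli FDR at α = 0.1
with the family defined as one component set (per channel/condition/kind/
method), then — only where the FDR-corrected test survives — two-sided
Mann–Whitney U of controls against each patient group (exact for small
tie-free samples, tie/continuity-corrected normal approximation otherwise)
with Bonferroni correction over the 4 patient contrasts at p ≤ 0.05. Effect
size is the Kruskal–Wallis eta squared, η²_H = (H − k + 1)/(n − k), which
can be slightly negative under the null and is reported as computed.

## Reliability and classification

Split-half reliability divides subjects into two group-balanced halves
(sizes differ by ≤ 1 within each group), fits PCA on each half and on the
full sample, and matches components by greedy maximum-|Spearman| assignment
of loading vectors (PCA order and sign are arbitrary across subsets). The
matched |r| of the first five components is labelled high (> 0.75),
moderate (> 0.5) or low.

One-vs-all classification uses ridge-penalized logistic regression (C = 1)
on component scores with stratified 5-fold CV; every subject is validated
once; fold ROC-AUCs are averaged. PCA is fit on all subjects before CV,
replicating the source design (a strict mode refitting PCA per training
fold exists but is off by default for fidelity). Significance comes from a
label-shuffle permutation test (default 1000 shuffles; the full CV is re-run
per shuffle) with the smoothed estimator p = (1 + #{null ≥ observed}) /
(1 + N), a deliberate deviation from the plain proportion to avoid exact
zeros (the plain proportion is available via `smoothed=False`).

## Synthetic cohorts

Each subject gets a first-order Markov hypnogram over 30-s epochs (dwell
times and transition weights configurable), a 1/f^slope broadband background
(unit SD; slope 1), a slow oscillation made of 0.3–1.5 Hz band-passed noise
scaled by a per-stage gain (N3 2.0 > N2 1.0 > N1 0.5 ≈ REM 0.4, smoothed at
transitions; a pure-0.75 Hz-sinusoid mode exists for convention checks), and
Hann-windowed oscillatory bursts (default 0.8 s, amplitude 3 background SD,
frequency uniform within the class band). Burst times are a Poisson process
on permitted-stage samples thinned twice: by the SO-power-quartile rate
multiplier and by the von Mises density at the SO phase, with the candidate
rate pre-inflated by both mean acceptance factors so quartile q's expected
rate is `event_rate_per_min × multiplier[q]`.

The SO state that drives the coupling — and is logged per event as ground
truth — is the *measurable* one: phase and 30-s bandpower of the base
recording itself, computed with the same operators the analysis uses.
Coupling to the clean SO component instead would add ~8 percentile points of
irreducible disagreement between ground truth and anything an analysis of
the finished recording can estimate.

The slow oscillation is global per subject (shared across channels);
background and event draws are independent per channel. All randomness
derives from a single master seed via stable spawn keys; identical seeds
give bit-identical cohorts. Recordings are scaled to µV (15 µV per unit)
and written as 16-bit EDF with a CSV hypnogram sidecar and a TSV event list.

### Default five-group template

Cohort sizes 39/16/16/17/11 (control/NREMP/NT1/iRBD/FM). Control coupling:
fast sigma 12–15 Hz at 4 events/min with quartile multipliers
(0.25, 0.75, 1.5, 3.5) — strongly concentrated at high SO power, as
spindle-like events are — trough-locked (µ = 0, κ = 4); slow sigma
10–12 Hz at 2/min, up-slope preference (µ = 2, κ = 2), concentrated at the
top quartile; phase-uniform theta 4–8 Hz at 2/min in all sleep stages.
Perturbations: NT1 halves the fast-sigma top-quartile multiplier
(3.5 → 1.75); iRBD additionally halves the fast-sigma phase concentration;
NREMP quarters the phase concentration with rates unchanged; FM adds a
phase-uniform 4–10 Hz class. Magnitudes are simulator parameters, not
claims about patients.

Two calibration constraints fixed these numbers at design time: per-band
rates stay below the detector's ~1 s collision ceiling (top-quartile
injected rates ≳ 25/min lose a third of events to merging, which
asymmetrically compresses exactly the contrasts the templates encode), and
hypnogram dwell times are short (N2 ≈ 2.5 min bouts) so that minutes-long
desk-scale records have a representative stage composition — a real night
averages over many sleep cycles, a 10-minute excerpt with 10-minute bouts
does not.

### What the simulator does not model

No K-complexes, artifacts, arousals, apnoea, EOG/EMG; channels are
statistically independent given the subject (real EEG channels are strongly
correlated); there is no between-subject trait variability in coupling
parameters — within a group, subjects differ only by realization noise.
Passing tests therefore show that the pipeline recovers known coupling
structure from realistic spectra at realistic SNR, not that it reproduces
clinical effect sizes or topographies.

## Validation experiments and problem sizes

The `experiments` module runs each validation from scratch (the acceptance
script reports its numbers; the test suite asserts them):

- watershed vs exhaustive oracle: 100 random noise-free surfaces with ≤ 10
  isolated Gaussian bumps — locations must match cell-exactly;
- trough-locked phase: bursts at every 2nd trough of a pure 0.75 Hz SO over
  45 min (~1000 events); the histogram circular mean must sit at 0 ± 0.05
  rad;
- von Mises recovery: κ = 4, µ = 0 at 20 events/min over 40 min (≥ 500
  events), recovered within ±0.15 rad;
- quartile-rate recovery: multiplier (1,1,1,2) at 3.5/min over ~16 h of N2
  (≥ 2000 events), SO at 3 background SD so the recovery isolates the
  coupling mechanism; top/bottom density ratio within 2 ± 0.3. The rate is
  deliberately low — collision losses at high rates bias the ratio down;
- conservation: density × minutes = counts (exact) and phase proportions
  sum to 1 on simulated cohorts;
- null calibration: 200 score-level null cohorts (all groups from one
  distribution, study-like sizes) — Kruskal–Wallis p uniform (KS) and
  post-cascade false positives within binomial error of α; permutation-test
  p uniform over 40 null replicates at 149 shuffles;
- reliability: a shared-motif cohort (SNR 5, 40 × 84) clears matched
  |Spearman| > 0.75 in ≥ 90 % of 50 splits; pure-noise cohorts stay below
  it in the median;
- NT1-like effect detection: 20 simulated five-group cohorts (10-min
  single-channel recordings, NREM condition, 3-Hz feature bins, concatenated
  power + phase PCA-10 scores, 200 permutations). At this desk scale the
  contrast is recoverable (a single engineered feature separates NT1 at
  AUC ≈ 0.8), but the generic PCA + logistic classifier is noise-limited:
  per-subject density estimates carry Poisson and stage-composition noise
  that whole-night recordings (1–2 orders of magnitude more sleep per
  subject) do not, so cross-validated AUCs are typically 0.6–0.8 rather
  than > 0.8. This limitation is inherent to the desk-scale data volume,
  not to the implementation — the acceptance suite reports it as measured;
- end-to-end: the full pipeline on 99 subjects × 10 min × 2 channels at
  100 Hz (0.1 s detector step, 200 permutations) completes on one CPU well
  inside 15 min.

## Numerical choices and degenerate inputs

Zero-power spectrogram rows are floored at machine epsilon with a warning.
Constant SO-power series yield percentile 50 everywhere with a warning; an
all-zero signal has undefined phase and is flagged invalid. A condition
with fewer than ten valid series samples is marked entirely invalid rather
than producing NaN percentiles. Ties in ranks use average ranks throughout.
Watershed flooding ties resolve deterministically (skimage's ordered
flooding). All-zero feature matrices are skipped with a drop note;
rank-deficient ICA fits are truncated to the effective rank and flagged.
Seeds derived from the master seed are SHA-256-based and stay below 2³¹.
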