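# Methods

## Synthetic cohort model

The generator emulates a five-stage emotion-induction protocol (baseline,
neutral, anger, happiness, sadness recall), one 3-minute single-channel PPG
recording per subject per stage, default 43 subjects at 1024 samples/s.

**Beat shape.** A beat is a raised-cosine rise of duration ST from the
valley level to valley + BVA, followed by a raised-cosine fall of duration
DT back to the valley level; the beat period (true VVI) is ST + DT, and PPI
emerges from consecutive peak times. The pulse shape itself is a free
choice — only the landmark geometry (one peak bounded by two valleys)
matters to the five indices — and raised cosines give exact, analytically
known extrema for recovery tests. The published stage table is internally
consistent with emergent intervals (baseline ST 196.01 + DT 650.84 =
846.85 ms ≈ reported VVI 846.90 ms), which is why VVI/PPI are not drawn
independently. No dicrotic notch, respiratory amplitude modulation,
arrhythmia or motion artifact is modelled.

**Stage parameters.** Population means/SDs of BVA (mV), ST (ms) and DT (ms)
per stage are the published raw-score values of a 43-patient hypertension
cohort (e.g. baseline ST 196.01 (50.12) ms, anger BVA 8.23 (2.89) mV).

**Variance structure.** The published SDs are treated as the marginal
spread of a stage and split into a between-subject and a within-subject
part: each subject draws one standard-normal effect per index — shared
across stages, because individual differences in pulse morphology are
stable traits, which is exactly what motivates differential features — and
the stage mean is shifted by `z · f · sd` with `f = 0.6`; beats then
scatter around the subject's stage mean with SD `sqrt(1 − f²) · sd = 0.8 ·
sd`. The split is a free simulator parameter, not an inferred quantity: the
source table does not decompose variance, and its SDs are strictly
between-subject SDs of stage means, so treating 0.8× them as beat-to-beat
scatter overstates within-recording noise relative to real PPG. Passing
tests therefore demonstrate pipeline correctness under a deliberately hard
noise regime, not field-accuracy on real recordings.

**Per-beat draws.** ST, DT and BVA are drawn independently per beat from
truncated normals (ST ∈ [80, 450] ms, DT ∈ [300, 1200] ms, BVA ≥ 0.5 mV)
whose pre-truncation location is shifted so the *truncated* expectation
equals the configured mean — plain truncation would bias baseline ST by
about +1.4 ms, enough to fail convergence checks at 10⁴ beats.

**Noise.** Additive white Gaussian noise (default SD 0.15 mV) and a 0.2 Hz
sinusoidal baseline wander (default amplitude 0.3 mV, random phase). All
randomness descends from one cohort seed through spawned per-subject seed
sequences, so a cohort is a pure function of (config, seed).

## Delineation

Peaks are local maxima thinned to a refractory spacing (default 0.33 s,
≈ 180 bpm), gated by prominence relative to the median candidate
prominence, then greedily re-selected best-prominence-first (earlier wins
ties). Valleys are the argmin strictly between consecutive retained peaks
(earliest sample on plateaus) plus the argmin before the first peak. Beat
i is (valley_i, peak_i, valley_{i+1}); trailing incomplete beats are
dropped. Timing is at sample resolution (index / fs, no sub-sample
interpolation), so ST + DT = VVI holds exactly by construction, and on
noise-free synthetic input every landmark is recovered to within one
sample.

Two numerical points shaped the default *cohort extraction* path
(`extract_cohort_features`):

- **Detection filter (0.1–8 Hz).** The raised-cosine valley is locally
  flat, so broadband noise makes the between-peak argmin wander tens of
  milliseconds. A zero-phase Butterworth band-pass to 8 Hz keeps the first
  several pulse harmonics (fundamental ≈ 1.2 Hz) while removing the noise
  that creates spurious ripple maxima. The generic `bandpass_filter`
  default remains 0.1–50 Hz, mirroring typical acquisition filtering; the
  extraction filter is bypassable (`bandpass=None`) and parameter-recovery
  analyses of clean synthetic signals run unfiltered.
- **Prominence gate (0.05 of median after smoothing).** Peak prominence on
  this signal family equals BVA, so a strong gate (e.g. 0.3 × median)
  censors genuinely small beats in the BVA left tail. A missed beat merges
  two cycles into one ~1.7 s interval, inflating segment interval-SD
  features by ~100 ms RMSE — far worse than any ripple maximum the gate
  could reject. These defaults were chosen by measuring segment-feature
  RMSE against the generator's truth tables. For raw, unsmoothed input
  `detect_peaks` keeps the stronger 0.3 default.

Filtering does shift the detected onset valley slightly toward the flatter
diastolic side (a near-constant +~30 ms on ST, mirrored in DT); being
common to all stages and subjects, it cancels in contrasts and does not
affect classification.

## Featurization

Segments are half-open 30-s windows keyed by the beat's onset-valley time;
a beat with onset exactly at 30.0 s belongs to the second window. Segment
statistics use the population SD (divisor n). The final beat's PPI is
undefined and excluded pairwise. Segments with fewer than 3 beats are
flagged invalid and dropped. The differential reference is the subject's
mean over their baseline segments — the lowest-variance realization of a
stage-level change score; segment-index-matched pairing was deliberately
not made the default since nothing ties segment 3 of baseline to segment 3
of anger. Baseline rows in baseline-vs-state tasks carry their own delta to
the same reference (zero only on average). In the 2C/3C/4C tasks only the
four recall stages participate; baseline rows carry no emotion label. The
2C positive class is {neutral, happiness} and negative {anger, sadness}
(the granularity tasks follow a valence reading of the circumplex model).

Z-scoring estimates per-column mean and population SD from training rows
only; a constant training column maps to 0 with a warning. In six-fold
cross-validation the statistics are re-estimated from the five training
folds at every split; resubstitution fits them on the full matrix,
consistent with all-train-all-test semantics.

## Classification and validation

RBF-kernel SVM, default C = 10, gamma = "auto" ≡ 1 / (n_features × pooled
feature variance) (= 0.1 after z-scoring ten features). Multi-class
problems train one binary machine per class against the rest; prediction is
the argmax of decision values, ties to the lowest class index. Folds are
deterministic: fold k = segment k of every (subject, stage) recording, so
no recording is split across train and test within a fold and no random
fold assignment exists to seed. Hyperparameters are fixed and logged; no
grid search is performed silently.

## Feature selection

Fitness is the accuracy of the same validation scheme used for reporting
(default six-fold CV). This mirrors the source protocol and therefore
optimizes on the reported folds — a selection bias that is documented
rather than silently "fixed"; evaluators are constructed per matrix, so a
nested scheme can be plugged in by supplying a different fitness callable.
Full search enumerates all 2ⁿ − 1 non-empty subsets (refused above n = 20);
ties resolve to the smaller subset, then the lexicographically smallest
bitstring. GA defaults: population 50, 100 generations, crossover 0.8,
per-bit mutation 1/n, elitism 1, early-stop patience 20, roulette selection
on min-max-scaled fitness; all-zero offspring are re-mutated until
non-empty. Subset evaluations are memoized. With elitism ≥ 1 the best-so-far
fitness is non-decreasing — asserted on the generation log.

## Problem sizes used in tests

Unit and property tests run on 8-subject (and 4-subject, for the
experiment-grid tests) cohorts and short fixed-geometry pulse trains; the
acceptance checks use the full 43-subject cohort for classification and
parameter recovery, and ≥ 600-beat noise-free recordings for grand-mean
recovery of the indices. Qualitative orderings (combined ≥ waveform
features; accuracy falling from 2-class to 4-class granularity) are
asserted as trends over several cohort seeds, not per seed.

## Known limitations

- The generator's i.i.d. beats make consecutive 30-s segments of one
  recording independent; real PPG segments are autocorrelated through slow
  autonomic drift, so real within-recording feature scatter is smaller and
  real subject separation larger than simulated here. Resubstitution
  accuracy on the default cohort consequently tops out below 100% for the
  hardest contrast (baseline vs neutral: the configured stage difference,
  ΔST 9.58 ms and ΔBVA −0.69 mV, is comparable to the segment-mean noise
  `0.8·sd/√35`), whereas the corresponding real-data figure is a clean
  ceiling.
- Amplitudes are in arbitrary-origin mV with valley level 0; no calibration
  to blood-pressure or perfusion units is attempted, and no blood-pressure
  channel is modelled.
- Delineation assumes one peak per cycle; signals with pronounced dicrotic
  notches would need the refractory distance left at ≥ 0.33 s to avoid
  double detection, and very bradycardic rhythms (> 1.65 s periods) exceed
  the generator's truncation bounds.
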