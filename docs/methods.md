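# Methods

This note documents the models, operational definitions, numerical choices
and known limitations behind `sudephys`. It describes what the code
computes and why the defaults are what they are; every empirical claim here
is one the test suite or `scripts/acceptance.py` computes itself.

## Study structure and retrospective alignment

A study is a set of subjects (genotype KO/WT x diet SD/KD x sex), each with
a death day (knockouts die of SUDEP; their paired wild-type littermate is
euthanized the same day and therefore shares the death day but is never a
survival event). Sessions of one modality recur roughly every 10 days until
death. Because mortality age varies widely, endpoints are re-indexed by
days prior to death (PTD): a session on day *r* with death on day *d* sits
at PTD = *d* − *r*. The day of death is PTD 0 and never carries a session;
sessions dated on or after the death day are rejected rather than coerced,
since no subject died during a recording. PTD values pool into closed
10-day bins, bin *k* = ceil(PTD/10) covering [10(*k*−1)+1, 10*k*]; a
session exactly 10*k* days before death therefore belongs to bin *k* (the
bins are half-open in the ceil sense — one consistent choice, since
equidistant assignment is otherwise ambiguous).

## Synthetic cohorts

The generator's defaults are the study conditions, not tuning knobs.

**Survival.** Ages at death are drawn from a normal with the cohort mean
and SD = SEM·√n (KO-SD: 57 ± 2 days SEM, n = 22; KO-KD: 77 ± 4, n = 19),
truncated below at day 22 (the day after weaning) and rounded to integer
days. A truncated normal is the minimal model reproducing a reported
mean ± SEM; it is a modeling convenience, not a claim about the mortality
process. Configurations whose truncation would remove more than half the
mass are rejected, because the sample mean could no longer converge to the
target.

A consequence worth knowing: rounding to integer days creates ties, and
ties cost the log-rank test a few points of power. At these cohort
parameters the Monte-Carlo probability of log-rank p < 0.001 is ≈ 0.92
(it is ≈ 0.95 for unrounded draws). The recovery tests assert the cohort
means to ± 3 SEM and report the separation rate as observed.

**Heart rate.** Wild-type segment means are Gaussian at the reference
parameters (770 ± 43 bpm), so their below-threshold mass is the ~2.3%
normal tail and their ± 2 SD coverage is ~95.4%. Knockout segment means
are a two-component mixture: the reference Gaussian plus a fixed
"bradycardic" component at 620 ± 30 bpm, chosen to sit clearly below the
684 bpm threshold. Only the mixing weight is calibrated — it solves
w·P(low < θ) + (1 − w)·P(high < θ) = target in closed form via normal
CDFs — which keeps calibration one-dimensional and well-posed. The real
study's wild-type *empirical* bradycardic fraction (≈ 7%) exceeds the
Gaussian tail because real rate distributions are heavier-tailed than a
Gaussian; the generator does not emulate that, and passing recovery tests
therefore validate the pipeline's arithmetic, not the Gaussianity of real
mouse heart rate.

**Oximetry.** SaO₂ samples at 5 Hz are a mixture of a baseline component
(SD 1%) and a hypoxemic-dip component fixed at 85 ± 3%. Two targets — the
stream mean and the below-90% fraction — determine two unknowns (weight
and baseline mean). The mean constraint pins the baseline mean for any
weight, reducing calibration to a scalar root problem; it can have two
roots (the baseline's own tail can also supply sub-90 mass), and the
larger root is taken so that the dip component carries the hypoxemia and
the baseline sits above the demarcation line. Each sample independently
fails at least one non-SaO₂ parameter with probability 0.1 (default), so
error-free counts in a 1-h session bracket the few-hundred-to-~1500 range
seen in practice; behavior labels alternate rest/active in ~60 s blocks
with no behavior-dependent SaO₂ shift.

**Airflow.** A quasi-sinusoidal breath train (default 120 breaths/min,
per-breath amplitude jitter 5%, additive noise SD 1% of amplitude) with
apneas injected as envelope scaling by (1 − depth) over a stated number of
cycles; injected events are returned as ground truth with a flag for
whether they meet the ≥ 90% / ≥ 2-cycle criterion.

**EEG/EMG.** States evolve as a first-order chain with transition matrix
p·I + (1 − p)·1πᵀ (stay probability p = 0.9), whose stationary law is the
configured occupancy π for any p — so occupancy targets are exact in
expectation while bouts last ~10 epochs, as in real hypnograms. Per 10-s
epoch, delta (0.5–4 Hz) and EMG (10–50 Hz) log₁₀ band powers are drawn
from state-conditional normals (wake: low delta/high EMG; NREM: high
delta/moderate EMG; REM: both low; SD 0.18 dex) and the traces are
band-limited Gaussian noise scaled to those powers, plus a small broadband
floor. Seizure epochs superimpose high-amplitude spike transients. The
delta band is fixed at 0.5–4 Hz (the acquisition band-pass begins at
0.5 Hz; the upper edge is the conventional delta boundary). Synthesis
supports the acquisition rate of 2 kHz but the drivers and tests run at
100–200 Hz, which preserves both feature bands (Nyquist ≥ 50 Hz) at a
fraction of the cost.

All generators consume an explicit seed or `numpy.random.Generator`;
identical (config, seed) reproduce byte-identical studies. The pipeline
expands one global seed into per-module substreams via
`SeedSequence(seed, spawn_key=(module,))`, so enabling or disabling one
modality never shifts another's draws.

## Analysis pipeline

**Seizures** enter as annotated events (severity is adjudicated upstream;
the module validates grades 1–6 but never re-scores). Burden is
Σ severity·duration in severity-seconds per 48-h session, unnormalized by
time. All events are included — no filtering.

**Sleep staging** log-transforms and z-scores the two band powers, takes
principal components, and partitions with 3-means initialized by a
deterministic farthest-point (maximin) rule — the initialization is a pure
function of the data, so staging is reproducible without an RNG and the
seed matters only for degenerate ties. Clusters map to states by profile,
delta first: the highest-mean-delta cluster is NREM (resolving "low-to-
medium EMG" without a second EMG threshold), then the higher-EMG remainder
is wake, the last REM. The mapping is rule-based, hence invariant to
cluster relabeling. Degenerate feature variance raises an error advising
manual configuration rather than guessing. Band power is the mean
Hann-tapered periodogram over the band; the estimator is deliberately
simple and the band means are what the classifier consumes. Epochs
overlapping seizure or husbandry-check intervals are excluded before
occupancy; occupancy normalizes over analyzed epochs and the excluded
count is reported so exclusion stays auditable.

**Bradycardia.** The wild-type reference pools clean segment means across
both WT diets (they are combined because the reference is a single
Gaussian) and uses the sample SD (n − 1). The threshold is mean − 2·SD
exactly; classification is strictly below. Noisy segments are excluded
from numerator and denominator alike, and a segment reaching
classification while flagged noisy is an error, not a silent skip. The
reference is estimated once from all pooled WT segments, not per-bin.

**Apnea.** The breath-amplitude envelope is a sliding maximum of |airflow|
over 0.6 of a cycle: long enough to always contain a flow extremum during
eupnea, short enough to collapse within a fraction of a cycle of a true
cessation edge, and — unlike Hilbert-magnitude envelopes, which ring at
amplitude steps — strictly local. The baseline is a causal running median
of the envelope over the preceding 10 breaths (robust to isolated deep
breaths). An apnea is a maximal run with envelope ≤ 10% of baseline
lasting at least 2·60/f s; the printed two-cycle formula is implemented as
a duration (its verbatim units are a frequency). Events at exactly 90%
depth count (the criterion is ≥). When no breathing rate is supplied it is
estimated by peak counting over the first 30 s. A pure-Python per-sample
scan (`detect_apneas_bruteforce`) re-derives the intervals independently
of the vectorized run extraction and the two must agree exactly.

**Oximetry.** A sample is error-free only if all eight parameter flags are
valid — a valid SaO₂ with any other failed parameter is excluded. Sessions
with fewer than 50 error-free samples are excluded entirely. Hypoxemia is
strictly below 90%. Per-subject fractions pool counts across the QC-passing
sessions of a bin (rather than averaging per-session fractions), so
concatenating streams within a session commutes with the computation;
cohort statistics are means of per-subject fractions.

**Survival.** Kaplan–Meier estimation and the log-rank test are delegated
to lifelines and cross-checked in the tests against a hand product-limit
estimator and a hand 2x2-per-event-time O/E accumulation. The mean is the
area under the restricted step function, which equals the arithmetic mean
exactly in the no-censoring case (asserted, not assumed). The hazard ratio
is the Mantel–Haenszel O/E form (O_A/E_A)/(O_B/E_B) with a log-scale CI
from se = √(1/E_A + 1/E_B); it needs no iterative fitting and satisfies
HR(A,B) = 1/HR(B,A). Cox regression is out of scope.

**Statistical battery.** The two-way ANOVA uses Type III sums of squares
(mortality makes the designs unbalanced) computed directly from sum-coded
design matrices by least squares: SS of an effect is the residual-SS
increase when its columns are dropped from the full model. Classical
η² = SS_effect/SS_total is reported (the partial variant is a one-line
change; classical is the default because the endpoint tables report shares
of total variance). The implementation agrees with
`statsmodels.anova_lm(typ=3)` under Sum coding to 1e-9 and is fast enough
to run 2000-replicate null simulations in seconds, which is how the
empirical type-I error of the battery is verified (0.05 ± binomial CI).
Welch's t (Welch–Satterthwaite df), Pearson χ² without continuity
correction, and tie-corrected Kruskal–Wallis come from scipy; Dunn's post
hoc z uses pooled mid-ranks with the tie term Σ(t³−t)/(12(N−1)) and Šidák
family-wise adjustment (1 − (1−p)^m) for consistency with the ANOVA
family (Bonferroni available). A Shapiro–Wilk gate (α = 0.05) routes
endpoints that reject normality to the rank-based battery; groups smaller
than 3 pass by default.

## Problem sizes

Default driver/test sizes are chosen so a full simulate → analyze round
trip stays interactive on one CPU: EEG/EMG at 100 Hz with a 1-h staging
window per subject (the 7-h window → 2520-epoch identity is exercised
separately), airflow at 100 Hz for 3-min sessions, oximetry at 5 Hz for
12-min sessions (≈ 540 error-free samples at the default error rate, inside
the realistic per-session range), 16 ECG segments per session with a 10%
noisy fraction. Recovery experiments average 100 seeded replicates; at
those sizes every configured target is recovered within Monte-Carlo error.

## Limitations

* Waveforms are statistical stand-ins: no ECG/EEG morphology, no seizure
  waveform realism, no circadian structure, no within-subject correlation
  across repeated sessions (draws are independent given the cohort/bin).
  Passing recovery tests validates the quantification arithmetic under the
  configured distributions, not distributional realism of mouse physiology.
* Seizure detection from raw EEG and video adjudication are out of scope;
  events and exclusion intervals are inputs.
* The ECG noise screen on real traces is a simple amplitude/variance
  heuristic; in synthetic data noise is a generator flag.
* Sleep-bout/transition statistics and REM theta are not modeled or
  quantified; only occupancy is.
* The staging partition (PCA + 3-means + delta-first mapping) is one
  defensible realization of "principal components segregate the states";
  agreement against generator ground truth (≥ 95% at default separation)
  is its acceptance surface.
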