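# Methods

## Problem and scope

`lungphase` covers the measurement side of breathing-phase detection in
chest-wall lung-sound recordings: turning audio into the spectrogram
representation that image-based detectors consume, cleaning scored
detections into a usable annotation, and quantifying how well two
annotation sources — human or automatic — agree.  Training an object
detector is out of scope; the detector is a contract (scored phase boxes),
with a simple energy-based baseline supplied so the chain runs without a
learned model.

## Data model

A phase interval is a closed-open span [start, end) in seconds with a class
(inspiration or expiration) and, for detector output, a confidence in
[0, 1].  The closed-open convention makes abutting phases measure-disjoint,
which matters because post-processing deliberately makes neighbouring boxes
abut.  Human-style annotation sets must be non-overlapping; detector sets
may overlap until post-processed.  Recording duration comes from the audio
file when available, otherwise from the TextGrid tier extent or the CSV
`duration_s` column — the time-based agreement measures need a total extent
for the negative (no-phase) class.

TextGrid reading accepts both the long and short Praat text dialects by
reducing both to a single token stream.  The phase-label mapping is a
configurable convention ({"inspiration", "i", "insp"} etc.,
case-insensitive), since annotation practice varies between labs.

## Spectrogram

STFT with 4096-sample segments, 3200-sample overlap (hop 896), Hann window,
no padding: a recording of N samples yields floor((N − 4096)/896) + 1
frames, so 10 s and 15 s files at 44.1 kHz give 488 and 734 columns.  Bins
with centre frequency ≥ 2000 Hz are discarded (186 rows remain at the
default rate); chest-wall lung sounds carry little energy above that and
the crop concentrates image resolution where the signal is.  Magnitudes are
expressed in dB relative to the file maximum and clipped at −80 dB — an
absolute scale would make image contrast depend on recording gain.  The
Hann window and the dB floor are package choices; they affect image
contrast, not geometry.  PNG export min-max scales to 8 bits, replicates
the single channel into three (the convention of RGB-pretrained detectors),
and puts low frequencies at the bottom.  A degenerate constant spectrogram
maps to 0 rather than dividing by zero dynamic range.

## Baseline detector

Band-pass 100–1500 Hz (4th-order Butterworth, zero-phase), RMS envelope
smoothed over 150 ms, hysteresis segmentation at 18 % (open) / 10 % (close)
of the file's peak envelope, candidates shorter than 250 ms discarded.
Classification assumes inspiration/expiration alternation: within each
adjacent candidate pair the louder member is inspiration, and a trailing
unpaired candidate continues the alternation.  Confidence is
sqrt(mean envelope / peak envelope): the square root is a deliberate
loudness compression so that a clearly audible expiration at ~0.4 of the
inspiration amplitude scores ~0.6 rather than ~0.35 — a linear scale would
let the default 50 % confidence pruning delete every quiet-but-real
expiration, turning the pruning stage into an accidental class filter.
All thresholds live in `DetectorConfig`.  The detector is deterministic
and makes no claim to clinical accuracy; it exists to exercise the
pipeline and as a reference implementation of the contract.

## Post-processing

Three stages, in order.  (1) Pruning is strictly-below: a box at exactly
the threshold survives.  (2) Duplicate suppression is greedy in descending
confidence (ties: earlier start, then earlier end), same-class only, with
overlap measured by Jaccard index by default — cross-class overlap is
legitimate phase adjacency, not duplication.  A fraction-of-smaller-box
criterion is available (`overlap="min"`) because "overlap > 50 %" admits
both readings; the default stays Jaccard for consistency with the box
agreement method.  (3) Overlap shrinking is a single left-to-right sweep
resolving each successive overlapping pair by shrinking both members by
half the overlap.  Residual overlaps after duplicate removal are small
(typically under 10 % of a box), so sweep order has negligible effect, but
a fixed order makes the output deterministic; an overlap so large that the
shrink would invert a box is an error rather than a silent repair.  The
chain is idempotent and never loses boxes at the shrink stage, so
n_input = n_output + n_pruned + n_suppressed exactly.

## Box agreement (method 1)

Same-class box pairs with Jaccard > 0.5 are candidate matches; matching is
one-to-one, greedy in descending Jaccard.  At a 0.5 threshold a box can
rarely have two admissible partners, and the greedy matching is verified
against exhaustive optimal matching on small random instances.  The
percentage-agreement denominator is the mean box count of the two sources:
symmetric (annotator-vs-annotator comparisons have no natural reference)
and equal to the intuitive matched fraction when counts agree; reference-
and max-count denominators are options.  Corpus aggregation pools counts
over files by default, with unweighted per-file averaging as an option.
Two empty sets agree 100 % by convention.

## Time agreement (method 2)

Confusion durations are computed exactly by interval sweeps (merge /
intersect / complement on sorted disjoint spans), not on a sampled grid;
the test suite cross-checks the sweep against an independent 1 ms
rasterization oracle.  The FP/FN orientation follows the definitions the
statistics were built on — FP = A − B with A the *reference* region — which
is the mirror of the usual screening convention; the
`orientation="conventional"` switch swaps roles explicitly, and CLI
reports carry both orientations labelled, rather than silently picking one.
Sensitivity and specificity with a zero denominator are undefined (NaN)
and excluded from corpus means.

Pseudo-kappa: p_o is the duration-weighted pooled agreement
(TP + TN)/total over the corpus ("fraction of time of agreement"); p_e is
the mean pooled agreement over `n_shuffles` random derangements of the
file pairing — a derangement, so no annotation is ever compared to its own
recording — with mismatched durations truncated to the shorter file.
κ = (p_o − p_e)/(1 − p_e); p_e = 1 is degenerate and flagged.  Defaults:
100 shuffles, 1000 bootstrap replicates (resampling recordings with
replacement, percentile 2.5/97.5), seed mandatory.  Implementation note:
the n×n matrix of cross-file agreement durations is precomputed once, so
each shuffle or bootstrap replicate is an O(n) table lookup; the statistic
is identical to the direct computation.  Verbal interpretation uses the
conventional scale with left-open bins, so 0.20/0.40/0.60/0.80 fall in the
lower category; κ ≤ 0 reads "no agreement".

Note that with phases occupying ~85 % of a recording, chance agreement p_e
is itself high (~0.75), so even a detector with near-perfect coverage
scores κ around 0.5–0.6 against truth.  This is a property of the
statistic's sensitivity to the small negative class, visible equally in
the specificity, not an implementation artefact.

## Synthetic data

The generator's defaults are the study conditions: 15 s mono files at
44.1 kHz, 15 breaths/min, I:E ratio 1:1.5, 15 % of each cycle silent
(split into a half-pause after each phase), expiration at 0.4 of
inspiration amplitude, per-phase duration jitter SD 0.1 s.  Audio is
100–1200 Hz band-passed white noise under a smooth (50 ms) amplitude
envelope with a −40 dB pause floor, placing all content inside the
spectrogram crop band.  The imperfect-annotator model jitters each
boundary with independent Gaussian noise (clipped so intervals stay valid
and non-overlapping), drops phases with probability `miss_prob`, and
inserts Poisson-distributed spurious short phases into silent gaps.

What the generator does *not* emulate: adventitious sounds (crackles,
wheezes), heart-sound contamination, airflow physiology, equipment and
site variability, or genuinely ambiguous phase boundaries.  Passing tests
therefore demonstrate that the measurement machinery is correct and that
the pipeline degrades monotonically with annotation noise — not that the
baseline detector would perform at any particular level on clinical
recordings.

## Problem sizes and numerics

The validation suite uses 500 randomized region pairs for the sweep-vs-grid
oracle, 50-file corpora for kappa calibration (|κ| < 0.05 on independent
corpora at 200 shuffles), 200 random scored-box sets for post-processing
guarantees, 1000 small instances for matching optimality, and 20-file ×
20-replicate corpora per jitter level (σ ∈ {0, 0.1, 0.3, 0.6} s) for the
degradation study; the acceptance script runs a 20-file corpus with 1000
bootstrap replicates.  Duration conservation (tp+fp+tn+fn = total) holds
to 1e-9 s; TextGrid/CSV round-trips preserve endpoints to 1e-6 s.  Ties in
duplicate suppression and shrink order are broken by earlier start then
earlier end; all stochastic components take explicit seeds and are
reproducible across platforms via numpy's seeded generators.

## Known limitations

- The baseline detector's alternation labelling mislabels phases when a
  candidate is missed or spurious; it has no proposal mechanism comparable
  to a learned detector.
- Pseudo-kappa is implemented for exactly two sources; no multi-annotator
  generalization.
- Bootstrap CIs resample recordings only; shuffle noise in p_e is averaged,
  not propagated.
- TextGrid support covers interval tiers in the two text dialects; point
  tiers are skipped and binary TextGrids are not read.
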