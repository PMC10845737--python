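# Methods

## Decision model

A case consists of 1–12 image sets, each carrying one algorithm
confidence score s ∈ [0, 1] and one pathologist score p ∈ {1..5}. Each
image set groups three candidate images ranked by the detector; the
set-level algorithm score is taken to be the best candidate score in the
set, which preserves the ranking semantics under which sets are presented.

The classification rule is evaluated in fixed order:

1. **positive** — #{sets with p = 5} ≥ 2 (the algorithm score is never
   consulted on this branch; p = 4 never counts);
2. **negative** — otherwise, if the unweighted mean of s over *all* of
   the case's sets is strictly < 0.6;
3. **in doubt** — otherwise (mean ≥ 0.6, boundary inclusive).

In-doubt cases are referred: the expert's call replaces the machine
label. Positive/negative labels stand even when an expert call is
recorded. Cohort sensitivity is computed among ganglion-present cases
only, pre-referral (in-doubt counted as not-yet-correct) and
post-referral. "Positive" always means ganglion cells present
(non-HSCR); the enum names carry the convention to keep the sign from
inverting silently.

Missing pathologist scores are rejected at the I/O boundary rather than
imputed: a score table row without a 1–5 value is a validation error.

## Discordance analysis

Set-level error labels use strict cutoffs: false negative iff p = 5 and
s < 0.3; false positive iff p = 1 and s > 0.7; s = 0.3 or 0.7 exactly is
concordant. The two conditions are mutually exclusive by construction
(they require different p).

Cause annotations are expert-assigned data carried on the records, never
inferred from images. In the per-stratum tables, cause counts are tallied
over discordant sets only; one set may carry several causes, and a
discordant set with no annotation is tallied as `unknown`. Cause
percentages are reported relative to the error-type total (FP or FN
count), matching how such tables are conventionally printed, so each
error type's cause percentages sum to ~100% (above 100% when multiple
causes co-occur).

Rates are stored at full precision; only the text renderers round, using
two decimals below 1% and one decimal otherwise. The chi-square test is
the Pearson statistic with E = (row total × column total)/N,
df = (r−1)(c−1), and an upper-tail p-value from `scipy.stats.chi2.sf`
(the regularized upper incomplete gamma function). A zero row or column
marginal raises a degenerate-table error; Yates' continuity correction
(|O−E| − 0.5, clipped at 0) is available for 2×2 tables. Pairwise
comparisons are reported uncorrected by default with an optional
Bonferroni helper, since multiple pairwise tests inflate the family-wise
error rate.

## Color distributions

Histograms use 256 bins per channel over 8-bit values and are normalized
per channel (each of R, G, B sums to 1 within 1e-9). The distance is the
squared L2 norm summed over all 768 bins with no channel averaging.
Whether published case-level distance magnitudes used per-channel or
concatenated-renormalized histograms, or averaged across channels, is not
determinable without the original images; the absolute magnitudes are
therefore not calibrated here, and only relative comparisons (ratios,
percent differences, orderings) are meaningful outputs. Case-level
aggregation is an image-unweighted mean of normalized histograms, so a
small image counts as much as a large one.

No background masking is applied by default; `background_mask` offers an
optional luminance threshold (mean channel value < 240) to exclude blank
glass when tiles contain large empty regions.

## Synthetic score model

No generative model of detector scores is published, so the generator
uses a Beta family for bounded support and easy separation control:

| parameter | default | meaning |
| --- | --- | --- |
| `n_cases` | 186 | validation-cohort scale |
| `prevalence_hscr` | 62/186 | fraction of ganglion-absent cases |
| `sets_per_case` | (8, 12) | uniform range; cohort averages ~12 sets/case |
| `dsa_true_dist` | Beta(5, 2) | scores of true-ganglion sets (mean 0.71) |
| `dsa_false_dist` | Beta(2, 5) | scores of negative sets (mean 0.29) |
| `artifact_prob` | 0.10 | chance a true-ganglion set has a technical artifact |
| `artifact_dsa_penalty` | 0.5 | score reduction under artifact (clipped to [0, 1]) |
| `mimic_prob` | 0.05 | chance a negative set is a high-scoring mimic |
| `ganglion_set_prob` | 0.7 | per-set chance of true ganglion content in a positive case |

Pathologist scores are categorical draws from a 2×5 confusion table
(rows: non-ganglion / ganglion content; default 80% mass on the correct
extreme). Artifacts act on the algorithm score only — a pathologist reads
through staining problems that derail the detector — so artifact-heavy
cohorts become false-negative dominant while mimic-heavy cohorts become
false-positive dominant, the two regimes observed across external and
home laboratories. Ganglion-absent cases contain no true-ganglion sets;
ganglion-present cases are forced to contain at least one. Expert calls
always equal ground truth, modelling reliable consultation.

Randomness: `numpy.random.default_rng` (PCG64) seeded through
`SeedSequence` fan-out, one child stream per case and per tile, so any
subset regenerates identically regardless of collection size.

What the score generator does **not** emulate: correlation of scores
within a case beyond shared content flags, drift of pathologist behavior
over time, set-to-set candidate overlap, and center-specific score
calibration. Passing tests therefore demonstrate the *machinery* —
decision rule, tabulation, statistics — under controlled regimes, not
the operating characteristics of any real detector.

## Tile renderer

Tiles are procedural, not learned: an eosinophilic field with
low-frequency brightness texture, scattered hematoxylin nuclei, plus
content-specific elements (large pale-cytoplasm blobs with dark rims and
an eccentric nucleolus for ganglion content; wavy pale bands for plexus).
This is adequate because only histogram-level behavior is consumed
downstream; no claim of photorealism is made. The default eosin color is
kept clear of the 8-bit ceiling so that scanner noise broadens histograms
instead of piling clipped pixels into bin 255.

Stain profiles apply a per-channel affine transform (gain, offset) after
rendering; scanner profiles apply Gaussian blur, then gamma, then
additive per-pixel Gaussian color noise, with a final clip to [0, 255]
and rounding. With identity stain and a neutral scanner the pipeline
returns the content layer bit-exactly, which anchors the renderer tests.

Two scanner preset families serve different purposes. `SCANNER_PROFILES`
emulates the study structure: two narrow-rendering devices whose
aggregate histograms sit close together (~0.0015 apart on 6-tile
aggregates) and one wide-spread device far from both (~0.004–0.008),
reproducing the wide-distribution / low-peak pattern.
`WELL_SEPARATED_SCANNERS` is the parameter-recovery harness: gamma
1.45 / 1.00 / 0.65 with spreads 1 / 7 / 18, separated enough that
single-tile histograms are attributable to their source device; the
recovery experiment uses 96×96 tiles, 12-tile aggregate references and
100 queries per profile.

## Numerical and design choices

- Classification means use `statistics.fmean`; the exhaustive rule check
  applies the same float arithmetic in the oracle, so grid boundary
  cases (mean exactly 0.6 up to rounding) agree by construction.
- Histogram normalization is validated at 1e-8 absolute tolerance;
  aggregation preserves it to 1e-9.
- Nearest-reference assignment breaks ties toward the first label in
  reference insertion order (strict `<` comparison).
- CSV round trips are bit-exact: scores are written with `%.17g` and read
  with pandas' `round_trip` float parser.
- Report JSON contains no timestamps and is key-sorted, so identical
  inputs give byte-identical outputs.
- Chi-square inputs must be integer counts; real-valued tables are
  rejected rather than silently rounded.

## Validation problem sizes

The regime-structure checks use 500-case cohorts (~5,000 image sets
each), large enough that the FN/FP asymmetry exceeds a 3:1 ratio with
margin at the default confusion rates. The scanner-recovery experiment
uses 300 query tiles (100 per profile); accuracy across seeds is
typically 94–100% against the 90% acceptance margin chosen for it. The
exhaustive decision-rule check enumerates all 30,855 score multisets for
cases of up to three sets on a 0.1 algorithm-score grid.

## Known limitations

- Absolute histogram-distance magnitudes depend on tile content mix and
  are not calibrated to any published value; only relative statements
  are supported.
- The cause taxonomy is carried as data; nothing validates that
  annotations are plausible for the images they describe.
- The decision rule's thresholds (0.6 mean-score cutoff, two-certain-set
  criterion, 0.3/0.7 discordance cutoffs) are fixed inputs from the
  system being evaluated, not fitted here; the package exposes them as
  parameters but provides no tuning machinery.
- Stratum comparisons assume independent image sets; sets from the same
  case are correlated in reality, which anticonservatively narrows
  chi-square p-values.
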