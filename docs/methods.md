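# Methods

## The assay and its statistical model

`wntscreen` analyses dual-luciferase reporter screens of the canonical
Wnt/β-catenin pathway. Each well of a 384-well plate carries cells with
two reporters: firefly luciferase driven by a β-catenin-activated
promoter (the experimental signal) and *Renilla* luciferase driven by a
constitutive promoter (an internal control proportional to viable cell
number). Each test chemical occupies one well per concentration per
replicate day; every plate also contains solvent-only vehicle wells and
six spiked control chemicals (three known pathway activators, three
inhibitors) at random positions.

The analysis chain is:

1. **Wnt luciferase ratio.** Per well, firefly / *Renilla*. Dividing by
   the internal control removes well-to-well variation in cell number
   and lysis efficiency — and, importantly, divides out pure toxicity,
   which depresses both channels equally.
2. **Plate median centering.** Within each (plate, replicate day), the
   ratio is divided by the plate median (the *Wnt ratio*) and the raw
   *Renilla* value is divided by its plate median (the *Cell Health*
   metric). Because a plate-wide multiplicative effect (reagent batch,
   reader gain, incubation time) scales every well equally, the median
   is an estimator of exactly that effect, robust to a minority of
   active or toxic wells. After centering, the plate median of both
   metrics is identically 1.
3. **log2 fold change.** Per well, log2(Wnt ratio) minus the mean
   log2(Wnt ratio) of the same plate's vehicle wells; likewise for Cell
   Health. Taking the vehicle wells (not the plate median) as the
   reference makes the fold change interpretable as "relative to
   solvent", even on plates where many wells are active.
4. **Replicate summarization.** Per chemical × concentration, values
   are averaged over plates within a day first, then over replicate
   days. Significance is a two-sided unpaired Welch *t*-test of the
   per-day log2 fold changes against the log2 fold changes of the
   vehicle wells on the plates that carried the chemical. With fewer
   than two values in either group, or zero variance in both groups
   with unequal means, the p-value is reported absent (NaN) rather than
   fabricated.
5. **Wnt Score.** Per chemical, the unweighted mean over concentrations
   of the log2 fold change multiplied by the mean Cell Health:

       WntScore = mean_c(log2FC) × mean_c(CellHealth)

   Cell Health near 1 leaves the activity estimate untouched; viability
   loss shrinks the score toward zero, penalizing chemicals whose
   apparent reporter modulation rides on toxicity. A variant
   (`variant="slope"`) additionally multiplies by the
   concentration-response slope of the log2 fold change; the default is
   the product form because it is the form the published >0.4 hit
   threshold was calibrated against. The variant used is recorded in
   the output metadata.
6. **Hit calling.** Activator: min p < 0.05, mean log2FC > +1, and
   |Wnt Score| > 0.4. Inhibitor: the same with mean log2FC < −1. The
   score threshold is applied to the absolute value so inhibitors
   (negative scores) can pass. Toxic: mean Cell-Health log2FC < −1 with
   p < 0.05; toxicity takes precedence in the single `hit_class` label
   but the activator/inhibitor facts are kept as boolean columns. No
   multiple-testing correction is applied by default (raw p-values are
   what the thresholds were defined on); Benjamini–Hochberg q-values
   are available behind `bh_correction=True` as a clearly labeled
   extension.
7. **QC.** Per plate × day: the Z-factor
   `1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|` (sample sd, n−1) of activator
   and of inhibitor control wells against vehicle wells, a sign check
   of each control family's mean log2 fold change (a violated sign
   flags a possible plate swap), and the coefficient of variation of
   the vehicle ratio. Equal control and vehicle means yield a −inf
   sentinel, never a fake finite score.

Slopes (`response_slope`, `toxicity_slope`) are ordinary least-squares
slopes against log10(concentration/µM) — linear summaries of
monotonicity and potency direction, not Hill fits. The package
deliberately does not fit EC50/Hill parameters to screen data: with one
well per concentration per day, four-parameter fits are underdetermined
and fragile.

## Cross-context toxicity and ΔΔCt

`compare_context_toxicity` median-centers a per-chemical toxicity
metric within each cellular context (division by the cross-chemical
median, so 1 = typical health), averages over concentrations, joins on
chemical id, and ranks by the absolute difference of centered values to
surface context-specific toxicants.

`delta_delta_ct` implements relative qPCR quantification: ΔCt =
Ct_target − Ct_reference per sample, ΔΔCt = mean ΔCt_treated − mean
ΔCt_control, fold change = 2^(−ΔΔCt) (amplification efficiency 2).
Per-replicate fold changes are also returned for downstream statistics.

## Structural clustering

Hit chemicals are grouped by topology-only structural similarity:

- **Atom pairs.** Each molecule (SMILES parsed by RDKit; hydrogens
  implicit) is reduced to a multiset of (descriptor, shortest-path bond
  distance, descriptor) keys, descriptor = (element, heavy-atom degree,
  π-electron count), distances by BFS, truncated at `max_dist` = 7
  bonds (the classic atom-pair truncation; configurable). Aromatic
  atoms carry π-count 1; otherwise a double bond contributes 1 and a
  triple bond 2. For a connected n-atom molecule with unbounded
  distance, the profile holds exactly n(n−1)/2 pairs.
- **Similarity.** Counted-multiset Tanimoto Σ min / Σ max (the binary
  unique-key variant is available behind `counted=False`). Distance =
  1 − similarity; the triangle inequality is not guaranteed and not
  relied upon.
- **Clustering.** Average-linkage agglomerative clustering
  (scipy linkage on the condensed distance matrix), with labels sorted
  before linkage so results are invariant to input row order; flat
  clusters by count or height.
- **Embedding.** Classical (Torgerson) MDS implemented in-package:
  double-center the squared distances, eigendecompose, embed on the
  top-k axes scaled by √eigenvalue. Negative and numerically-null
  eigenvalues (< 10⁻¹² of the largest) are clipped to zero, and each
  axis is sign-fixed so its first nonzero loading is positive, making
  the embedding deterministic. On genuinely Euclidean input the
  embedding reproduces all pairwise distances to machine precision.

## Exposure prioritization

Predicted human intake tables (mg per kg bodyweight per day, per
chemical and demographic) are joined to the score table. The upper 95%
confidence bound is the default ranking statistic, with the median
estimate carried as an alternative; percentiles use mean ranks for
ties, so they are invariant under monotone transforms of the exposure
scale. Hits sort above non-hits and by exposure descending within
class; hits lacking an exposure record are listed in a separate annex
rather than silently dropped. The exposure-inference model itself is
out of scope — its output is consumed as a table, and a seeded
lognormal generator (`simulate_exposure_table`) stands in for it in
tests and demos.

## The synthetic screen generator

Real raw plate data for this kind of screen are rarely redistributable,
so the package ships a generator whose ground truth makes every
downstream stage testable. Per well:

    renilla = baseline_renilla × plate_effect × viability(c) × ε_r
    firefly = baseline_firefly × plate_effect × activity(c) × viability(c) × ε_f

with Hill activation `activity = 1 + (emax − 1)·c^n/(c^n + EC50^n)`,
Hill viability `1/(1 + (c/TC50)^h)`, a lognormal per-(plate, day) scale
shared by both channels, and independent per-well lognormal noise
(optional channel correlation). This structure gives the normalization
a recoverable target: the plate effect is exactly what median centering
must remove, and viability cancels in the ratio while remaining visible
in the *Renilla* channel.

Defaults, chosen once as realistic screen conditions: six half-log
concentrations 0.1–31.6 µM (a conventional screening series), four
replicate days with one well per chemical × concentration × day, 16
vehicle wells per plate, six controls (three activators with emax 8,
three inhibitors with emax 1/8, EC50 0.5 µM) at two technical-replicate
wells each, re-randomized positions per plate, `noise_sigma` 0.2 and
`plate_effect_sigma` 0.15 (log-scale sds matching the 15–25%
luminescence CVs typical of dual-glo assays), baselines 10,000/5,000
RLU. Everything is reproducible from a single integer seed.

What the generator does **not** emulate — hence what passing tests do
not show about real data: edge/evaporation gradients and other spatial
plate artifacts, cross-talk between adjacent wells, compound
fluorescence or color quenching interfering with luminescence,
pipetting dropouts, day-dependent drift of control potency, and
non-Hill (e.g. biphasic) pharmacology. Conclusions about those require
real plates.

## Numerical and design notes

- Sample standard deviations (n−1) throughout (t-tests, Z-factors,
  vehicle CV).
- The Welch test with four replicate days is slightly liberal (its true
  type-I rate at α = 0.05 is ≈ 0.056–0.06 for n = 4 vs a large vehicle
  pool); this is a property of small-sample t-testing, shared with the
  plain screen-wise t-test the analysis mirrors, and is why calibration
  is checked against a binomial interval rather than asserted exact.
  The calibration experiment uses a single test concentration so each
  chemical contributes one independent test.
- Wells with *Renilla* = 0 are flagged dead and excluded with a
  warning; plates without vehicle wells are an error (the fold-change
  reference is undefined); plates without control wells are flagged in
  QC but not fatal.
- Concentrations are held in µM internally; readers convert from an
  optional units column (nM, mM, M) at the boundary.
- Result tables are TSV with a fixed column order and 12 significant
  digits, so write → read round-trips are lossless at that precision;
  the pipeline manifest stores a sha256 checksum per table, making any
  post-hoc edit detectable and rerun identity checkable.
- Two empty atom-pair profiles (single-atom molecules) compare as
  similarity 1 only when they came from the identical SMILES string,
  else 0, with a warning either way.

## Problem sizes

The test suite and the acceptance script run screens of 10–550 test
chemicals (one or six concentrations, four days — up to ≈ 13,000
wells), a 20-molecule four-family fixture for clustering, and 20-point
planar configurations for MDS; these sizes give stable statistics
(binomial half-width ≈ ±0.019 at n = 500 for the calibration check)
while keeping a full run in tens of seconds.

## Known limitations

- Hit calling uses fixed thresholds, not decision theory; the
  thresholds are exposed (`HitThresholds`) and logged per run.
- The Wnt Score is a heuristic composite; its slope variant and the
  product form can disagree for non-monotone responses.
- Atom-pair similarity ignores stereochemistry, charges beyond the
  element symbol, and 3-D shape; structurally dissimilar chemicals with
  a shared mechanism will not cluster.
- `compare_context_toxicity` assumes both context metrics are positive
  and median-scaled comparably; it ranks, it does not test.
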