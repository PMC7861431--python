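# Methods

`cfcna` implements copy-number alteration (CNA) analysis for shallow
whole-genome sequencing of plasma cell-free DNA (cfDNA), the workflow used in
liquid-biopsy screening of solid tumours and, in its original form, in
non-invasive prenatal testing (NIPT).  Reads are counted in fixed 500 kb bins
over the 22 autosomes; everything downstream operates on those bin counts.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Copy-number mixture model

A fraction `f` of the cell-free DNA derives from tumour (or foetal) cells.  A
genomic segment present at integer copy number `c` in those cells changes the
expected relative coverage of its bins by the mixture factor

    coverage ratio = (2(1 - f) + c f) / 2,      effect size e = f (c - 2) / 2.

All quantitative interpretation inverts this relation: the tumour copy number
implied by an observed effect size is `c = 2 + 2 e / f` (for example
`e = 4.5%` at `f = 3%` gives `c = 5`).  An *amplification* is a gain reaching
at least 5 copies in the tumour cells, i.e. `e / f >= 1.5`; when no fraction
estimate is available the fallback rule is `e > 4.5%`.  The boundary
`e/f = 1.5` is classified as amplification so that the rule coincides exactly
(bit-for-bit, because the classifier evaluates the same expression) with
`c >= 5`.

## Reference panel and within-sample normalization

The expectation for each bin is built from a panel of unaffected samples.
Normalization is *within-sample*: for each target bin `t` a set `R_t` of up
to `n_ref = 100` reference bins is chosen from **other chromosomes** (so a
whole-chromosome event cannot normalize itself away), and the normalized
value of the target in a sample is

    v_t = count_t / mean(count over R_t, same sample).

Reference bins are ranked by the across-panel variance of the per-sample
log-ratio `log(count_t / count_candidate)`; bins whose counts track the
target across samples share its locus bias (GC content, mappability) and
cancel it.  A bin with fewer than `min_ref = 25` usable candidates, or a zero
median count, is masked rather than imputed.  Panel mean `mu_t` and SD
`sigma_t` of `v_t` give the per-bin z-score of a test sample,
`z_t = (v_t - mu_t) / sigma_t`, and the effect size `e_t = v_t / mu_t - 1`.
`sigma_t` is floored at `1e-4 mu_t`, purely numerical safety for degenerate
panels, far below any real panel's variability.

Panel sample QC scores each sample by its mean absolute error,
`MAE = mean_t |v_t / mu_t - 1|`; samples with `MAE > 2.5%` are excluded
(strictly above: a sample exactly at the threshold is retained).  The MAE is
computed against the *leave-one-out* panel mean: on panels of hundreds of
samples this is indistinguishable from the full-panel mean, but on small
panels the full-panel mean contains the sample itself and deflates its MAE by
`(N-1)/N`, blurring the strict boundary.

Small panels overfit: reference bins are selected to minimize panel-internal
variance, so held-out samples show inflated z-scores (empirically, z SD ~1.3
against a 20-sample panel, ~1.2 against 100, approaching 1 for large panels).
The method is designed for panels of several hundred samples; panel members
themselves are audited with leave-one-out statistics, which do not suffer
this bias.

### Recurrent-artifact blacklist

Bins called in two or more panel samples (each called leave-one-out against
the rest) are blacklisted, together with any user-supplied static regions
(segmental duplications, variable centromeres), and the result is a merged
interval list.  The screening z uses **robust** leave-one-out statistics
(median and 1.4826·MAD): an all-or-none artifact present in ~10% of panel
samples inflates the moment SD of its own bin and caps its plain z near 4
regardless of artifact size — it would mask itself.  The median spread is
untouched by a minority artifact, so robust screening detects it; case
calling keeps moment statistics, as in the upstream method.

## Within-sample z-score caller

Segmentation combines consecutive bins with Stouffer's method,
`Z = sum(z_i) / sqrt(n)`.  Per chromosome, *all* contiguous windows over
usable bins are evaluated exhaustively (O(n²) per chromosome is trivial at
~500 bins); the window with maximal |Z| among those with `|Z| >= 4.95` and
`|mean e| >= 1.5%` (both inclusive) and concordant signs of `Z` and `mean e`
is emitted, and the flanks are re-scanned recursively.  Ties in |Z| break
toward the longer window, then the leftmost, making output deterministic.
Mixed-sign windows are penalized naturally by cancellation; no post-hoc
re-segmentation is applied, so adjacent gains of different magnitude can
merge — the known weakness of this segmentation style, under which focal
amplifications may be reported inside a broader gain.

## Targeted analysis

A configurable list of cancer-associated regions is scored per sample: a
single-gene target takes the z and effect size ("ratio") of its containing
bin; a larger region takes the medians over its overlapping usable bins
(median, not peak — robust to one outlier bin, invariant to bin order).
Hits are reported at an exploratory cut `z >= 3.0` and a stringent cut
`z > 5.0`; the inclusive/strict convention is the one under which the two
printed hit counts of the emulated study are simultaneously consistent.  At
`z >= 3.0`, roughly `0.001 x n_regions x n_samples` false positives are
expected and reported as an annotation, not a filter.  The packaged region
and actionable-gene BEDs (GRCh37) are explicit reconstructions — marked
non-authoritative in the files — and are user-replaceable.

## Tumour-fraction HMM

The second caller is a simplified ichor-style hidden Markov model over
`x_t = log2(1 + e_t)`.  States are integer copy numbers {1, 2, 3, 4, 5}
(diploid baseline, no ploidy search, no subclone states; amplifications above
5 are absorbed by the top state and quantified later via effect size).  For a
candidate fraction `f` the state means are fixed at
`log2((2(1-f) + c f)/2)`; the only free emission parameter is a shared
Gaussian SD, estimated by EM (the likelihood is checked non-decreasing per
iteration).  `f` is profiled over a grid (0 to 0.5, step 0.005) and the
maximum-likelihood `f` wins; states are decoded by Viterbi.

Three numerical choices matter:

- **State prior.** A pure gain is exactly ridge-degenerate: `(c=3, f)` and
  `(c=5, f/3)` have identical means.  A weak per-bin penalty
  `kappa |c - 2|` with `kappa = 0.05` resolves the ridge toward the least
  extreme state, so a lone trisomy decodes as c=3.  The flip side: a lone
  true amplification with no accompanying loss decodes as a gain at an
  inflated `f` — one reason fraction estimators need both gains and losses.
- **Segment persistence.** Self-transition probability 0.9999 by default.
  This parameter must scale with chromosome length in bins:
  `HmmConfig.desk()` uses 0.999 for the reduced test genome (~1,000 bins,
  30–60 bins per chromosome), where 0.9999 would imply expected segments of
  10,000 bins.
- **When is `f` defined?**  The estimate is reported as defined only when
  (a) the best-`f` log-likelihood beats the `f = 0` likelihood by at least
  2, and (b) the decoded path contains at least 40 aberrant bins (~20 Mb at
  500 kb bins).  Profiles with only one or two short CNAs therefore yield an
  undefined fraction even when the z-score caller fires — reproducing the
  documented behaviour of fraction estimators on sparse profiles, which need
  large gain *and* loss events for an accurate estimate.  Both constants are
  package choices, stated here because the emulated study's tool reports
  them only qualitatively.

Decoded non-neutral segments with `|2^log2R - 1| >= 1.5%` become calls, on
the same effect-size floor as the z-score caller.

## Interpretation layer

Calls from either caller are filtered before interpretation: chromosomes 19
(GC-rich, known normalization problems), X and Y are excluded; effect sizes
below 1.5% are dropped; calls mostly covered by the blacklist are removed
(the three filters commute).  Survivors are classified cancer-associated.
Short (≤3 bins), very strong (|e| ≥ 25%) calls are flagged likely-germline
for review, never deleted.  Chromosomal instability (CIN) is called when
cancer-associated gains/losses occupy ten or more distinct chromosomes.
Empirical confidence tiers follow the study's verification analysis: a call
is high-confidence if it is >30 Mb with effect >3%, or 5–30 Mb (2–30 Mb for
the HMM caller) with effect >5%.  Tissue concordance uses any-overlap with
matching direction (the reciprocal fraction is configurable; the emulated
study states none), and each patient falls in exactly one concordance group:
TP (tissue and plasma), T, P, or N.

## Synthetic data: what it emulates and what it does not

The generator produces bin counts with the structure the callers assume:

- a **shared bias profile** per panel: a smooth unimodal function of a
  GC-like covariate times per-bin lognormal jitter (sd 0.05), fixed across
  samples — the correlated locus bias that reference-bin selection exploits;
- **Gamma-Poisson counts**: variance `m (1 + dispersion·m)`, dispersion
  1e-4 by default, Poisson in the limit — the standard shallow-WGS
  over-dispersion assumption.  The emulated study does not model counts, so
  the dispersion is an assumption, not a calibration;
- **copy-number spikes** applied as the mixture factor above,
  length-weighted for partially overlapped bins; trisomy positive controls
  are whole-chromosome c=3 spikes at a foetal fraction.

Problem sizes used by the test suite, chosen once as scaled-down but
realistic study conditions: a *desk genome* of 22 autosomes, 3–6 Mb each at
100 kb bins (~980 bins), sequenced to ~4,000 reads/bin — the per-bin depth
of a 23M-read sample on the full 500 kb grid — with a 50-sample panel; and
the *full GRCh37 autosomal grid* at 500 kb (~5,800 bins) with a 20-sample
panel at 14M reads/sample, the low end of the study's 14–49M range, for the
trisomy positive-control replicates.

Not emulated: read-level artifacts (mappability holes, duplicated regions),
GC dependence of fragment recovery beyond the static bias, germline CNVs,
clonal haematopoiesis, and subclonal mixtures of more than one clone per
segment.  Passing tests therefore demonstrate the statistical machinery —
normalization, segmentation, fraction recovery, thresholds — under the
assumed noise model, not performance on real sequencing, which depends on
artifact structure the blacklist and a large real panel must absorb.

## Known limitations

- Small reference panels (tens of samples) inflate held-out z-scores through
  reference-selection overfitting; use hundreds of samples in practice.
- The exhaustive window scan is quadratic per chromosome; fine at 500 kb
  bins, slow below ~10 kb bins.
- The HMM assumes a diploid baseline; genome-doubled tumours will be
  mis-decoded (full ploidy search is out of scope).
- The fraction grid tops out at 0.5; cfDNA fractions above that are outside
  the intended shallow-sequencing regime.
- The packaged target-region and actionable-gene lists are reconstructions
  for demonstration, not clinical content.
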