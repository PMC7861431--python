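# cfcna

Copy-number alteration (CNA) calling and interpretation for **shallow
whole-genome sequencing of plasma cell-free DNA** (liquid biopsy).  The
package is aimed at people evaluating NIPT-style low-coverage pipelines for
cancer ctDNA analysis: it takes per-bin read counts (500 kb bins, GRCh37
autosomes), normalizes them against a reference panel of unaffected samples,
and calls CNAs with two complementary callers, then interprets the calls
clinically.

## The model

A fraction *f* of plasma cell-free DNA derives from tumour cells.  A segment
at tumour copy number *c* changes the relative coverage of its bins by

&nbsp;&nbsp;&nbsp;&nbsp;ratio = (2(1−f) + c·f) / 2,&nbsp;&nbsp;&nbsp;
effect size *e* = f·(c−2)/2,&nbsp;&nbsp;&nbsp;
so&nbsp; *c* = 2 + 2·e/f.

On top of this mixture model:

- **Within-sample z-score caller** (`WithinSampleModel`): each bin is
  normalized by the mean count of ~100 reference bins *from other
  chromosomes* in the *same sample* (cancelling depth and shared locus
  bias); per-bin z-scores against the panel are combined over contiguous
  windows with Stouffer's method, Z = Σzᵢ/√n, and windows with |Z| ≥ 4.95
  and |mean e| ≥ 1.5% are called exhaustively/greedily.
- **Tumour-fraction HMM** (`TumourFractionHMM`): a copy-state hidden Markov
  model over per-bin log2 ratios whose state means are fixed functions of
  *f*; *f* is profiled over a grid, the emission SD fitted by EM, and the
  Viterbi path yields segments plus a ctDNA-fraction estimate (reported as
  undefined on sparse profiles).
- **Targeted analysis**: single-bin z for gene targets, median z over bins
  for larger regions, reported at z ≥ 3.0 and z > 5.0.
- **Panel QC and blacklist**: panel samples with mean absolute error > 2.5%
  are excluded; bins recurrently called within the panel are blacklisted.
- **Interpretation**: chromosome 19/X/Y exclusion, effect-size floor,
  amplification calling (e/f ≥ 1.5 ⇔ tumour copy number ≥ 5; fallback
  e > 4.5%), chromosomal instability (CIN: calls on ≥ 10 chromosomes),
  empirical confidence tiers, tissue concordance (TP/T/P/N groups) and
  per-patient / cohort summaries.

A synthetic-data module generates panels, foetal-trisomy positive controls
and tumour plasma samples with known truth, so the whole pipeline is testable
without sequencing data.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import cfcna as cf
from cfcna.hmm import HmmConfig, TumourFractionHMM

# a reduced 22-autosome genome (~980 x 100 kb bins) and a 50-sample panel
grid = cf.BinGrid.desk()
bias = cf.BiasProfile.random(grid, seed=21)
panel = cf.build_panel(cf.simulate_panel(grid, 50, 4_000_000, bias, seed=22))

# a plasma sample at ctDNA fraction 5%: chr3 trisomy + chr7 monosomy
end3 = int(grid.end[grid.chrom_indices("3")[-1]])
end7 = int(grid.end[grid.chrom_indices("7")[-1]])
truth = cf.SimTruth("patient", 0.05,
                    (("3", 0, end3, 3), ("7", 0, end7, 1)), seed=5)
counts, _ = cf.simulate_case(grid, bias, truth, 4_000_000)

res = cf.WithinSampleModel(counts, panel, "patient").fit()
print(res.summary())
hres = TumourFractionHMM(res.profile, HmmConfig.desk()).fit()
print(hres.summary())
```

prints

```
Within-sample z-score CNA calls: patient
  usable bins: 981 / 981
  thresholds : |Z| >= 4.95, |effect| >= 1.5%
  calls      : 2
  chrom      start        end         dir   Z        effect  bins
  3      200000       5700000     gain  14.21    +0.029  55
  7      0            5100000     loss  -12.25   -0.025  51

Tumour-fraction HMM: patient
  ctDNA fraction : 5.5%
  log-likelihood : 2127.23 (emission SD 0.0267)
  aberrant bins  : 109
  chrom  start        end          c  log2R    effect  bins
  3      200000       5700000      3  +0.0410  +0.029  55
  7      0            5100000      1  -0.0375  -0.026  51
  8      0            300000       1  -0.0213  -0.015  3
```

Both callers recover the spiked events: a chromosome-3 gain and a
chromosome-7 loss with effect sizes near the theoretical f·(c−2)/2 = ±2.5%,
and the HMM estimates the ctDNA fraction at 5.5% (true 5%).  Interpretation
then converts effects to copy numbers, e.g. a 21% effect at fraction 8.4%:

```python
>>> cf.estimate_copy_number(0.21, 0.084)
7.0
>>> cf.classify_amplification(0.21, 0.084)
'amplification'
```

## Command line

```sh
cfcna simulate --out-dir sim --n-panel 20 --seed 1      # synthetic cohort
cfcna build-panel --counts sim/panel_counts.tsv --out-dir panel
cfcna call --counts sim/case_counts.tsv --panel panel --out-prefix case
cfcna targeted --counts sim/case_counts.tsv --panel panel --out targeted.tsv
cfcna interpret --calls case.wc.tsv --out summary.tsv
cfcna reproduce-tables                                   # fixture counts
```

`cfcna reproduce-tables` recomputes the headline counts from the packaged
per-patient and targeted-analysis tables (44 patients; e.g. 18 targeted hits
at z > 5.0 in 11 patients, 17 patients plasma-positive by the z-score
caller, 15 CIN).

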