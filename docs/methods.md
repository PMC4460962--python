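# Methods

## Overview

`modrep` implements a module-level route to drug repositioning: instead of
correlating whole expression signatures of drug and disease, it identifies
(1) gene modules whose per-sample enrichment separates good from bad
prognosis in several independent patient cohorts and (2) per-drug modules
of genes whose baseline expression tracks the drug's growth-inhibition
activity across a cell-line screen panel, then (3) connects the two module
collections by gene overlap. The working hypothesis is that a drug whose
sensitivity machinery overlaps the disease's prognostic machinery is a
repositioning candidate (or, when the association is adverse, a risk
signal).

## Single-sample KS enrichment

For one sample, all N measured genes are ranked by expression. Rank
direction is a convention, not a fact of the data: the default puts rank 1
at the *highest* expression (the convention of signature-matching screens);
`rank_direction: ascending` is available for sensitivity analysis. Ties are
broken by ascending gene identifier, which makes every downstream number
bit-reproducible at the cost of a (negligible, data-independent) bias for
exactly tied values.

With the set's sorted rank positions V(1)<…<V(t), the score is
a = max_j[j/t − V(j)/N] (top enrichment), b = max_j[V(j)/N − (j−1)/t]
(bottom enrichment), KS = a if a>b else −b, and 0 when a = b. The a = b
case is genuinely ambiguous — equal evidence at both extremes — and 0 is
the symmetric choice. Scores lie in [−1, 1]; a set occupying the top t
ranks scores exactly 1 − t/N.

A subtlety worth recording: reversing the ranking (p → N+1−p) does **not**
exchange a and b exactly; it maps a → b − 1/N and b → a + 1/N (a
discretisation effect of the step ECDF). The sign of the score is
guaranteed to flip only when |a − b| > 2/N. The property tests assert the
exact identity rather than a naive antisymmetry.

Sets are intersected with the measured genes first; sets with fewer than
`min_set_size` (default 5) surviving members are excluded — KS on one or
two genes is single-gene noise, not a module statement. N is always the
cohort's own measured-gene count.

## Prognostic module selection

Per module and cohort, the good/bad outcome groups are compared with the
unequal-variance Welch t statistic on the enrichment scores, two-sided p
from Welch–Satterthwaite degrees of freedom. Two-sided is deliberate: both
directions of prognostic association are of interest (protective modules
exist). Selection requires p < `alpha_prognosis` (default 0.05, raw) in
*every* cohort. No multiple-testing correction is applied by default — the
multi-cohort intersection is itself the (informal) false-positive control,
and the raw-threshold intersection is the procedure this package
implements; `bh: true` switches each cohort to a Benjamini–Hochberg FDR
criterion for users who prefer an explicit guarantee. The selected list is
ordered by the worst (largest) per-cohort p so reports are deterministic.

Degenerate inputs are hard errors, not silent NaNs: groups of fewer than
two samples, and modules whose scores are constant and equal in both groups
(zero pooled variance).

## Drug sensitivity modules

The screen table may hold several rows per (drug, cell line) — e.g. runs at
different highest-tested concentrations. These are aggregated by the mean
of −log10 GI50; means of log-scale potencies are geometric means of
concentrations, the standard summary. Drugs measured in fewer than
`coverage_frac` (default 0.8) of the panel's cell lines are dropped — the
"matched with the screen" step that shrinks a raw compound list to the
usable one; the drop count is logged so the funnel is auditable.

Cell-line names are matched exactly after upper-casing and whitespace
stripping. No fuzzy matching: a silently wrong match is worse than a loudly
dropped line, and unmatched names are logged.

Per drug, each gene's baseline expression across the matched lines is
Pearson-correlated with the activity profile over pairwise-complete
observations; the two-sided p uses t = r·sqrt((n−2)/(1−r²)) on n−2 df.
`min_pairs` (default 30) guards that t approximation on a 60-line panel;
genes with fewer complete pairs or zero variance are skipped and counted.
Genes with p < `alpha_sensitivity` of **either** sign form the module —
sign is kept in the per-gene stats for interpretation, but a negatively
correlated (resistance-associated) gene is as informative a link as a
positive one.

## Linkage, ranking, Effect Score

The overlap universe M is the intersection of genes measured in all
disease cohorts and in the cell-line baseline — the only genes that could
have appeared in both module types. All sets are intersected with the
universe before counting. The link p-value is the upper hypergeometric
tail including the observed overlap itself, computed via the survival
function of `scipy.stats.hypergeom` (verified in tests against exact
rational enumeration). Raw α = 0.05 on link p-values by default, mirroring
the selection stage.

Drugs are ranked by S_d = number of significant links; ties break by the
drug's best link p, then identifier. The Effect Score S_d/(P/2), with P
the number of prognostic modules, is reported as defined — it exceeds 1
when a drug links more than half the modules and reaches 2 at full
linkage; it is intentionally not clipped. A signature mode
(`rank_by_signature`) ranks drugs by raw overlap count with a fixed
prognostic gene list instead of module-wise links, for comparing the
module approach against classic gene signatures.

## The synthetic-data generator

The generator emulates the study conditions end to end: by default three
cohorts of 60 good + 60 bad samples over 2,000 genes; 200 gene sets of
size 20 of which 20 are planted; a 60-cell-line panel screened with 20
drugs, one effective; all emitted in the exact exchange formats the
readers take, plus a ground-truth manifest.

Structure of the planted signal:

* **Disease-program pool.** The 20 planted sets draw their members from a
  shared pool of `pool_size` = 2 × set_size = 40 genes, so planted modules
  overlap heavily. This mirrors real annotation collections, where the
  prognosis-associated terms are near-duplicate descriptions of one
  proliferation program. It is also a structural requirement of any
  rank-based single-sample score: planting 20 *disjoint* sets would shift
  20% of the universe in bad samples and displace every other gene's
  rank, making genuinely null sets outcome-associated (measured effect
  size ≈ 0.9 on decoy KS scores). With a 40-gene pool the displacement is
  negligible and decoys stay null.
* **Co-expression.** Pool genes share a per-sample latent factor with
  loading 0.7 (each gene stays marginally N(0,1)). Co-regulation is what
  makes a module a module; it is also what lets a drug's activity, which
  can only track the module's *average* expression, correlate detectably
  with each *member* gene (with independent members the per-gene
  correlation would be ρ/√t ≈ 0.16 — invisible at n = 60).
* **Outcome effect.** Pool genes are shifted by +delta (default 1.5) in
  bad-outcome samples of every cohort — poor-prognosis tumours
  over-express the proliferation program. Decoy sets draw members from
  non-pool genes only, so they are exactly null with respect to outcome.
* **Drug screen.** The cell-line baseline reuses the same factor
  structure. An effective drug's activity is ρ·z + √(1−ρ²)·noise (ρ
  default 0.7) with z the standardised per-line mean expression of one
  planted set; decoy drugs are pure noise. Values are emitted as
  −log10 GI50 around 6, in the Standard Agent column layout, with
  two-concentration replicate rows planted for a random 10% of
  (drug, line) pairs to exercise the aggregation rule.

Everything is deterministic given the seed, and the emitted files
round-trip byte-identically through the readers.

What the generator does **not** emulate: microarray noise models, probe
effects, cohort batch structure, heavy-tailed expression, dose–response
curve shape, or correlated decoy structure. Passing tests therefore show
the statistical machinery is correct and calibrated under a clean
generative model — not that the pipeline's biological conclusions on real
GEO/DTP data would be robust to those artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script use the default conditions above
(2,000 genes × 120 samples × 3 cohorts; 200 sets; 60 lines × 20 drugs),
which the vectorised KS and correlation code runs in about a second; the
null-calibration check repeats cohort generation and selection over 20
seeds. Enrichment is evaluated by one lexsort per sample plus one sort of
each set's positions per sample; Welch tests and correlations are computed
in vectorised form and cross-checked against their scalar definitions in
tests. Hypergeometric tails come from scipy's survival function (log-space
internally); p-values are clamped into (0, 1] — an underflowed 0 is
reported as the smallest positive float rather than breaking the
"p ∈ (0, 1]" contract. Expression files are re-read with round-trip float
parsing so that write→read→write is bit-identical.

## Known limitations

* Outcome must arrive dichotomised; there is no survival-time modelling.
* Probe-to-gene mapping is reduced to "keep the duplicate row with the
  highest mean"; users with probe-level data should collapse upstream.
* Raw-α intersection selection has no formal error-rate guarantee (the BH
  flag exists for that).
* The Effect Score depends on P, the number of recovered modules, so it is
  comparable across drugs within one run, not across runs.
* With overlapping prognostic modules (the realistic case), module links
  are not independent: one shared mechanism can light up many modules.
  S_d counts modules, not mechanisms.
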