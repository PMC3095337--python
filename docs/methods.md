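# Methods

This note records the models, defaults and numerical choices behind
`xstress`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Presence calling and breadth

A sample-level presence call requires `min_reps` (default 2) replicate
detection p-values strictly below `alpha` (default 0.05).  The
inequality is strict on purpose: a p-value exactly at the threshold is
absent, so the printed cutoff "p < 0.05" is implemented literally.
Marginal detection states are not modeled — the input is a single
detection p-value per replicate, thresholded once.

Breadth classes (always / never / specific / nonspecific) partition
the genes by construction; `specific` means exactly one sample.  With
a one-sample compendium the present-in-the-only-sample state is
reported as `always`.  Organ specificity is evaluated against
*samples*, not organs: one replicate-supported presence in any
non-target sample (including samples labeled `other`) disqualifies a
gene, so the organ sets are pairwise disjoint and exclude
constitutively expressed genes whenever more than one organ is
sampled.

## Regularized t-test

The two-condition test shrinks each gene's pooled variance toward a
background estimated from the `window` = 101 genes nearest in rank of
mean log2 intensity (truncated at the ends of the ranking; one shared
background per contrast, computed from the pooled per-gene variance of
both groups).  The prior weight `conf` = 9 acts as pseudo-observations:

    s~^2 = (conf * bg + (n1+n2-2) * s^2) / (conf + n1+n2-2)
    df   = conf + n1 + n2 - 2

Both hyperparameters are exposed; the defaults follow the published
recommendations of the Bayesian-regularization family of microarray
tests for small replicate numbers.  In the `conf` -> 0 limit the test
equals the pooled Student t to 1e-10, which the suite checks.

Degenerate inputs: a gene with zero regularized variance (possible in
noise-free simulations) gets p = 0 when the means differ and p = 1
otherwise, so the noise-free limit is exactly separable.

**Calibration.**  Under a homoscedastic null the test is
*conservative*: with 3 + 3 replicates the claimed df (13) overstates
the information in the shrunk denominator, and the measured type-I
rate at alpha = 0.05 is ~0.039 over 10,000 null genes.  The suite
therefore asserts the one-sided property — the rejection rate never
exceeds the nominal level (within Monte-Carlo error) and stays within
a factor of two of it — rather than a symmetric band around 0.05.
False-positive control is what the downstream gates rely on, and
conservatism costs a little power, not validity.

## PPDE mixture

P-values of a contrast are modeled as f(p) = lam + (1-lam) * a *
p^(a-1) with a < 1, fit by EM (shape MLE a = -sum r / sum(r log p)
with posterior weights r; shape clamped to [1e-4, 1 - 1e-6]; p-values
floored at 1e-300 before taking logs).  The raw mixture is not
identifiable as a -> 1, because Beta(a,1) contains a uniform
sub-density of mass a.  Two consequences:

* the reported null weight `lambda0` is the canonical flat mass
  lam + (1-lam) * a.  Under a pure-uniform null it converges to 1;
  for a planted 80% uniform + 20% Beta(0.1, 1) mixture its population
  value is 0.8 + 0.2 * 0.1 = 0.82, which the fit recovers;
* PPDE is the posterior weight of the strictly decreasing density
  remainder, ppde(p) = (1-lam) a (p^(a-1) - 1) / f(p).  It is
  monotone non-increasing in p, 0 at p = 1, and -> 1 as p -> 0, so the
  PPDE > 0.96 gate behaves as intended while a pure null produces no
  gate passes at all.

EM convergence is judged on the identifiable parameters (flat mass and
shape), since along the a -> 1 ridge the raw lam wanders without
changing the density; a fit that exhausts `max_iter` is returned
flagged as non-converged.

DEG calling is the compound rule p < 0.05 AND PPDE > 0.96 (both
strict), direction from the sign of the log2 fold change; a
significant gene with a fold change of exactly 0 stays unchanged.
Time-course contrasts are collapsed per gene: up if up at >= 1 time
point and down at none (symmetrically for down), anything conflicting
is unchanged, and the single displayed fold change is the earliest
significant time point in the called direction.

## Response classes and core sets

Every DEG of each species receives exactly one class by looking up all
its orthologs' directions: common (>= 1 same direction) takes
precedence over opposite (>= 1 reversed, none same), then
ortholog-unchanged, then no-ortholog.  The precedence for mixed
1:many groups is not derivable from a partition alone, so it is a
configuration switch (`common_first` default, `opposite_first`
available).  Percentages are reported raw and rounded to the nearest
integer, since published accounts print integers.  Core (pan-stress)
sets intersect the per-stress direction calls; core overlap counts
ortholog *groups*, so a 1:2 group contributes one pair.

## Enrichment statistics

The two-proportion z uses the pooled standard error and two-sided
normal p-values; z^2 equals the Pearson chi-square without continuity
correction, which the suite verifies to 1e-9.  A degenerate pooled
proportion (0 or 1) is reported as z = 0, p = 1.  Genes carrying
several functional categories count once in each (the tests are
marginal, not partition-based).  TF-family tests restrict both
numerator and denominator to the TF complement.  No multiple-testing
correction is applied by default — flags use the raw p < 0.01
(relaxed 0.02) convention — and an optional Benjamini-Hochberg
adjustment exists for users who want it.  The genome denominator is
always an explicit argument, never inferred, because "the genome" may
mean all genes or expressed genes depending on the analysis.

## Promoter k-mers and 3'UTR motifs

Counting is occurrence-based by default: overlapping windows on the
supplied (sense) strand, windows containing N skipped, with the
invariant that total counts equal total valid windows.  A
per-promoter-presence mode and a both-strands mode are available
behind flags; in the latter a motif and its reverse complement share
counts.  Promoters shorter than the nominal 1 kb are scanned as-is —
frequencies are normalized by scanned windows, so ratios are
length-robust.  Ratios with a zero genome count are reported as
missing rather than infinite.

Shortlisting is the compound rule p < 0.01 AND ratio >= 1.2 or <= 0.8;
top-ranking takes the n = 3 largest significant ratios above 1 with
lexicographic tie-breaks.  Clustering sorts rows and columns by label
before computing average-linkage/correlation-distance trees, making
the output deterministic and permutation-invariant; a constant matrix
has no defined correlation distance and is rejected with a hint to
widen the shortlist.

The 3'UTR scan is presence-based (genes with >= 1 hit) because UTR
annotation is sparse and occurrence counts would be dominated by a few
long UTRs.  The motif catalog is an editable file of named exact
strings with a stabilising/destabilising class each; the shipped
default contains the DST conserved core (ATAGAT) and the ARE pentamer
(ATTTA) as destabilising entries plus two clearly labeled synthetic
stabilising placeholders for users to replace from the literature.

## Synthetic data generator

The generator emulates the statistical assumptions the pipeline makes,
with defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes_a / n_genes_b | 3,000 / 2,000 | two gene universes (scaled-down genomes) |
| frac_orthologous_a / _b | 0.37 / 0.61 | per-gene Bernoulli ortholog membership |
| n_stresses, n_replicates | 4, 3 | drought/salt/cold/heat, ctl+trt pairs |
| presence_class_mix | .16/.26/.05/.53 | always/never/specific/nonspecific |
| frac_de_per_stress | 0.15 | DE fraction among detectable genes |
| log2fc_effect, sigma_within | 2.0, 0.25 | planted effect vs replicate SD |
| response_class_mix | .25/.10/.35/.30 | common/opposite/a-only/b-only pairs |
| core_counts | 9/3 common, 7/3 opposite, ... | planted pan-stress genes |
| promoter_length, gc_content | 1,000 bp, 0.42 | i.i.d. background sequence |
| detection p model | U(0,.04) / U(.06,1) | present / absent replicates |

Design points worth recording:

* **Determinism.**  Every artifact draws from a labeled RNG substream
  derived from the master seed (seed + CRC32 of the label), so equal
  configs give byte-identical files and adding an artifact never
  perturbs the others.
* **Presence first.**  Breadth classes are drawn first as a clean
  multinomial; DE genes are then sampled only among genes detectable
  (present in control and/or treated) for that stress.  This keeps the
  realized breadth mix exactly on the configured proportions instead
  of letting the DE layer distort it.
* **Ortholog groups.**  Membership is Bernoulli per gene and species;
  the richer side's excess is concentrated into ~`frac_one_to_many`
  of the groups, which is what creates 1:many groups.
* **Detection p-values** are drawn from non-overlapping intervals
  around the 0.05 threshold, so presence calls recover the planted
  truth *exactly*; the interval bounds are configurable for power
  studies where overlap is wanted.
* **Motif planting** replaces bases at non-overlapping random
  positions (preserving promoter length) and computes the number of
  inserted copies from the *measured* background occurrences, with a
  correction for the target set's own contribution to the genome
  denominator.  The realized set-vs-genome ratio therefore lands on
  the requested fold up to insertion side effects, independent of
  sampling noise in the background.
* **Opposite pairs** get equal-magnitude, opposite-sign effects.

What the generator does **not** emulate: probe-level noise and
cross-hybridization, chip spatial artifacts, intensity-dependent
variance (variances are homoscedastic on the log scale, so the
background-variance window is exercised but not stressed), real
promoter composition beyond GC content (no CpG-like structure, no
positional bias of elements), or correlated expression between
orthologs beyond the planted classes.  Passing the recovery suite
therefore shows the *logic* of the pipeline is right and its
statistics are calibrated under their stated assumptions — not that
those assumptions hold on any particular platform.

## Problem sizes used by the validation suite

The test suite and `scripts/acceptance.py` run the default 3,000 +
2,000-gene conditions for expression recovery, a 10,000 / 7,000-gene
universe for the ortholog-fraction and breadth-mix checks, 10,000 null
genes for t-test calibration, 10,000 p-values for the mixture
recovery, and a 3,750-gene universe (yielding a ~500-promoter target
set) for motif recovery — sizes at which the binomial 3-SE bands used
in the assertions are diagnostic.  The full suite runs in well under a
minute on one CPU.

## Known limitations

* The regularized test's null conservatism (above) means reported
  sensitivities are mildly pessimistic relative to a perfectly
  calibrated test.
* The single Beta(a,1) alternative cannot represent p-value densities
  that rise near 1 (e.g. from variance misspecification); richer beta
  mixtures are out of scope.
* The exhaustive 6-mer scan treats motifs as exact strings — no
  degenerate positions or PWMs — matching the counting design it
  implements, not the state of the art in motif discovery.
* One-to-many response classification reports a single class per
  focal gene; per-pair listings are available in the `counterparts`
  column for users who need finer accounting.
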