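# Methods notes

This note records the modelling choices behind `p53cc`: the analysis
procedure and its assumptions, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## The analysis model

The pipeline treats a tumor cohort as (i) a per-sample TP53 genotype and
(ii) a gene × sample expression matrix, and asks how mutation shifts the
expression of a fixed p53-pathway gene set within each cancer type.  The
unit of comparison is deliberately the *cancer type*, not the sample:
each type is summarized by the vector of per-gene log2 ratios of median
mutant to median wild-type TPM.  Medians make the summary robust to the
heavy right tail of expression data; ratios cancel any per-sample
scaling that TPM normalization has not already removed; the log2 makes
up- and down-regulation symmetric.  The cost of this design is power —
downstream cluster contrasts operate on 21 (or 34) profiles — which is
why the contrast statistics are exact tests rather than asymptotic ones
wherever group sizes allow.

Genotype calls are rule-based, not probabilistic.  Truncating variants
(nonsense, frameshift) count as mutations outright.  Missense variants
are looked up in a transactivation reference that records each mutant's
residual activity on eight p53 target promoters; only missense changes
with lost p21 transactivation qualify.  Samples whose only recognized
variant retains p21 activity are dropped from *all* groups — they are
neither functionally mutant nor genetically wild-type — and so are
samples whose only variant is of an unclassifiable class (splice,
in-frame indel) under the default policy.  Dropping them from wild-type
denominators as well as mutant numerators keeps the two groups cleanly
separated at the cost of a slightly smaller cohort.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `af_threshold` | 0.20 | allele-frequency cutoff; strict (> 0.20), so a variant at exactly 0.20 is ignored |
| `p21_loss_threshold` | 75 %-of-WT | p21 activity at or below which a missense mutant counts as loss-of-function.  The wild-type assay range sits above this; no canonical cutoff exists, so it is configurable rather than hard-coded |
| `tpm_floor` | 1.0 TPM | low-expression floor for the gene filter; a gene is dropped when its per-type median is below the floor in strictly more than half of the cohort's cancer types |
| `ratio_floor` | 0.01 TPM | floor applied to group medians before the log2 ratio; removes division-by-zero without affecting genes that passed the TPM ≥ 1 filter (every flooring event is logged) |
| `min_group` | 10 | minimum mutant and wild-type (cohort A) or GOF and non-GOF (cohort B) cases per cancer type |
| `alpha` | 0.05 | significance level of every test; no multiple-testing correction by default |
| `k` | 2 | number of clusters cut from the dendrogram |
| `wilcoxon_mode` | exact | profile-level tests; sample-level tests use `auto` (exact up to pooled N = 50, normal beyond) |

One wording ambiguity in the filter deserves a note: "below the floor in
more than half of the *cases*" versus "of the *cancer types*".  The
implementation counts cancer types — each type contributes one median —
because that is the reading under which the candidate set reduces from
67 to 63 genes, and it is also the scale on which the medians are
defined.  The filter is computed per cohort, so cohorts A and B can in
principle keep different sets (on the bundled fixture they agree).

A related ambiguity is whether the GOF share of a cancer type is taken
over its mutant cases or all cases; the package uses mutant cases as the
denominator, which is the only reading consistent with types whose GOF
share exceeds their mutation rate.

## Statistical conventions

* **Wilcoxon rank-sum, exact.**  Mid-ranks over the pooled sample; the
  permutation distribution of the smaller group's rank sum is built by
  the shift (convolution) algorithm on doubled ranks, so ties need no
  approximation; two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
  Enumeration is guarded at pooled N ≤ 100.
* **Wilcoxon rank-sum, normal.**  z = (W − m(N+1)/2)/√(mn(N+1)/12),
  two-sided, no continuity correction and no tie correction.  Both modes
  are exposed because small-sample contrasts of published summary
  columns are reproduced by the normal form, while the exact form is the
  better default at these group sizes.
* **Fisher exact.**  Probability-ordering two-sided definition: sum the
  (multivariate) hypergeometric probabilities of every margin-matched
  table whose probability is ≤ the observed one × (1 + 1e-7); the factor
  absorbs floating-point noise at ties.  r × c tables use exhaustive
  Freeman–Halton enumeration guarded at 10⁷ tables.  A zero margin
  returns p = 1 with a warning.
* **Discreteness of exact tests.**  At a 17-vs-4 split the exact
  rank-sum test can only attain a size of 0.0404 at nominal α = 0.05;
  the test suite checks the empirical null rate against this analytic
  size.  The calibration experiment in `experiments.null_type1_experiment`
  instead uses 40 profiles split 20/20, where the attainable size is
  0.0491 — essentially nominal — so that the empirical rate is
  informative about the implementation rather than about discreteness.
* **Clustering.**  Pearson distance d = 1 − r (signed, not |r|:
  anticorrelated response profiles are maximally distant), centered by
  default with an uncentered option.  Complete linkage is the naive
  O(n³) agglomeration — profile counts are tens, not thousands — with
  ties broken on the lexicographically smallest pair of member-label
  tuples, making the dendrogram independent of input order.  The k-cut
  removes the k−1 highest merges (the last ones, by monotonicity) and
  numbers clusters by decreasing size.

## The synthetic-data generator

The generator emulates the *shape* of a TCGA-style pan-cancer resource:
per-sample FPKM expression over a 67-gene pathway catalog (plus *MKI67*
and ~200 background genes that put column totals near 10⁶, so TPM values
land on a realistic scale), a MAF-like variant table, a transactivation
reference, and the pathway category map.  Expression is log-normal
(per-gene baseline + N(0, 1) log2 noise); four catalog genes are planted
below the TPM floor in every type.

Planted structure and the reasoning behind it:

* **Two cluster responses.**  Mutant samples of cluster-1 types
  up-regulate the cell-cycle category and *MKI67* by
  `mutant_effect_fold` (default 2); mutant samples of cluster-2 types
  up-regulate the apoptosis category by the same fold instead.  Giving
  the second cluster its own shared response, rather than leaving it as
  pure noise, is what makes the planted partition recoverable: profiles
  that share no signal are mutually uncorrelated, scatter at distance
  ≈ 1 from everything, and cannot form a cohesive cluster under any
  linkage.  Cohesive minority clusters are also what real pan-cancer
  data show.
* **Per-type signatures.**  Every cancer type carries a per-gene log2
  offset ~ N(0, 0.35) applied to all of its mutant samples.  GOF and
  non-GOF mutants share it, which is precisely why the cohort-B
  dendrogram pairs each type's two profiles as siblings; 0.35 is large
  enough to separate sibling distances (~0.15) from
  nearest-non-partner distances (~0.4) yet small enough not to blur the
  cluster partition.
* **Genotype plumbing.**  Mutant counts per type are deterministic
  rounds of the configured fractions (so cohort membership is stable
  across seeds); allele frequencies are drawn from U(0.25, 0.60), away
  from the 0.20 threshold, so planted genotypes are recovered exactly;
  5 % of samples carry only a retained-activity missense variant
  (planted "excluded") and 5 % of wild-type samples carry a
  sub-threshold variant (planted "ignored").  A handful of cluster-1
  types are planted with only 5 GOF cases to keep them out of cohort B,
  reproducing a 21-type cohort A with a 17-type cohort B.
* **Transactivation table.**  Activities of the seven non-p21 targets
  are a linear function of p21 activity plus noise calibrated to a
  Pearson r of 0.78, the middle of the 0.70–0.83 range typical of the
  real assay data.

What the generator does **not** emulate: count-level noise
(negative-binomial dispersion — the pipeline consumes continuous
FPKM/TPM, so log-normal suffices), mutation spectra, copy number, tumor
purity, batch effects, or correlated co-expression structure beyond the
planted blocks.  Passing the recovery experiments therefore shows that
the pipeline's inference machinery is correct and calibrated under its
own model, not that real tumor cohorts will produce any particular
partition.

## Problem sizes used in validation

The study-shaped fixture runs 21 types × 120 samples ≈ 2.5k samples and
268 genes; a full pipeline run takes well under a second after
generation.  The recovery experiment uses 20 seeds of that fixture; the
null calibration uses 500 replicates of a 63 × 40 ratio matrix (31,500
exact tests, pooled through a cached permutation distribution).  These
sizes give Monte-Carlo standard errors of ~0.0014 on the type-I rate
while keeping the whole validation suite in the minutes range.

## Known limitations

* The genotype rules ignore nonsense-mediated decay, loss of
  heterozygosity, splice variants (beyond the exclusion policy) and
  germline/somatic status.
* No covariate adjustment (age, sex, stage) anywhere; contrasts are
  marginal.
* k is a configuration input, not selected from the data; no bootstrap
  or consensus clustering.
* The exact r × c Fisher test is exhaustive only; very large tables need
  a Monte-Carlo approach that is deliberately out of scope.
* `functional_class` inference from p21 activity alone collapses the
  "partially functional" band into the functional side of the single
  threshold unless a class column is provided.
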