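# Methods

This note describes the statistical models implemented in `asbqtl`, the
synthetic data generator used to exercise them, and the numerical and design
choices behind the implementation.

## Problem

Allele-specific binding (ASB) is an unequal distribution of ChIP-seq reads
between the two alleles at a heterozygous site under a peak. Because both
alleles sit in the same nucleus, an allelic imbalance points at a cis-acting
variant — potentially the site itself — altering local binding or histone
modification. The package asks whether the *flanking DNA sequence alone*
predicts the direction and strength of the imbalance, and uses agreement
between sequence-based predictions and observed imbalance to nominate
candidate causal regulatory variants (asbQTL), which are then checked for
enrichment in independent functional annotations.

## ASB calling

Per animal and site, with `ref` and `alt` read counts and `N = ref + alt`,
the test statistic is

    x = (ref - alt)^2 / N,

which is the Pearson chi-square statistic with 1 degree of freedom for the
null of binomial(N, 1/2) sampling. Animals with fewer than 10 reads at a site
are ignored. A site is retained when (i) at least one animal is imbalanced at
p < 0.05, (ii) at least 5% of animals are imbalanced, and (iii) the site is
biallelic across animals. Counts of the imbalanced animals are aggregated and
the site's phenotype is

    y = agg_alt / (agg_ref + agg_alt) - 1/2,

in (-1/2, 1/2), with sign giving the direction of imbalance. Exclusion counts
are reported in an audit table.

## Neighborhood BLUP

The phenotype of a site is predicted from *other* sites with similar local
sequence. Two sites are neighbors when they carry the same ordered
(ref, alt) allele pair and at least 7 of the 10 flanking bases (5 each side)
match. For a neighborhood of n sites with phenotypes y_i and aggregated
depths N_i, the model is y_i = u + s_i + e_i with var(s_i) = sigma_s^2 (a
per-site deviation), var(e_i) = 1/(4 N_i) (the binomial sampling variance of
y near 1/2), and a ridge prior var(u) = sigma_u^2. The best linear unbiased
prediction of u has the closed form

    w_i   = 4 N_i / (4 N_i sigma_s^2 + 1)
    u_hat = (sum_i w_i y_i) / (sum_i w_i + 1 / sigma_u^2),

which equals the generic GLS/mixed-model solution
sigma_u^2 1' V^{-1} y with V = diag(1/(4N) + sigma_s^2) + sigma_u^2 J
(verified against that oracle to 1e-10 in the tests). The variance pair is
chosen over a fixed grid by maximizing the Pearson correlation between
observed y and leave-one-out u_hat across sites with nonempty neighborhoods;
the grid covers the reference optima (sigma_s^2, sigma_u^2) = (0.035, 0.001)
and (0.07, 0.003).

## Gapped k-mer classifier and deltaSVM

Peak sequence is modeled with gapped k-mers: l = 10 bp windows with k = 6
informative positions (C(10,6) = 210 masks, 210 * 4^6 = 860,160 features).
Every l-bp window of a sequence (and, by default, its reverse complement)
adds one count to each (mask, letters) feature it realizes. Positives are
consensus peak sequences — per-sample peaks with -log10 P > 200, merged by
overlap, kept when >= 50% of samples contribute, autosomal, and <= 2000 bp.
Negatives are length- and GC-matched (+-0.02, adaptively widened to at most
+-0.10) background segments, 5 per positive, sampled outside all positives.
Rows are scaled to unit Euclidean norm and a linear soft-margin SVM is
trained; for small n the dual is solved on the precomputed normalized gram
matrix, for larger n an equivalent hinge-loss primal solver is used on the
explicit sparse features. Either way the model is stored as one dense weight
vector over the feature space, so the score of any 10-mer is a plain sum of
feature weights.

deltaSVM of a variant takes its 19-bp context (9 bp each side), replaces the
middle base with ref and with alt, and sums the alt-minus-ref scores of the
10 sliding windows covering the variant. Identical alleles score exactly 0
and swapping alleles negates the score.

Classifier quality is reported as 5-fold stratified cross-validated auROC
and auPRC on the training material.

## Combination and candidate selection

Observed phenotypes are regressed on both predictors by ordinary least
squares, y = b0 + b1 u_hat + b2 deltaSVM + e. Candidates per method are the
sites with the largest |score| (n_top = min(1000, 10% of scored sites) by
default; sites with y = 0 are excluded since they carry no direction).
A method's direction accuracy is the fraction of its candidates with
sign(score) = sign(y); a zero score counts as a mismatch. Two methods'
accuracies are compared with the two-proportion Pearson chi-square
n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the matched/mismatched 2x2 table.

## Enrichment validation

Every SNP in the study falls into exactly one of four ordered categories per
method: candidate asbQTL; non-candidate ASB sites; non-ASB variants under a
peak; SNPs not under a peak. For each annotation (ASB in an independent
cohort at p < 0.01, eQTL sites, aseQTL sites, conserved elements) the
proportion of annotated sites is compared between adjacent categories with a
1-df chi-square test (no continuity correction); a pair is flagged enriched
iff p < 0.01 and the earlier category's proportion is greater. Empty
categories yield missing proportions and skipped tests, not zeros.

## Synthetic data generator

The generator produces a study whose ground truth is known, at desk scale:

- **Genome and peaks.** Uniform-composition chromosomes (GC 0.45 by
  default); peaks placed disjointly by a stars-and-bars draw of gaps, with
  lengths 150–400 bp. Per-sample peak calls jitter the true peaks by up to
  ±10 bp; a configured fraction are "strong" (-log10 P > 200) and a fraction
  are shared across >= 50% of samples, so consensus calling has real work to
  do.
- **Motif and effects.** Each peak carries a planted 14-bp motif (consensus
  TGACTCATGCGTCA) whose position-weight matrix interleaves dominant-base
  probabilities between 0.62 and 0.95; the first instance is centered within
  ±40 bp of the peak summit. A causal variant substitutes a base at one of
  four central motif offsets, and its allelic shift is
  delta = effect_scale * (w_alt - w_ref) / max_diff, where w are per-base
  log-enrichment weights — so delta is a deterministic function of sequence,
  which is exactly what the sequence-based predictors assume. Defaults give
  |delta| of approximately 0.12, 0.18, 0.20 or 0.30.
- **Counts.** Per animal and site, depth is negative binomial
  (mean 30, var = m + 0.3 m^2) and alt reads are binomial(N, 1/2 + delta).
  A beta-binomial overdispersion hook exists but is off by default. An
  independent 3-animal validation cohort is drawn the same way.
- **Annotations.** Causal sites are annotated (eQTL/aseQTL) with probability
  `annotation_overlap`, non-causal sites at a 0.1 base rate; conserved
  elements cover the motif instances.

Thirty percent of under-peak heterozygous sites are causal; the rest, and
all off-peak SNPs, have delta = 0.

## Determinism and numerics

- All randomness flows from one root seed. Independent stages draw from
  named substreams (`SeedSequence([seed, crc32(label)])`), so adding a stage
  never perturbs another stage's stream.
- Floating-point output uses a fixed `%.10g` format; the model is stored as
  a raw `.npy` weight vector plus a JSON sidecar (no archive timestamps), so
  a rerun with the same configuration is byte-identical.
- The chi-square tail is computed by the standard survival function;
  p-values at perfect balance are exactly 1.
- Feature matrices are CSR with int32 indices; row normalization is done in
  place on the CSR data. Training sequences are center-cropped to 150 bp and
  positives capped at 150 (deterministic subsample) to bound memory; peaks
  concentrate motif signal at the summit, so the crop retains it. The full
  default pipeline peaks near 2 GB of RSS and runs in ~3 minutes on one CPU.

## Limitations

- The generator's genome has uniform base composition; GC-matching of
  negatives is therefore easier than on a real genome.
- Neighborhoods are built from exact flank matching on 5+5 bp; at small
  study sizes many sites have empty neighborhoods and shrink to 0.
- The MLR is ordinary least squares on a bounded response; no
  heteroscedasticity correction is applied.
- Direction accuracies and enrichment tests are computed on simulated data;
  no claims are made about real-cohort effect sizes.
- The beta-binomial allelic overdispersion hook is untested against real
  overdispersion levels and is off by default.
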