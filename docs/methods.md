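# Methods

This note documents the statistical model, the tunable parameters, the
synthetic data the tests run on, and the numerical and design choices made
where more than one reasonable option existed.

## Correlation model

Within one cancer, every (mRNA *m*, lncRNA *l*) pair receives three
coefficients computed over the samples shared by the two matrices **and**
the tumor-purity table (samples without a purity estimate are excluded with
a warning; at least 3 shared samples are required):

- `R`, the Pearson product-moment correlation; `S`, the Spearman
  correlation, computed as Pearson of mid-ranks so ties are handled; the
  closed-form `1 − 6Σd²/(r(r²−1))` is valid only without ties and is used
  purely as a test oracle on tie-free inputs.
- `D = (R + S)/2`, the direct coefficient. The purity correlations
  `D(m,t)` and `D(t,l)` use the same combined form, since the partial
  coefficient is defined in terms of D.
- `P = (D(m,l) − D(m,t)·D(t,l)) / sqrt((1 − D(m,t)²)(1 − D(t,l)²))`, the
  first-order partial coefficient given purity. Applied to *averaged*
  Pearson/Spearman coefficients this recursion is not guaranteed to stay in
  [−1, 1] (the three D values need not form a positive-semidefinite
  correlation structure), so the result is clamped to [−1, 1]; excursions
  beyond 1e−12 are logged at debug level. Values within 1e−12 of the
  boundary are treated as floating-point noise.
- `H = L(|β·D + (1−β)·P|)` with `L(x) = 1/(exp(c·x + d) + 1)`. The
  objective `|β·D + (1−β)·P|` is linear in β, so its maximum over [0, 1] is
  attained at an endpoint and `H = L(max(|D|, |P|))`; the β-grid property
  test verifies this analytically obvious fact against brute force. A tie
  `|D| = |P|` reports β = 1 (prefer the direct coefficient) — any β gives
  the same H, so the tie-break only fixes the reported diagnostic.

Defaults `c = −15`, `d = ln(1999)` put `L(0) = 1/2000`, the midpoint at
x ≈ 0.507, `L(0.3) ≈ 0.043` and `L(0.7) ≈ 0.948`: the transform saturates
weak correlations to ≈0 and strong ones to ≈1. `c < 0` is enforced so L is
increasing.

H is unsigned because L acts on an absolute value; the sign of the selected
coefficient is retained in the output table for diagnostics, but ranking
uses H only. A signed ranking (propagating the correlation sign through the
transform) is a plausible alternative convention; the unsigned form follows
the definition of H literally.

Pairs involving a zero-variance gene, or a conditioning correlation of
exactly ±1, have no defined coefficient and are **skipped**, never scored
as 0 — a constant gene must not rank.

## Enrichment

Per lncRNA, mRNAs with `H > 0.5` (strict) form a ranked list, descending in
H with lexicographic tie-breaks; lncRNAs with empty lists are omitted. Each
list is tested against each pathway with the preranked weighted running-sum
statistic: hits advance the sum by `|score|^w / N_R` (`N_R` = total hit
weight, exponent `w = 1` by default, `w = 0` gives the unweighted
Kolmogorov–Smirnov-like form), misses retreat by `1/(N − n_hits)`; ES is
the signed maximum-magnitude deviation. A list whose genes are all hits has
ES = 1 by construction — and a degenerate permutation null (every
relabeling reproduces the observation), so such pairs can never reach
significance. `min_size = 1` is interpreted as "at least one pathway member
present in the ranked list"; `max_size = 5000` applies to the raw pathway
size.

The null shuffles hit labels over list positions, keeping scores fixed.
The one-sided p on the side of the observed ES sign uses add-one smoothing,
`p = (1 + #extreme) / (1 + #same-sign)`, so p > 0 always and |lncRES| < 1
strictly in practice; a permutation p of exactly 0 is ill-defined. Each
(lncRNA, pathway) pair derives its own generator from the master seed and a
SHA-256 hash of the pair's identifiers, making results independent of
iteration order. 10 000 permutations resolve p down to ~10⁻⁴, comfortably
below the 0.0025 that the |lncRES| > 0.995 cutoff corresponds to.

FDR is Benjamini–Hochberg within each lncRNA's pathway tests (mirroring
per-lncRNA enrichment runs producing one table per lncRNA); a `global_fdr`
flag pools all tests instead. ES = 0 takes the non-negative lncRES branch.
Extraction keeps pairs with `|lncRES| > 0.995` **and** `fdr < 0.05`, both
strict — boundary values are excluded.

## Differential expression and Pscore

The DE stage is intentionally simple and pluggable: counts-per-million
library normalization, `log2(CPM + 1)`, logFC as the difference of group
means on that scale, a two-sided Wilcoxon rank-sum p-value, and BH
adjustment across the tested lncRNAs. This replaces a negative-binomial
count model (e.g. edgeR's); for the rank- and threshold-based use the score
makes of DE calls, the simplification changes little, but exact
fold-change estimates and p-values will differ from a count-model fit, and
the stage should be swapped for one when count-level inference matters.
A gene is DE when `adj_p < 0.01` and `|logFC| > 1.5`, both strict. DE is
evaluated for every union irlncRNA in every cancer with ≥ 3 tumor and ≥ 3
normal samples, so the breadth count `NC(l)` ranges over all analyzed
cancers, not only those in which the lncRNA was extracted.

The normalization `N` in the Pscore is divide-by-maximum: per pathway
column for `NC(l,w)`, across lncRNAs for `NC(l)` and for the mean |logFC|.
Divide-by-max preserves zero ("not observed anywhere" stays 0) and maps the
maximum to 1, so the sum of `n_pathways + 2` terms divided by
`n_pathways + 2` lies in [0, 1]; min–max scaling would zero the weakest
lncRNA, contradicting the meaning of `NC = 0`. The fold-change term uses
|log2 FC| — consistent with the DE criterion and symmetric under up/down
regulation, where a raw fold change would not be. Whether pathway terms
should be normalized per pathway or globally is a genuinely open choice;
per-pathway is the default because it weights every pathway's dynamic range
equally. The denominator generalizes to `n_pathways + 2` (19 for the
standard 17-pathway immune collection) so the score remains a [0, 1]
average under any pathway collection.

Ranked lncRNAs are binned either by equal membership (`equal_count`, first
bins absorb the remainder) or by equal Pscore width (`equal_range`, bins
may be empty; identical scores degenerate into the first bin), with
lexicographic tie-breaks, and compared against a reference list (e.g. a
disease-lncRNA database) per bin.

## Evaluation statistics

A lncRNA is infiltration-related when |Spearman correlation| with at least
one of six immune-cell infiltration levels exceeds 0.2 with BH-adjusted
p < 0.05 (adjustment pooled over all lncRNA × cell-type tests). The 0.2 /
0.05 defaults are conventions of this implementation — there is no single
standard cutoff for "correlated with infiltration" — and both are exposed
as parameters, as is a Pearson switch. Rates with zero denominators are
reported as NaN rather than silently dropped.

## Synthetic data

`irlnc.synthetic` generates the fixture data all recovery tests run on.
Expression is log-normal: per-gene baseline + factor loadings + Gaussian
noise on the log2 scale, exponentiated. Each pathway has a per-sample
latent factor; one pathway's factor is standardized `(1 − purity)` with
purity ~ U(0.3, 0.9), so its members rise with immune admixture. Planted
lncRNAs either load directly on a pathway factor ("direct") or track
`1 − purity` itself ("purity-mediated"); nulls are independent noise.
Tumor samples of DE-planted lncRNAs are multiplied by `2^logFC`. Purity is
reported for tumor samples only, so the correlation stage runs within
tumors — where a tumor-wide fold change is a constant factor and cannot
distort correlations.

Standard conditions: 5 cancers sharing one namespace, 3 pathways × 14
member mRNAs, 6 moderately loaded background mRNAs per pathway (60 mRNAs),
20 lncRNAs, 50 tumor + 20 normal samples, member/lncRNA noise SD 0.25.
Background genes (loading 0.75, noise SD 0.66) target a lncRNA correlation
of ~0.7 — above the 0.5 rank threshold but clearly below the ~0.93 of true
members — so every planted list reliably contains non-member "misses";
without them the permutation null is degenerate (see above). The pan-cancer
planting includes a high-pathogenicity lncRNA (all cancers, logFC 2.5), a
low-pathogenicity one (one cancer, no DE), a purity-mediated one (all
cancers) and a mid-range one (3 cancers, logFC 1.8).

What the generator does **not** emulate: negative-binomial count noise and
mean–variance coupling, realistic library-size variation, correlated
pathway factors, batch effects, or TCGA-scale gene and sample counts
(tens of thousands of genes, 33 cancers). Log-normal expression was chosen
because every downstream statistic is rank- or correlation-based, so the
marginal family matters little; passing recovery tests therefore
demonstrates that the pipeline's logic recovers planted correlation and
enrichment structure at realistic effect sizes, not that it is calibrated
against sequencing-count noise. Problem sizes throughout the tests and the
reproduction script (60 × 20 genes, 70 samples, 5 cancers, 10 seeds) were
chosen as the smallest configuration at which all stages — including the
cross-cancer normalizations — behave non-trivially.

## Numerical and interface choices

- Correlations just outside [−1, 1] from floating point are clamped at
  tolerance 1e−12; the partial coefficient is additionally clamped
  unconditionally (rationale above).
- The permutation estimator never returns 0 or values above 1; `lncres`
  validates p ∈ (0, 1].
- All writers emit TSV with deterministic (sorted) row order; the
  correlation table is written at 6 decimal places; `run-all` with
  identical config and seeds is byte-identical.
- Missing purity excludes a sample (warning), missing biotype drops a gene
  (logged count); an empty mRNA or lncRNA side after the biotype split is
  an error, as is a purity value outside [0, 1].
- CLI exit codes: 2 for a missing input file, 3 for a validation/format
  failure.

## Known limitations

- The DE stage is a rank-sum approximation, not a count model (above).
- The permutation p is plain Monte Carlo; no adaptive/multilevel p-value
  refinement is implemented, so p below ~1/n_perm is unreachable.
- Unsigned H discards the direction of co-expression; downstream calls do
  not distinguish activating from repressive relationships.
- Tumor purity is an input, not estimated; infiltration levels likewise.
- Survival analysis and single-cell clustering are out of scope; the
  evaluation module consumes pre-computed labels and infiltration tables.
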