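# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
its output.

## Data model

A sample is one individual carrying a uniparental haplotype: an aligned
mitochondrial control-region sequence (fixed alignment length, default 643
columns covering the two hypervariable segments, rCRS 16024–16385 and
73–340) or a Y-STR repeat-count profile over a fixed locus panel (16 Yfiler
loci by default). Each sample has a haplogroup label in phylotree-style
nomenclature and a subpopulation code; subpopulations live on an undirected
adjacency graph. The packaged graph has the 13 Finnish county-level codes
with ordinary geographic neighbourhood as edges; it is data plumbing, not an
inference — any connected graph can be supplied.

Haplogroup labels are tokenized at letter/digit alternations ("U5b1" → U, 5,
b, 1) and assigned to clusters by the longest explicit scheme token that is
a whole-token prefix. The default scheme maps U and V to HUNT
(hunter-gatherer-associated), H, J, T, K to FARM (farmer-associated), and
lists HV, D, I, N, R, W, X, Z explicitly as OTHER, so that "HV1" can never
be captured by the one-letter H token. Unknown or unmatched labels fall in
OTHER but stay in every denominator. K sits in FARM because the analysis
convention groups it with the farmer package despite its deeper phylogenetic
position; the scheme is a configuration object, not a constant.

The optional motif classifier assigns a control-region sequence to a
haplogroup only when exactly one full motif match dominates all other full
matches by motif-set inclusion; everything else is UNASSIGNED. The deliberate
consequence is that removing a haplogroup from the table can generalize a
call to its motif-subset ancestor (U5 → U) but can never flip it sideways to
an incomparable haplogroup.

## Diversity estimators

Haplotype diversity uses Nei's (1987) unbiased estimator
H = n/(n−1)(1 − Σp²) with the analytic variance
Var(H) = 2/(n(n−1)) [2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²].
The n/(n−1) factor is required for a sample of n all-distinct haplotypes to
report H = 1 exactly, matching how such cells are conventionally printed.
The estimator is undefined at n = 1 and the package refuses it rather than
printing the conventional placeholder 1.

Nucleotide diversity is the mean over all n(n−1)/2 sequence pairs of the
per-pair per-site difference d_ij/L_ij, where sites with `N` or `-` in
either sequence are excluded pair by pair (pairwise deletion). This
mean-of-ratios convention makes π exactly equal to its brute-force
definition on any input, including inputs with missing data; its SD comes
from Tajima's (1983) total variance with the mean cross-class comparable
length as L. Reported SDs are analytic, not resampling-based; permutation
randomization is reserved for the differentiation tests.

## AMOVA

Differentiation uses the two-level Excoffier–Smouse–Quattro decomposition of
squared distances: SS_total = (1/N)Σ_{i<j} d²; SS_within = Σ_p (1/n_p)
Σ_{i<j∈p} d²; σ²_b = SS_within/(N−P); σ²_a = (SS_among/(P−1) − σ²_b)/n′ with
n′ = (N − Σn_p²/N)/(P−1); Φ_ST = σ²_a/(σ²_a+σ²_b). Distance models: 0/1
haplotype identity (conventional F_ST), pairwise sequence mismatch counts
(sequence Φ_ST), or summed squared repeat differences (R_ST-style Φ_ST, the
default for Y-STR data, matching the common tooling default; the choice is
a parameter). Negative variance components are reported as-is — clamping is
a presentation choice, and for exactly mirrored samples the estimator
yields Φ_ST = −1/(n_p−1) by construction, approaching 0 from below with
sample size. The permutation test shuffles individuals among populations
preserving sizes and applies the +1 correction, so p can never be 0.

## Border scan

The scan enumerates every unordered bipartition of the adjacency graph in
which **both** sides induce connected subgraphs (exhaustive over 2^(n−1)−1
splits; refused above 24 nodes). For each candidate it fits a binomial GLM
with logit link — intercept plus a side indicator — to the
per-subpopulation HUNT counts and, separately, FARM counts, and scores the
split with S = p_HUNT · p_FARM using two-sided Wald p-values. Wald is the
default reported by standard GLM tooling; with a single binary covariate the
MLE coincides with the pooled 2×2 log odds ratio and SE
√(1/a+1/b+1/c+1/d), which is also how the fit is initialized, so the
in-house IRLS (tolerance 1e−10, ≤100 iterations) converges in one or two
steps. Complete separation (zero or full successes pooled on a side) is
flagged non-converged with the penalized score p = 1, so degenerate splits
cannot win. Ties in S break toward the more balanced split, then canonical
lexicographic order. The sign convention: side A is the SW-like side and
β < 0 means lower odds in it.

The validity control draws k (default 10) bipartitions uniformly at random
among the **non**-contiguous ones (rejection sampling) and scores them
identically. On data with a genuine border, the contiguous optimum sits
orders of magnitude below this null range.

Two statistical facts about the scan, established by simulation with the
generator below, matter for interpretation:

- **The minimum is selection-biased.** Even with no border at all, the best
  S over ~170 contiguous candidates is far smaller than 10 unselected
  non-contiguous products and ranks at or near the bottom of the null draws
  almost always. The correctly calibrated null check is therefore the rank
  of a *pre-specified* split's S among the null products — which is
  uniform under no border — never the rank of the scanned optimum.
- **Exact recovery is noise-limited at realistic sample sizes.** With
  cluster contrasts of published scale (HUNT 0.211 vs 0.339, FARM 0.560 vs
  0.454) and ~380–440 samples per region over 13 subpopulations (~64 per
  subpopulation), the planted border is the exact argmin in roughly a third
  of replicates; the winner is otherwise a one- or two-subpopulation
  neighbour of the truth. Recovery rises to ~90% at four times and 100% at
  ten times the sample size. Per-subpopulation counts of ~64 carry binomial
  noise of ±4, routinely enough to tip the ranking between adjacent splits.
  Point estimates of the border's exact course at such sample sizes should
  be read with that uncertainty in mind; the side membership of most
  subpopulations is far more stable than the full split.

Per-haplogroup bias estimates reuse the same GLM per haplogroup (membership
vs side) on a fixed partition, skipping haplogroups under 10 carriers, with
significance tiers at p < 0.05/0.01/0.001.

## Bias–age correlation

Haplogroup age contrasts (age in Europe minus age in the Near East, years)
are external inputs; the packaged table is synthetic and exists only so the
examples run. Bias (β) and contrast are joined on normalized labels (≥3
required); the report carries the squared Pearson correlation, Spearman ρ
with average ranks for ties, and a two-sided permutation p for ρ (+1
corrected), seeded.

## Synthetic-data generator

The generator is the package's instrument for testing every stage without
external data. Its defaults encode the study conditions of the motivating
system:

- 13 subpopulations on the packaged graph; planted border = the SW/NE
  split (AL, TU, HA, VA, UU, LMO vs MI, CF, KU, KY, NC, OU, LA); region
  totals 389 (SW) and 443 (NE) for mtDNA, 306/243 for Y, spread evenly over
  each side's subpopulations.
- Baseline haplogroup frequencies = the NE-region column of the published
  frequency tables; on the planted side, HUNT-member logits are shifted
  down and FARM-member logits up, the vector renormalized. The two shifts
  are calibrated (by alternating one-dimensional root solves, exact to
  1e−11) so the planted side's cluster sums hit the published SW values
  0.211/0.560 — the NE side keeps 0.339/0.454 by construction. Y presets
  calibrate N1c/I1 the same way (0.376/0.556 in the SW against 0.667/0.239).
- Within each haplogroup, haplotype classes follow a Hoppe-urn/Ewens
  innovation process with θ = 40 (mtDNA; θ = 30 for Y), giving expected
  class counts Σθ/(θ+i−1) and haplotype diversities of ~0.95–0.99, the
  range observed in real control-region and Y-STR data.
- mtDNA classes are realized by infinite-sites "sprinkling": each new class
  adds 1 + Poisson(2) private mutations on positions never reused within
  the haplogroup, so the distance between two classes is the size of the
  union of their private sets. At sample sizes far above the defaults the
  643 positions can run out; the pool then caps the private count at what
  remains rather than failing.
- Y classes descend from a per-haplogroup ancestral profile by a stepwise
  mutation model: per locus, Poisson(depth·μ) events of ±1 repeat
  (floored at 1), with depth 200 generations and μ = 0.002 per locus per
  generation — mid-range of published Y-STR rates, giving
  E[(X₁−X₂)²] = 2·depth·μ ≈ 0.8 per locus between two descendants.

A star genealogy underlies within-haplogroup variation — classes hang
independently off the root — because the analysis consumes frequency
spectra, not genealogies. The generator therefore does **not** emulate
coalescent correlation structure, population growth, migration along the
graph, or mutation-model detail (no rate heterogeneity among sites or
loci). Passing tests demonstrate correct arithmetic and calibrated power on
spectra of realistic shape; they do not validate demographic inference,
which the package deliberately does not attempt.

Every dataset is accompanied by a truth record (planted split, shifts,
realized counts); recovery tests read it, the analysis pipeline never does.
A single integer seed makes output byte-identical.

## Numerical conventions and degenerate inputs

- Frequencies are exact ratios; printed tables round to 3 decimals.
- H and π refuse n < 2; single-class spectra give π = 0 with L = alignment
  length in the variance.
- Sequence comparison upper-cases and treats `N` and `-` as missing.
- Permutation p-values use the +1 correction throughout.
- All report writers serialize numerics at 12 significant digits, making
  write-then-parse round trips lossless at that precision.
- The alignment length default 643 follows the reported aligned length of
  the two control-region segments (whose raw coordinate span is 630;
  the difference is indel columns in the alignment). All computation is on
  alignment columns, so nothing depends on resolving that discrepancy.

## Problem sizes used in the shipped checks

The end-to-end checks run the full pipeline at the study scale: 832-sample
mtDNA datasets (100 replicates for power, 500 for null calibration of the
scan) and 549-sample Y datasets, with permutation counts of 99–10 000
depending on context. These sizes keep the whole suite in the minutes
range on a single core while leaving Monte-Carlo error well inside every
asserted tolerance.
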