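# ancientborder

Tools for detecting and characterizing spatial genetic structure in
uniparental markers — mitochondrial control-region sequences and Y-STR
haplotypes — sampled across a set of geographically adjacent subpopulations.
The motivating system is Finland, where haplogroups associated with
Mesolithic hunter-gatherers (mtDNA U and V) concentrate in the north-east
while haplogroups associated with Neolithic farmers (H, J, T, K) concentrate
in the south-west, a division interpreted as the vestige of an ancient
subsistence border.

The package is aimed at population geneticists who want to go from per-sample
haplogroup/haplotype tables to (i) frequency and diversity summaries,
(ii) differentiation statistics, and (iii) a formal, spatially aware test for
a frequency border.

## What it computes

**Diversity indices.** Haplogroup frequencies *f*, number of distinct
haplotypes *A*, Nei's unbiased haplotype diversity

&nbsp;&nbsp;&nbsp;&nbsp;*Ĥ* = *n*/(*n*−1) · (1 − Σᵢ *p*ᵢ²)

with its analytic sampling SD, and per-site nucleotide diversity *π* (mean
per-pair per-site difference under pairwise deletion of `N`/`-`) with
Tajima's total variance for its SD.

**Differentiation.** Two-level AMOVA (Excoffier–Smouse–Quattro variance
decomposition of squared molecular distances) giving Φ_ST — with sequence
mismatch or squared STR repeat-difference distances — or conventional F_ST
with 0/1 haplotype identity, plus a permutation p-value
(*p* = (1 + #{Φ*ᵖᵉʳᵐ* ≥ Φ*ᵒᵇˢ*}) / (*n*ₚₑᵣₘ + 1)).

**Border scan.** The core procedure: enumerate every bipartition of the
subpopulation adjacency graph whose two sides are both connected
("contiguous" splits), fit a binomial logit GLM (intercept + side) to the
per-subpopulation counts of the HUNT and FARM haplogroup clusters, and score
each split by the product of the two two-sided Wald p-values,
*S* = *p*_HUNT · *p*_FARM. The split minimizing *S* is the inferred border;
its validity is judged against *S* for random **non**-contiguous splits.

**Bias–age correlation.** Per-haplogroup side bias (log odds ratio from the
same GLM) correlated with externally supplied haplogroup age contrasts
(Pearson R², Spearman ρ with a permutation p-value).

**Synthetic data.** A generator that plants a known border on the adjacency
graph: haplogroup labels from logit-shifted frequency vectors, haplotype
spectra from an Ewens-type innovation process (new class with probability
θ/(θ+i−1)), realized as infinite-sites control-region sequences or
stepwise-mutation Y-STR profiles. Every dataset ships with a truth record
for recovery testing.

## Worked example

```python
from ancientborder import (finland_graph, mtdna_finland_config,
                           scan_border, simulate_dataset)
from ancientborder.cli import _counts_by

config = mtdna_finland_config()          # published-scale SW/NE contrasts
records, truth = simulate_dataset(config, seed=2021)
graph = finland_graph()
hunt, farm, totals = _counts_by(records, config.scheme, graph)
result = scan_border(hunt, farm, totals, graph, null_draws=10, seed=2021)
```

prints (via `python examples/02_border_scan.py`):

```
planted border : ['AL', 'HA', 'LMO', 'TU', 'UU', 'VA']
best split     : ['AL', 'HA', 'LMO', 'TU', 'UU', 'VA']
p_HUNT = 3.98e-06   p_FARM = 0.000167
product S      : 6.67e-10
non-contiguous null products: 0.00488 .. 0.514
```

The scan searched all 173 contiguous bipartitions of the 13-node graph and
returned exactly the planted border. Its score is some seven orders of
magnitude below the best of ten random non-contiguous splits — the signature
of a genuine geographic cline rather than a multiple-testing artifact.
The `examples/` directory holds one short script per capability (diversity
tables, border scan, AMOVA on Y-STR data, bias–age correlation, simulation
round trip); each prints the numbers it computes and a line on what they
mean. A thin CLI mirrors the library
(`ancientborder simulate|summarize|scan|amova|bias|correlate`).

## Layout

- `src/ancientborder/` — the library (`records`, `io`, `haplogroups`,
  `diversity`, `amova`, `borderscan`, `biasage`, `simulate`, `fixtures`, `cli`)
- `src/ancientborder/data/` — packaged Finland adjacency graph, default
  cluster scheme, synthetic example motif/age tables
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — models, estimators, numerical choices, limitations
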