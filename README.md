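# eigenmet

Analysis toolkit for staged developmental time courses, built around two
questions: *which temporal programs of gene expression structure a
developmental series, and how does the metabolome change across the same
stages?* The motivating system is *Drosophila* embryogenesis sampled in
twelve 2-hour bins from egg laying to hatching, but nothing in the code
is specific to flies.

## What it computes

**Eigengene decomposition.** A genes × timepoints abundance matrix *D*
is factored by singular value decomposition,

```
D = U S Vᵀ,
```

mapping (transcript) × (time) space to (eigengene) × (eigentime) space.
Each row of *Vᵀ* is an **eigengene** — a unit-norm temporal pattern
shared across genes — and column *i* of *U* holds every gene's loading
on eigengene *i*. The share of expression captured by eigengene *i* is
the **eigenexpression fraction**

```
eᵢ = sᵢ / Σⱼ sⱼ,
```

and the order of the spectrum is summarised by the normalised Shannon
entropy

```
d = −(1/ln n) Σᵢ eᵢ ln eᵢ,   0 ≤ d ≤ 1,
```

with *d* = 0 when one pattern dominates and *d* = 1 when all patterns
contribute equally. Genes most associated with a pattern are ranked by
their (sign-oriented) loading, top 500 by default.

**Gene-set enrichment.** Whether an annotated catalog (say, 1,228
metabolic genes in a 17,000-gene universe) is over-represented among a
pattern's top genes is tested with the exact hypergeometric upper tail

```
P(X ≥ k) = Σ_{i=k}^{min(K,m)} C(K,i) C(M−K,m−i) / C(M,m),
```

evaluated in log-space so p-values of order 10⁻²⁰ are exact.

**Metabolite time courses.** Replicated GC-MS peak areas are divided by
each sample's internal standard (e.g. D4-succinate), expressed relative
to the baseline bin (baseline median fixed at 100), summarised as
box-plot statistics, and each later bin is compared with baseline by an
unpaired Welch t-test (α = 0.01 by default). Within-sample metabolite
ratios (e.g. lactate/pyruvate) and bulk nutrient-store assays
(TAG/glycogen/protein; baseline-relative means, SEM, Student t-test at
α = 0.05) are handled the same way.

**Synthetic data.** `eigenmet.simulate` plants known temporal patterns,
enrichment signal and metabolite fold changes with configurable noise,
and returns the ground truth alongside each dataset, so the entire
pipeline is testable end to end without external downloads.

## Worked example

`examples/enrichment_test.py` ranks genes on the planted mid-rise
pattern of a simulated 17,000 × 12 matrix and tests a planted metabolic
catalog:

```
P(X ≥ 99 | M=17000, K=1228, m=500) = 1.107e-20  (log10 p = -19.96)
planted oversampling ratio 2.89 (realized 2.69)
observed overlap k = 98 of m = 500; p = 3.728e-20
```

The first line is the desk-scale tail evaluation itself: drawing 500
genes from a 17,000-gene universe containing 1,228 annotated ones and
seeing 99 annotated genes has probability ~10⁻²⁰. The planted catalog
(oversampled ~2.9-fold among the pattern's top loadings) produces an
overlap of 98/500 after ranking, which the test calls overwhelmingly
significant — the round trip from planted signal to detected enrichment.

`examples/eigengene_decomposition.py` shows the spectrum side:

```
patterns returned: 12
top-3 cumulative fraction: 0.959
Shannon entropy d = 0.325  (0 = one pattern dominates)
planted pattern 2: recovered with |r| = 0.9960 (SNR 28)
```

Twelve timepoints give exactly twelve eigengenes; three planted
programs carry ~96% of the expression, hence the low entropy, and each
planted pattern is recovered nearly perfectly at the default
signal-to-noise. The other examples (`metabolite_timecourse.py`,
`nutrient_stores.py`) walk through the metabolomics branch.

There is also a thin CLI (`eigenmet simulate|svd|rank|enrich|metab|stores|report`)
for running the same pipeline on files from a shell; `eigenmet report
--config run.yaml` runs every configured stage.

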