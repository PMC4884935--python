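# Methods

This note documents the models and procedures `coexmod` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Pipeline overview

The analysis compares two sample groups (labelled CT and DS by default)
measured on a common gene panel. Stages, in execution order:

1. **Preprocessing** — quality-flag masking (≥ 2 flags → NA), log2
   conversion (non-positive intensities → NA with a warning), probe →
   gene collapse (NA-ignoring mean per symbol; the collapse rule is a
   package choice — it is symmetric and order-independent), and the
   per-group NA filter: a gene is dropped when its NA count in *either*
   group reaches the modality limit (3 for mRNA arrays, 2 for the
   smaller miRNA arrays). Filtering is mask-only and idempotent.
2. **Differential expression** — SAM for genes, unpaired t-test for
   miRNAs (below).
3. **Networks** — per group, Pearson correlation over the group's
   samples (pairwise-complete; a pair with fewer than 6 mutually
   complete samples is *undefined* and never creates an edge), hard
   absolute threshold |r| ≥ τ, sign kept as an edge attribute, isolated
   genes dropped. DE networks use the SAM-called genes; CO ("complete")
   networks use all filtered genes.
4. **Hierarchy, communities, coarse graining, miRNA integration** —
   described below.

All randomness flows from one top-level seed; every stage is a pure
function of (inputs, config), so a run manifest (seed + config hash) is
sufficient to reproduce the outputs bit for bit.

## Differential expression

**SAM (genes).** Two-class unpaired moderated statistic
d_i = (m̄₂ − m̄₁)/(s_i + s₀), with s_i the pooled standard error. s₀ is
chosen by the percentile search: candidates are the {0, 5, …, 100}th
percentiles of s; for each candidate, genes are binned into 100
s-quantile windows and the coefficient of variation of the windows'
scaled median absolute deviations of d is minimised — the winning s₀
makes d's scatter independent of s. The null is estimated by permuting
group labels (default 1,000 draws in the API, exhaustive if fewer
distinct assignments exist; the bundled pipeline uses 200, which is
ample at 10 + 10 samples). A gene is called when its ordered d deviates
from the permutation-averaged expected order statistic by more than
delta (asymmetric cut-up/cut-low thresholds), and
FDR = median permutation false-call count / observed calls. No π₀
correction is applied — the estimate is deliberately the simple median
ratio, which is conservative. Delta is user-set; a helper reports the
delta → (calls, FDR) table so users pick delta at their target FDR.

**t-test (miRNAs).** Equal-variance pooled t (the convention of the
classic microarray suites), raw p < 0.05, no multiple-testing
correction. Degenerate zero-variance rows with equal means get t = 0,
p = 1. The t statistic is reported as group1-vs-group2; the up/down
direction (relative to group 2) is recorded separately from the sign of
the mean difference.

**Abundant miRNAs.** A miRNA is "abundant" when its linear-scale mean
expression is at least `factor` (default 30) times the global average
of per-miRNA linear means, *in both groups*. The global mean (rather
than median) is the baseline; this is configurable.

## Threshold selection and stability

`select_threshold` returns the **largest** grid value τ such that

- the giant component holds ≥ `min_giant_fraction` of the non-isolated
  nodes (1.0 where the data are expected to be globally connected;
  the pipeline default is 0.3 because block-structured/modular data
  cannot put every node in one component at informative thresholds),
- the Louvain partitions at τ ± `stability_delta` (default 0.005) agree
  with the partition at τ: adjusted Rand index ≥ 0.8 on shared nodes.

If no grid value qualifies the selector raises with a per-τ diagnostics
table. `robustness_sweep` reports (N, L, Q, community count, ARI vs a
reference partition) across a τ range, the quantitative form of the
claim that small threshold changes do not alter community structure.

## Scale-free testing

Degrees are fit by the discrete power-law maximum likelihood:
α̂ maximises −n·ln ζ(α, x_min) − α·Σ ln x (exact Hurwitz-zeta
likelihood, bounded search α ∈ (1, 10]); x_min is scanned over observed
values keeping ≥ 10 tail points and chosen to minimise the K-S distance
between the empirical and fitted tail CDFs. An optional semiparametric
bootstrap (empirical body + power-law tail resamples) gives a
goodness-of-fit p; constant or near-constant degree sequences are
flagged degenerate rather than fitted. A seeded inverse-CDF sampler for
discrete power laws supports parameter-recovery testing (the far tail
beyond the 10⁵-term CDF table uses the continuous approximation, hit
with negligible probability at the sizes used).

## Node hierarchy (k₀, k₁)

k₁(v) counts edges joining a node at breadth-first distance 1 from v to
a node at distance 2 — edges *leaving* the immediate neighbourhood.
Edges internal to ring 1 are deliberately excluded: they do not leave
the neighbourhood, and this makes k₁ invariant to ring-1 densification
(a tested property). Categories are declared from quantile cutoffs on
the (k₀, k₁) cloud, since any fixed numeric boundary would be arbitrary
across networks of different size and density:

- hub: k₀ ≥ the 0.90 quantile of k₀ **and** k₀ > median(k₀) (the strict
  median condition means uniform-degree graphs declare no hubs);
- VIP: not a hub, k₀ ≤ the 0.50 quantile, and all neighbours hubs
  (fraction configurable);
- high-hub: hub with k₁ ≥ the 0.90 quantile of k₁ and k₁ > 0.

Precedence is high-hub > hub > VIP; the union is the high-hierarchy
(HH) set. All four cutoffs are configuration with the defaults above,
chosen to yield sparse HH sets (a few dozen genes on networks of a few
hundred nodes).

## Communities and coarse graining

Louvain (greedy modularity: local moves + aggregation) is run as
best-of-10 seeded restarts scored by exact modularity; the partition is
deterministic given the seed. Modularity Q = Σ_α (E_αα/L − (d_α/2L)²)
is evaluated with `Fraction` arithmetic on the integer edge and degree
counts, so identical partitions give bit-identical Q and the value can
be compared exactly against direct enumeration. Community labels are
A, B, C, … in decreasing size (ties broken by smallest member id), so
community A is always the largest.

The mixing matrix holds E_αβ (between-community edge counts; within
counts on the diagonal) and W_αβ = E_αβ/(|α||β|); the size-product
normalisation removes the bias toward large communities. Edge
conservation (Σ diagonal + Σ upper triangle = L) is exact and tested. A
community's *node strength* is Σ_β≠α W_αβ, its total probability of
connecting elsewhere. The CGCS contracts each community to one node
(attributes: size, within-density 2E_αα/(|α|(|α|−1)), defined as 0 for
singletons since W is a distinct-pair quantity) with W_αβ edge weights;
for CO networks it can be restricted to communities containing ≥ 1 HH
gene. Community subnetworks are rebuilt (same group, same τ) only for
communities of ≥ 100 genes by default.

## miRNA integration

Target tables are file inputs (miRNA, gene, evidence ∈ {validated,
predicted}); live database queries are out of scope so runs are
reproducible offline. DE-network integration keeps every validated
interaction whose gene is a DE gene present in the network and admits
predicted interactions only for HH genes; CO-network integration
restricts the gene side to HH genes (both evidence levels admitted
there). miRNAs with no surviving interaction are dropped; when the same
pair appears as both validated and predicted, validated wins.
Direction, abundance and hierarchy are stored as node attributes.

## Synthetic data: what it emulates and what it does not

The generator mimics a two-group single-channel microarray study:
baselines uniform in [6, 12] log2 units, Gaussian noise (default
σ = 0.3–0.4 log2), planted gene modules driven by one latent factor per
module with loadings uniform in [0.7, 1], one-sided differential
expression (+effect in group 2 only, mirroring designs where all DE
genes move one way), completely-at-random NAs, and a companion miRNA
table (641 × (8 + 8) at full scale, with 47 down- / 6 up-regulated at
2 log2 units and 6 abundant miRNAs at 50× baseline).

Two constructions make the *planted truth* hold by construction rather
than merely in expectation, which matters at these small sample sizes:

- **Module factors are orthogonalised within each group** (QR of the
  factor draws). Independently drawn factors over 10 samples are
  frequently correlated at |r| > 0.5 by chance, which would silently
  merge two "distinct" planted modules and make ground truth false as
  planted. `factor_strength` is the factor's variance share at loading
  1, so it maps directly onto within-module correlation and is
  monotone in it (a tested property).
- **Abundant miRNA rows are pinned per group** so their realized linear
  mean is exactly `abundance_factor ×` the realized non-abundant
  baseline; the planted abundant set then satisfies the 30× rule in
  both groups deterministically (50·n/(n + 50·k) ≥ 30 at the default
  proportions).

Not emulated: probe-level array artefacts (dye, spatial effects),
heavy-tailed or gene-dependent noise, correlated missingness,
between-module correlation structure, and realistic hub topology inside
modules (planted modules are single-factor blocks, which become
near-cliques after thresholding). Passing the planted-recovery tests
therefore shows the machinery is correct on blockwise-correlated data;
it does not certify performance on real arrays, where module boundaries
are soft and noise is structured.

## Problem sizes and defaults in the bundled checks

The test suite and the acceptance script run the generator at reduced
scale — 150–300 genes with three 50-gene modules for network stages,
6,000 null miRNAs for t-test calibration, 10,000 draws for power-law
recovery — sizes chosen so every property of interest (recovery,
calibration, conservation, exactness) is measurable with tight
statistics while a full run stays interactive. The full-scale defaults
(13,000 genes × (10+10); 641 miRNAs × (8+8)) remain the config
defaults for real use.

## Known limitations

- SAM's s₀ search and permutation scheme follow the classic two-class
  unpaired recipe; paired and multi-class designs are not implemented.
- The hierarchy cutoffs are quantile conventions, not estimates; two
  networks' HH sets are comparable only under the same config.
- Louvain is a heuristic: the restart policy makes it deterministic and
  near-optimal on small graphs (tested against exhaustive enumeration)
  but offers no global guarantee.
- The giant-component criterion for threshold selection is a
  configurable fraction; on strongly modular data it must be relaxed
  below 1.0, which the pipeline default (0.3) reflects.
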