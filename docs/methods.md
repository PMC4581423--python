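# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Study design and data model

The pipeline targets a paired two-group design: the same infants,
classified breast-fed (BF) or formula-fed (FF), measured on two layers —
microbial species percent abundance (compositional, sparse, species ×
sample) and host log2 gene expression (gene × sample). A third layer is a
literature co-mention table: for each (species, gene) pair, 2×2 abstract
counts (both mentioned / species only / gene only / neither) from a
corpus of size N. Group labels are arbitrary strings; `BF`/`FF` is the
canonical pair and every group-wise operation requires ≥2 samples per
group.

## Differential screening (moderated t)

Both omics layers are screened with the same empirical-Bayes two-sample
machinery. For feature g with pooled variance `s²_g` on `df = n₁+n₂−2`
degrees of freedom, the prior `(d₀, s₀²)` is estimated by moment matching
on `z_g = log s²_g`: the excess of `Var(z)` over `trigamma(df/2)` is
inverted through the trigamma function to give `d₀`, and the mean of `z`
(offset by digamma terms) gives `s₀²`. The trigamma inverse uses Newton
iteration with asymptotic starting values. Shrinkage is
`s̃²_g = (d₀s₀² + df·s²_g)/(d₀+df)`; the moderated t is referred to a t
distribution on `d₀+df` df. Two degenerate branches: non-positive excess
variance means the features are consistent with one common variance
(`d₀ = ∞`, all `s̃² = s₀²`, normal reference); `moderation=False` is the
`d₀ = 0` limit and reproduces the ordinary pooled two-sample t exactly.
Features with zero variance in both groups get missing t and p; missing
p propagates through BH and never selects.

Selection is BH-adjusted `p ≤ α` **and** `|log₂FC| ≥ fc_min` (defaults
0.05 and 2; both are flags). The fold-change threshold is read on the
log2 scale and two-sided, the common convention for moderated-t
pipelines. Abundances are transformed `log2(x + pseudocount)` first
(pseudocount 0.01 on the percent scale, configurable) so the roughly
multiplicative, zero-inflated abundance data meet the screen's Gaussian
working assumption; the pseudocount is deliberately small relative to a
1% abundance so that presence/absence structure survives as large
negative values rather than being smoothed away.

logFC is `mean(FF) − mean(BF)` (second group over first); the contrast
is recorded in the result's metadata.

## Species co-abundance networks

Similarity is Bray-Curtis, `s = 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, between species
profiles across one group's samples. It tolerates shared zeros (a pair of
sparse vectors is compared only on their mass) and, unlike correlation,
is usable at n = 6; note it is *not* scale-invariant — it compares
absolute percent profiles, which is intended on compositional data where
all columns sum to 100. A pair of species both absent from the group has
no defined similarity; such species stay isolated nodes.

The stability filter interprets "mean less than k standard deviations
above zero" per pair: a bootstrap over the group's samples (B_boot = 200
draws with replacement) gives each pair a mean and SD, and pairs with
`mean < k·SD` (k = 2) are discarded as sampling noise. This is the only
reading that yields a per-edge decision from that rule; k and B_boot are
parameters. With B_boot = 1 the SD is undefined and every pair is flagged
unstable (warned, nothing passes silently). Networks are unweighted after
filtering, with the bootstrap-mean similarity kept as edge metadata.

Whole-network significance: double-edge-swap randomization holds every
node's degree fixed (10·|E| attempted swaps per draw; graphs with <2
edges or no swappable pair are returned unchanged, so tiny graphs like a
triangle — the unique realization of its degree sequence — are handled
gracefully). The test statistic defaults to the average clustering
coefficient, because edge count is invariant under a degree-preserving
null; the statistic is a flag (`edge_count`, `clustering`,
`mean_weight`). Both an empirical p `(1 + #{null ≥ obs})/(B+1)` and a
normal-fit z-score p are reported: the empirical estimator is valid but
granular at 1/(B+1), while the z-score supports p-values finer than the
permutation count when the null is well behaved (it is undefined, and
reported missing, when the null is constant).

## Gene co-expression networks

Pearson correlation within each group's columns over a shared gene
universe; unweighted edges at `r ≥ 0.8`. The default keeps positive
correlations only — a co-expression edge asserts joint activity, and the
cutoff is quoted unsigned — with `mode="absolute"` behind a flag.
Correlations are undefined (missing, never 0) when a gene is constant;
missing correlations never create edges. Density `2|E|/(|V|(|V|−1))` and
the BF/FF density ratio are the comparison read-outs. With six samples
per group an `r ≥ 0.8` threshold admits ~3% of independent pairs, so
absolute densities are noisy; the ratio between conditions over the same
universe is the meaningful quantity.

## Literature relations and validation

Fisher's exact test (two-sided, hypergeometric enumeration) screens each
pair's 2×2 co-mention table; pairs with raw `p < 0.05` are accepted, as
a deliberately permissive first-pass screen whose acceptances are then
validated against the omics data; BH adjustment is available behind a
flag. Accepted genes are typed `de_gene` if they passed the expression
screen, else `transient_gene`.

Validation correlates species abundance with gene expression across the
shared samples (per feeding group by default, matching how a taxon can be
absent under one feeding mode; pooled by flag). Pairs with a constant
vector (e.g. species absent from the group) get missing r. The baseline
is the mean |r| over 1000 uniformly random (species, gene) pairs,
excluding accepted relations so real signal does not contaminate the
null — exclusion is the conservative choice. With 12 pooled samples the
null E|r| is ≈ 0.25, so a baseline near 0.25 is expected, not a bug.

## Multi-layer topology

The three layers union into one typed graph per condition. Node types:
`species`; `de_gene` for genes in the DE set; `transient_gene` for genes
that enter only through the literature layer. Edge types are preserved
(`co_abundance`, `co_expression`, `literature_relation`); optional
prefixes namespace the species and gene id spaces and a collision is an
error. Shortest paths are unweighted (all layers equal). Diameter and
mean path length are computed on the largest connected component —
merged networks contain isolated nodes, so the all-pairs maximum is
infinite and the LCC convention is the only one yielding finite numbers.
The reachability profile counts nodes of each type within BFS distance
L ∈ {1,2,3} of a start node, averaged over **all** start nodes by
default: a single random start is irreproducible, and the all-starts
average is its expectation; `n_starts` with a seed reproduces the
sampled variant.

## Functional enrichment

Upper-tail hypergeometric `P(X ≥ k)` per term, BH across terms. The
universe is the measured genes (not all annotated genes) — the
conservative choice when the query derives from the measured platform —
and the query must be a subset of it. Annotations come from a GMT file;
duplicate members collapse; terms are intersected with the universe.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 6+6 samples, 35 species with
zero-inflated log-normal percent abundances renormalized to 100 per
sample, 300 genes, and planted structure for every stage — 4
differentially abundant species (log2 effect 3 in FF), 20 DE genes
(log2 effect 3), condition-specific co-expression blocks (denser under
BF), 15 literature pairs with co-mention rates inflated 20× over an
independent corpus, and abundance→expression coupling (β = 1 times the
standardized species abundance added to the gene) so correlation
validation has recoverable positive signal. One root seed fans out to
named child streams; every generator is a pure function of (parameters,
seed).

Calibrated defaults, fixed by Monte-Carlo before the test suite was
frozen:

- `dispersion = 0.3` (log-scale within-group SD) and `zero_prob = 0.3`.
  Planted effects go on sub-dominant taxa: boosting a dominant taxon
  would deflate every species' share under compositional closure and
  erode the planted fold change itself. At these settings the
  differential screen recovers ≥3 of 4 planted species in ~87% of seeds.
- `within_block_r = 0.99`. With n = 6, sample correlations scatter
  widely (Fisher-z SD ≈ 0.58), so a population correlation of 0.9 almost
  never yields a complete clique at cutoff 0.8 across a 25-gene block's
  300 pairs; at 0.99 the block survives as a clique in ~97% of seeds.
  Equally, a planted block cannot be expected to be exactly *empty* in
  the other condition: ~3% of independent pairs clear 0.8 at n = 6, so
  tests assert low off-condition density rather than emptiness.
- `base_rate = 0.02` mentions per abstract, corpus 10⁵. At 0.01 the
  expected co-mention count is 10 and the two-sided Fisher test is
  conservative enough that the null acceptance rate falls below 3%; at
  0.02 it sits near the nominal 5%.

Not emulated: phylogenetic correlation among species, realistic taxon
abundance distributions beyond log-normal, batch effects, sequencing or
probe-level noise, and any text-mining artifacts (the corpus model is
independent binomial mentions). Passing tests therefore demonstrate that
the machinery recovers planted structure under idealized sampling noise
at the study's sample sizes — not that real data of this shape will
yield equally clean recovery.

## Numerical conventions and degenerate inputs

- Shannon index in nats; `0·ln 0 := 0`; all-zero vectors yield NaN
  (reported missing), not an exception, in per-sample reports.
- BH: step-up via the standard implementation; NaN p-values propagate.
- Fisher two-sided convention: sum of table probabilities ≤ observed
  (with a 1+1e-9 relative tie guard in the test oracle).
- Degree-preserving rewiring counts *attempted* swaps; rejected
  proposals (self-loop/multi-edge) are not retried, which keeps the
  draw count deterministic.
- Permutation p uses the add-one estimator; it can never report 0.
- Bootstrap SD uses ddof = 1; a single bootstrap draw yields infinite SD
  (flagged unstable) rather than 0.
- Pipeline outputs carry `# feednet config=<hash> seed=<n>` headers; the
  config hash covers the scientific parameters but not the output
  directory, so identical analyses in different directories are
  byte-comparable. The manifest lists SHA-256 of every output.

## Problem sizes

Tests and the acceptance script run at the study's native scale (6+6
samples, 35 species, 300 genes) with 100-seed Monte-Carlo for recovery
rates, 1000 permutations for the network test inside the acceptance
script, and reduced permutation/bootstrap counts (20–100) inside the
end-to-end reproducibility tests, where the assertion is about
determinism rather than power.

## Known limitations

- The bootstrap stability filter is permissive on dense, even
  communities: most positive-similarity pairs are stable, so co-abundance
  networks can be dense; the permutation test then judges the network's
  wiring, not its density.
- With six samples per group, individual correlations (both co-expression
  edges and validation r) are noisy; only aggregate read-outs (densities,
  ratios, rate comparisons against baselines) should be interpreted.
- Fisher screening without multiplicity control accepts ~5% of null
  pairs by design; downstream validation, not the screen, carries the
  evidential weight.
- The moderated-t on log-transformed compositional abundances ignores
  the compositional constraint (no log-ratio transform); planted-truth
  recovery shows it works at the intended effect sizes, but strong
  compositional coupling (a dominant taxon changing) can induce spurious
  negative fold changes in other taxa.
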