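# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Differential expression

The pipeline starts from a normalized log2 expression matrix; probe-level
preprocessing (background correction, normalization, array QC) is upstream
and out of scope.

**Expression filter.** A gene is kept when its expression exceeds
`min_level` = 2 log2 units in at least `min_samples` = 3 samples *and* its
row standard deviation is at least `min_sd` = 0.1. The SD cut is read as a
minimum-variability filter: a maximum would discard exactly the genes that
carry contrast information. The SD is the sample SD (ddof = 1); the choice
is arbitrary at this scale but fixed for reproducibility.

**Moderated t.** For a two-arm contrast each gene contributes
Δ = mean_a − mean_b, pooled residual variance s² and df = n_a + n_b − 2.
The variance prior s² ~ s₀²·χ²_{d₀}/d₀ (scaled inverse-chi-square) is
estimated from *all* filtered genes of the contrast — shrinkage must be
calibrated on the ensemble, never on hits — by moment matching on
e_g = log s²_g − ψ(df/2) + log(df/2): the excess of var(e) over
mean(ψ′(df/2)) identifies d₀ through ψ′(d₀/2) = excess, solved by monotone
Newton iteration (relative tolerance 1e-8), and s₀² follows from mean(e).
Non-positive excess yields d₀ = +∞ with s₀² = exp(mean(e)); in that limit
the moderated t reduces to a z-statistic against s₀². Genes with zero
residual variance are excluded from the prior fit (their log variance is
undefined); an all-zero-variance input is an error. On heteroscedastic
data the whole path (d₀, s₀², t, p) agrees with limma's `eBayes` to
~1e-12 relative (cross-checked in the test suite via Rscript).

Degenerate cases: zero posterior variance gives a signed-infinite t with
p = 0, flagged in the log; d₀ → 0 recovers the ordinary two-sample t
(asserted at d₀ = 1e-12).

**Multiple testing and DEG calling.** BH adjustment delegates to
statsmodels; the brute-force step-up definition is kept as an independent
oracle in the tests. DEG thresholds are FDR < 0.05 (exclusive) and signed
linear fold change |FCH| ≥ 2 (inclusive). The boundary orientation cannot
be recovered from a prose threshold; it is pinned this way so reported
counts are reproducible to the digit. FCH is computed from the filtered
log2 matrix arm means, ±2^|Δlog2| with 0 mapping to +1.

**Probe collapse.** Where rows are probes rather than genes, the
gene-level table keeps the probe with maximal |t| per gene, ties broken by
lexicographically smaller probe id. Probe-level rows are retained for DEG
*counting*; the collapse is used for ranked lists, ortholog joins and
enrichment, where duplicate gene ids would distort set statistics.

## Cross-species concordance

**Ortholog translation** expands many-to-many pairs to all targets by
default (`one_to_one` mode available); a target reachable from both the up
and the down half is dropped from both, preserving disjointness, and
counted in the log. Gene identifiers are opaque case-sensitive strings
throughout.

**Ranked-list overlap.** O(k) = |top-k ∩ target| is computed in one
cumulative pass. The null draws one uniform permutation of the universe
per replicate and reads the whole curve from its cumulative sums —
marginally identical to independently sampling k genes without replacement
for every k, at O(G) per replicate. Curves within a replicate are
correlated across k, but only pointwise summaries (mean and central 95%
empirical band) are reported, so this is immaterial. The universe is the
set of measured (filtered, gene-level) genes, not the genome: a ranking
can only select from what was measured. Defaults: K = 5000 ranks,
n_reps = 5000 replicates, 95% band (the confidence level is a choice;
no canonical level exists for this construction).

## Enrichment and connectivity

The weighted-KS running sum uses hit weights |r_i|^p with p = 1 (the
classic choice; p = 0 gives the unweighted KS statistic) over the
fold-change-ranked table (moderated t available as an alternative metric).
ES is the extremum of P_hit − P_miss; if every member weight is zero
(all-zero ranking statistics) the hit steps fall back to uniform so the
score stays defined.

The null permutes *gene sets* (uniform random sets of matched size), not
phenotypes: five samples per arm admit only 126 distinct relabelings, far
too few for a stable NES. NES = ES / mean(|ES_null|) over sign-matched
null values; p is the add-one-smoothed sign-matched tail fraction; FDR q
is the pooled-null tail-ratio (fraction of null NES beyond |NES*| divided
by fraction of observed NES beyond it), clipped to [1/(n_null+1), 1].
Defaults n_perm = 1000, seed always explicit. NES and FDR are validated by
properties and simulation only — no external reference values exist for
the permutation scheme.

CS = ½(ES_up − ES_down) is reported to two decimals; recomputing a printed
CS from printed two-decimal ES values can differ by up to ±0.005 from a CS
derived from unrounded ES.

## Treatment response

The texts this pipeline serves rarely define "improvement" algebraically;
the package pins the semantics as linear interpolation on the log2 scale:

* improvement% = 100·(m_dis − m_trt)/(m_dis − m_naive). 0% = still at the
  disease level, 100% = back to naive; the same formula serves up- and
  down-regulated genes by sign cancellation. Genes with |m_dis − m_naive| ≤
  ε = 0.1 log2 units (the expression-filter SD scale) are excluded from
  summaries and counted; values are clipped to [−200, 300] so a handful of
  noise-dominated ratios cannot dominate a mean (clips logged).
* FCH toward recovery = 2^|m_dis − m_trt|, signed positive when the
  movement reduces the distance to naive; no movement gives +1.
* modulated fraction = disease DEGs that are DEGs of the treated-vs-disease
  contrast at the same cut-offs, by default *requiring opposite direction*
  (a drug pushing a disease gene further from naive is not modulation);
  both toggles are exposed because either convention is defensible.

Summaries aggregate over disease DEGs, overall and stratified into genes
shared with a (translated) human signature vs species-unique genes.

## Synthetic generator

Mouse model per gene: x = μ_g + β_g·𝟙[disease-derived arm]·(1 − ρ_{g,arm})
+ ε, ε ~ N(0, σ²_g), with μ_g ~ N(6, 1.5²) (typical log2 intensity range),
σ²_g ~ d₀s₀²/χ²_{d₀} with (d₀, s₀²) = (4, 0.04) (a realistic
microarray-scale variance prior), frac_de = 0.2, effect magnitudes
|β| = 1 + Gamma(2, 0.5) — the floor guarantees |FCH| ≥ 2 is attainable by
construction and the right tail mimics the wide fold-change ranges real
disease signatures show — sign up-biased by 0.5, and recovery
ρ ~ Beta(2, 2) per gene and treatment arm (ρ = 0 in the disease arm by
definition; fixed-ρ overrides exist for limit checks). Arms are naive,
disease, trtA, trtB with n = 5 each, the common design scale for mouse
profiling studies. The human study (LS vs NL, n = 10/10) shares
frac_shared = 0.4 of ortholog-covered mouse DE genes as sign-concordant DE
orthologs, adds 10% human-only DE genes, and reuses the noise model.
Ortholog coverage 0.9 with 5% many-to-many sources.

Deliberately *not* emulated: probe-level structure, batch and platform
effects, intensity-dependent variance, saturation, and correlated genes.
Passing tests therefore demonstrate correctness of the statistics under
the stated model, not robustness to real-array artifacts — on real data
the filter, the shrinkage and the null bands all inherit whatever
violations the data carry.

All generators are pure functions of (config, seed); the orchestrator
spawns per-stage sub-seeds deterministically from one master seed, so a
whole pipeline run is byte-reproducible (checksummed in the tests).

## Problem sizes used in validation

Simulation-based checks run at G = 5000 genes, n = 5 per arm (20 seeds for
the global-null FDR check, 10 for parameter recovery), the scale at which
the moment estimator's sampling error is small relative to the ±20%
recovery band for d₀; Monte-Carlo calibration of the overlap null uses a
2000-gene universe at 5000 replicates; end-to-end determinism runs the
full pipeline at G = 400 with reduced replicate counts, which exercises
identical code paths at a fraction of the cost.

## Known limitations

* Two-group contrasts only: no multi-factor designs, paired samples or
  array weights.
* The ranked-overlap null is unmatched (no gene-length or
  expression-level matching).
* Gene-set permutation NES is not comparable numerically to
  phenotype-permutation NES from other tools, though signs and orderings
  agree in practice.
* The improvement metrics are arm-mean statistics; they carry no per-gene
  uncertainty and should be read as descriptive summaries.
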