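# Methods

This note documents the models, conventions and design choices behind
`secsig`, in the order the pipeline runs. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study model

The generators emulate a four-condition tumor-cell panel — parental (`P`),
treatment-resistant (`PTR`), and IFN-receptor-knockdown variants of both
(`P_KD`, `PTR_KD`) — assayed by bulk RNA-seq, a multi-exposure cytokine
antibody array, and qRT-PCR, plus the two annotation resources the analysis
filters on. A designated *planted* gene set carries the true
treatment-induced secretory program; correct pipelines should recover it.

**Counts.** Gene counts are negative binomial with mean–dispersion
parameterization `Var = μ + φμ²` (default dispersion `φ = 0.2`, a typical
bulk RNA-seq value for cell-line replicates). Baseline log2 means are
uniform on `[3, 10]` (≈8–1000 expected counts), spanning realistic dynamic
range. Planted genes gain `planted_log2fc` (default 3.0) in `PTR`, reduced
by the fraction `kd_reversal` (default 1.0, i.e. fully IFN-dependent) in
`PTR_KD`. Per-sample library-size factors are log-normal (sd 0.2) so that
library normalization is non-trivial. Default depth: `n_per_group = 3`, the
usual cell-line RNA-seq design.

**Annotation.** The secretome has size `round(secretome_fraction · n_genes)`
(default fraction 0.25, roughly the share of genes annotated to the
extracellular-region GO term) and always contains the planted genes. Every
planted gene carries a type-I "up" IFN record with fold change ≥ 1.5;
non-planted genes carry one independently with probability `ifn_fraction`
(default 0.30, reflecting how broad curated IFN-regulation databases are at
permissive query settings). Secondary type-II/III records, some below the
1.5 threshold, exercise the threshold and type logic.

**Array.** One membrane per condition, imaged at exposures of 1, 5 and 30 s.
Spot volume = gain × (background + abundance·2^effect) × log-normal spot
noise (sd 0.10), clipped at a saturation ceiling of 65535 (16-bit detector
full scale — the phenomenon that motivates shortest-exposure selection).
The noise draw belongs to the physical spot, so unsaturated volumes scale
exactly with exposure gain. Target abundances are log-uniform over
`2^[7,11]` so that all targets are detectable at the 3×background rule while
strong signals saturate at the longest exposure.

**qPCR.** One log2 unit of expression equals one CT cycle; planted genes'
CTs drop by `planted_log2fc` cycles in `PTR`. Housekeeping genes (Gapdh,
Actb) have fixed baselines and no condition effect. Technical noise is
Gaussian with sd 0.15 cycles, a typical technical-replicate spread.

**Seeding.** Every generator is a pure function of (config, seed). The
global seed fans out to fixed per-assay child streams
(`SeedSequence([seed, offset])`), so changing one assay's structure never
reshuffles another assay's draws.

**What the generator does *not* emulate:** GC/length biases, batch effects,
gene–gene correlation, isoform structure, array spot bleed-over or spatial
gradients, qPCR primer-efficiency differences, and any immune-cell mixture
signal. Passing tests therefore demonstrate the correctness of the
*computational* pipeline under a clean generative model, not robustness to
every artifact of real data.

## Expression stage

*Filtering.* The retained set is genes with raw-library CPM ≥ `min_cpm`
(default 1) in at least `min_samples` samples (default: the smallest
condition group size) — the common count-filter convention. An empty result
warns rather than errors.

*Upper-quartile normalization.* Per sample, `f_s` = 75th percentile (linear
interpolation) of the sample's **nonzero** counts divided by its library
size; factors are rescaled to unit geometric mean; CPM divides by
`library × f̃_s`. This makes CPM invariant to uniform rescaling of a
sample's counts, preserves within-sample ranks, and keeps the column sum at
the closed form `10⁶ / f̃_s`.

*Differential calls.* log2 fold change of group-mean CPM with a pseudocount
(default 1.0 on the CPM scale) keeps every value finite; |log2FC| ≥ 2 is
called differential, boundary inclusive. No dispersion estimation or
moderated statistic is used: the downstream ranking is defined directly on
log2FC, and the rank list always contains *all* genes, with exact ties
broken lexicographically so ordering is a pure function of the input.

The pseudocount slightly shrinks estimated effects of low-expression genes
(the planted-gene mean estimate sits a few tenths below the true log2FC at
default depth); this is intrinsic to any offset-log estimator and is left
as is.

## Proteomic stage

The detection rule ("signals could be detected") is a declared convention:
a target is detected when its duplicate-mean volume exceeds an absolute
threshold, defaulting to 3× the mean background volume of the candidate
grid. Selection returns the shortest detected, unsaturated exposure;
detection only at saturation is flagged and uses the shortest saturated
exposure; no detection anywhere yields intensity 0 with an `undetected`
flag (never NaN). Quantification is
`max(0, target − background) / (reference − background)` on the *same*
grid — negative background-subtracted values are clamped to zero
(physical non-negativity), duplicates are summarized by the arithmetic
mean, and the positive-control division cancels membrane-wide gain. Arrays
are typically n = 1, so no test statistic is produced at this stage.

## qPCR stage

Housekeeping aggregation is the arithmetic mean of CTs (equivalently the
geometric mean of expression levels), the standard multi-housekeeping
practice; cross-sample condition summaries are geometric means because
expression is ratio-scale. Two conventions are implemented because wet-lab
write-ups sometimes print the ΔCt exponent with the opposite sign:
`standard` (`2^-(CT_gene − CT_HK)`; expression falls as target CT rises) and
`as_printed` (the exact reciprocal). The printed-form variant would make
expression *increase* with the target's CT, which contradicts the physics
of amplification; `standard` is the default, the discrepancy is surfaced
here rather than silently resolved, and the two conventions are verified to
be exact reciprocals.

## Signature integration

Candidates come from the preliminary list: secretome members, IFN-regulated
at fold change ≥ 1.5, transcript log2FC ≥ +2 (≤ −2 for the mirrored
down-signature). The final rule requires, per candidate: a significant
proteomic record in the expected direction for `PTR_vs_P`; a significant
opposite-direction record for `KD_vs_PTR` (any modality by default, because
knockdown reversal is routinely assessed by both protein array and qRT-PCR;
a strict-proteomic mode exists); and overall confirmation by at least one
transcriptomic *and* one proteomic method. The cross-modality reading was
chosen over a plain "any two methods" count because it subsumes it whenever
evidence spans both modalities and is the stronger, more interpretable
requirement; `confirmation_mode="any_two"` preserves the weaker reading.

"Significant" for replicate-free assays (array n = 1, summary qPCR/ELISA
fold changes) means |log2 ratio| ≥ an effect floor, default 0.58 ≈ 1.5-fold,
standing in for by-eye calls on blots and membranes. Signature ordering is
alphabetical. Protein-to-gene mapping is an explicit table; unmapped targets
are skipped with a warning — silent fuzzy matching is worse than a hard
gap. The derivation log records each step's verdict per candidate, making
the selection funnel auditable, and each rule step can be toggled to probe
monotonicity (removing a conjunct can only grow the signature).

## Enrichment and scoring

The enrichment score is the weighted Kolmogorov–Smirnov-style running sum
(hits add `|metric|^p` normalized over the set's hits; misses subtract
`1/(N − N_hits)`); the ES is the running-sum value of maximal absolute
deviation, taking the first extremum when magnitudes tie exactly. The
running sum is computed as hit-fraction minus miss-fraction cumulatives so
that its floating-point values match the closed form bit for bit. With
`p = 0` the score reduces to the classical KS statistic and is invariant to
strictly monotone metric rescaling; the default is `p = 1`, the weighting
used by the reference preranked tools. A set covering the whole universe is
an error (the miss decrement is undefined); all-zero metrics with `p > 0`
fall back to equal hit increments.

Significance uses gene-set permutation (default 1000): null sets of the same
size are drawn uniformly without replacement, one RNG stream per gene set
seeded from (global seed, set index) so results are independent of
evaluation order. `NES = ES / mean(|null ES| of matching sign)`; the FDR
q-value is the sign-stratified ratio of tails over the pooled observed and
null NES, clipped to [0, 1], with a BH-style ascending cumulative minimum so
a more extreme NES never carries a larger q. Sets with zero overlap are
flagged and excluded from the FDR pool. The conventional significance
read-out is FDR q ≤ 0.25.

Signature scoring is deliberately simple: the arithmetic mean CPM of the
set genes present per sample (missing genes are reported), compared across
conditions with Welch's unequal-variance t-test; with one sample on a side
only the difference of means is reported, and two degenerate equal-constant
groups give p = 1 by convention.

## Pipeline and configuration

`PipelineConfig` is schema-validated (unknown keys rejected, defaults
filled, thresholds positive; permutation counts below 100 warn). The full
run writes every intermediate artifact as headered TSV/CSV — diffable and
binary-free — plus a JSON manifest with the seed, thresholds, per-stage
record counts and a SHA-256 per file; re-running the same configuration
reproduces byte-identical artifacts (manifests differ only in timestamp).
Stage-level logging of record counts makes the derivation funnel visible
end to end.

## Problem sizes used in the test suite

Unit tests run on a 300-gene, 10-planted study; the end-to-end recovery
check runs the default 2000-gene, 50-planted study across 50 seeds, and the
enrichment read-out check uses 2000-gene rankings at 1000 permutations
across 20 seeds — sizes chosen so the full suite completes in a few minutes
on one CPU while keeping every stage statistically meaningful.

## Known limitations

- The exact-set recovery of all planted genes in a single run is limited by
  the sampling noise of the log2FC estimator: at triplicate depth and
  dispersion 0.2 its sd is ≈ 0.5, so with a planted effect of 3 against a
  threshold of 2 a planted gene clears the DE gate with probability ≈ 0.95,
  and runs with 50 planted genes usually drop one or two at that gate
  (never downstream, and false positives are essentially absent). Exact
  recovery of large planted sets therefore requires deeper replication or
  a larger planted effect, not a different rule.
- The FDR estimator is a documented ratio-of-tails variant; numerical
  agreement with any specific external GSEA release is not claimed —
  internal consistency, determinism and oracle equivalence are the
  contracts. The weighted ES itself is cross-checked against an independent
  implementation in the test suite.
- Interferome-style lookups are closed-world over the supplied local table;
  curation differences across database versions are out of scope.
- Evidence integration is set-logical, as in the underlying workflow; no
  cross-assay meta-analytic weighting is attempted.
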