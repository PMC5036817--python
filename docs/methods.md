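# Methods

## Data model

A replicate-level panel holds one Cq value (or a missing marker) for every
(gene, sample, replicate) triple, plus one group label per sample. Cq is
the PCR cycle at which fluorescence crosses threshold; one cycle is one
doubling at perfect efficiency, so effects that are multiplicative on
transcript abundance are additive on the Cq scale. The pipeline assumes
the instrument's Cq values are already efficiency-corrected and therefore
uses a single amplification base for all assays (default 2.0,
configurable per run, not per gene).

Genes and samples are kept in sorted order, making a panel a pure
function of its set of reactions: file row order, and gene/sample
permutations generally, cannot change any result.

## QC: replicate aggregation and the exclusion rule

Replicates are collapsed by the arithmetic mean of the non-missing Cq
values — no outlier rejection, matching common analysis-software
behaviour. A gene × sample cell is *non-amplified* when all of its
replicates are missing. The default (`cell`) exclusion mode drops a gene
when any cell is non-amplified: one sample without signal makes the gene
unusable as a panel-wide reference, and every downstream statistic
requires a complete matrix. The stricter `replicate` mode drops a gene on
any single missing replicate. Replicate-level missing counts are reported
in either mode, because the reaction-failure rate is the interpretable QC
number. No Cq ceiling (e.g. Cq > 35) is applied by default.

## Relative quantities

With base b and per-gene anchor Cq:

    log2RQ(g, s) = log2(b) · (anchor_g − Cq(g, s))

The default anchor is the per-gene mean Cq, which centres each gene's
log2RQ at zero (geometric-mean-centred RQ); the `min` anchor scores
against the highest-expressing sample. The anchor only shifts each gene
by a constant, so every pairwise-ratio statistic (geNorm, ΔCt,
NormFinder after its centring step) is invariant to the choice; the
mean anchor is the default because it makes normalization-factor
centring (geometric mean of NF over samples = 1) an exact, testable
identity.

## Stability algorithms

**geNorm.** V_jk = SD over samples of (log2RQ_j − log2RQ_k), n−1
denominator; M_j = mean of V_jk over partners. The worst gene
(highest M) is eliminated and M recomputed until two genes remain; these
two are mutually unrankable by construction and are ordered by their
final-round M (ties by input order) so that rank aggregation has a total
order — a flag can instead hand both to the aggregator as tied rank 1.5.
Ties in M during elimination remove the gene later in input order, for
determinism. The V-curve uses normalization factors built from the final
ranking: NF_n = per-sample mean log2RQ of the top-n genes,
V(n/n+1) = SD over samples of (NF_n − NF_{n+1}); the recommended panel
size is the smallest n with V < 0.15. Default thresholds M < 0.5 and
V < 0.15 are the classical acceptability cut-offs.

**NormFinder-style model.** After removing each sample's across-gene
mean (which absorbs loading differences exactly), the group means of
gene i give raw intergroup deviations d_ig around the sample-size-
weighted gene mean (so Σ_g n_g·d_ig = 0; an `--unweighted` flag uses
equal group weights). Within-group variances are corrected for the
variance contributed by the panel mean, v̄_g/(k−1), and rescaled by
k/(k−2), floored at ε = 1e−12 to keep near-degenerate panels legal —
hence the k ≥ 3 requirement. The between-group variance of deviations,
γ̂² = max(0, Σ d²/(k(G−1)) − mean(σ̂²/n)), shrinks each deviation by
γ̂²/(γ̂² + σ̂²ᵢg/n_g), and the stability value is
ρᵢ = (1/G) Σ_g (|d̃ᵢg| + √(σ̂²ᵢg/n_g)); with a single group ρ reduces to
the corrected within-group SD. This is a reconstruction of the published
two-way decomposition with empirical-Bayes shrinkage; agreement with the
original spreadsheet tool is expected at the level of rankings, not
digits, and all tests of it are accordingly rank- or property-based.

An important, deliberate property: deviations are measured against the
panel average, so only group shifts *relative to the panel-mean shift*
are identifiable. If several candidate genes are regulated in the same
direction, every null gene acquires an apparent opposite deviation. The
ground-truth recovery tests therefore centre planted shifts across the
panel, and the candidate-recovery simulation uses an unregulated
candidate panel — the realistic situation, since RG candidates are by
construction genes not expected to respond to the condition. The
converse effect (biased references distorting target fold changes) is
asserted explicitly in the evaluation tests.

**BestKeeper.** Per-gene SD and CV% of raw Cq, and Pearson correlation
with the BestKeeper index (per-sample geometric mean of all candidates'
Cq; r is undefined for a constant gene). Ranking is by SD ascending with
CV% as tie-break; the classical SD ≤ 1 cycle acceptability flag is
reported but never removes genes, and r is reported but not ranked on.
Because it works on raw Cq, BestKeeper is intentionally *not* invariant
to per-sample loading offsets — the suite asserts this asymmetry against
the log-ratio methods.

**Comparative ΔCt.** Mean over partner genes of SD of pairwise Cq
differences. Algebraically this is the full-panel geNorm M under a
shared efficiency base; the implementation goes through the gene
covariance matrix (Var(x−y) = Var x + Var y − 2 Cov) while geNorm computes
each pair directly, and the suite checks the two routes agree to 1e−12.

**Aggregation.** Each method contributes ranks (midrank ties allowed);
the comprehensive score is the geometric mean of the four ranks, ordered
ascending with ties broken by best single-method rank, then input order.
Consensus sets are plain intersections of top-n lists across rankings.

## Normalization and group comparison

NF_s is the geometric mean of the reference genes' RQ in sample s;
NRQ(t, s) = RQ(t, s)/NF_s. Group differences in NRQ are tested per
target with the two-sided Mann–Whitney U test (U reported as
min(U_A, U_B); exact null distribution when the combined n ≤ 16 with no
ties, otherwise normal approximation with tie and continuity
corrections, via scipy). Fold change is the ratio of group medians
(means by flag), matching the nonparametric test; significance is
annotated at 0.05 and 0.01. No multiple-testing correction is applied by
default — evaluations involve a handful of targets with per-gene
reporting — but a Bonferroni flag exists.

## Synthetic data

Cq(g, s, r) = B_g + L_s + Δ_g·[group(s) = test] + ε_gs + τ_gsr, with
baseline B_g ~ U(18, 32) cycles, loading L_s ~ N(0, 0.5), biological
noise ε ~ N(0, σ_g) (designed-stable genes σ ∈ [0.1, 0.25], unstable
[0.5, 2.0]), group shift Δ_g (0 for designed-stable genes; negative Δ =
up-regulation), and technical replicate noise τ ~ N(0, 0.1). Values are
floored at 1 cycle. Dropout is planted deterministically for a seed:
affected genes receive fixed replicate-failure counts, placed by default
in the highest-Cq cells first (detection-limit censoring; a uniform
random mode exists), with at least one fully-missing cell per affected
gene guaranteed when requested. The ground-truth record (per-gene
parameters, loading draws, dropout cells) suffices to reconstruct the
noise-free panel exactly.

The fixed study-scale scenario has 112 genes × 47 samples (23 control +
24 infected) × 3 replicates = 15 792 reactions with exactly 1516 planted
failures spread over 41 high-Cq filler genes, leaving 71 complete genes.
It embeds a ten-gene designed-stable block (including *Il2rg*, *Itgb2*,
*Myd88*, *Stat6*, *Hprt*), five classical RG candidates with poor-to-
moderate stability (*Ubc*, *B2m*, *Polr2a*, *Tbp*, *Pgk1*), and three
infected-up-regulated targets (*Cxcl10* −2.8, *Ifng* −2.2, *Tnf* −1.8
cycles). The bookkeeping counts are structural, so they hold for any
seed.

What the generator does **not** emulate: gene-specific amplification
efficiencies, correlated biological noise between genes (all ε are
independent), non-Gaussian heavy-tailed Cq error, plate/batch effects
beyond the scalar loading offset, and dropout that is probabilistic in
the signal level rather than planted by count. Passing tests therefore
demonstrate correctness of the algorithms and recoverability under the
assumed additive model, not robustness to those real-data features.

## Numerical choices and edge cases

- SDs and variances use the n−1 denominator throughout.
- Pairwise variances from the covariance route are clipped at 0 before
  the square root; exact zeros from the direct route may differ by ~1e−9
  in degenerate (constant-difference) panels.
- NormFinder's variance floor ε = 1e−12; γ̂² clipped at 0.
- geNorm elimination ties: later input order removed first; aggregation
  ties: best single rank, then input order. All procedures are exactly
  reproducible for a given input and seed.
- Degenerate inputs fail loudly: < 3 genes (geNorm ranking, NormFinder),
  < 2 samples, any group with < 2 samples, empty comparison groups,
  all-genes-excluded QC.

## Problem sizes in the test suite

Simulation-based checks run at the sizes their claims need and no more:
the candidate-recovery study uses 100 panels of 30 genes × 48 samples,
NormFinder's rank-recovery uses one 15-gene × 400-sample panel, and
type-I error control uses 200 three-gene × 40-sample replicates. The
whole suite completes in well under a minute on a single core.
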