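# Methods

## Model and parameterizations

`adigen` decomposes the genetic value of a biallelic locus with known
parental origin into additive, dominance, and imprinting parts. Writing
the four ordered genotypes (paternal allele first) as ref|ref, ref|alt,
alt|ref, alt|alt, the *genotypic* coding assigns additive scores
Z = (0, 1, 1, 2), dominance scores H = (0, 1, 1, 0), and imprinting
scores S = (0, −1, +1, 0). S contrasts the two heterozygote
configurations, so a positive imprinting effect means the
paternal-alt/maternal-ref heterozygote has the higher value. Two further
codings are provided: *centered* (the genotypic codes shifted to mean
zero under Hardy–Weinberg proportions) and *noia* (the
natural-and-orthogonal-interactions codes, whose additive/breeding-value
and dominance-deviation scores are uncorrelated at a locus in exact HW
proportions). All three share the same imprinting code, and per-locus
constants are absorbed by the model intercept.

Individual-level genetic values are treated as Gaussian random effects
with covariances given by genomic relationship matrices (GRMs) pooled
over markers: the standard allele-frequency-centered additive matrix A
(`(Z−2p)` cross products over `Σ2pq`), the genotypic dominance matrix D
(`(H−2pq)` over `Σ2pq(1−2pq)`), the imprinting matrix P (raw S over
`Σ2pq`), and the dominance-deviation matrix D* (NOIA codes over
`Σ(2pq)²`). {A, D, P} parameterize the genotypic decomposition and
{A, D*, P} the classical breeding-value/dominance-deviation one. Markers
are filtered to MAF ≥ 0.01 (and, for association work, Hardy–Weinberg
chi-square p ≥ 1e−6, one degree of freedom on unordered counts, no
continuity correction) before GRMs are built; allele frequencies come
from all genotyped individuals in the loaded dataset.

## REML estimation

Variance components are estimated by average-information (AI) REML.
Per iteration the code forms V = Σσ²cGc + σ²eI, its Cholesky inverse,
and the projection P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹; scores are
−½(tr(PGc) − yᵀPGcPy) (traces via elementwise products, never matrix
products) and the AI matrix is ½·wᵢᵀPwⱼ with wᵢ = GᵢPy, so each
iteration costs one n³ inverse plus O(n²) extras.

Step control matters more than textbook presentations suggest: with
three GRMs that are nearly exchangeable at small n, plain AI steps can
cycle indefinitely between overshoot and recovery, and a likelihood
surface with a long flat ridge can fool a likelihood-change stopping
rule. The scheme used here is monotone ascent over a candidate list: an
active-set AI step (components at the zero boundary with outward
gradient are pinned and leave the AI system) truncated at the boundary
along its direction; the same AI step with violating components clamped
to zero (the only move that can lift the remaining components when the
truncated step degenerates to a no-op), also at fractions ½, ¼, 1/10;
then an EM step. No-op candidates are discarded and the first candidate
that does not decrease the restricted likelihood — checked with a
Cholesky-only evaluation — is accepted; EM is non-decreasing, so
progress is guaranteed, and the first iteration is always EM.
Convergence requires both a relative likelihood change below 1e−8 *and*
a near-zero scaled score for every free component — the second condition
protects against declaring victory after two consecutively tiny fallback
steps on a ridge (cap 200 iterations; non-convergence is flagged, never
silent). Variances are constrained to ≥ 1e−8 of the phenotypic
variance. Starting values: each genetic component at Vp/(2g), residual
at Vp/2.

Standard errors come from the inverse AI matrix at the optimum,
proportion standard errors by the delta method with the full AI
covariance. BLUPs are σ̂²c·Gc·V̂⁻¹(y − Xb̂), and the residual BLUP
σ̂²e·V̂⁻¹(y − Xb̂), so the components and residual reconstruct y exactly.
The reported log-likelihood includes its constants (and a −log|XᵀX|
term) so that it equals the error-contrast (null-space projection)
formula in `direct_loglik`, which serves as an independent oracle.

Testing σ²c = 0 uses the boundary-corrected likelihood-ratio test: under
the null the parameter sits on the boundary of its space, so LR is
compared to the ½χ²₀ + ½χ²₁ mixture (p = ½·Pr(χ²₁ > LR), p = ½ at
LR = 0). A one-sided Wald test is provided for comparison; the LRT is
the default.

## Equivalence of the two decompositions

The genotypic {A, D, P} and breeding-value {A, D*, P} models satisfy an
exact per-locus identity: the NOIA dominance code equals the centered
genotypic dominance code plus (p − q) times the centered additive code.
Consequently individual imprinting values — and, in the fits, the
imprinting variance *proportion* — agree essentially exactly (observed
differences ~1e−11). Total genetic values, H², and residuals agree only
asymptotically: D* contains additive×dominance cross terms of relative
size O(1/√m), and the two models' fitted variance splits differ by the
REML sampling noise at finite n. At this package's desk scales
(n ≤ 2000, m ≤ 5000) the H² difference is of order 1e−2 and
per-individual differences of order 1e−1; both shrink as n and m grow
toward the population scale (tens of thousands of individuals, 50k
markers) where near-exact agreement is observed. `compare_decompositions`
reports all four discrepancies so users can judge the regime they are in.

## Synthetic populations

The generator emulates a dairy genomic-evaluation regime: paternal
half-sib families (default 20 daughters per sire) with a fraction of
full-sib litters (default 20% of matings produce 2 daughters — full sibs
are the main source of dominance/imprinting relationships, without which
those components are barely estimable), genotyped sires and dams, and
phenotypes on daughters only. Founder haplotype alleles are independent
Bernoulli draws with per-locus alt frequency from U(0.05, 0.95); an
optional first-order Markov copy process (`ld_rho`) adds local haplotype
correlation for association-peak realism, off by default since the GRM
theory assumes linkage equilibrium. Offspring arise by gene drop with
independent Mendelian transmission per locus, and the true parental
origin of every allele is recorded as the phase.

Traits are built from QTLs sampled without replacement per effect class,
standard-normal effects, and genetic-value vectors rescaled so each
class's sample variance hits its target fraction of a unit total
phenotypic variance exactly (the residual takes the remainder). Preset
scenarios mimic a moderate-heritability production trait
("milk": 0.338/0.040/0.008 additive/dominance/imprinting) and a
low-heritability fertility trait ("dpr": 0.044/0.011/0.015), each with
1000 additive and 10, 100, or 1000 dominance and imprinting QTLs.

What the simulator deliberately omits: linkage disequilibrium and
realistic genome structure, selection, assortative mating, inbreeding,
genotyping error, and multi-generation pedigrees. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to the full messiness of real
dairy data.

## Association scans

The two-step (GRAMMAR-style) scan fits the polygenic three-component
model once and regresses its residuals on each SNP's (Z, H, S) codes by
OLS with t-tests; constant or collinear code columns make the affected
effect untestable (reported as missing) rather than failing. This is
fast but conservative: residuals are shrunk by V̂⁻¹, and a causal SNP's
own contribution is partially absorbed by the GRMs (proximal
contamination), so two-step p-values at true QTLs are attenuated —
the reason the one-step mixed-model test (GLS on the raw phenotype with
null-model variance components held fixed; Wald tests) is provided for
re-testing candidates, and the reason leave-one-chromosome-out GRMs
(`loco_grm`) are offered for validation designs. Conditional scans add
chosen variants' additive (optionally plus dominance) codes as fixed
covariates. The genome-wide significance default is 1e−6; a Bonferroni
column is emitted for convenience but no further correction is applied.

## Prediction

Genetic values of unphenotyped individuals are predicted per component as
G_{n×t}·G_{t×t}⁻¹·û_t and summed over the model's components (the
printed form of the imprinting term in the source equation reads
P_{n×t}·P⁻¹_{n×t}, which has no meaning for a rectangular matrix; it is
read as P⁻¹_{t×t}, parallel to the additive and dominance terms).
Singular training blocks fall back to a pseudo-inverse with the
condition number logged; an explicit diagonal ridge is available but off
by default. k-fold cross-validation builds each GRM once on all
phenotyped individuals (frequencies from the full dataset) and slices
fold blocks from it; variance components are re-estimated per training
split by default (a whole-data-reuse mode exists). Reported metrics
follow the field: accuracy = Pearson correlation of prediction with
phenotype, unbiasedness = regression slope of phenotype on prediction;
model pairs sharing folds are compared with paired t-tests. Note that
the paired t-test resolves accuracy differences of a few thousandths:
fitting unneeded components costs a small, fold-consistent accuracy
penalty that such a test can flag as "significant" even when the models
are practically equivalent.

## Problem sizes and validation design

The validation suite runs desk-scale versions of the study design:
variance-recovery suites at n = 1500 daughters, m = 2000 markers, 20
replicates per scenario (means compared with simulated truth within two
empirical standard errors); the GWAS calibration/power suite at
n = 2000, m = 2500, 20 replicates; cross-validation comparisons at
n = 1500, k = 10. The acceptance script runs the two central scenarios
at n = 2000, m = 5000 with 20 replicates. These sizes were chosen so the
whole suite completes on a single CPU in well under half an hour;
anything larger (including the source study's n = 10,000 × 100
replicates) is reachable through `SimulationConfig`/`run_scenario`
arguments.

Known limitations, beyond the simulator scope above: constrained REML
estimates of variance fractions near zero are right-skewed (boundary
truncation), so replicate means of tiny components (e.g. an imprinting
fraction of 0.008) carry an upward finite-sample bias that shrinks with
n; a related leakage effect inflates the imprinting fraction when the
additive architecture is sparse relative to the marker panel — the
mismatch between the causal-locus covariance and the all-marker A matrix
is partly absorbed by the P component (measured: ~+0.012 of phenotypic
variance at n = 2000 with 1000 causal loci among 2000 markers, ~+0.001
when every marker is causal), again vanishing at population scale; two-step scan power at desk scale is materially below what its
non-centrality alone would suggest (see the attenuation discussion
above); and cross-validated gains from dominance components in half-sib
populations are fractions of a percent, at the edge of what 10-fold CV
can resolve.
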