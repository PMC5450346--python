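# adigen

Dissecting complex traits into **additive**, **dominance**, and
**parent-of-origin (imprinting)** components from phased SNP genotypes —
variance decomposition, association scans, and genomic prediction, with a
built-in simulator of dairy-style trio populations so the entire pipeline
runs and validates itself without external data.

The package is aimed at quantitative geneticists working with pedigreed,
genotyped populations (dairy cattle being the motivating case: genotyped
sire–dam–daughter trios with yield-deviation phenotypes) who want to ask
how much phenotypic variance non-additive effects explain, whether
individual QTLs act through dominance or imprinting, and whether modeling
those effects improves genomic selection.

## The model

With phase known, each biallelic genotype falls in one of four ordered
classes (paternal allele first): `ref|ref`, `ref|alt`, `alt|ref`,
`alt|alt`. Their genetic values decompose as

```
G = R + a·(0,1,1,2) + d·(0,1,1,0) + i·(0,−1,+1,0)
```

so the imprinting effect *i* is the contrast between the two heterozygote
configurations — the quantity that is invisible without parent-of-origin
information. Per-individual genetic values are modeled as random effects,

```
y = Xb + a + d + i + e,
a ~ N(0, σ²ₐ A),  d ~ N(0, σ²_d D),  i ~ N(0, σ²_p P),  e ~ N(0, σ²ₑ I),
```

with genomic relationship matrices pooled over markers (p = alt frequency,
q = 1 − p):

* `A_ij = Σ_k (Z_ik − 2p_k)(Z_jk − 2p_k) / Σ_k 2p_k q_k`
* `D_ij = Σ_k (H_ik − 2p_k q_k)(H_jk − 2p_k q_k) / Σ_k 2p_k q_k (1 − 2p_k q_k)`
* `P_ij = Σ_k S_ik S_jk / Σ_k 2p_k q_k`
* `D*_ij = Σ_k H*_ik H*_jk / Σ_k (2p_k q_k)²` — the dominance-deviation
  (NOIA) alternative, for the classical breeding-value decomposition

where Z, H, S are the additive/dominance/imprinting codes above and H* the
orthogonal dominance-deviation code. Variance components are estimated by
average-information REML with EM fallback and non-negativity constraints;
components are tested against zero with the boundary-corrected
likelihood-ratio test (½χ²₀ + ½χ²₁). Association scans use a two-step
GRAMMAR-style residual regression (with mixed-model re-testing of
candidates), and prediction of new individuals follows
`ĝ_n = A_nt A_tt⁻¹ â_t + D_nt D_tt⁻¹ d̂_t + P_nt P_tt⁻¹ î_t`.

## Worked example

```python
import numpy as np
from adigen import (SimulationConfig, simulate_dataset, allele_freq,
                    code_genotypes, build_grms, fit_greml)

# milk-like trait: 33.8% additive, 4% dominance, 0.8% imprinting variance
cfg = SimulationConfig(n_individuals=1500, n_markers=2500,
                       n_qtl=(1000, 100, 100),
                       target_fractions=(0.338, 0.040, 0.008), seed=7)
ds = simulate_dataset(cfg)

cows = ds.genotypes.subset_samples(ds.phenotypes.ids)
p = allele_freq(cows)
cows = cows.subset_variants(np.minimum(p, 1 - p) >= 0.01)   # MAF filter
coded = code_genotypes(cows, "genotypic")
grms = build_grms(coded, ("A", "D", "P"))
y, X = ds.phenotypes.design()
fit = fit_greml(y, X, grms)
print(fit.summary().round(4).to_string(index=False))
print(f"H2 = {fit.H2:.3f}  h2 = {fit.h2:.3f}  ({fit.n_iter} iterations)")
```

Output:

```
component  sigma2  se_sigma2  proportion  se_proportion
        A  0.4271     0.0614      0.4080         0.0501
        D  0.0679     0.0485      0.0648         0.0462
        P  0.0152     0.0448      0.0145         0.0427
        e  0.5367     0.0580      0.5127         0.0603
H2 = 0.487  h2 = 0.408  (7 iterations)
```

Each fitted proportion sits within two standard errors of its simulated
fraction (0.338 / 0.040 / 0.008) — one dataset at n=1500 carries
substantial sampling noise, which is why the validation suite averages
over 20 replicates. `fit.blups` holds per-cow estimates of each
component. The same objects feed `two_step_scan` (per-SNP
additive/dominance/imprinting tests on the polygenic residuals),
`conditional_scan`, `cross_validate` (10-fold genomic prediction with
accuracy and bias per fold), and `compare_models` (paired t-tests between
ADD, ADD+DOM, ADD+DOM+IMP).

A `adigen` command-line interface orchestrates the same stages from a YAML
config (`adigen simulate|grm|reml|gwas|predict|all --config run.yaml`),
writing TSV artifacts and JSON manifests for reproducible runs.

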