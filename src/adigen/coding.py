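"""Genotype design codes for additive, dominance, and imprinting effects.

Three parameterizations of the four ordered genotype classes
(ref|ref, ref|alt, alt|ref, alt|alt), writing ``p`` for the alt-allele
frequency and ``q = 1 - p``:

``genotypic``
    additive Z = (0, 1, 1, 2), dominance H = (0, 1, 1, 0),
    imprinting S = (0, -1, +1, 0).  The raw biological coding: Z counts
    alt alleles, H flags heterozygotes, and S contrasts the two
    heterozygote configurations (paternal-alt minus maternal-alt).
``centered``
    additive (-2p, q-p, q-p, 2q), dominance (-2pq, 1-2pq, 1-2pq, -2pq);
    the genotypic codes centered to mean zero under Hardy-Weinberg
    proportions.  Additive and dominance codes remain correlated.
``noia``
    additive (-2p, q-p, q-p, 2q), dominance (-2p^2, 2pq, 2pq, -2q^2);
    the natural-and-orthogonal-interactions parameterization whose
    additive (breeding value) and dominance-deviation codes are
    uncorrelated at a locus in exact Hardy-Weinberg proportions.

The imprinting code S is the same in all three schemes, and the overall
per-class constant (the locus mean) is absorbed by the model intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import PhasedGenotypeMatrix

SCHEMES = ("genotypic", "centered", "noia")

#: imprinting codes per ordered class, identical across schemes
IMPRINTING_CODES = (0.0, -1.0, 1.0, 0.0)


@dataclass(frozen=True)
class CodingScheme:
    """Per-class additive/dominance/imprinting codes as functions of p.

    ``additive_codes(p)`` etc. return a (4, m) array for an m-vector p,
    rows ordered (ref|ref, ref|alt, alt|ref, alt|alt).  The per-locus
    constant term (overall mean) is absorbed by the model intercept.
    """

    name: str

    def __post_init__(self):
        if self.name not in SCHEMES:
            raise ValueError(f"unknown coding scheme {self.name!r}; choose from {SCHEMES}")

    def additive_codes(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        q = 1.0 - p
        if self.name == "genotypic":
            return np.stack([np.zeros_like(p), np.ones_like(p), np.ones_like(p), 2 * np.ones_like(p)])
        return np.stack([-2 * p, q - p, q - p, 2 * q])

    def dominance_codes(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        q = 1.0 - p
        if self.name == "genotypic":
            return np.stack([np.zeros_like(p), np.ones_like(p), np.ones_like(p), np.zeros_like(p)])
        if self.name == "centered":
            pq2 = 2 * p * q
            return np.stack([-pq2, 1 - pq2, 1 - pq2, -pq2])
        return np.stack([-2 * p**2, 2 * p * q, 2 * p * q, -2 * q**2])

    def imprinting_codes(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return np.stack([np.full_like(p, c) for c in IMPRINTING_CODES])


@dataclass
class CodedMatrix:
    """Design codes Z (additive), H (dominance), S (imprinting) for n x m genotypes."""

    Z: np.ndarray
    H: np.ndarray
    S: np.ndarray
    p: np.ndarray  # alt-allele frequency per variant
    scheme: str
    sample_ids: list[str] = field(default_factory=list)
    variants: "object" = None  # pandas DataFrame, optional annotation

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_variants(self) -> int:
        return self.Z.shape[1]


def allele_freq(gm: PhasedGenotypeMatrix) -> np.ndarray:
    """Alt-allele ('allele 2') frequency p_k = alt count / 2n per variant.

    Requires a fully observed matrix (run :func:`adigen.io.fill_missing_hwe`
    first).
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if gm.any_missing():
        raise ValueError(
            "missing genotypes present; run adigen.io.fill_missing_hwe first"
        )
    return (gm.paternal.sum(axis=0) + gm.maternal.sum(axis=0)) / (2.0 * gm.n_samples)


def code_genotypes(
    gm: PhasedGenotypeMatrix,
    scheme: str | CodingScheme = "genotypic",
    p: np.ndarray | None = None,
) -> CodedMatrix:
    """Map ordered genotypes to (Z, H, S) design codes under ``scheme``.

    ``p`` may be supplied to reuse frequencies estimated on a larger
    reference set (e.g. when coding a subset of individuals); by default it
    is computed from ``gm`` itself.
    """
    if isinstance(scheme, str):
        scheme = CodingScheme(scheme)
    if p is None:
        p = allele_freq(gm)
    else:
        p = np.asarray(p, dtype=float)
        if p.shape != (gm.n_variants,):
            raise ValueError("p has wrong length")
    if gm.any_missing():
        raise ValueError(
            "missing genotypes present; run adigen.io.fill_missing_hwe first"
        )
    cls = gm.genotype_class()  # (n, m) in {0,1,2,3}
    cols = np.arange(gm.n_variants)
    if scheme.name == "genotypic":
        Z = (gm.paternal + gm.maternal).astype(float)
        H = ((cls == 1) | (cls == 2)).astype(float)
    else:
        Z = scheme.additive_codes(p)[cls, cols]
        H = scheme.dominance_codes(p)[cls, cols]
    S = np.zeros(cls.shape)
    S[cls == 1] = -1.0
    S[cls == 2] = 1.0
    return CodedMatrix(
        Z=Z, H=H, S=S, p=p, scheme=scheme.name,
        sample_ids=list(gm.sample_ids), variants=gm.variants,
    )


def hwe_chisq_pvalues(gm: PhasedGenotypeMatrix) -> np.ndarray:
    """One-degree-of-freedom chi-square Hardy-Weinberg test p-value per variant.

    Unordered genotype counts are used (the two heterozygote configurations
    are pooled); no continuity correction.  Monomorphic variants return
    p = 1 (no departure is testable).
    """
    cls = gm.genotype_class()
    if np.any(cls < 0):
        raise ValueError("missing genotypes present; fill or drop them first")
    n = gm.n_samples
    n_hom_ref = (cls == 0).sum(axis=0)
    n_het = ((cls == 1) | (cls == 2)).sum(axis=0)
    n_hom_alt = (cls == 3).sum(axis=0)
    p = (n_het + 2 * n_hom_alt) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.stack([n_hom_ref, n_het, n_hom_alt]).astype(float)
    poly = (p > 0) & (p < 1)
    chi2 = np.zeros(gm.n_variants)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs - exp) ** 2 / exp
    chi2[poly] = contrib[:, poly].sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[~poly] = 1.0
    return pvals


def filter_variants(
    gm: PhasedGenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> np.ndarray:
    """Boolean mask of variants passing MAF and Hardy-Weinberg filters.

    A variant is kept iff min(p, 1-p) >= ``maf_min`` and the 1-df
    chi-square HWE p-value >= ``hwe_p_min``.  Monomorphic variants are
    always excluded (their codes are degenerate).
    """
    p = allele_freq(gm)
    maf = np.minimum(p, 1.0 - p)
    mask = maf >= max(maf_min, np.finfo(float).tiny)
    mask &= hwe_chisq_pvalues(gm) >= hwe_p_min
    return mask
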