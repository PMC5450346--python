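"""In-memory containers for phased genotypes, pedigrees, and phenotypes.

The central object is :class:`PhasedGenotypeMatrix`, which stores, for each
individual and biallelic SNP, the paternal and the maternal allele
separately.  Knowing which parent transmitted which allele is what makes
parent-of-origin (imprinting) analysis possible: the two heterozygote
configurations
``ref|alt`` (paternal ref, maternal alt) and ``alt|ref`` are kept distinct.

Allele coding: 0 = reference allele, 1 = alternate allele, -1 = missing.
The four ordered genotype classes are indexed ``2*paternal + maternal``:

====== ================ =======================
index  ordered genotype  description
====== ================ =======================
0      ref|ref           homozygous reference
1      ref|alt           het, maternal alt
2      alt|ref           het, paternal alt
3      alt|alt           homozygous alternate
====== ================ =======================

A heterozygote whose parental origin could not be determined is stored with
both alleles set to missing and flagged in ``unphased_het``; its allele
*dosage* is still known (1) even though its phase is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: column order of the variant table
VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


def variant_table(records: Sequence[tuple]) -> pd.DataFrame:
    """Build a variant annotation table from (chrom, pos, id, ref, alt) tuples."""
    df = pd.DataFrame(list(records), columns=list(VARIANT_COLUMNS))
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class PhasedGenotypeMatrix:
    """Ordered (parent-of-origin aware) genotypes for n individuals x m SNPs.

    Parameters
    ----------
    paternal, maternal
        ``(n, m)`` int8 arrays over {0, 1, -1}; -1 marks a missing allele.
    sample_ids
        Individual identifiers, length n, unique.
    variants
        DataFrame with columns chrom, pos, id, ref, alt; positions must be
        strictly increasing within each chromosome.
    unphased_het
        Optional ``(n, m)`` boolean mask marking heterozygotes of unknown
        phase (their alleles are stored as missing but dosage is 1).
    """

    paternal: np.ndarray
    maternal: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame
    unphased_het: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        if self.paternal.shape != self.maternal.shape or self.paternal.ndim != 2:
            raise ValueError("paternal and maternal arrays must share an (n, m) shape")
        n, m = self.paternal.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one variant")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match genotype columns")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        if self.unphased_het is None:
            self.unphased_het = np.zeros((n, m), dtype=bool)
        else:
            self.unphased_het = np.asarray(self.unphased_het, dtype=bool)
            if self.unphased_het.shape != (n, m):
                raise ValueError("unphased_het mask has wrong shape")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.paternal.shape[0]

    @property
    def n_variants(self) -> int:
        return self.paternal.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.paternal.shape

    # -- derived views ---------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) as float, NaN where unknown.

        Phase-unknown heterozygotes have known dosage 1.
        """
        d = (self.paternal + self.maternal).astype(float)
        d[(self.paternal == MISSING) | (self.maternal == MISSING)] = np.nan
        d[self.unphased_het] = 1.0
        return d

    def genotype_class(self) -> np.ndarray:
        """Ordered genotype class 2*paternal + maternal; -1 where phase/allele unknown."""
        cls = (2 * self.paternal + self.maternal).astype(np.int8)
        cls[(self.paternal == MISSING) | (self.maternal == MISSING)] = MISSING
        return cls

    def any_missing(self) -> bool:
        return bool(
            np.any(self.paternal == MISSING) or np.any(self.maternal == MISSING)
        )

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, ids: Sequence[str]) -> "PhasedGenotypeMatrix":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:10]}")
        rows = np.array([index[s] for s in ids])
        return replace(
            self,
            paternal=self.paternal[rows],
            maternal=self.maternal[rows],
            sample_ids=list(ids),
            variants=self.variants,
            unphased_het=self.unphased_het[rows],
        )

    def subset_variants(self, mask: np.ndarray) -> "PhasedGenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return replace(
            self,
            paternal=self.paternal[:, cols],
            maternal=self.maternal[:, cols],
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[cols].reset_index(drop=True),
            unphased_het=self.unphased_het[:, cols],
        )


@dataclass
class Pedigree:
    """Three-column pedigree: individual, sire, dam ("0" = unknown parent)."""

    records: pd.DataFrame  # columns: id, sire, dam

    UNKNOWN = "0"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        df.columns = ["id", "sire", "dam"]
        df = df.astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate pedigree ids: {dup[:10]}")
        self.records = df.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {
            r.id: [p for p in (r.sire, r.dam) if p != self.UNKNOWN]
            for r in self.records.itertuples()
        }
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in parent:
            if start in state:
                continue
            stack = [(start, iter(parent[start]))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if nxt not in parent:
                        continue
                    if state.get(nxt) == 0:
                        raise ValueError(f"pedigree cycle involving {nxt}")
                    if nxt not in state:
                        state[nxt] = 0
                        stack.append((nxt, iter(parent[nxt])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()

    def trios(self) -> pd.DataFrame:
        """Rows where both parents are known."""
        r = self.records
        return r[(r["sire"] != self.UNKNOWN) & (r["dam"] != self.UNKNOWN)]

    def founders(self) -> list[str]:
        r = self.records
        return r.loc[
            (r["sire"] == self.UNKNOWN) & (r["dam"] == self.UNKNOWN), "id"
        ].tolist()


@dataclass
class PhenotypeTable:
    """Per-individual adjusted phenotypes (e.g. yield deviations) plus covariates."""

    values: pd.Series  # index: individual id, float values (NaN = missing)
    trait_name: str = "trait"
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.astype(str)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate ids in phenotype table")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            self.covariates.index = self.covariates.index.astype(str)
            if not self.covariates.index.equals(self.values.index):
                self.covariates = self.covariates.reindex(self.values.index)

    @property
    def ids(self) -> list[str]:
        return self.values.index.tolist()

    def complete_cases(self) -> "PhenotypeTable":
        keep = self.values.notna()
        cov = self.covariates.loc[keep] if self.covariates is not None else None
        return PhenotypeTable(self.values[keep], self.trait_name, cov)

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (y, X) over complete cases; X is intercept plus covariates."""
        cc = self.complete_cases()
        y = cc.values.to_numpy()
        n = len(y)
        if cc.covariates is None or cc.covariates.shape[1] == 0:
            X = np.ones((n, 1))
        else:
            X = np.column_stack([np.ones(n), cc.covariates.to_numpy(dtype=float)])
        return y, X
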