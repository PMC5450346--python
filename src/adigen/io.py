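"""File input/output and parent-of-origin phasing.

File conventions
----------------
* **Phased VCF 4.2**: GT written with ``|`` for phased entries; by package
  convention the **first allele is the paternal one** (declared in the
  header we write).  Unphased heterozygotes (``0/1``) are loaded as
  phase-missing, not dropped.
* **Pedigree**: whitespace-separated, three columns ``id sire dam`` with
  ``0`` for an unknown parent.
* **Phenotypes**: TSV with a header; first column ``id``, then one column
  per trait, optionally followed by covariate columns.

Phasing of a daughter's genotype uses her parents' genotypes: homozygotes
are trivially phased and a heterozygote is resolved whenever at least one
parent is homozygous (Mendelian transmission then forces the origin of each
allele).  Mendelian-inconsistent entries are set to missing and counted
rather than raised, matching routine genotype QC practice.  Entries that
remain missing (or phase-unresolved) afterwards can be filled by sampling
ordered genotypes from their Hardy-Weinberg multinomial distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, Pedigree, PhasedGenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

PATERNAL_FIRST_HEADER = (
    "##phasing=partial\n"
    '##adigen_phase_convention="first allele listed in GT is the paternal allele"\n'
)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> PhasedGenotypeMatrix:
    """Load a biallelic, (partially) phased VCF into a PhasedGenotypeMatrix.

    Phased GT entries (``a|b``) are interpreted paternal-first.  Unphased
    heterozygotes are flagged as phase-missing; unphased homozygotes are
    unambiguous and stored as phased.  Multiallelic sites raise an error
    naming the variant.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pat_cols: list[np.ndarray] = []
    mat_cols: list[np.ndarray] = []
    unph_cols: list[np.ndarray] = []
    records: list[tuple] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic or non-biallelic site {v.CHROM}:{v.POS} "
                f"({v.ID or '.'}: ALT={v.ALT}); split or drop it first"
            )
        gts = v.genotypes  # list of [allele0, allele1, phased]
        n = len(gts)
        pat = np.empty(n, dtype=np.int8)
        mat = np.empty(n, dtype=np.int8)
        unph = np.zeros(n, dtype=bool)
        for i, (a0, a1, phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                pat[i] = mat[i] = MISSING
            elif phased or a0 == a1:
                pat[i], mat[i] = a0, a1
            else:  # unphased heterozygote: dosage known, origin unknown
                pat[i] = mat[i] = MISSING
                unph[i] = True
        pat_cols.append(pat)
        mat_cols.append(mat)
        unph_cols.append(unph)
        records.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
    vcf.close()
    if not records:
        raise ValueError(f"no variants in {path}")
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    return PhasedGenotypeMatrix(
        paternal=np.column_stack(pat_cols),
        maternal=np.column_stack(mat_cols),
        sample_ids=samples,
        variants=variants,
        unphased_het=np.column_stack(unph_cols),
    )


def write_vcf(gm: PhasedGenotypeMatrix, path: str | Path) -> None:
    """Write a PhasedGenotypeMatrix as an uncompressed VCF 4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(PATERNAL_FIRST_HEADER)
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        pat, mat, unph = gm.paternal, gm.maternal, gm.unphased_het
        for k, var in enumerate(gm.variants.itertuples(index=False)):
            cells = []
            for i in range(gm.n_samples):
                if unph[i, k]:
                    cells.append("0/1")
                elif pat[i, k] == MISSING or mat[i, k] == MISSING:
                    cells.append("./.")
                else:
                    cells.append(f"{pat[i, k]}|{mat[i, k]}")
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                "\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigree and phenotypes
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str,
        names=["id", "sire", "dam"],
    )
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.records.to_csv(path, sep=" ", header=False, index=False)


def read_phenotypes(
    path: str | Path,
    trait: str | None = None,
    covariate_columns: list[str] | None = None,
) -> PhenotypeTable:
    """Read a TSV phenotype file (id column first) into a PhenotypeTable.

    When ``trait`` is None the first non-id column is used.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if trait is None:
        candidates = [c for c in df.columns if c not in (covariate_columns or [])]
        if not candidates:
            raise ValueError(f"no trait column found in {path}")
        trait = candidates[0]
    if trait not in df.columns:
        raise KeyError(f"trait column {trait!r} not in {path}")
    cov = df[covariate_columns].astype(float) if covariate_columns else None
    return PhenotypeTable(df[trait].astype(float), trait_name=trait, covariates=cov)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.values.rename(pheno.trait_name).to_frame()
    if pheno.covariates is not None:
        df = df.join(pheno.covariates)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def load_dataset(
    vcf_path: str | Path,
    ped_path: str | Path,
    pheno_path: str | Path,
    trait: str | None = None,
    covariate_columns: list[str] | None = None,
) -> tuple[PhasedGenotypeMatrix, Pedigree, PhenotypeTable]:
    """Load and cross-align the genotype / pedigree / phenotype trio.

    Every pedigree individual and every phenotyped individual must be
    genotyped; offenders are listed in the error.  Parents recorded as "0"
    (unknown) are exempt.
    """
    gm = read_vcf(vcf_path)
    ped = read_pedigree(ped_path)
    pheno = read_phenotypes(pheno_path, trait=trait, covariate_columns=covariate_columns)
    genotyped = set(gm.sample_ids)
    bad_ped = [i for i in ped.ids if i not in genotyped]
    if bad_ped:
        raise ValueError(
            f"pedigree individuals without genotypes: {bad_ped[:10]}"
            + (" ..." if len(bad_ped) > 10 else "")
        )
    bad_ph = [i for i in pheno.ids if i not in genotyped]
    if bad_ph:
        raise ValueError(
            f"phenotyped individuals without genotypes: {bad_ph[:10]}"
            + (" ..." if len(bad_ph) > 10 else "")
        )
    return gm, ped, pheno


# ---------------------------------------------------------------------------
# Trio phasing
# ---------------------------------------------------------------------------

@dataclass
class TrioPhaseResult:
    paternal: np.ndarray
    maternal: np.ndarray
    unresolved: np.ndarray  # heterozygous, phase not determined
    n_mendel_errors: int


def trio_phase(
    child: np.ndarray, sire: np.ndarray, dam: np.ndarray
) -> TrioPhaseResult:
    """Phase a child's genotype dosages (0/1/2/-1) using parent dosages.

    Homozygotes are always phased.  A heterozygote is phased when exactly
    one transmission pattern is Mendelian-consistent (which requires at
    least one homozygous parent); when both patterns are consistent it is
    left unresolved.  Mendelian-impossible entries become missing and are
    counted.  A missing parent genotype is treated as able to transmit
    either allele.
    """
    child = np.asarray(child)
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    if not (child.shape == sire.shape == dam.shape):
        raise ValueError("child, sire and dam vectors must have equal length")
    m = child.shape[0]
    pat = np.full(m, MISSING, dtype=np.int8)
    mat = np.full(m, MISSING, dtype=np.int8)
    unresolved = np.zeros(m, dtype=bool)

    def can_give(parent: np.ndarray, allele: int) -> np.ndarray:
        # parent dosage can transmit `allele`? missing parent -> yes
        if allele == 0:
            return (parent == 0) | (parent == 1) | (parent == MISSING)
        return (parent == 1) | (parent == 2) | (parent == MISSING)

    errors = 0
    for hom, allele in ((child == 0, 0), (child == 2, 1)):
        ok = hom & can_give(sire, allele) & can_give(dam, allele)
        pat[ok] = allele
        mat[ok] = allele
        errors += int(np.count_nonzero(hom & ~(can_give(sire, allele) & can_give(dam, allele))))

    het = child == 1
    # option A: paternal=0, maternal=1 ; option B: paternal=1, maternal=0
    opt_a = het & can_give(sire, 0) & can_give(dam, 1)
    opt_b = het & can_give(sire, 1) & can_give(dam, 0)
    only_a = opt_a & ~opt_b
    only_b = opt_b & ~opt_a
    pat[only_a], mat[only_a] = 0, 1
    pat[only_b], mat[only_b] = 1, 0
    unresolved[:] = opt_a & opt_b
    errors += int(np.count_nonzero(het & ~opt_a & ~opt_b))

    if errors:
        logger.info("trio_phase: %d Mendelian-inconsistent entries set to missing", errors)
    return TrioPhaseResult(pat, mat, unresolved, errors)


def phase_offspring(gm: PhasedGenotypeMatrix, ped: Pedigree) -> PhasedGenotypeMatrix:
    """Re-phase every pedigree trio in ``gm`` from parental dosages.

    Convenience wrapper applying :func:`trio_phase` row by row; individuals
    without two genotyped parents are left untouched.
    """
    index = {s: k for k, s in enumerate(gm.sample_ids)}
    pat = gm.paternal.copy()
    mat = gm.maternal.copy()
    unph = gm.unphased_het.copy()
    dos = gm.dosage()
    for row in ped.trios().itertuples(index=False):
        if row.id not in index or row.sire not in index or row.dam not in index:
            continue
        i, s, d = index[row.id], index[row.sire], index[row.dam]
        child = np.nan_to_num(dos[i], nan=MISSING).astype(np.int8)
        res = trio_phase(
            child,
            np.nan_to_num(dos[s], nan=MISSING).astype(np.int8),
            np.nan_to_num(dos[d], nan=MISSING).astype(np.int8),
        )
        pat[i], mat[i] = res.paternal, res.maternal
        unph[i] = res.unresolved
    return replace(gm, paternal=pat, maternal=mat, unphased_het=unph)


# ---------------------------------------------------------------------------
# Hardy-Weinberg multinomial fill
# ---------------------------------------------------------------------------

def fill_missing_hwe(gm: PhasedGenotypeMatrix, seed: int) -> PhasedGenotypeMatrix:
    """Fill missing ordered genotypes by Hardy-Weinberg multinomial sampling.

    For a variant with alt-allele frequency ``p`` (estimated from observed
    entries, phase-unknown heterozygotes contributing one alt allele), a
    fully missing entry is drawn from the four ordered classes with
    probabilities ``(q^2, pq, pq, p^2)``; a phase-unknown heterozygote is
    assigned ``ref|alt`` or ``alt|ref`` with probability 1/2 each.
    Observed entries are never altered.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pat = gm.paternal.copy()
    mat = gm.maternal.copy()
    dos = gm.dosage()

    # alt-allele frequency per variant from everything observed
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(dos), axis=0)
        if np.any(n_obs == 0):
            bad = gm.variants.loc[n_obs == 0, "id"].tolist()
            raise ValueError(f"variants with all entries missing: {bad[:10]}")
        p = np.nansum(dos, axis=0) / (2.0 * n_obs)

    fully_missing = (gm.paternal == MISSING) & ~gm.unphased_het
    # sample ordered genotypes column-wise so probabilities follow p_k
    for k in np.flatnonzero(fully_missing.any(axis=0)):
        rows = np.flatnonzero(fully_missing[:, k])
        pk, qk = p[k], 1.0 - p[k]
        probs = np.array([qk * qk, pk * qk, pk * qk, pk * pk])
        cls = rng.choice(4, size=rows.size, p=probs / probs.sum())
        pat[rows, k] = (cls >= 2).astype(np.int8)
        mat[rows, k] = (cls % 2).astype(np.int8)

    unph_rows, unph_cols = np.nonzero(gm.unphased_het)
    if unph_rows.size:
        pat_alt = rng.random(unph_rows.size) < 0.5
        pat[unph_rows, unph_cols] = pat_alt.astype(np.int8)
        mat[unph_rows, unph_cols] = (~pat_alt).astype(np.int8)

    return replace(
        gm,
        paternal=pat,
        maternal=mat,
        unphased_het=np.zeros_like(gm.unphased_het),
    )
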