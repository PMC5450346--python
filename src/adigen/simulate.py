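"""Synthetic dairy-style populations with known genetic architecture.

The generator emulates the data regime of a dairy genomic evaluation:
trio-structured pedigrees (genotyped sire, dam, and daughter) organized in
paternal half-sib families with an optional share of full-sib litters,
biallelic SNPs near Hardy-Weinberg equilibrium simulated in linkage
equilibrium, and phenotypes built from additive, dominance, and
parent-of-origin (imprinting) QTL effects plus Gaussian noise.

Founder haplotypes are drawn with per-locus alt-allele frequencies from a
uniform law (default U(0.05, 0.95)); offspring genotypes arise by gene
drop with independent Mendelian transmission per locus, so the true
parental origin of every allele is known.  QTL effects are standard normal
and each class's genetic-value vector is rescaled so the realized variance
hits the requested fraction of the (unit) phenotypic variance exactly;
the residual takes the remaining fraction.

Scenario presets mirror a validation design for three-component variance
decomposition: a moderate-heritability production trait ("milk", fractions
0.338 / 0.040 / 0.008 for additive / dominance / imprinting) and a
low-heritability fertility trait ("dpr", 0.044 / 0.011 / 0.015), each with
1000 additive QTLs and 10, 100, or 1000 dominance and imprinting QTLs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import allele_freq, code_genotypes
from .containers import Pedigree, PhasedGenotypeMatrix, PhenotypeTable
from .greml import fit_greml
from .grm import build_grms

#: trait-mimicking target variance fractions (additive, dominance, imprinting)
TRAIT_FRACTIONS = {
    "milk": (0.338, 0.040, 0.008),
    "dpr": (0.044, 0.011, 0.015),
}

SCENARIOS = {
    f"{trait}_{nq}": (trait, (1000, nq, nq))
    for trait in TRAIT_FRACTIONS
    for nq in (10, 100, 1000)
}


@dataclass
class FamilyStructure:
    """Half-sib sire families with an optional fraction of full-sib litters."""

    n_sires: int | None = None  # derived from daughters_per_sire when None
    daughters_per_sire: int = 20
    full_sib_litter_size: int = 2
    full_sib_fraction: float = 0.2  # fraction of matings producing a litter


@dataclass
class SimulationConfig:
    n_individuals: int = 2000  # phenotyped daughters
    n_markers: int = 5000
    n_qtl: tuple[int, int, int] = (1000, 100, 100)  # additive, dominance, imprinting
    target_fractions: tuple[float, float, float] = TRAIT_FRACTIONS["milk"]
    family_structure: FamilyStructure = field(default_factory=FamilyStructure)
    freq_range: tuple[float, float] = (0.05, 0.95)  # founder alt-frequency law
    n_chromosomes: int = 10
    ld_rho: float = 0.0  # optional first-order haplotype correlation
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.target_fractions):
            raise ValueError("variance fractions must lie in [0, 1]")
        if sum(self.target_fractions) > 1.0 + 1e-12:
            raise ValueError("variance fractions must sum to at most 1")
        if any(nq > self.n_markers for nq in self.n_qtl):
            raise ValueError("more QTLs than markers in a class")
        fs = self.family_structure
        if fs.n_sires is not None:
            if fs.n_sires * fs.daughters_per_sire < self.n_individuals:
                raise ValueError(
                    "family structure cannot produce the requested number of "
                    f"daughters: {fs.n_sires} sires x {fs.daughters_per_sire}"
                )


@dataclass
class SimTruth:
    """Ground truth of a simulated trait."""

    qtl_indices: dict[str, np.ndarray]  # per class: marker column indices
    qtl_effects: dict[str, np.ndarray]  # rescaled per-QTL effects
    genetic_values: pd.DataFrame  # per-individual a, d, i
    fractions: dict[str, float]  # realized variance fractions (incl. "e")
    sigma2: dict[str, float]


@dataclass
class SimulatedDataset:
    genotypes: PhasedGenotypeMatrix
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    truth: SimTruth


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _founder_haplotypes(rng, n_hap: int, p: np.ndarray, rho: float) -> np.ndarray:
    m = p.size
    if rho <= 0.0:
        return (rng.random((n_hap, m)) < p).astype(np.int8)
    # first-order Markov copy process along each chromosome arm
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < p[0]
    for k in range(1, m):
        fresh = (rng.random(n_hap) < p[k]).astype(np.int8)
        copy = rng.random(n_hap) < rho
        H[:, k] = np.where(copy, H[:, k - 1], fresh)
    return H


def simulate_population(cfg: SimulationConfig) -> tuple[PhasedGenotypeMatrix, Pedigree]:
    """Gene-drop a trio-structured population; returns genotypes + pedigree.

    The genotype matrix contains sires, dams, and daughters with the true
    simulated transmission recorded as the phase.  Determinism: the same
    config (including seed) yields a bit-identical dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    n_d = cfg.n_individuals
    m = cfg.n_markers
    fs = cfg.family_structure
    n_sires = fs.n_sires or -(-n_d // fs.daughters_per_sire)

    # assign daughters to sires and matings (one dam per mating)
    sire_of: list[int] = []
    dam_of: list[int] = []
    litters: list[int] = []
    n_dams = 0
    for s in range(n_sires):
        assigned = 0
        quota = min(fs.daughters_per_sire, n_d - len(sire_of))
        while assigned < quota:
            litter = (
                fs.full_sib_litter_size
                if (quota - assigned >= fs.full_sib_litter_size
                    and rng.random() < fs.full_sib_fraction)
                else 1
            )
            for _ in range(litter):
                sire_of.append(s)
                dam_of.append(n_dams)
                litters.append(litter)
            n_dams += 1
            assigned += litter
        if len(sire_of) >= n_d:
            break
    sire_of_arr = np.asarray(sire_of)
    dam_of_arr = np.asarray(dam_of)

    p = rng.uniform(*cfg.freq_range, size=m)
    sire_h = _founder_haplotypes(rng, 2 * n_sires, p, cfg.ld_rho).reshape(n_sires, 2, m)
    dam_h = _founder_haplotypes(rng, 2 * n_dams, p, cfg.ld_rho).reshape(n_dams, 2, m)

    cols = np.arange(m)[None, :]
    pat_pick = rng.integers(0, 2, size=(n_d, m))
    mat_pick = rng.integers(0, 2, size=(n_d, m))
    d_pat = sire_h[sire_of_arr[:, None], pat_pick, cols]
    d_mat = dam_h[dam_of_arr[:, None], mat_pick, cols]

    sire_ids = [f"S{k + 1:04d}" for k in range(n_sires)]
    dam_ids = [f"M{k + 1:05d}" for k in range(n_dams)]
    daughter_ids = [f"C{k + 1:05d}" for k in range(n_d)]

    paternal = np.vstack([sire_h[:, 0, :], dam_h[:, 0, :], d_pat]).astype(np.int8)
    maternal = np.vstack([sire_h[:, 1, :], dam_h[:, 1, :], d_mat]).astype(np.int8)
    sample_ids = sire_ids + dam_ids + daughter_ids

    per_chrom = -(-m // cfg.n_chromosomes)
    chroms = [str(1 + k // per_chrom) for k in range(m)]
    pos = [1000 * (k % per_chrom) + 1000 for k in range(m)]
    variants = pd.DataFrame(
        dict(
            chrom=chroms,
            pos=pos,
            id=[f"snp{k + 1}" for k in range(m)],
            ref="A",
            alt="B",
            founder_freq=p,  # the alt frequency each locus was drawn with
        )
    )
    gm = PhasedGenotypeMatrix(paternal, maternal, sample_ids, variants)

    founders = [(i, Pedigree.UNKNOWN, Pedigree.UNKNOWN) for i in sire_ids + dam_ids]
    offspring = [
        (daughter_ids[k], sire_ids[sire_of_arr[k]], dam_ids[dam_of_arr[k]])
        for k in range(n_d)
    ]
    ped = Pedigree(pd.DataFrame(founders + offspring, columns=["id", "sire", "dam"]))
    return gm, ped


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def simulate_trait(
    gm: PhasedGenotypeMatrix,
    cfg: SimulationConfig,
    pedigree: Pedigree | None = None,
) -> SimulatedDataset:
    """Overlay a trait with the configured QTL architecture on ``gm``.

    Phenotypes are generated for pedigree non-founders (the daughters) when
    a pedigree is supplied, otherwise for every individual.  Per class
    (additive / dominance / imprinting), QTL positions are sampled without
    replacement, effects are standard normal, and the class's genetic-value
    vector is rescaled so its sample variance equals the target fraction of
    the unit total phenotypic variance exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    if pedigree is not None:
        founders = set(pedigree.founders())
        pheno_ids = [s for s in gm.sample_ids if s not in founders]
        if not pheno_ids:
            pheno_ids = list(gm.sample_ids)
    else:
        pheno_ids = list(gm.sample_ids)
    sub = gm.subset_samples(pheno_ids)
    coded = code_genotypes(sub, "genotypic")
    design = {"a": coded.Z, "d": coded.H, "i": coded.S}

    n = len(pheno_ids)
    qtl_indices: dict[str, np.ndarray] = {}
    qtl_effects: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    for cls, n_qtl, frac in zip("adi", cfg.n_qtl, cfg.target_fractions):
        if frac > 0.0 and n_qtl == 0:
            raise ValueError(
                f"target fraction {frac} for class {cls!r} but zero QTLs configured"
            )
        if n_qtl == 0 or frac == 0.0:
            qtl_indices[cls] = np.empty(0, dtype=int)
            qtl_effects[cls] = np.empty(0)
            values[cls] = np.zeros(n)
            fractions[cls] = 0.0
            continue
        idx = rng.choice(gm.n_variants, size=n_qtl, replace=False)
        eff = rng.standard_normal(n_qtl)
        raw = design[cls][:, idx] @ eff
        v = float(np.var(raw, ddof=1))
        if v <= 0.0:
            raise ValueError(
                f"degenerate genetic values for class {cls!r} (all QTLs uninformative)"
            )
        scale = np.sqrt(frac / v)  # unit total phenotypic variance
        qtl_indices[cls] = idx
        qtl_effects[cls] = eff * scale
        values[cls] = (raw - raw.mean()) * scale
        fractions[cls] = frac

    sigma2_e = 1.0 - sum(fractions.values())
    e = rng.standard_normal(n) * np.sqrt(sigma2_e) if sigma2_e > 0 else np.zeros(n)
    y = values["a"] + values["d"] + values["i"] + e

    truth = SimTruth(
        qtl_indices=qtl_indices,
        qtl_effects=qtl_effects,
        genetic_values=pd.DataFrame(values, index=pheno_ids),
        fractions={**fractions, "e": sigma2_e},
        sigma2={**fractions, "e": sigma2_e},  # unit phenotypic variance
    )
    pheno = PhenotypeTable(pd.Series(y, index=pheno_ids), trait_name=cfg.trait_name)
    ped = pedigree if pedigree is not None else Pedigree(
        pd.DataFrame(
            [(s, Pedigree.UNKNOWN, Pedigree.UNKNOWN) for s in gm.sample_ids],
            columns=["id", "sire", "dam"],
        )
    )
    return SimulatedDataset(gm, ped, pheno, truth)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Convenience: population plus trait in one call."""
    gm, ped = simulate_population(cfg)
    return simulate_trait(gm, cfg, ped)


# ---------------------------------------------------------------------------
# scenario replication
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    scenario: str
    truth: dict[str, float]
    estimates: pd.DataFrame  # one row per replicate

    def summary(self) -> pd.DataFrame:
        cols = ["frac_A", "frac_D", "frac_P", "H2"]
        truth = [
            self.truth["a"],
            self.truth["d"],
            self.truth["i"],
            self.truth["a"] + self.truth["d"] + self.truth["i"],
        ]
        if self.estimates.empty:
            return pd.DataFrame(
                dict(component=cols, truth=truth, mean=np.nan, sd=np.nan,
                     deviation=np.nan, se_mean=np.nan)
            )
        means = self.estimates[cols].mean()
        sds = self.estimates[cols].std(ddof=1)
        n = len(self.estimates)
        return pd.DataFrame(
            dict(
                component=cols,
                truth=truth,
                mean=means.to_numpy(),
                sd=sds.to_numpy(),
                deviation=means.to_numpy() - np.asarray(truth),
                se_mean=sds.to_numpy() / np.sqrt(n),
            )
        )


def fit_dataset(
    ds: SimulatedDataset,
    kinds: tuple[str, ...] = ("A", "D", "P"),
    maf_min: float = 0.01,
) -> "GremlFit":
    """Filter markers, build GRMs on the phenotyped individuals, fit REML."""
    pheno_ids = ds.phenotypes.ids
    sub = ds.genotypes.subset_samples(pheno_ids)
    mask = np.minimum(allele_freq(sub), 1 - allele_freq(sub)) >= maf_min
    sub = sub.subset_variants(mask)
    scheme = "noia" if "Dstar" in kinds else "genotypic"
    coded = code_genotypes(sub, scheme)
    grms = build_grms(coded, kinds)
    y, X = ds.phenotypes.design()
    return fit_greml(y, X, grms, check_psd=False)


def run_scenario(
    scenario_name: str,
    n_replicates: int,
    seed: int,
    n_individuals: int = 2000,
    n_markers: int = 5000,
    **cfg_overrides,
) -> ScenarioResult:
    """Repeat simulate -> GRMs -> REML for a preset scenario.

    Presets: milk_10 / milk_100 / milk_1000 / dpr_10 / dpr_100 / dpr_1000,
    the suffix being the number of dominance and imprinting QTLs (additive
    QTLs are always 1000).  Non-convergent replicates are kept but flagged.
    """
    if scenario_name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario_name!r}; choose from {sorted(SCENARIOS)}"
        )
    trait, n_qtl = SCENARIOS[scenario_name]
    fracs = TRAIT_FRACTIONS[trait]
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=max(n_replicates, 0))
    rows = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_markers=n_markers,
            n_qtl=n_qtl,
            target_fractions=fracs,
            trait_name=trait,
            seed=int(rep_seeds[r]),
            **cfg_overrides,
        )
        ds = simulate_dataset(cfg)
        fit = fit_dataset(ds)
        rows.append(
            dict(
                replicate=r,
                frac_A=fit.proportions["A"],
                frac_D=fit.proportions["D"],
                frac_P=fit.proportions["P"],
                frac_e=fit.proportions["e"],
                H2=fit.H2,
                logL=fit.logL,
                converged=fit.converged,
                n_iter=fit.n_iter,
            )
        )
    estimates = pd.DataFrame(
        rows,
        columns=[
            "replicate", "frac_A", "frac_D", "frac_P", "frac_e",
            "H2", "logL", "converged", "n_iter",
        ],
    )
    truth = dict(a=fracs[0], d=fracs[1], i=fracs[2])
    return ScenarioResult(scenario_name, truth, estimates)
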