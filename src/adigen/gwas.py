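"""Single-marker association scans for additive, dominance, and imprinting effects.

Two strategies are provided:

* **Two-step scan** (GRAMMAR-style): fit the polygenic three-component
  mixed model once, then regress its residuals on each SNP's additive (Z),
  dominance (H), and imprinting (S) codes by ordinary least squares with
  per-coefficient t-tests.  Fast, slightly conservative in power.
* **One-step test**: generalized least squares on the raw phenotype with
  the polygenic covariance V = sum_c sigma2_c G_c + sigma2_e I held fixed
  at the null-model estimates; per-coefficient Wald tests.  Used to re-test
  candidate signals from the two-step scan.

The association design uses the genotypic coding (Z in 0/1/2, H in 0/1,
S in 0/-1/+1).  Conditional scans add the codes of chosen covariate
variants as fixed covariates, the standard device for deciding whether a
peak reflects a single underlying QTL.  Leave-one-chromosome-out (LOCO)
relationship matrices avoid proximal contamination when validating a
signal.  The conventional genome-wide significance threshold is 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .coding import CodedMatrix
from .containers import PhasedGenotypeMatrix
from .greml import GremlFit
from .grm import GRM, build_grm

GENOME_WIDE_ALPHA = 1e-6

_EFFECTS = ("a", "d", "i")


def _design_columns(coded: CodedMatrix, k: int) -> dict[str, np.ndarray]:
    return {"a": coded.Z[:, k], "d": coded.H[:, k], "i": coded.S[:, k]}


def _ols_row(y: np.ndarray, cols: dict[str, np.ndarray], extra: np.ndarray | None):
    """OLS of y on intercept + extra covariates + testable SNP codes.

    Constant (or collinear) SNP columns are reported untestable (NaN)
    rather than failing.
    """
    n = y.size
    parts = [np.ones((n, 1))]
    if extra is not None and extra.size:
        parts.append(extra)
    testable = []
    for name in _EFFECTS:
        c = cols[name]
        if np.ptp(c) > 0:
            testable.append(name)
            parts.append(c[:, None])
    X = np.hstack(parts)
    # drop collinear testable columns (e.g. Z and H identical when no
    # homozygote-alt individuals are present)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r[0, 0]))
    if not np.all(keep):
        n_fixed = X.shape[1] - len(testable)
        testable = [t for t, k_ in zip(testable, keep[n_fixed:]) if k_]
        X = X[:, keep]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        return {f"{e}_k": np.nan for e in _EFFECTS}
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    out: dict[str, float] = {}
    n_fixed = X.shape[1] - len(testable)
    for name in _EFFECTS:
        if name in testable:
            j = n_fixed + testable.index(name)
            t = beta[j] / se[j]
            out[f"{name}_k"] = float(beta[j])
            out[f"se_{name}"] = float(se[j])
            out[f"p_{name}"] = float(2.0 * stats.t.sf(abs(t), df))
        else:
            out[f"{name}_k"] = np.nan
            out[f"se_{name}"] = np.nan
            out[f"p_{name}"] = np.nan
    return out


def two_step_scan(
    fit: GremlFit,
    coded: CodedMatrix,
    covariate_matrix: np.ndarray | None = None,
    skip: set[int] | None = None,
    model_tag: str = "two_step",
) -> pd.DataFrame:
    """Regress polygenic-model residuals on each SNP's (Z, H, S) codes.

    Returns one row per variant with effect estimates, SEs, and t-test
    p-values for the additive, dominance, and imprinting coefficients.
    """
    if list(coded.sample_ids) != list(fit.sample_ids):
        raise ValueError("coded matrix and fit cover different individuals")
    e = fit.blups["e"].to_numpy()
    rows = []
    maf = np.minimum(coded.p, 1 - coded.p)
    var_ids = (
        coded.variants["id"].tolist()
        if coded.variants is not None
        else [str(k) for k in range(coded.n_variants)]
    )
    for k in range(coded.n_variants):
        if skip and k in skip:
            continue
        row = dict(variant=var_ids[k], maf=float(maf[k]), model=model_tag)
        row.update(_ols_row(e, _design_columns(coded, k), covariate_matrix))
        rows.append(row)
    return pd.DataFrame(rows)


def conditional_scan(
    fit: GremlFit,
    coded: CodedMatrix,
    covariate_variants: list[int | str],
    include_dominance: bool = True,
) -> pd.DataFrame:
    """Two-step scan conditioning on chosen variants' codes as covariates.

    Covariate variants contribute their additive code, plus their dominance
    code when ``include_dominance`` is set.  The covariate variants
    themselves are skipped in the scan.
    """
    var_ids = coded.variants["id"].tolist() if coded.variants is not None else []
    idx: list[int] = []
    for v in covariate_variants:
        if isinstance(v, str):
            if v not in var_ids:
                raise KeyError(f"covariate variant {v!r} not found")
            idx.append(var_ids.index(v))
        else:
            idx.append(int(v))
    if not idx:
        return two_step_scan(fit, coded)
    cov_cols = [coded.Z[:, j] for j in idx]
    if include_dominance:
        cov_cols += [coded.H[:, j] for j in idx]
    extra = np.column_stack(cov_cols)
    return two_step_scan(
        fit, coded, covariate_matrix=extra, skip=set(idx), model_tag="two_step_cond"
    )


def one_step_test(
    y: np.ndarray,
    X: np.ndarray | None,
    coded: CodedMatrix,
    variant_index: int,
    grms: list[GRM],
    sigma2: dict[str, float] | np.ndarray,
    maf_min: float = 0.01,
) -> dict:
    """Mixed-model Wald test of one SNP's additive/dominance/imprinting effects.

    The polygenic covariance uses the variance components of the null model
    (full {A, D, P} or reduced {A}) without per-SNP re-estimation; the
    response is the raw phenotype.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    maf = min(coded.p[variant_index], 1 - coded.p[variant_index])
    if maf < maf_min:
        raise ValueError(
            f"variant {variant_index} fails the MAF filter ({maf:.4f} < {maf_min})"
        )
    if isinstance(sigma2, dict):
        theta = [sigma2[g.kind] for g in grms] + [sigma2["e"]]
    else:
        theta = list(np.asarray(sigma2, dtype=float))
    V = theta[-1] * np.eye(n)
    for th, g in zip(theta[:-1], grms):
        V += th * (g.matrix if isinstance(g, GRM) else np.asarray(g))
    cols = _design_columns(coded, variant_index)
    testable = [e for e in _EFFECTS if np.ptp(cols[e]) > 0]
    W = np.hstack([X] + [cols[e][:, None] for e in testable])
    try:
        cf = cho_factor(V)
        VinvW = cho_solve(cf, W)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular mixed-model equations at variant {variant_index}"
        ) from err
    WtVinvW = W.T @ VinvW
    try:
        cov = np.linalg.inv(WtVinvW)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular mixed-model equations at variant {variant_index}"
        ) from err
    beta = cov @ (VinvW.T @ y)
    se = np.sqrt(np.diag(cov))
    model = "one_step_full" if len(grms) > 1 else "one_step_reduced"
    var_ids = coded.variants["id"].tolist() if coded.variants is not None else None
    out = dict(
        variant=var_ids[variant_index] if var_ids else str(variant_index),
        maf=float(maf),
        model=model,
    )
    p_fixed = X.shape[1]
    for e in _EFFECTS:
        if e in testable:
            j = p_fixed + testable.index(e)
            z = beta[j] / se[j]
            out[f"{e}_k"] = float(beta[j])
            out[f"se_{e}"] = float(se[j])
            out[f"p_{e}"] = float(2.0 * stats.norm.sf(abs(z)))
        else:
            out[f"{e}_k"] = np.nan
            out[f"se_{e}"] = np.nan
            out[f"p_{e}"] = np.nan
    return out


def loco_grm(coded: CodedMatrix, exclude_chrom: str, kind: str = "A") -> GRM:
    """GRM from all variants *not* on ``exclude_chrom`` (leave-one-chromosome-out)."""
    if coded.variants is None:
        raise ValueError("coded matrix carries no chromosome annotation")
    chroms = coded.variants["chrom"].astype(str)
    if str(exclude_chrom) not in set(chroms):
        raise KeyError(f"chromosome {exclude_chrom!r} absent from the data")
    keep = (chroms != str(exclude_chrom)).to_numpy()
    if not keep.any():
        raise ValueError("excluding that chromosome leaves zero markers")
    sub = CodedMatrix(
        Z=coded.Z[:, keep],
        H=coded.H[:, keep],
        S=coded.S[:, keep],
        p=coded.p[keep],
        scheme=coded.scheme,
        sample_ids=coded.sample_ids,
        variants=coded.variants.loc[keep].reset_index(drop=True),
    )
    return build_grm(sub, kind)


def ld_r2(gm: PhasedGenotypeMatrix, variant_i: int, variant_j: int) -> float:
    """Squared Pearson correlation of allele dosages between two variants."""
    d = gm.dosage()
    x, y = d[:, variant_i], d[:, variant_j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("monomorphic variant: LD undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def manhattan_plot(results: pd.DataFrame, effect: str = "d", ax=None):
    """Minimal -log10(p) Manhattan-style plot of a scan result (optional)."""
    import matplotlib.pyplot as plt  # optional dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    p = results[f"p_{effect}"].to_numpy()
    ax.scatter(np.arange(len(p)), -np.log10(p), s=4)
    ax.axhline(-np.log10(GENOME_WIDE_ALPHA), color="red", ls="--", lw=0.8)
    ax.set_xlabel("variant index")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{effect} effect")
    return ax
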