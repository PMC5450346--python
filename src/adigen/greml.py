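"""REML variance-component estimation with genomic relationship matrices.

The model is

    y = X b + u_1 + ... + u_g + e,
    u_c ~ N(0, sigma2_c G_c),   e ~ N(0, sigma2_e I),

with each G_c a genomic relationship matrix (typically the additive,
dominance, and imprinting kinds A, D, P — or A, Dstar, P for the classical
breeding-value / dominance-deviation decomposition).  Estimation is by
average-information (AI) REML with an expectation-maximization first step
and EM fallback whenever an AI step would leave the parameter space;
variances are constrained to be non-negative (active set at the zero
boundary).  Standard errors come from the inverse AI matrix, proportion
standard errors from the delta method, and BLUPs of each random component
from sigma2_c * G_c * Vinv * (y - X bhat).

Testing a variance component against zero uses the boundary-corrected
likelihood-ratio test with the 1/2 chi2_0 + 1/2 chi2_1 null mixture (the
parameter sits on the boundary of its space under the null); a one-sided
Wald variant is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, null_space, solve

from .grm import GRM

logger = logging.getLogger(__name__)

#: relative log-likelihood convergence tolerance
REML_TOL = 1e-8
MAX_ITER = 200

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GremlFit:
    """Result of a multi-component REML fit."""

    sigma2: dict[str, float]  # per component (genetic kinds + "e")
    se_sigma2: dict[str, float]
    proportions: dict[str, float]  # sigma2 / phenotypic variance
    se_proportions: dict[str, float]
    H2: float  # broad-sense: sum of genetic proportions
    h2: float  # narrow-sense: additive proportion
    logL: float
    fixed_effects: np.ndarray
    se_fixed_effects: np.ndarray
    blups: pd.DataFrame  # per-individual component predictions + residual
    converged: bool
    n_iter: int
    sample_ids: list[str] = field(default_factory=list)
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.sigma2.values())
        if total > 0:
            assert abs(sum(self.proportions.values()) - 1.0) < 1e-8

    @property
    def n(self) -> int:
        return len(self.blups)

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.sigma2:
            rows.append(
                dict(
                    component=k,
                    sigma2=self.sigma2[k],
                    se_sigma2=self.se_sigma2[k],
                    proportion=self.proportions[k],
                    se_proportion=self.se_proportions[k],
                )
            )
        return pd.DataFrame(rows)


def _prepare(y, X, grms):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X rows do not match y length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    mats, kinds, ids = [], [], None
    for g in grms:
        if isinstance(g, GRM):
            mats.append(g.matrix)
            kinds.append(g.kind)
            if ids is None and g.sample_ids:
                ids = list(g.sample_ids)
            elif ids is not None and g.sample_ids and list(g.sample_ids) != ids:
                raise ValueError("GRMs are not aligned to the same individuals")
        else:
            mats.append(np.asarray(g, dtype=float))
            kinds.append(f"g{len(kinds) + 1}")
    for M in mats:
        if M.shape != (n, n):
            raise ValueError("GRM dimension does not match phenotype length")
    if not 1 <= len(mats) <= 3:
        raise ValueError("supply between 1 and 3 genetic components")
    if ids is None:
        ids = [str(i) for i in range(n)]
    return y, X, mats, kinds, ids


def _check_psd(mats, kinds):
    from scipy.linalg import eigvalsh

    for M, k in zip(mats, kinds):
        lo = eigvalsh(M, subset_by_index=[0, 0])[0]
        hi = eigvalsh(M, subset_by_index=[M.shape[0] - 1, M.shape[0] - 1])[0]
        if lo < -1e-6 * max(hi, 1.0):
            raise ValueError(
                f"GRM {k} is not positive semidefinite (min eig {lo:.3e})"
            )


def _loglik_chol(y, X, mats, theta):
    """Restricted log-likelihood only (no Vinv formed) for step control."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for th, M in zip(theta[:-1], mats):
        V += th * M
    cf = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    VinvX = cho_solve(cf, X)
    Vinvy = cho_solve(cf, y)
    XtVinvX = X.T @ VinvX
    cf2 = cho_factor(XtVinvX)
    logdetXtVinvX = 2.0 * np.sum(np.log(np.diag(cf2[0])))
    Xty = X.T @ Vinvy
    yPy = float(y @ Vinvy) - float(Xty @ cho_solve(cf2, Xty))
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (logdetV + logdetXtVinvX - logdetXtX + yPy + (n - p) * _LOG2PI)


def _reml_pieces(y, X, mats, theta):
    """Core per-iteration quantities for AI-REML.

    Returns (logL, score, AI, Py, Vinv, P, XtVinvX_chol, bhat).
    """
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for th, M in zip(theta[:-1], mats):
        V += th * M
    cf = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = cho_solve(cf, np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cf2 = cho_factor(XtVinvX)
    logdetXtVinvX = 2.0 * np.sum(np.log(np.diag(cf2[0])))
    bhat = cho_solve(cf2, VinvX.T @ y)
    P = Vinv - VinvX @ cho_solve(cf2, VinvX.T)
    Py = P @ y
    yPy = float(y @ Py)
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    logL = -0.5 * (
        logdetV + logdetXtVinvX - logdetXtX + yPy + (n - p) * _LOG2PI
    )
    # score and AI over all components (genetic ones then residual)
    w = [M @ Py for M in mats] + [Py]
    trPG = [float(np.sum(P * M)) for M in mats] + [float(np.trace(P))]
    score = np.array(
        [-0.5 * (t - float(Py @ wi)) for t, wi in zip(trPG, w)]
    )
    k = len(w)
    AI = np.empty((k, k))
    Pw = [P @ wi for wi in w]
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ Pw[j])
    return logL, score, AI, Py, Vinv, P, cf2, bhat, trPG, w


def fit_greml(
    y: np.ndarray,
    X: np.ndarray | None,
    grms: list,
    tol: float = REML_TOL,
    max_iter: int = MAX_ITER,
    check_psd: bool = True,
    verbose: bool = False,
) -> GremlFit:
    """Fit the multi-component mixed model by AI-REML.

    Parameters
    ----------
    y
        Phenotype vector (pre-adjusted, e.g. yield deviations).
    X
        Fixed-effect design; ``None`` means intercept only.
    grms
        One to three :class:`~adigen.grm.GRM` objects (or raw matrices)
        aligned to ``y``.
    """
    y, X, mats, kinds, ids = _prepare(y, X, grms)
    if check_psd:
        _check_psd(mats, kinds)
    n, p = X.shape
    vp = float(np.var(y, ddof=1))
    if vp <= 0:
        raise ValueError("phenotype has zero variance")
    g = len(mats)
    floor = 1e-8 * vp
    # starting values: genetic components split half the phenotypic
    # variance evenly, residual takes the other half
    theta = np.array([vp / (2.0 * g)] * g + [vp / 2.0])

    logL_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logL, score, AI, Py, Vinv, P, cf2, bhat, trPG, w = _reml_pieces(
            y, X, mats, theta
        )
        if verbose:
            logger.info("iter %d logL %.6f theta %s", it, logL, theta)
        # converged only when the likelihood is stable AND the gradient is
        # flat for every free component: a small likelihood change alone can
        # also mean the last fallback step was simply tiny (flat ridge)
        free = (theta > 2.0 * floor) | (score > 0)
        grad_scale = np.abs(score) * np.maximum(theta, 1e-3 * vp)
        stationary = not free.any() or float(grad_scale[free].max()) < 1e-3
        if (
            it > 1
            and abs(logL - logL_prev) < tol * max(1.0, abs(logL))
            and stationary
        ):
            converged = True
            break
        logL_prev = logL

        def em_step(th):
            # EM update: theta_i + theta_i^2 (y'PG_iPy - tr(PG_i)) / n
            new = th.copy()
            for i in range(g + 1):
                quad = float(Py @ w[i])
                new[i] = th[i] + th[i] ** 2 * (quad - trPG[i]) / n
            return np.maximum(new, floor)

        def ai_delta(th):
            # active set: components at the zero boundary whose gradient
            # points outward stay pinned and leave the AI system
            free = (th > 2.0 * floor) | (score > 0)
            delta = np.zeros_like(th)
            if free.any():
                delta[free] = solve(AI[np.ix_(free, free)], score[free], assume_a="pos")
            return delta, free

        def truncated_ai(th):
            # shrink the whole step so no component crosses zero: preserves
            # the ascent direction but can degenerate to a no-op when some
            # component already sits near the boundary
            delta, free = ai_delta(th)
            neg = delta < 0
            alpha = 1.0
            if np.any(neg):
                alpha = min(1.0, float(np.min((th[neg] - floor) / -delta[neg])))
            proposal = th + alpha * delta
            proposal[~free] = floor
            return np.maximum(proposal, floor)

        def clamped_ai(th):
            # take the full step and pin the violating components at zero:
            # changes direction, but is the only move that can lift the
            # remaining components past a boundary-blocked truncated step
            delta, free = ai_delta(th)
            proposal = th + delta
            proposal[~free] = floor
            return np.maximum(proposal, floor)

        def is_noop(cand):
            return float(np.max(np.abs(cand - theta))) < 1e-12 * vp

        # candidate steps in order of preference; the first one that does
        # not decrease the likelihood is accepted (monotone ascent; EM alone
        # is provably non-decreasing but cannot lift a component off zero)
        candidates: list[np.ndarray] = []
        if it > 1:
            try:
                candidates.append(truncated_ai(theta))
                clamp = clamped_ai(theta)
                for frac in (1.0, 0.5, 0.25, 0.1):
                    candidates.append(
                        np.maximum(theta + frac * (clamp - theta), floor)
                    )
            except np.linalg.LinAlgError:
                pass
        candidates.append(em_step(theta))
        candidates = [c for c in candidates if not is_noop(c)]
        if not candidates:
            converged = bool(stationary)
            break
        accepted = None
        best, best_ll = None, -np.inf
        for cand in candidates:
            ll = _loglik_chol(y, X, mats, cand)
            if ll > best_ll:
                best, best_ll = cand, ll
            if ll >= logL - 1e-10:
                accepted = cand
                break
        if accepted is None and best_ll < logL - 1e-10:
            # no candidate improves: numerically stuck extremum
            converged = bool(stationary)
            break
        theta = accepted if accepted is not None else best

    # final quantities at the converged parameters
    logL, score, AI, Py, Vinv, P, cf2, bhat, trPG, w = _reml_pieces(y, X, mats, theta)
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    try:
        AIinv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        AIinv = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(AIinv), 0.0))

    total = float(theta.sum())
    fractions = theta / total
    # delta-method SEs for fractions f_i = theta_i / sum(theta)
    se_frac = np.empty_like(fractions)
    for i in range(g + 1):
        grad = -theta[i] / total**2 * np.ones(g + 1)
        grad[i] += 1.0 / total
        se_frac[i] = np.sqrt(max(float(grad @ AIinv @ grad), 0.0))

    resid_fixed = y - X @ bhat
    Vinv_r = Vinv @ resid_fixed
    blup_cols = {}
    for i, (k, M) in enumerate(zip(kinds, mats)):
        blup_cols[k] = theta[i] * (M @ Vinv_r)
    blup_cols["e"] = theta[-1] * Vinv_r
    blups = pd.DataFrame(blup_cols, index=ids)

    names = list(kinds) + ["e"]
    sigma2 = {k: float(t) for k, t in zip(names, theta)}
    proportions = {k: float(f) for k, f in zip(names, fractions)}
    genetic_props = [proportions[k] for k in kinds]
    h2 = proportions.get("A", genetic_props[0])
    se_b = np.sqrt(np.diag(cho_solve(cf2, np.eye(p))))
    return GremlFit(
        sigma2=sigma2,
        se_sigma2={k: float(s) for k, s in zip(names, se)},
        proportions=proportions,
        se_proportions={k: float(s) for k, s in zip(names, se_frac)},
        H2=float(sum(genetic_props)),
        h2=float(h2),
        logL=float(logL),
        fixed_effects=bhat,
        se_fixed_effects=se_b,
        blups=blups,
        converged=converged,
        n_iter=it,
        sample_ids=ids,
        kinds=tuple(kinds),
    )


def direct_loglik(y, X, grms, sigma2) -> float:
    """Restricted log-likelihood via an explicit error-contrast projection.

    Independent of the AI-REML code path: projects y onto an orthonormal
    basis K of the null space of X' and evaluates the (n - p)-dimensional
    Gaussian log-density of K'y with covariance K'VK.  Matches the
    log-likelihood reported by :func:`fit_greml` at the same parameters.

    ``sigma2`` lists the genetic variances in the order of ``grms``
    followed by the residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sigma2 = np.asarray(sigma2, dtype=float)
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, float) for g in grms]
    if sigma2.size != len(mats) + 1:
        raise ValueError("sigma2 must list each genetic variance then the residual")
    V = sigma2[-1] * np.eye(n)
    for th, M in zip(sigma2[:-1], mats):
        V += th * M
    K = null_space(X.T)  # n x (n - p), orthonormal
    KVK = K.T @ V @ K
    sign, logdet = np.linalg.slogdet(KVK)
    if sign <= 0:
        raise ValueError("V is singular for the given variance components")
    Ky = K.T @ y
    quad = float(Ky @ np.linalg.solve(KVK, Ky))
    d = K.shape[1]
    return -0.5 * (logdet + quad + d * _LOG2PI)


def test_component_zero(full: GremlFit, reduced: GremlFit) -> dict:
    """Boundary-corrected likelihood-ratio test that one variance is zero.

    The reduced model must omit exactly one genetic component of the full
    model.  Under the null the LR statistic follows the 1/2 chi2_0 + 1/2
    chi2_1 mixture (the tested variance lies on the boundary), so
    p = 0.5 * Pr(chi2_1 > LR), with LR clamped at zero.
    """
    if full.sample_ids != reduced.sample_ids:
        raise ValueError("full and reduced models were fitted on different individuals")
    dropped = set(full.kinds) - set(reduced.kinds)
    if len(dropped) != 1 or not set(reduced.kinds) <= set(full.kinds):
        raise ValueError(
            "reduced model must omit exactly one genetic component of the full model"
        )
    lr = max(0.0, 2.0 * (full.logL - reduced.logL))
    p = 0.5 if lr == 0.0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return dict(component=dropped.pop(), lr=lr, p_value=p)


def wald_test_component(fit: GremlFit, kind: str) -> dict:
    """One-sided Wald test of sigma2_kind = 0 (for comparison with the LRT)."""
    z = fit.sigma2[kind] / fit.se_sigma2[kind]
    return dict(component=kind, z=z, p_value=0.5 * float(stats.chi2.sf(z * z, df=1)))


@dataclass
class DecompositionComparison:
    """Agreement between the genotypic {A, D, P} and NOIA {A, Dstar, P} fits."""

    fit_genotypic: GremlFit
    fit_noia: GremlFit
    H2_diff: float
    imprinting_proportion_diff: float
    max_additive_plus_dominance_diff: float
    max_residual_diff: float

    def max_abs_diff(self) -> float:
        return max(
            abs(self.H2_diff),
            abs(self.imprinting_proportion_diff),
            self.max_additive_plus_dominance_diff,
            self.max_residual_diff,
        )


def compare_decompositions(
    y: np.ndarray,
    X: np.ndarray | None,
    grms_genotypic: list,
    grms_noia: list,
    **fit_kwargs,
) -> DecompositionComparison:
    """Fit both variance decompositions and report their agreement.

    ``grms_genotypic`` holds {A, D, P} (genotypic dominance), ``grms_noia``
    {A, Dstar, P} (dominance deviation).  The two models are theoretically
    equivalent under Hardy-Weinberg and linkage equilibrium: same broad-sense
    heritability, same imprinting proportion, same per-individual sums of
    additive and dominance predictions, and same residuals.
    """
    fit1 = fit_greml(y, X, grms_genotypic, **fit_kwargs)
    fit2 = fit_greml(y, X, grms_noia, **fit_kwargs)
    if not (fit1.converged and fit2.converged):
        raise RuntimeError("at least one decomposition fit did not converge")
    dom1 = "D" if "D" in fit1.kinds else fit1.kinds[1]
    dom2 = "Dstar" if "Dstar" in fit2.kinds else fit2.kinds[1]
    ad1 = fit1.blups[fit1.kinds[0]] + fit1.blups[dom1]
    ad2 = fit2.blups[fit2.kinds[0]] + fit2.blups[dom2]
    imp1 = fit1.proportions.get("P", fit1.proportions[fit1.kinds[-1]])
    imp2 = fit2.proportions.get("P", fit2.proportions[fit2.kinds[-1]])
    return DecompositionComparison(
        fit_genotypic=fit1,
        fit_noia=fit2,
        H2_diff=fit1.H2 - fit2.H2,
        imprinting_proportion_diff=imp1 - imp2,
        max_additive_plus_dominance_diff=float(np.max(np.abs(ad1 - ad2))),
        max_residual_diff=float(np.max(np.abs(fit1.blups["e"] - fit2.blups["e"]))),
    )
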