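"""Genomic prediction of unphenotyped individuals and cross-validation.

A fitted variance decomposition yields BLUPs of each genetic component for
the training individuals; a new individual's component value is predicted
by projecting through the cross-relationship block,

    ghat_new = G_{n x t} G_{t x t}^{-1} uhat_t,

summed over the components in the model (additive only, additive +
dominance, or additive + dominance + imprinting).  Cross blocks must come
from the same marker set and allele frequencies as the training matrices,
which is guaranteed here by building each GRM once on the full sample and
slicing training/new blocks out of it.

k-fold cross-validation reports, per fold, the prediction *accuracy*
(Pearson correlation between predicted total genetic value and phenotype)
and *unbiasedness* (regression coefficient of phenotype on prediction,
ideally 1).  Models sharing fold assignments are compared by paired
t-tests across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import allele_freq, code_genotypes
from .containers import PhasedGenotypeMatrix, PhenotypeTable
from .greml import GremlFit, fit_greml
from .grm import GRM, build_grms

logger = logging.getLogger(__name__)

MODELS = {
    "ADD": ("A",),
    "ADD_DOM": ("A", "D"),
    "ADD_DOM_IMP": ("A", "D", "P"),
}

#: condition number above which the training block is pseudo-inverted
COND_MAX = 1e10


@dataclass
class PredictionResult:
    model_tag: str
    predictions: pd.DataFrame  # per new individual: components + ghat
    fold_assignments: pd.Series | None = None  # id -> fold
    accuracy: np.ndarray | None = None  # per fold
    bias: np.ndarray | None = None  # per fold

    @property
    def ghat(self) -> pd.Series:
        return self.predictions["ghat"]


def predict_new(
    fit: GremlFit,
    cross_blocks: dict[str, np.ndarray],
    train_grms: list[GRM],
    new_ids: list[str] | None = None,
    ridge: float = 0.0,
) -> PredictionResult:
    """Predict genetic components of new individuals from a training fit.

    ``cross_blocks[kind]`` is the (n_new x n_train) relationship block for
    each genetic kind in the fit.  A pseudo-inverse replaces the plain
    solve when the training block is numerically singular (the condition
    number is logged); alternatively pass ``ridge`` > 0 to add a diagonal
    stabilizer.
    """
    comp_preds: dict[str, np.ndarray] = {}
    n_new = None
    for g in train_grms:
        kind = g.kind
        if kind not in fit.kinds:
            continue
        B = np.asarray(cross_blocks[kind], dtype=float)
        if B.shape[1] != g.n:
            raise ValueError(
                f"cross block for kind {kind} has {B.shape[1]} training columns, "
                f"GRM has {g.n}"
            )
        n_new = B.shape[0]
        u = fit.blups[kind].to_numpy()
        M = g.matrix + (ridge * np.eye(g.n) if ridge > 0 else 0.0)
        cond = np.linalg.cond(M)
        if cond > COND_MAX:
            logger.info(
                "training %s block condition number %.2e; using pseudo-inverse",
                kind, cond,
            )
            comp_preds[kind] = B @ (np.linalg.pinv(M) @ u)
        else:
            comp_preds[kind] = B @ np.linalg.solve(M, u)
    if n_new is None:
        raise ValueError("no genetic component of the fit has a cross block")
    for kind in ("A", "D", "P"):
        if kind not in comp_preds:
            comp_preds[kind] = np.zeros(n_new)  # component absent from model
    ghat = comp_preds["A"] + comp_preds["D"] + comp_preds["P"]
    index = list(new_ids) if new_ids is not None else list(range(n_new))
    preds = pd.DataFrame({**comp_preds, "ghat": ghat}, index=index)
    tag = next(
        (t for t, kinds in MODELS.items() if set(kinds) == set(fit.kinds)),
        "+".join(fit.kinds),
    )
    return PredictionResult(model_tag=tag, predictions=preds)


def make_folds(ids: list[str], k: int, seed: int) -> pd.Series:
    """Random partition of ids into k folds (deterministic given seed)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold = np.empty(len(ids), dtype=int)
    fold[perm] = np.arange(len(ids)) % k
    return pd.Series(fold, index=ids, name="fold")


def cross_validate(
    gm: PhasedGenotypeMatrix,
    phenotypes: PhenotypeTable,
    model_tag: str = "ADD_DOM_IMP",
    k: int = 10,
    seed: int = 0,
    refit_per_fold: bool = True,
    whole_data_fit: GremlFit | None = None,
) -> PredictionResult:
    """k-fold cross-validated genomic prediction.

    GRMs are built once on all phenotyped individuals (allele frequencies
    from the full dataset) and sliced per fold.  By default variance
    components are re-estimated on each training split; set
    ``refit_per_fold=False`` to reuse a whole-data fit's components.
    Folds whose held-out phenotypes have zero variance are skipped with a
    warning.
    """
    if model_tag not in MODELS:
        raise KeyError(f"unknown model {model_tag!r}; choose from {sorted(MODELS)}")
    kinds = MODELS[model_tag]
    pheno = phenotypes.complete_cases()
    ids = pheno.ids
    sub = gm.subset_samples(ids)
    p = allele_freq(sub)
    keep = np.minimum(p, 1 - p) >= 0.01
    coded = code_genotypes(sub.subset_variants(keep), "genotypic")
    grms = build_grms(coded, kinds)
    y_all = pheno.values

    folds = make_folds(ids, k, seed)
    acc, bias, kept_folds = [], [], []
    pred_frames = []
    for f in range(k):
        test_ids = folds.index[folds == f].tolist()
        train_ids = folds.index[folds != f].tolist()
        y_test = y_all[test_ids].to_numpy()
        if np.ptp(y_test) == 0 or len(test_ids) < 3:
            logger.warning("fold %d skipped: degenerate held-out phenotypes", f)
            continue
        train_grms = [g.subset(train_ids) for g in grms]
        y_train = y_all[train_ids].to_numpy()
        if refit_per_fold or whole_data_fit is None:
            fit = fit_greml(y_train, None, train_grms, check_psd=False)
        else:
            # reuse whole-data variance components, re-derive BLUPs on the
            # training split by a single constrained evaluation
            fit = fit_greml(
                y_train, None, train_grms, max_iter=1, check_psd=False
            )
            fit = _replace_components(fit, y_train, train_grms, whole_data_fit)
        blocks = {g.kind: g.block(test_ids, train_ids) for g in grms}
        res = predict_new(fit, blocks, train_grms, new_ids=test_ids)
        ghat = res.ghat.to_numpy()
        if np.ptp(ghat) == 0:
            logger.warning("fold %d skipped: constant predictions", f)
            continue
        acc.append(float(np.corrcoef(ghat, y_test)[0, 1]))
        slope = float(np.polyfit(ghat, y_test, 1)[0])
        bias.append(slope)
        kept_folds.append(f)
        pred_frames.append(res.predictions.assign(fold=f))
    predictions = (
        pd.concat(pred_frames) if pred_frames else pd.DataFrame(columns=["ghat"])
    )
    return PredictionResult(
        model_tag=model_tag,
        predictions=predictions,
        fold_assignments=folds,
        accuracy=np.asarray(acc),
        bias=np.asarray(bias),
    )


def _replace_components(fit, y_train, train_grms, whole_fit):
    """Recompute BLUPs on a training split with frozen variance components."""
    from scipy.linalg import cho_factor, cho_solve

    n = y_train.size
    theta = [whole_fit.sigma2[g.kind] for g in train_grms] + [whole_fit.sigma2["e"]]
    V = theta[-1] * np.eye(n)
    for th, g in zip(theta[:-1], train_grms):
        V += th * g.matrix
    cf = cho_factor(V)
    ones = np.ones((n, 1))
    Vinv1 = cho_solve(cf, ones)
    b = float((Vinv1.T @ y_train) / (ones.T @ Vinv1))
    r = y_train - b
    Vinv_r = cho_solve(cf, r)
    blups = {
        g.kind: theta[i] * (g.matrix @ Vinv_r) for i, g in enumerate(train_grms)
    }
    blups["e"] = theta[-1] * Vinv_r
    fit.blups = pd.DataFrame(blups, index=[str(s) for s in train_grms[0].sample_ids])
    fit.sigma2 = {g.kind: theta[i] for i, g in enumerate(train_grms)}
    fit.sigma2["e"] = theta[-1]
    return fit


def compare_models(results: list[PredictionResult]) -> pd.DataFrame:
    """Paired t-tests across folds on accuracy and bias for each model pair.

    All results must share fold assignments (same partition of the same
    individuals).
    """
    if len(results) < 2:
        raise ValueError("need at least two prediction results to compare")
    base = results[0].fold_assignments
    for r in results[1:]:
        if r.fold_assignments is None or not r.fold_assignments.equals(base):
            raise ValueError("prediction results have mismatched fold assignments")
    rows = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            for metric in ("accuracy", "bias"):
                x = getattr(a, metric)
                z = getattr(b, metric)
                if x.size != z.size:
                    raise ValueError("fold counts differ between results")
                diff = x - z
                if np.allclose(diff, 0.0):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_rel(x, z)
                rows.append(
                    dict(
                        model_1=a.model_tag,
                        model_2=b.model_tag,
                        metric=metric,
                        mean_1=float(np.mean(x)),
                        mean_2=float(np.mean(z)),
                        mean_diff=float(np.mean(diff)),
                        t=float(t),
                        p_value=float(p),
                    )
                )
    return pd.DataFrame(rows)
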