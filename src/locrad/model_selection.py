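"""Feature selection and logistic classification cascade.

The cascade, applied to a feature table of (sub-)regions with binary
recurrence labels:

1. exclude features whose Pearson correlation with the region voxel count
   exceeds 0.5 in magnitude (volume-confounded descriptors) and constant
   features (undefined correlation);
2. z-score the remainder and run principal component analysis on the
   correlation structure, retaining components by Horn's parallel analysis
   (eigenvalues above the 95th percentile of 1000 column-permutation nulls);
3. group features by their strongest absolute Spearman correlation to the
   retained component scores;
4. per group, keep the single feature with the largest univariate
   logistic-regression AUC, provided its Wald slope p-value is below 0.05;
5. fit a multivariable logistic regression on the representatives and prune
   it by backward elimination on the Akaike Information Criterion
   (AIC = 2k - 2 log L), removing while removal lowers the AIC.

The classification cut-off is the 75th percentile of the training-cohort
predictions.  Confidence intervals come from 2000 stratified (per-class)
bootstrap replicates of the AUC; evaluation for the fixed-size scheme is
leave-one-patient-out cross-validation with the full cascade re-run inside
every training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2, rankdata, spearmanr

__all__ = [
    "SelectionResult",
    "LogisticModel",
    "EvaluationResult",
    "filter_voxel_correlation",
    "horn_retained_components",
    "group_by_component",
    "select_representatives",
    "fit_backward_aic",
    "apply_model",
    "classification_cutoff",
    "bootstrap_auc_ci",
    "run_cascade",
    "loocv_patient",
    "rank_auc",
]

logger = logging.getLogger(__name__)

R_MAX = 0.5
P_MAX = 0.05
HORN_PERMUTATIONS = 1000
HORN_QUANTILE = 95.0
BOOTSTRAP_REPLICATES = 2000
CUTOFF_PERCENTILE = 75.0
RIDGE_PENALTY = 1e-6


@dataclass
class SelectionResult:
    """Book-keeping of the selection cascade (excluded and chosen features)."""

    excluded_by_voxel_correlation: dict[str, float] = field(default_factory=dict)
    excluded_constant: list[str] = field(default_factory=list)
    retained_features: list[str] = field(default_factory=list)
    retained_pc_count: int = 0
    groups: dict[str, int] = field(default_factory=dict)
    representatives: dict[int, dict] = field(default_factory=dict)


@dataclass(frozen=True)
class LogisticModel:
    """A fitted logistic classifier: p = sigmoid(intercept + coef . x)."""

    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    classification_cutoff: float = 0.5


@dataclass
class EvaluationResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    fold_aucs: list[float] = field(default_factory=list)


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic; ties get half credit."""
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


# ---------------------------------------------------------------------------
# Logistic fitting with a ridge-stabilised fallback


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Fit a logistic regression, returning (params, llf, pvalues).

    Tries the statsmodels MLE first; on non-convergence or separation the
    fit is stabilised with a tiny ridge penalty (1e-6 on the slopes) and the
    log-likelihood reported is the unpenalised one at the stabilised optimum.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation handled by the fallback
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.all(
            np.isfinite(res.params)
        ) and np.all(np.abs(res.params) < 1e6):
            return np.asarray(res.params), float(res.llf), np.asarray(res.pvalues)
    except Exception:
        pass
    params, llf, _ = _ridge_logit(Xc, y, RIDGE_PENALTY)
    # Wald statistics are unusable near separation (Hauck-Donner); report
    # likelihood-ratio p-values against the intercept-only model instead
    p1 = float(np.mean(y))
    llf0 = len(y) * (p1 * np.log(max(p1, 1e-12)) + (1 - p1) * np.log(max(1 - p1, 1e-12)))
    lr_p = float(chi2.sf(2.0 * (llf - llf0), df=max(Xc.shape[1] - 1, 1)))
    pvals = np.full(Xc.shape[1], lr_p)
    pvals[0] = 1.0
    return params, llf, pvals


def _ridge_logit(Xc: np.ndarray, y: np.ndarray, penalty: float):
    """Ridge-penalised logistic MLE (penalty on slopes only, not intercept)."""
    y = np.asarray(y, dtype=float)
    pen = np.full(Xc.shape[1], penalty)
    pen[0] = 0.0

    def negll(beta):
        eta = Xc @ beta
        # log(1 + exp(eta)) - y*eta, computed stably
        ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        return ll + 0.5 * np.sum(pen * beta**2)

    def grad(beta):
        p = expit(Xc @ beta)
        return Xc.T @ (p - y) + pen * beta

    beta0 = np.zeros(Xc.shape[1])
    res = optimize.minimize(negll, beta0, jac=grad, method="L-BFGS-B")
    beta = res.x
    p = expit(Xc @ beta)
    llf = float(np.sum(y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
    logger.info("logistic MLE unstable; ridge-stabilised fit used")
    return beta, llf, None


def _aic(llf: float, k: int) -> float:
    return 2.0 * k - 2.0 * llf


# ---------------------------------------------------------------------------
# Cascade stages


def filter_voxel_correlation(
    table: pd.DataFrame,
    feature_names,
    r_max: float = R_MAX,
) -> SelectionResult:
    """Drop features correlated with the sub-region voxel count (|r| > r_max).

    Volume-driven features would let the classifier learn region size rather
    than density texture; constant features are dropped too (their
    correlation is undefined).
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 rows, got {len(table)}")
    res = SelectionResult()
    nvox = table["roi_voxel_count"].to_numpy(dtype=float)
    nv_c = nvox - nvox.mean()
    nv_ss = float((nv_c**2).sum())
    for name in feature_names:
        x = table[name].to_numpy(dtype=float)
        xc = x - x.mean()
        x_ss = float((xc**2).sum())
        if x_ss == 0.0:
            res.excluded_constant.append(name)
            continue
        r = float((xc * nv_c).sum() / np.sqrt(x_ss * nv_ss)) if nv_ss > 0 else 0.0
        if abs(r) > r_max:
            res.excluded_by_voxel_correlation[name] = r
        else:
            res.retained_features.append(name)
    return res


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _correlation_eigenvalues(Z: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the correlation matrix of standardized Z."""
    n = Z.shape[0]
    s = np.linalg.svd(Z / np.sqrt(n), compute_uv=False)
    eig = np.zeros(Z.shape[1])
    eig[: s.size] = s**2
    return eig


def horn_retained_components(
    X: np.ndarray,
    n_permutations: int = HORN_PERMUTATIONS,
    quantile: float = HORN_QUANTILE,
    rng: np.random.Generator | None = None,
):
    """Horn's parallel analysis on the correlation structure.

    Columns are z-scored; the observed eigenvalues are compared, rank by
    rank, with the ``quantile`` percentile of eigenvalues from
    ``n_permutations`` null tables obtained by independently permuting each
    column.  Retention stops at the first component that does not beat its
    null.  Returns (retained count, PCA scores [n, retained], loadings).
    """
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError(f"need >= 3 rows and >= 2 features, got {X.shape}")
    Z = _standardize(X)
    if np.all(Z == 0):
        raise ValueError("all features constant: nothing to decompose")
    obs = _correlation_eigenvalues(Z)
    null = np.empty((n_permutations, p))
    for b in range(n_permutations):
        perm = rng.random((n, p)).argsort(axis=0)  # independent column shuffles
        null[b] = _correlation_eigenvalues(np.take_along_axis(Z, perm, axis=0))
    thresh = np.percentile(null, quantile, axis=0)
    retained = 0
    for k in range(p):
        if obs[k] > thresh[k]:
            retained += 1
        else:
            break
    # component scores and loadings from the observed decomposition
    _, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    scores = Z @ Vt[:retained].T if retained else np.empty((n, 0))
    loadings = Vt[:retained].T * s[:retained]
    return retained, scores, loadings


def group_by_component(
    X: np.ndarray, feature_names, scores: np.ndarray
) -> dict[str, int]:
    """Assign each feature to the retained component it tracks most closely.

    The criterion is the largest absolute Spearman correlation between the
    feature and the component scores (rank-based, so any monotone transform
    of a component maps to that component); ties go to the lower-index
    component.  No feature is orphaned.
    """
    n_comp = scores.shape[1]
    groups: dict[str, int] = {}
    for j, name in enumerate(feature_names):
        rhos = []
        for c in range(n_comp):
            rho = spearmanr(X[:, j], scores[:, c]).statistic
            rhos.append(0.0 if np.isnan(rho) else abs(float(rho)))
        groups[name] = int(np.argmax(rhos))  # argmax takes first (lowest) on ties
    return groups


def select_representatives(
    table: pd.DataFrame,
    groups: dict[str, int],
    y: np.ndarray,
    p_max: float = P_MAX,
) -> dict[int, dict]:
    """Per group, the feature with the largest univariate AUC at p < p_max.

    Univariate logistic regressions supply both the Wald slope p-value and
    the predictions whose AUC is ranked.  A group contributes nothing if no
    feature clears the p-value gate.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    reps: dict[int, dict] = {}
    for name, comp in groups.items():
        x = table[name].to_numpy(dtype=float)
        params, llf, pvals = _logit_fit(x[:, None], y)
        pred = expit(params[0] + params[1] * x)
        auc = rank_auc(y, pred)
        pval = float(pvals[1])
        if pval >= p_max or np.isnan(auc):
            continue
        cur = reps.get(comp)
        if cur is None or auc > cur["auc"]:
            reps[comp] = {"feature": name, "auc": auc, "p_value": pval}
    return reps


def fit_backward_aic(
    table: pd.DataFrame,
    features,
    y: np.ndarray,
) -> tuple[LogisticModel, list[float]]:
    """Multivariable logistic regression pruned by backward AIC elimination.

    Starting from the full model, the variable whose removal lowers the AIC
    the most is removed; elimination stops when no removal lowers the AIC.
    Returns the final model and the (non-increasing) AIC path.  An
    intercept-only model is a legal outcome when nothing is predictive.
    """
    features = list(features)
    y = np.asarray(y, dtype=float)

    def fit(feats):
        X = table[feats].to_numpy(dtype=float) if feats else np.empty((len(y), 0))
        params, llf, _ = _logit_fit(X, y)
        return params, _aic(llf, len(feats) + 1)

    params, aic = fit(features)
    path = [aic]
    while features:
        candidates = []
        for f in features:
            sub = [g for g in features if g != f]
            p_sub, aic_sub = fit(sub)
            candidates.append((aic_sub, f, sub, p_sub))
        best_aic, best_f, best_sub, best_params = min(candidates, key=lambda t: t[0])
        if best_aic < aic:
            features, params, aic = best_sub, best_params, best_aic
            path.append(aic)
            logger.info("backward AIC: removed %s (AIC %.3f)", best_f, aic)
        else:
            break
    return (
        LogisticModel(
            features=tuple(features),
            coefficients=tuple(float(b) for b in params[1:]),
            intercept=float(params[0]),
        ),
        path,
    )


def apply_model(model: LogisticModel, features: pd.DataFrame | dict) -> np.ndarray:
    """Predicted recurrence probability p = sigmoid(intercept + sum b_i x_i)."""
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise KeyError(f"missing model features: {missing}")
    eta = np.full(len(features), model.intercept)
    for name, beta in zip(model.features, model.coefficients):
        eta = eta + beta * features[name].to_numpy(dtype=float)
    return expit(eta)


def classification_cutoff(
    train_predictions, percentile: float = CUTOFF_PERCENTILE
) -> float:
    """The training-cohort prediction percentile used as decision threshold.

    Regions with p >= cutoff are classified recurrent, i.e. the top quartile
    of training predictions at the default 75th percentile.  Linear
    interpolation between order statistics, as everywhere in the package.
    """
    preds = np.asarray(train_predictions, dtype=float)
    if preds.size == 0:
        raise ValueError("no training predictions")
    return float(np.percentile(preds, percentile))


def bootstrap_auc_ci(
    y,
    predictions,
    n_replicates: int = BOOTSTRAP_REPLICATES,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> EvaluationResult:
    """Percentile CI of the AUC from stratified bootstrap replicates.

    Each replicate resamples with replacement within each class, preserving
    the original class counts exactly.  Replicates where the AUC is
    undefined cannot occur (both classes always present by construction).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = np.asarray(y, dtype=bool)
    predictions = np.asarray(predictions, dtype=float)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    point = rank_auc(y, predictions)
    n1, n0 = pos.size, neg.size
    pos_scores = predictions[pos]
    neg_scores = predictions[neg]
    if n_replicates * n1 * n0 <= 5 * 10**7:
        # vectorised Mann-Whitney over all replicates at once
        ps = pos_scores[rng.integers(0, n1, size=(n_replicates, n1))]
        ns = neg_scores[rng.integers(0, n0, size=(n_replicates, n0))]
        gt = (ps[:, :, None] > ns[:, None, :]).sum(axis=(1, 2))
        eq = (ps[:, :, None] == ns[:, None, :]).sum(axis=(1, 2))
        aucs = (gt + 0.5 * eq) / (n1 * n0)
    else:
        aucs = np.empty(n_replicates)
        for b in range(n_replicates):
            idx = np.concatenate(
                [rng.choice(pos, n1, replace=True), rng.choice(neg, n0, replace=True)]
            )
            aucs[b] = rank_auc(y[idx], predictions[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return EvaluationResult(auc=point, ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# The full cascade and patient-level LOOCV


@dataclass
class CascadeResult:
    selection: SelectionResult
    model: LogisticModel
    aic_path: list[float]
    cutoff: float
    train_predictions: np.ndarray


def run_cascade(
    table: pd.DataFrame,
    feature_names,
    r_max: float = R_MAX,
    p_max: float = P_MAX,
    cutoff_percentile: float = CUTOFF_PERCENTILE,
    rng: np.random.Generator | int | None = None,
) -> CascadeResult:
    """Run the full selection + modelling cascade on a training table.

    ``table`` must carry ``label`` (control/recurrent) and
    ``roi_voxel_count`` columns besides the features.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = (table["label"] == "recurrent").to_numpy()
    selection = filter_voxel_correlation(table, feature_names, r_max=r_max)
    retained = selection.retained_features
    if len(retained) < 2:
        raise ValueError("fewer than 2 features survive the voxel-count filter")
    X = table[retained].to_numpy(dtype=float)
    n_comp, scores, _ = horn_retained_components(X, rng=rng)
    selection.retained_pc_count = n_comp
    if n_comp == 0:
        logger.warning("parallel analysis retained no component; intercept-only model")
        model = LogisticModel(features=(), coefficients=(), intercept=0.0)
        preds = apply_model(model, table)
        return CascadeResult(selection, model, [], classification_cutoff(preds, cutoff_percentile), preds)
    selection.groups = group_by_component(X, retained, scores)
    selection.representatives = select_representatives(table, selection.groups, y, p_max=p_max)
    rep_features = [v["feature"] for v in selection.representatives.values()]
    if not rep_features:
        logger.warning("no group representative passed p < %.3g; intercept-only model", p_max)
        model, path = fit_backward_aic(table, [], y)
    else:
        model, path = fit_backward_aic(table, rep_features, y)
    preds = apply_model(model, table)
    cutoff = classification_cutoff(preds, cutoff_percentile)
    model = LogisticModel(model.features, model.coefficients, model.intercept, cutoff)
    return CascadeResult(selection, model, path, cutoff, preds)


def loocv_patient(
    table: pd.DataFrame,
    feature_names,
    r_max: float = R_MAX,
    p_max: float = P_MAX,
    rng: np.random.Generator | int | None = None,
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Leave-one-patient-out cross-validation of the full cascade.

    Only patients contributing both classes of sub-regions enter (others are
    excluded with a log message).  For every fold the entire cascade —
    voxel-count filter, parallel analysis, grouping, representatives,
    backward AIC — is re-run on the remaining patients; the held-out
    patient's sub-regions are then scored.  Folds with an undefined AUC
    (held-out patient single-class after exclusions) are reported as NaN,
    never dropped silently.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eligible = []
    for pid, grp in table.groupby("patient_id"):
        if grp["label"].nunique() == 2:
            eligible.append(pid)
        else:
            logger.info("LOOCV: patient %s excluded (single-class sub-regions)", pid)
    if len(eligible) < 3:
        raise ValueError(f"need >= 3 eligible patients, got {len(eligible)}")
    sub = table[table["patient_id"].isin(eligible)]
    records = []
    for pid in eligible:
        train = sub[sub["patient_id"] != pid]
        test = sub[sub["patient_id"] == pid]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        cascade = run_cascade(
            train, feature_names, r_max=r_max, p_max=p_max,
            rng=np.random.default_rng(fold_seed),
        )
        preds = apply_model(cascade.model, test)
        y_test = (test["label"] == "recurrent").to_numpy()
        auc = rank_auc(y_test, preds)
        records.append(
            {
                "patient_id": pid,
                "n_subregions": len(test),
                "n_recurrent": int(y_test.sum()),
                "auc": auc,
                "features": ";".join(cascade.model.features),
            }
        )
    folds = pd.DataFrame(records)
    defined = folds["auc"].dropna()
    result = EvaluationResult(
        auc=float(defined.mean()) if len(defined) else float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        fold_aucs=[float(a) for a in folds["auc"]],
    )
    return result, folds
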