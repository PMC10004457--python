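"""Two-stage two-group discrimination study over a radiomic feature table.

Stage 1 screens the 144 standardized features with an L1-penalized
(LASSO) binomial model: the penalty is chosen by stratified 5-fold
cross-validation at the minimum mean CV error (weighted binomial
deviance), with each sample weighted by its class's empirical prior
probability.  Stage 2 ranks the surviving features by a two-sided
Wilcoxon rank-sum test with Holm-Bonferroni adjustment, and reports per
feature: raw and adjusted p, per-group variances, the empirical ROC
curve with AUC and a stratified percentile-bootstrap 95% CI, and the
Youden-optimal operating point (SN, SP, informedness I = SN + SP - 1).

The recurrence group (LRRC) is the positive class, and higher feature
values score toward it; an AUC below 0.5 is reported as-is.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import l1_min_c
from statsmodels.stats.multitest import multipletests

from .features import CohortTable
from .imaging import Group

__all__ = [
    "standardize",
    "lasso_select",
    "wilcoxon_rank_sum",
    "holm_bonferroni",
    "roc_curve_auc",
    "auc_ci",
    "operating_point",
    "informedness",
    "FeatureResult",
    "DiscriminationReport",
    "run_discrimination",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stage 0: standardization


def standardize(table: CohortTable) -> CohortTable:
    """Z-score every feature across all samples (both groups pooled).

    Uses the n-1 standard deviation.  Zero-dispersion features carry no
    discriminative information and are dropped with a warning.
    """
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 samples")
    X = table.features
    sd = X.std(ddof=1)
    dead = sd[~(sd > 0)].index
    if len(dead):
        logger.warning("dropping %d zero-dispersion features: %s", len(dead), list(dead[:5]))
    keep = sd[sd > 0].index
    Z = (X[keep] - X[keep].mean()) / sd[keep]
    out = CohortTable.__new__(CohortTable)  # bypass the 144-column invariant
    out.features = Z
    out.labels = table.labels
    out.modality = table.modality
    out.skipped = list(table.skipped)
    return out


# ---------------------------------------------------------------------------
# Stage 1: LASSO screening


def _sample_weights(y: np.ndarray, weighting: str) -> np.ndarray:
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    prior = np.where(y == 1, n_pos / n, n_neg / n)
    if weighting == "prior":
        return prior
    if weighting == "inverse_prior":
        return 1.0 / (2.0 * prior)
    if weighting == "none":
        return np.ones(n)
    raise ValueError(f"unknown weighting {weighting!r}")


def _weighted_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


def _fit_l1(X, y, C, w):
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000, tol=1e-7, random_state=0
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y, sample_weight=w)
    return model


def lasso_select(
    table: CohortTable,
    *,
    folds: int = 5,
    seed: int = 0,
    weighting: str = "prior",
    n_lambdas: int = 60,
) -> tuple[list[str], pd.Series, dict]:
    """Screen features with cross-validated L1-penalized logistic regression.

    The penalty path descends from the value at which the first
    coefficient activates; the intercept-only (null) model is an explicit
    candidate, so on uninformative data the selection can be empty.  Ties
    in CV error resolve toward the sparser model.

    Returns ``(selected_keys, coefficients, info)`` with the keys ordered
    by decreasing |coefficient| in the full-data refit at the chosen
    penalty.
    """
    y = table.y()
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    X = table.features.to_numpy()
    w = _sample_weights(y, weighting)

    # CV folds must keep both classes; StratifiedKFold guarantees it when
    # each class has >= folds members.
    n_min = min(int(y.sum()), int((1 - y).sum()))
    if n_min < folds:
        raise ValueError(f"smallest class ({n_min}) cannot stratify into {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    c_min = l1_min_c(X, y, loss="log")
    Cs = c_min * np.logspace(-0.05, 3.0, n_lambdas)  # ascending C = descending penalty

    dev = np.zeros((folds, n_lambdas + 1))  # column 0: intercept-only null model
    for f, (tr, va) in enumerate(skf.split(X, y)):
        p0 = float(np.sum(w[tr] * y[tr]) / np.sum(w[tr]))
        dev[f, 0] = _weighted_deviance(y[va], np.full(va.size, p0), w[va])
        for j, C in enumerate(Cs):
            m = _fit_l1(X[tr], y[tr], C, w[tr])
            p = m.predict_proba(X[va])[:, 1]
            dev[f, j + 1] = _weighted_deviance(y[va], p, w[va])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))  # ties resolve to the sparser candidate

    if best == 0:
        logger.warning("LASSO CV error is minimized by the null model; empty selection")
        coefs = pd.Series(0.0, index=table.features.columns)
        info = {"chosen_C": None, "cv_error": float(mean_dev[0]), "null_error": float(mean_dev[0])}
        return [], coefs, info

    C_star = float(Cs[best - 1])
    full = _fit_l1(X, y, C_star, w)
    coefs = pd.Series(full.coef_[0], index=table.features.columns)
    nz = coefs[coefs != 0.0]
    selected = list(nz.reindex(nz.abs().sort_values(ascending=False).index).index)
    if not selected:
        logger.warning("LASSO full-data refit shrank every coefficient to zero")
    info = {
        "chosen_C": C_star,
        "cv_error": float(mean_dev[best]),
        "null_error": float(mean_dev[0]),
    }
    return selected, coefs, info


# ---------------------------------------------------------------------------
# Stage 2: univariate ranking


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have <= 10 members and the pooled
    values are tie-free; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def roc_curve_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC curve and AUC with the positive class scoring high.

    AUC is the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie),
    computed from rank sums so ties are handled exactly.  An AUC below
    0.5 is reported as-is (orientation is fixed, never flipped).
    """
    s = np.asarray(scores, dtype=float)
    yb = np.asarray(labels).astype(int)
    if yb.min() == yb.max():
        raise ValueError("both classes must be present")
    n_pos = int(yb.sum())
    n_neg = yb.size - n_pos
    ranks = sps.rankdata(s)
    auc = (ranks[yb == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(yb, s, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(auc)


def _auc_from_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for (reps, n_pos) vs (reps, n_neg) score matrices."""
    n_pos = pos.shape[1]
    n_neg = neg.shape[1]
    ranks = sps.rankdata(np.concatenate([pos, neg], axis=1), axis=1)
    return (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_ci(
    scores,
    labels,
    *,
    level: float = 0.95,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap confidence interval for the AUC.

    Each class is resampled with replacement within itself, so every
    replicate keeps both classes.
    """
    s = np.asarray(scores, dtype=float)
    yb = np.asarray(labels).astype(int)
    pos = s[yb == 1]
    neg = s[yb == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 samples per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, pos.size, size=(reps, pos.size))]
    bn = neg[rng.integers(0, neg.size, size=(reps, neg.size))]
    aucs = _auc_from_matrix(bp, bn)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, (alpha / 2.0, 1.0 - alpha / 2.0))
    return float(lo), float(hi)


def informedness(sn: float, sp: float) -> float:
    """Youden's J: informedness I = SN + SP - 1."""
    return sn + sp - 1.0


def operating_point(curve: pd.DataFrame) -> tuple[float, float, float, float]:
    """Youden-optimal threshold on an ROC curve.

    Maximizes J = SN + SP - 1; ties break toward higher specificity.
    Returns ``(sn, sp, informedness, threshold)``.
    """
    sn = curve["tpr"].to_numpy()
    sp = 1.0 - curve["fpr"].to_numpy()
    j = sn + sp - 1.0
    order = np.lexsort((-sp, -j))  # best J first, then highest SP
    i = order[0]
    return float(sn[i]), float(sp[i]), informedness(float(sn[i]), float(sp[i])), float(
        curve["threshold"].iloc[i]
    )


# ---------------------------------------------------------------------------
# Full study


@dataclass
class FeatureResult:
    feature: str
    rank: int
    lasso_coef: float
    p_raw: float
    p_holm: float
    var_pos: float           # sigma^2 in the recurrence group (standardized units)
    var_neg: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sn: float
    sp: float
    informedness: float
    threshold: float


@dataclass
class DiscriminationReport:
    modality: str
    n_pos: int
    n_neg: int
    folds: int
    seed: int
    weighting: str
    bootstrap_reps: int
    alpha: float
    selection_empty: bool
    selected: list[str]
    lasso_info: dict
    results: list[FeatureResult]
    config_hash: str = ""

    def significant(self) -> list[FeatureResult]:
        return [r for r in self.results if r.p_holm < self.alpha]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_table(self) -> pd.DataFrame:
        """Human-readable summary (Rank, RF, AUC, SN, SP, I and p-values)."""
        rows = [
            {
                "Rank": r.rank,
                "RF": r.feature,
                "AUC": r.auc,
                "AUC 95% CI": (r.auc_ci_low, r.auc_ci_high),
                "SN": r.sn,
                "SP": r.sp,
                "I": r.informedness,
                "p": r.p_raw,
                "p (Holm)": r.p_holm,
                "var LRRC": r.var_pos,
                "var NO LRRC": r.var_neg,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_discrimination(
    table: CohortTable,
    *,
    folds: int = 5,
    seed: int = 0,
    weighting: str = "prior",
    bootstrap_reps: int = 2000,
    alpha: float = 0.05,
    n_lambdas: int = 60,
) -> DiscriminationReport:
    """Standardize, LASSO-screen, then rank features univariately.

    If the LASSO selection is empty, the univariate stage runs on all
    features and the report is flagged ``selection_empty`` (the Holm
    family is then the full feature set, which is conservative).
    """
    counts = table.n_per_group()
    n_pos = counts[Group.LRRC]
    n_neg = counts[Group.NO_LRRC]
    if min(n_pos, n_neg) < 1:
        raise ValueError(f"both groups required: {counts}")

    z = standardize(table)
    selected, coefs, info = lasso_select(
        z, folds=folds, seed=seed, weighting=weighting, n_lambdas=n_lambdas
    )
    selection_empty = len(selected) == 0
    tested = list(z.features.columns) if selection_empty else selected

    y = z.y()
    praw = []
    for key in tested:
        vals = z.features[key].to_numpy()
        praw.append(wilcoxon_rank_sum(vals[y == 1], vals[y == 0]))
    padj = holm_bonferroni(praw)

    order = np.lexsort((np.asarray(praw), padj))  # adjusted-then-raw ascending
    results: list[FeatureResult] = []
    for rank, i in enumerate(order, start=1):
        key = tested[i]
        vals = z.features[key].to_numpy()
        curve, auc = roc_curve_auc(vals, y)
        if bootstrap_reps > 0:
            lo, hi = auc_ci(vals, y, reps=bootstrap_reps, seed=seed + 1 + i)
        else:
            lo = hi = auc
        sn, sp, inf, thr = operating_point(curve)
        results.append(
            FeatureResult(
                feature=key,
                rank=rank,
                lasso_coef=float(coefs.get(key, 0.0)),
                p_raw=float(praw[i]),
                p_holm=float(padj[i]),
                var_pos=float(np.var(vals[y == 1], ddof=1)),
                var_neg=float(np.var(vals[y == 0], ddof=1)),
                auc=auc,
                auc_ci_low=lo,
                auc_ci_high=hi,
                sn=sn,
                sp=sp,
                informedness=inf,
                threshold=thr,
            )
        )

    cfg = {
        "modality": table.modality.value,
        "folds": folds,
        "seed": seed,
        "weighting": weighting,
        "bootstrap_reps": bootstrap_reps,
        "alpha": alpha,
        "n_lambdas": n_lambdas,
    }
    return DiscriminationReport(
        modality=table.modality.value,
        n_pos=n_pos,
        n_neg=n_neg,
        folds=folds,
        seed=seed,
        weighting=weighting,
        bootstrap_reps=bootstrap_reps,
        alpha=alpha,
        selection_empty=selection_empty,
        selected=selected,
        lasso_info=info,
        results=results,
        config_hash=_config_hash(cfg),
    )
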