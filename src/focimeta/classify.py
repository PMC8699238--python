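"""Cluster-ID classification: how well does spatial cluster membership alone
predict the condition label?

The feature set is deliberately minimal - a one-hot indicator of the surviving
cluster per focus - so any calibrated classifier can at best rank foci by
their cluster's label-1 proportion.  That ceiling is computed exactly by
:func:`proportion_score_auc` (tied pairs count 0.5) and bounds the
cross-validated AUC of the fitted models; the evaluation therefore reports
chance-adjacent numbers honestly rather than optimistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .exceptions import ConfigError, EmptyInputError, ValidationError

MODEL_SPECS = ("gradient_boosted_trees", "random_forest", "logistic")
_PROB_CLIP = 1e-15


@dataclass
class EvalReport:
    """Cross-validated metrics for one model."""

    model_spec: str
    auc: float
    auc_pr: float
    logloss: float
    n_folds: int
    seed: int
    params: dict = field(default_factory=dict)


def encode_onehot(foci: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """One-hot encode the ``cluster_id`` column of a filtered foci table.

    Returns ``(X, y)`` with indicator columns in sorted cluster-id order and
    the binary label vector.  Requires at least two distinct clusters -
    a single surviving cluster carries no discriminative information.
    """
    if len(foci) == 0:
        raise EmptyInputError("no foci to encode")
    for col in ("cluster_id", "label"):
        if col not in foci.columns:
            raise ValidationError(f"foci table has no {col!r} column")
    ids = sorted(foci["cluster_id"].unique(), key=str)
    if len(ids) < 2:
        raise ValidationError("only one surviving cluster; nothing to discriminate")
    X = pd.DataFrame(
        {cid: (foci["cluster_id"] == cid).astype(np.int8).to_numpy() for cid in ids},
        index=foci.index,
    )
    y = foci["label"].to_numpy(dtype=int)
    return X, y


def dataset_from_contingency(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Expand a K x 2 count table into the per-focus dataset it determines.

    With cluster id as the only feature, the dataset is fully determined by
    its counts: the expansion emits exactly O(cluster, label) identical rows
    per cell in deterministic order (clusters in table order, label-1 rows
    first) and one-hot encodes them.
    """
    rows = []
    for cid, rec in table.iterrows():
        rows += [(cid, 1)] * int(rec["label1"])
        rows += [(cid, 0)] * int(rec["label0"])
    foci = pd.DataFrame(rows, columns=["cluster_id", "label"])
    return encode_onehot(foci)


def make_classifier(model_spec: str, seed: int = 0, **overrides):
    """Instantiate a model from the fixed menu with a reproducible seed."""
    if model_spec == "gradient_boosted_trees":
        params = dict(n_estimators=100, max_depth=6, learning_rate=0.3,
                      importance_type="gain", random_state=seed, n_jobs=1,
                      eval_metric="logloss")
        params.update(overrides)
        return XGBClassifier(**params)
    if model_spec == "random_forest":
        params = dict(n_estimators=200, random_state=seed, n_jobs=1)
        params.update(overrides)
        return RandomForestClassifier(**params)
    if model_spec == "logistic":
        params = dict(C=1.0, max_iter=1000, random_state=seed)
        params.update(overrides)
        return LogisticRegression(**params)
    raise ConfigError(f"unknown model_spec {model_spec!r}; one of {MODEL_SPECS}")


def _oof_probabilities(X, y, model_spec, n_folds, seed, **overrides) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValidationError(
            f"cannot stratify {n_folds} folds with class counts {counts.tolist()}"
        )
    # canonical row order (features then label) so pooled metrics do not
    # depend on how the caller happened to order identical rows
    order = np.lexsort(tuple(X.T) + (y,))
    Xs, ys = X[order], y[order]
    oof = np.empty(len(ys), dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(Xs, ys):
        model = make_classifier(model_spec, seed=seed, **overrides)
        model.fit(Xs[train], ys[train])
        oof[test] = model.predict_proba(Xs[test])[:, 1]
    return ys, oof


def crossval_evaluate(X, y, model_spec: str = "gradient_boosted_trees",
                      n_folds: int = 5, seed: int = 0, **overrides) -> EvalReport:
    """Stratified k-fold evaluation with pooled out-of-fold probabilities.

    AUC is the rank-based (Mann-Whitney) statistic with tied pairs scored
    0.5 - essential here because one-hot cluster data is massively tied;
    AUC-PR is step-integrated average precision; logloss clips probabilities
    to [1e-15, 1 - 1e-15].  Deterministic given the seed.
    """
    ys, oof = _oof_probabilities(X, np.asarray(y, dtype=int), model_spec,
                                 n_folds, seed, **overrides)
    clipped = np.clip(oof, _PROB_CLIP, 1 - _PROB_CLIP)
    return EvalReport(
        model_spec=model_spec,
        auc=float(roc_auc_score(ys, oof)),
        auc_pr=float(average_precision_score(ys, oof)),
        logloss=float(log_loss(ys, clipped)),
        n_folds=n_folds,
        seed=seed,
        params=dict(overrides),
    )


_SEARCH_SPACE = {
    "gradient_boosted_trees": {
        "n_estimators": [50, 100, 200],
        "max_depth": [2, 3, 4, 6],
        "learning_rate": [0.05, 0.1, 0.3],
    },
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
}


def random_search_evaluate(X, y, model_spec: str = "gradient_boosted_trees",
                           n_draws: int = 20, n_folds: int = 5,
                           seed: int = 0) -> EvalReport:
    """Seeded random hyperparameter search (at most ``n_draws`` draws), best
    cross-validated AUC wins.  Models without a search space fall back to a
    single default evaluation."""
    space = _SEARCH_SPACE.get(model_spec)
    if not space:
        return crossval_evaluate(X, y, model_spec, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(seed)
    seen, best = set(), None
    for _ in range(n_draws):
        draw = tuple((k, v[rng.integers(len(v))]) for k, v in sorted(space.items()))
        if draw in seen:
            continue
        seen.add(draw)
        report = crossval_evaluate(X, y, model_spec, n_folds=n_folds, seed=seed,
                                   **dict(draw))
        if best is None or report.auc > best.auc:
            best = report
    return best


def proportion_score_auc(table: pd.DataFrame) -> float:
    """Exact AUC of scoring every focus by its cluster's label-1 proportion.

    This is the Bayes-optimal ranking attainable from cluster identity alone,
    computed in closed form over all label-1/label-0 pairs with ties counted
    0.5.  Any cross-validated model on the same one-hot features is bounded
    by it (up to fold-estimation noise).
    """
    n1 = table["label1"].to_numpy(dtype=float)
    n0 = table["label0"].to_numpy(dtype=float)
    tot = n1 + n0
    keep = tot > 0
    n1, n0, tot = n1[keep], n0[keep], tot[keep]
    if n1.sum() == 0 or n0.sum() == 0:
        raise ValidationError("both labels must be present")
    p = n1 / tot
    order = np.argsort(p, kind="stable")
    n1, n0, p = n1[order], n0[order], p[order]
    wins = ties = 0.0
    for j in range(len(p)):
        lower = p < p[j]
        equal = p == p[j]
        wins += n1[j] * n0[lower].sum()
        ties += n1[j] * n0[equal].sum()
    return float((wins + 0.5 * ties) / (n1.sum() * n0.sum()))


def feature_importance(model, feature_names, X=None, y=None,
                       method: str = "gain", seed: int = 0) -> pd.DataFrame:
    """Per-indicator importances scaled so the maximum is 1.

    ``gain`` uses the tree ensemble's split-gain importances (error for
    models that have none); ``permutation`` is the model-agnostic
    alternative and needs ``X`` and ``y``.
    """
    if method == "gain":
        if not hasattr(model, "feature_importances_"):
            raise ConfigError(
                f"{type(model).__name__} exposes no split-gain importances; "
                "use method='permutation'"
            )
        raw = np.asarray(model.feature_importances_, dtype=float)
    elif method == "permutation":
        if X is None or y is None:
            raise ConfigError("permutation importance requires X and y")
        result = permutation_importance(model, np.asarray(X, float), y,
                                        scoring="roc_auc", n_repeats=10,
                                        random_state=seed)
        raw = np.maximum(result.importances_mean, 0.0)
    else:
        raise ConfigError(f"unknown method {method!r}")
    if len(raw) != len(feature_names):
        raise ValidationError("feature_names length does not match the model")
    top = raw.max()
    scaled = raw / top if top > 0 else raw
    out = pd.DataFrame({"importance": raw, "scaled_importance": scaled},
                       index=pd.Index(feature_names, name="feature"))
    return out.sort_values("importance", ascending=False)
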