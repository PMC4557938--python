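"""Niche classification: feature filtering, OVR linear SVMs under LOOV,
prediction confidence, F-scores, high-weight features and clustering.

Ecological niche labels are non-exclusive (a genome may be a biofilm former
*and* a plant pathogen), so classification is one-vs-rest: one independent
binary linear SVM per niche. Because cohorts are small relative to the
feature count, validation is leave-one-out (LOOV): each genome in turn is
held out, the SVM is trained on the rest — with the cost parameter C picked
by an internal stratified 10-fold cross-validation over a fixed grid — and
the held-out genome's predicted class and signed hyperplane distance are
recorded.

The confidence of a validation prediction with decision value x is

    confidence = 1 - integral_0^z phi(t) dt = 1.5 - Phi(z),

where z = |x| / SD(|decision values of the training positives|) and phi/Phi
are the standard normal density/CDF. Confidences of at least 0.95 are
flagged significant. Note the literal statistic is maximal at the
hyperplane; a conventional margin-centred variant is available via
``confidence_mode="centered"``.

Per-niche predictive power is summarised by the F-score (harmonic mean of
precision and recall of the positive class), and the most predictive
features are those whose final-model SVM weight lies more than two sample
standard deviations from the mean weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import NichecastError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary statistics

def f_score(tp: int, fp: int, fn: int) -> float:
    """F = 2PR/(P+R) with P = tp/(tp+fp), R = tp/(tp+fn).

    Undefined (NaN) when either denominator is zero; 0.0 by convention when
    precision and recall are both defined but zero.
    """
    if min(tp, fp, fn) < 0:
        raise NichecastError("confusion counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        return float("nan")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def confidence(
    decision_value: float,
    training_positive_distances: np.ndarray,
    mode: str = "literal",
) -> float:
    """Prediction confidence from the SVM decision value of a held-out sample.

    ``mode="literal"`` uses z = |decision| / SD(|positive training
    distances|); ``mode="centered"`` instead measures the decision value's
    deviation from the mean positive training distance before normalising.
    The returned value lies in (0.5, 1] and decreases as z grows.
    """
    d = np.abs(np.asarray(training_positive_distances, dtype=float))
    if d.size < 2:
        raise NichecastError("confidence needs at least 2 training positive distances")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise NichecastError(
            "standard deviation of positive training distances is 0; "
            "confidence is undefined for this classifier"
        )
    if mode == "centered":
        x = abs(decision_value - float(np.asarray(training_positive_distances, float).mean()))
    elif mode == "literal":
        x = abs(decision_value)
    else:
        raise NichecastError(f"unknown confidence mode {mode!r}")
    z = x / sd
    return float(1.0 - (norm.cdf(z) - 0.5))


def filter_features(
    features: pd.DataFrame,
    min_nonzero_fraction: float = 0.5,
    min_sd: float = 0.2,
) -> pd.DataFrame:
    """Keep features non-zero in more than ``min_nonzero_fraction`` of genomes
    and with sample standard deviation strictly greater than ``min_sd``.

    Both inequalities are strict, so a feature non-zero in exactly half the
    genomes, or with SD exactly at the floor, is dropped.
    """
    n = features.shape[0]
    if n == 0:
        raise NichecastError("empty feature matrix")
    nonzero = (features != 0).sum(axis=0)
    sd = features.std(axis=0, ddof=1)
    keep = (nonzero > min_nonzero_fraction * n) & (sd > min_sd)
    if not keep.any():
        raise NichecastError(
            f"feature filter removed all {features.shape[1]} features "
            f"(max nonzero fraction {nonzero.max() / n:.2f}, max SD {sd.max():.3f}); "
            f"thresholds: nonzero fraction > {min_nonzero_fraction}, SD > {min_sd}"
        )
    return features.loc[:, keep]


def high_weight_features(weights: pd.Series | np.ndarray) -> pd.Series:
    """Flag features whose weight deviates from the mean by more than 2 sample SDs."""
    w = pd.Series(weights) if not isinstance(weights, pd.Series) else weights
    if w.size < 3:
        raise NichecastError("high-weight extraction needs at least 3 features")
    sd = float(w.std(ddof=1))
    if sd == 0:
        log.warning("all feature weights identical; no high-weight features")
        return pd.Series(False, index=w.index)
    return (w - w.mean()).abs() > 2 * sd


# ---------------------------------------------------------------------------
# OVR SVM under leave-one-out validation

@dataclass
class SVMConfig:
    """Training configuration for the one-vs-rest LOOV SVMs.

    ``c_grid`` is searched by an internal stratified ``cv_folds``-fold CV on
    the training split; ties go to the smallest C. ``filter_per_fold`` refits
    the feature filter inside every LOOV round on the training genomes only,
    which removes the (mild) selection leakage of the default global filter.
    """

    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 10
    seed: int = 0
    apply_filter: bool = True
    filter_per_fold: bool = False
    min_nonzero_fraction: float = 0.5
    min_sd: float = 0.2
    confidence_mode: str = "literal"
    significance_level: float = 0.95
    class_weight: str | None = None  # None or "balanced"


@dataclass
class NicheReport:
    """LOOV outcome for one niche: per-genome predictions plus the final model."""

    niche: str
    predictions: pd.DataFrame  # genome-indexed: true, predicted, decision, confidence, significant, c_selected
    f_score: float
    c_final: float
    weights: pd.Series  # final model trained on all genomes
    high_weight: pd.Series
    fold_weights: pd.DataFrame  # one row per LOOV round, for inspection
    seed: int


@dataclass
class NichePredictionReport:
    """Bundle of per-niche LOOV reports for one feature set."""

    per_niche: dict[str, NicheReport] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def f_scores(self) -> pd.Series:
        return pd.Series({n: r.f_score for n, r in self.per_niche.items()}, name="f_score")


def _select_c(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> float:
    """Pick C from the grid by stratified k-fold CV accuracy; ties -> smallest C."""
    counts = np.bincount(y, minlength=2)
    n_splits = int(min(config.cv_folds, counts.min()))
    if n_splits < 2:
        log.warning("too few members of one class for internal CV; defaulting to smallest C")
        return min(config.c_grid)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    best_c, best_acc = None, -1.0
    for c in sorted(config.c_grid):
        accs = []
        for tr, te in folds:
            clf = SVC(kernel="linear", C=c, class_weight=config.class_weight)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_c, best_acc = c, acc
    return best_c


def loov_ovr_svm(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    config: SVMConfig | None = None,
) -> NichePredictionReport:
    """Train one-vs-rest linear SVMs with leave-one-out validation.

    For every niche column of ``labels`` with at least two positive and two
    negative genomes, each genome is held out once; the SVM trained on the
    remainder predicts its class. Reported per niche: per-genome predictions
    with decision values, confidences and significance flags; the LOOV
    F-score; and the weight vector (with high-weight flags) of a final model
    trained on all genomes with its own CV-selected C.

    Niches with fewer than two members of either class are skipped with a
    warning and listed in ``report.skipped``.
    """
    config = config or SVMConfig()
    if not features.index.equals(labels.index):
        missing = labels.index.difference(features.index).tolist() \
            + features.index.difference(labels.index).tolist()
        raise NichecastError(f"feature and label genome ids differ; offending ids: {missing}")

    base = filter_features(features, config.min_nonzero_fraction, config.min_sd) \
        if config.apply_filter and not config.filter_per_fold else features
    n = base.shape[0]
    report = NichePredictionReport()

    for niche in labels.columns:
        y = labels[niche].astype(bool).astype(int).to_numpy()
        n_pos, n_neg = int(y.sum()), int(n - y.sum())
        if n_pos < 2 or n_neg < 2:
            log.warning("niche %r skipped: %d positive / %d negative genomes (need >=2 each)",
                        niche, n_pos, n_neg)
            report.skipped.append(niche)
            continue

        rows = []
        fold_weights = []
        for i in range(n):
            train_mask = np.ones(n, dtype=bool)
            train_mask[i] = False
            if config.apply_filter and config.filter_per_fold:
                cols = filter_features(features.iloc[train_mask],
                                       config.min_nonzero_fraction, config.min_sd).columns
                Xdf = features[cols]
            else:
                Xdf = base
            X = Xdf.to_numpy(dtype=float)
            ytr = y[train_mask]
            if len(np.unique(ytr)) < 2:
                log.warning("niche %r, held-out %s: training fold degenerate (single class); "
                            "prediction undefined", niche, base.index[i])
                rows.append({"true": bool(y[i]), "predicted": None, "decision": np.nan,
                             "confidence": np.nan, "significant": False, "c_selected": np.nan})
                fold_weights.append(pd.Series(np.nan, index=Xdf.columns))
                continue
            c = _select_c(X[train_mask], ytr, config)
            clf = SVC(kernel="linear", C=c, class_weight=config.class_weight)
            clf.fit(X[train_mask], ytr)
            decision = float(clf.decision_function(X[i:i + 1])[0])
            pos_dist = clf.decision_function(X[train_mask][ytr == 1])
            conf = confidence(decision, pos_dist, config.confidence_mode)
            rows.append({
                "true": bool(y[i]),
                "predicted": decision > 0,
                "decision": decision,
                "confidence": conf,
                "significant": conf >= config.significance_level,
                "c_selected": c,
            })
            fold_weights.append(pd.Series(clf.coef_[0], index=Xdf.columns))

        preds = pd.DataFrame(rows, index=base.index.copy())
        preds.index.name = "genome"
        tp = int(((preds["true"]) & (preds["predicted"] == True)).sum())  # noqa: E712
        fp = int((~preds["true"] & (preds["predicted"] == True)).sum())  # noqa: E712
        fn = int((preds["true"] & (preds["predicted"] == False)).sum())  # noqa: E712
        f = 0.0 if tp == 0 else f_score(tp, fp, fn)

        c_final = _select_c(base.to_numpy(dtype=float), y, config)
        final = SVC(kernel="linear", C=c_final, class_weight=config.class_weight)
        final.fit(base.to_numpy(dtype=float), y)
        weights = pd.Series(final.coef_[0], index=base.columns, name="weight")

        report.per_niche[niche] = NicheReport(
            niche=niche,
            predictions=preds,
            f_score=float(f),
            c_final=float(c_final),
            weights=weights,
            high_weight=high_weight_features(weights),
            fold_weights=pd.DataFrame(fold_weights, index=base.index.copy())
                .reindex(columns=base.columns),
            seed=config.seed,
        )
    return report


# ---------------------------------------------------------------------------
# high-weight feature overlap across niches

def niche_overlap(feature_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive-membership summary of high-weight feature sets across niches.

    For every non-empty subset of niches, counts the features belonging to
    exactly that subset, with the percentage taken over the union of all
    sets (percentages sum to 100). One row per subset; boolean membership
    columns plus ``count`` and ``percent``.
    """
    niches = list(feature_sets)
    if len(niches) < 2:
        raise NichecastError("niche overlap needs at least 2 niches")
    union = set().union(*feature_sets.values())
    patterns: dict[tuple[bool, ...], int] = {}
    for feat in union:
        pat = tuple(feat in feature_sets[n] for n in niches)
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = []
    for size in range(1, len(niches) + 1):
        for subset in combinations(range(len(niches)), size):
            pat = tuple(i in subset for i in range(len(niches)))
            count = patterns.get(pat, 0)
            pct = 100.0 * count / len(union) if union else 0.0
            rows.append(dict(zip(niches, pat)) | {"count": count, "percent": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical clustering baseline

def cluster_profiles(
    features: pd.DataFrame,
    metric: str = "braycurtis",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of genomes over a feature matrix.

    Defaults to Bray-Curtis dissimilarity with group-average (UPGMA)
    linkage, the canonical pairing for count-profile community data. Returns
    the scipy linkage matrix plus the leaf labels in row order.
    """
    if features.shape[0] < 2:
        raise NichecastError("clustering needs at least 2 genomes")
    dist = pdist(features.to_numpy(dtype=float), metric=metric)
    if not np.isfinite(dist).all():
        raise NichecastError(f"non-finite pairwise {metric} distances (all-zero rows?)")
    Z = scipy_linkage(dist, method=method)
    return Z, [str(g) for g in features.index]


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a newick string with branch lengths."""
    root = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"
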