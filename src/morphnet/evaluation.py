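"""Performance metrics, baseline classifiers and the label-flip permutation test.

ASD is the positive class throughout, so sensitivity is the ASD detection
rate.  Baselines (random forest, SVM, XGBoost, autoencoder + logistic head)
consume the flattened 108 x 108 network, i.e. 11,664 features, and are
evaluated under the same cross-validation plan as the CNN.  The permutation
test follows the label-flip protocol: per iteration a uniformly random 20%
of the labels is inverted, the classifier is refit, and its accuracy enters
the empirical null; significance is the fraction of null accuracies reaching
the observed one (add-one estimator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classifier import CVPlan
from .network import MorphNetwork
from .nn import Adam, Dense, ReLU


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc: float | None
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)

    def as_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
        }


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion-matrix metrics at a score threshold plus AUC from the scores.

    Metrics whose denominator is empty (e.g. sensitivity with no positives)
    are reported as None rather than 0.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    f1 = None
    if prec is not None and sen is not None and (prec + sen) > 0:
        f1 = 2 * prec * sen / (prec + sen)
    auc = roc_auc(y, s) if len(np.unique(y)) == 2 else None
    return MetricsReport(
        accuracy=_safe_div(tp + tn, y.size),
        sensitivity=sen,
        specificity=spe,
        f1=f1,
        auc=auc,
        confusion=(tp, fp, tn, fn),
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability that a random positive outscores a random negative."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_curve_points(labels: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    empirical_p: float
    flip_fraction: float


def flip_labels(labels: np.ndarray, flip_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_flip = int(np.floor(flip_fraction * labels.size))
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    out = labels.copy()
    out[idx] = 1 - out[idx]
    return out


def permutation_test(
    fit_eval: Callable[[np.ndarray, np.ndarray], float],
    features: np.ndarray,
    labels: Sequence[int],
    n_perm: int = 5000,
    flip_fraction: float = 0.2,
    seed: int = 0,
    full_permutation: bool = False,
) -> PermutationResult:
    """Label-flip permutation test of classification accuracy.

    ``fit_eval(features, labels) -> accuracy`` is refit per iteration on
    labels with a random ``flip_fraction`` subset inverted (or a full label
    permutation when ``full_permutation``).  The empirical p-value uses the
    add-one estimator (1 + #{null >= observed}) / (1 + n_perm).
    """
    if not (0.0 < flip_fraction < 1.0):
        raise ValueError("flip_fraction must be in (0, 1)")
    y = np.asarray(labels, dtype=int)
    observed = float(fit_eval(features, y))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        if full_permutation:
            yb = y[rng.permutation(y.size)]
        else:
            yb = flip_labels(y, flip_fraction, rng)
        null[b] = fit_eval(features, yb)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        empirical_p=float(p),
        flip_fraction=flip_fraction,
    )


def make_logistic_surrogate(
    n_splits: int = 3, seed: int = 0
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Cross-validated accuracy of a logistic head on flattened features.

    A lightweight stand-in for full CNN retraining inside the permutation
    loop.  Stratified k-fold accuracy keeps the statistic fine-grained (one
    prediction per subject, so fewer ties in the permutation null) and the
    balanced class weight removes the majority-class advantage that label
    flipping would otherwise hand to the null refits.  The fold assignment
    is fixed across calls so only the labels vary.
    """

    def fit_eval(features: np.ndarray, labels: np.ndarray) -> float:
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        # label-free standardization: identical for the observed statistic
        # and every null refit, and it speeds dual coordinate descent a lot
        mu = features.mean(axis=0)
        sd = features.std(axis=0)
        sd[sd == 0] = 1.0
        x = (features - mu) / sd
        clf = LogisticRegression(
            solver="liblinear", dual=True, max_iter=50, tol=0.1,
            class_weight="balanced", random_state=seed,
        )
        cv = StratifiedKFold(n_splits, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return float(cross_val_score(clf, x, labels, cv=cv).mean())

    return fit_eval


# ---------------------------------------------------------------------------
# Baselines on flattened networks


def flatten_networks(networks: Iterable[MorphNetwork]) -> np.ndarray:
    """(N, n*n) feature matrix; 108 x 108 networks give 11,664 features."""
    return np.stack([net.flatten() for net in networks])


class DenseAutoencoder:
    """Fully connected autoencoder; reconstruction pretraining, then the
    frozen encoder's latent code feeds a logistic classification head."""

    def __init__(
        self,
        n_features: int,
        hidden: tuple[int, ...] = (512, 64),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        dims = [n_features, *hidden]
        self.encoder: list = []
        for a, b in zip(dims[:-1], dims[1:]):
            self.encoder += [Dense(a, b, rng=rng), ReLU()]
        self.encoder = self.encoder[:-1]  # linear bottleneck code
        self.decoder: list = []
        for a, b in zip(dims[::-1][:-1], dims[::-1][1:]):
            self.decoder += [Dense(a, b, rng=rng), ReLU()]
        self.decoder = self.decoder[:-1]  # linear output layer
        self.head = LogisticRegression(max_iter=500)

    def _params(self):
        return [p for lay in (*self.encoder, *self.decoder) for p in lay.parameters()]

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(np.float32)
        for lay in self.encoder:
            h = lay.forward(h, training=False)
        return h

    def pretrain(
        self,
        x: np.ndarray,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        rng = np.random.default_rng(seed)
        opt = Adam(self._params(), lr=lr)
        x = x.astype(np.float32)
        losses = []
        for _ in range(epochs):
            order = rng.permutation(x.shape[0])
            total = 0.0
            for start in range(0, x.shape[0], batch_size):
                idx = order[start : start + batch_size]
                h = x[idx]
                for lay in (*self.encoder, *self.decoder):
                    h = lay.forward(h, training=True)
                diff = h - x[idx]
                loss = float(np.mean(diff**2))
                opt.zero_grad()
                g = (2.0 * diff / diff.size).astype(np.float32)
                for lay in reversed((*self.encoder, *self.decoder)):
                    g = lay.backward(g)
                opt.step()
                total += loss * idx.size
            losses.append(total / x.shape[0])
        return losses

    def fit_head(self, x: np.ndarray, y: np.ndarray) -> None:
        self.head.fit(self.encode(x), y)

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self.encode(x))[:, 1]


BASELINE_METHODS = ("RF", "SVM", "XGB", "AE")


def run_baselines(
    networks: list[MorphNetwork],
    labels: Sequence[int],
    plan: CVPlan,
    methods: Sequence[str] = BASELINE_METHODS,
    seed: int = 0,
    ae_hidden: tuple[int, ...] = (512, 64),
    ae_epochs: int = 30,
) -> dict[str, MetricsReport]:
    """Train each baseline under the CNN's CV plan; pool test-fold scores.

    Per repeat, the model fits on the plan's training + validation subjects
    and scores the held-out test group; metrics are computed on the pooled
    test predictions across repeats.
    """
    unknown = set(m.upper() for m in methods) - set(BASELINE_METHODS)
    if unknown:
        raise ValueError(f"unknown baseline methods: {sorted(unknown)}")
    x = flatten_networks(networks)
    y = np.asarray(labels, dtype=int)
    reports: dict[str, MetricsReport] = {}
    for method in (m.upper() for m in methods):
        pooled_scores, pooled_labels = [], []
        threshold = 0.5
        for r in range(plan.n_repeats):
            train_idx, val_idx, test_idx = plan.split(r)
            fit_idx = np.concatenate([train_idx, val_idx])
            xtr, ytr = x[fit_idx], y[fit_idx]
            xte = x[test_idx]
            if method == "RF":
                clf = RandomForestClassifier(n_estimators=300, random_state=seed + r)
                clf.fit(xtr, ytr)
                scores = clf.predict_proba(xte)[:, 1]
            elif method == "SVM":
                # margin scores; the decision threshold for SVM sits at 0
                scaler = StandardScaler().fit(xtr)
                clf = SVC(kernel="rbf", random_state=seed + r)
                clf.fit(scaler.transform(xtr), ytr)
                scores = clf.decision_function(scaler.transform(xte))
                threshold = 0.0
            elif method == "XGB":
                from xgboost import XGBClassifier

                clf = XGBClassifier(
                    n_estimators=200,
                    max_depth=3,
                    learning_rate=0.1,
                    eval_metric="logloss",
                    random_state=seed + r,
                )
                clf.fit(xtr, ytr)
                scores = clf.predict_proba(xte)[:, 1]
            else:  # AE
                scaler = StandardScaler().fit(xtr)
                ae = DenseAutoencoder(x.shape[1], hidden=ae_hidden, seed=seed + r)
                ae.pretrain(scaler.transform(xtr), epochs=ae_epochs, seed=seed + r)
                ae.fit_head(scaler.transform(xtr), ytr)
                scores = ae.predict_scores(scaler.transform(xte))
            pooled_scores.extend(scores)
            pooled_labels.extend(y[test_idx])
        reports[method] = compute_metrics(pooled_labels, pooled_scores, threshold)
    return reports
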