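"""Training of the bottleneck residual classifier under nested 10-fold CV.

Subjects are randomly, equally partitioned into 10 groups S1..S10 for every
repeat; S10 is the held-out test group and the remaining nine groups are
repartitioned into 10 subgroups of which one serves as the validation set for
early stopping.  The whole plan is re-randomized per repeat (20 repeats by
default) and is fully determined by its seed.  Training minimizes binary
cross-entropy with Adam; the paper-faithful defaults are learning rate 1e-5
and minibatch size 32, while desk-scale runs typically raise the learning
rate and cap the epoch count (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MorphNetwork
from .nn import Adam, ModelConfig, ResNetClassifier, sigmoid

BCE_CLAMP = 1e-7


def bce_loss(y: float | np.ndarray, y_hat: float | np.ndarray) -> float | np.ndarray:
    """Binary cross-entropy -(y ln yhat + (1-y) ln(1-yhat)), clamped at 1e-7."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), BCE_CLAMP, 1.0 - BCE_CLAMP)
    out = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class Hyperparameters:
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20


@dataclass
class CVPlan:
    """Nested fold assignments for every repeat.

    ``outer[r, i]`` is subject i's outer group (1..n_folds) in repeat r; the
    test group is always the last one.  ``inner[r, i]`` is the inner subgroup
    (0..n_inner-1) for non-test subjects and -1 for test subjects;
    ``val_subgroup[r]`` marks which inner subgroup validates.
    """

    subject_ids: list[str]
    n_folds: int
    n_repeats: int
    outer: np.ndarray
    inner: np.ndarray
    val_subgroup: np.ndarray
    seed: int

    @property
    def test_group(self) -> int:
        return self.n_folds

    def split(self, repeat: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (train_idx, val_idx, test_idx) for one repeat."""
        test = np.nonzero(self.outer[repeat] == self.test_group)[0]
        non_test = self.outer[repeat] != self.test_group
        val = np.nonzero(non_test & (self.inner[repeat] == self.val_subgroup[repeat]))[0]
        train = np.nonzero(non_test & (self.inner[repeat] != self.val_subgroup[repeat]))[0]
        return train, val, test

    def partition_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.outer).tobytes())
        h.update(np.ascontiguousarray(self.inner).tobytes())
        h.update(np.ascontiguousarray(self.val_subgroup).tobytes())
        return h.hexdigest()


def make_cv_plan(
    phenotypes: pd.DataFrame,
    n_folds: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    n_inner: int | None = None,
) -> CVPlan:
    """Random equal partition into ``n_folds`` outer groups per repeat, with
    the non-test groups repartitioned into ``n_inner`` subgroups (default 10,
    one of them the validation set)."""
    subject_ids = list(phenotypes["subject_id"])
    n = len(subject_ids)
    if n < n_folds:
        raise ValueError(f"{n} subjects cannot fill {n_folds} folds")
    n_inner = n_inner or n_folds
    rng = np.random.default_rng(seed)
    outer = np.zeros((n_repeats, n), dtype=np.int32)
    inner = np.full((n_repeats, n), -1, dtype=np.int32)
    val_subgroup = np.zeros(n_repeats, dtype=np.int32)
    for r in range(n_repeats):
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, n_folds), start=1):
            outer[r, chunk] = fold
        non_test = np.nonzero(outer[r] != n_folds)[0]
        perm_in = rng.permutation(non_test)
        for sub, chunk in enumerate(np.array_split(perm_in, n_inner)):
            inner[r, chunk] = sub
        val_subgroup[r] = rng.integers(n_inner)
    return CVPlan(
        subject_ids=subject_ids,
        n_folds=n_folds,
        n_repeats=n_repeats,
        outer=outer,
        inner=inner,
        val_subgroup=val_subgroup,
        seed=seed,
    )


@dataclass
class TrainedModel:
    config: ModelConfig
    model: ResNetClassifier
    training_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(x)

    def save(self, path: str) -> None:
        """Checkpoint: architecture description + parameter payload (.npz)."""
        import dataclasses
        import json as _json

        state = self.model.get_state()
        np.savez_compressed(
            path,
            config=_json.dumps(dataclasses.asdict(self.config)),
            n_arrays=len(state),
            **{f"arr_{i}": a for i, a in enumerate(state)},
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        import json as _json

        with np.load(path, allow_pickle=False) as data:
            cfg_dict = _json.loads(str(data["config"]))
            cfg_dict["channels_per_stage"] = tuple(cfg_dict["channels_per_stage"])
            cfg = ModelConfig(**cfg_dict)
            model = ResNetClassifier(cfg)
            state = [data[f"arr_{i}"] for i in range(int(data["n_arrays"]))]
        model.set_state(state)
        return cls(config=cfg, model=model)


def networks_to_array(networks: list[MorphNetwork]) -> np.ndarray:
    """Stack similarity matrices into the (N, 1, n, n) classifier input."""
    return np.stack([net.matrix for net in networks]).astype(np.float32)[:, None]


def labels_from_phenotypes(phenotypes: pd.DataFrame) -> np.ndarray:
    """ASD is the positive class (1), TC the negative (0)."""
    return (phenotypes["dx"].to_numpy() == "ASD").astype(np.float64)


def train_single(
    model: ResNetClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fit one model with Adam + early stopping on validation BCE.

    Returns the per-epoch training log; the model is left holding the
    parameters of its best validation epoch.
    """
    opt = Adam(model.parameters(), lr=hyper.learning_rate)
    n = x_train.shape[0]
    bs = min(hyper.batch_size, n)
    best_val = np.inf
    best_state = model.get_state()
    patience_left = hyper.early_stop_patience
    log = []
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward_logits(xb, training=True)
            probs = sigmoid(logits)
            loss = float(np.mean(bce_loss(yb, probs)))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward_from_logits(
                ((probs - yb) / idx.size).astype(np.float32)
            )
            opt.step()
            epoch_loss += loss * idx.size
        epoch_loss /= n
        if x_val.shape[0] > 0:
            val_probs = model.predict_proba(x_val)
            val_loss = float(np.mean(bce_loss(y_val, val_probs)))
        else:
            val_loss = epoch_loss
        log.append({"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.get_state()
            patience_left = hyper.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.set_state(best_state)
    model.recalibrate_batch_norm(x_train)
    return pd.DataFrame(log)


def train(
    networks: list[MorphNetwork],
    phenotypes: pd.DataFrame,
    plan: CVPlan,
    model_config: ModelConfig | None = None,
    hyper: Hyperparameters | None = None,
) -> tuple[dict[int, TrainedModel], pd.DataFrame]:
    """Train one model per repeat on the plan's inner split; score S10.

    Returns the per-repeat trained models and a fold-result table with one
    row per (repeat, test subject): ``subject_id, repeat, fold, score,
    label, pred``.
    """
    model_config = model_config or ModelConfig()
    hyper = hyper or Hyperparameters()
    if len(networks) != len(phenotypes):
        raise ValueError("need exactly one network per phenotype row")
    x = networks_to_array(networks)
    y = labels_from_phenotypes(phenotypes)
    subject_ids = np.asarray(plan.subject_ids)
    models: dict[int, TrainedModel] = {}
    rows = []
    for r in range(plan.n_repeats):
        train_idx, val_idx, test_idx = plan.split(r)
        assert not (set(test_idx) & (set(train_idx) | set(val_idx)))
        cfg = ModelConfig(
            input_size=model_config.input_size,
            n_stages=model_config.n_stages,
            channels_per_stage=model_config.channels_per_stage,
            bottleneck_reduction=model_config.bottleneck_reduction,
            stage_stride=model_config.stage_stride,
            use_batch_norm=model_config.use_batch_norm,
            use_dropout=model_config.use_dropout,
            seed=int((model_config.seed * 1000003 + r) % (2**31)),
        )
        model = ResNetClassifier(cfg)
        rng = np.random.default_rng([plan.seed, 2, r])
        log = train_single(
            model, x[train_idx], y[train_idx], x[val_idx], y[val_idx], hyper, rng
        )
        trained = TrainedModel(config=cfg, model=model, training_log=log)
        models[r] = trained
        scores = model.predict_proba(x[test_idx])
        for i, s in zip(test_idx, scores):
            rows.append(
                {
                    "subject_id": subject_ids[i],
                    "repeat": r,
                    "fold": plan.test_group,
                    "score": float(s),
                    "label": int(y[i]),
                    "pred": int(s >= 0.5),
                }
            )
    return models, pd.DataFrame(rows)
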