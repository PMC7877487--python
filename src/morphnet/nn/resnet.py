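"""Five-stage bottleneck residual network for similarity-matrix images.

The classifier consumes a single-channel n x n matrix (108 x 108 by default)
and applies five serial bottleneck residual stages.  Each stage computes
F(X) + skip(X) where F is 1x1 reduce -> 3x3 (stride 2) -> 1x1 expand, every
convolution is followed by batch normalization before the activation, and the
skip is a stride-2 1x1 projection whenever resolution or width changes.
Global average pooling and a single linear unit produce the classification
logit; sigmoid(logit) is the predicted probability of the positive (ASD)
class.  Dropout is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm2d, Conv2d, Dense, GlobalAvgPool2d, Layer, ReLU, sigmoid


@dataclass
class ModelConfig:
    input_size: int = 108
    n_stages: int = 5
    channels_per_stage: tuple[int, ...] = (16, 32, 64, 128, 256)
    bottleneck_reduction: int = 4
    stage_stride: int = 2
    use_batch_norm: bool = True
    use_dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels_per_stage) != self.n_stages:
            raise ValueError("channels_per_stage must list one width per stage")
        if self.use_dropout:
            raise ValueError("dropout is not part of this architecture")
        size = self.input_size
        for _ in range(self.n_stages):
            size = -(-size // self.stage_stride)
        if size < 1 or self.input_size < 2**self.n_stages:
            raise ValueError(
                f"input_size {self.input_size} incompatible with "
                f"{self.n_stages} stride-{self.stage_stride} stages"
            )

    def stage_sizes(self) -> list[int]:
        sizes = [self.input_size]
        for _ in range(self.n_stages):
            sizes.append(-(-sizes[-1] // self.stage_stride))
        return sizes


class Bottleneck(Layer):
    """1x1 reduce -> 3x3 stride-s -> 1x1 expand, with projection skip."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: int,
        rng: np.random.Generator,
        reduction: int = 4,
        batch_norm: bool = True,
    ):
        c_mid = max(c_out // reduction, 1)
        self.conv1 = Conv2d(c_in, c_mid, 1, 1, bias=not batch_norm, rng=rng)
        self.conv2 = Conv2d(c_mid, c_mid, 3, stride, bias=not batch_norm, rng=rng)
        self.conv3 = Conv2d(c_mid, c_out, 1, 1, bias=not batch_norm, rng=rng)
        self.bn1 = BatchNorm2d(c_mid) if batch_norm else None
        self.bn2 = BatchNorm2d(c_mid) if batch_norm else None
        self.bn3 = BatchNorm2d(c_out) if batch_norm else None
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        self.project = stride != 1 or c_in != c_out
        if self.project:
            self.conv_skip = Conv2d(c_in, c_out, 1, stride, bias=not batch_norm, rng=rng)
            self.bn_skip = BatchNorm2d(c_out) if batch_norm else None

    def parameters(self) -> list:
        layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.project:
            layers += [self.conv_skip, self.bn_skip]
        return [p for lay in layers if lay is not None for p in lay.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, training)
        if self.bn1 is not None:
            h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        if self.bn2 is not None:
            h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        h = self.conv3.forward(h, training)
        if self.bn3 is not None:
            h = self.bn3.forward(h, training)
        if self.project:
            s = self.conv_skip.forward(x, training)
            if self.bn_skip is not None:
                s = self.bn_skip.forward(s, training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gm = g
        if self.bn3 is not None:
            gm = self.bn3.backward(gm)
        gm = self.conv3.backward(gm)
        gm = self.relu2.backward(gm)
        if self.bn2 is not None:
            gm = self.bn2.backward(gm)
        gm = self.conv2.backward(gm)
        gm = self.relu1.backward(gm)
        if self.bn1 is not None:
            gm = self.bn1.backward(gm)
        gm = self.conv1.backward(gm)
        if self.project:
            gs = g
            if self.bn_skip is not None:
                gs = self.bn_skip.backward(gs)
            gs = self.conv_skip.backward(gs)
        else:
            gs = g
        return gm + gs


class ResNetClassifier:
    """The full residual classifier; caches stage activations for Grad-CAM."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.stages: list[Bottleneck] = []
        c_in = 1
        for c_out in cfg.channels_per_stage:
            self.stages.append(
                Bottleneck(
                    c_in,
                    c_out,
                    cfg.stage_stride,
                    rng,
                    reduction=cfg.bottleneck_reduction,
                    batch_norm=cfg.use_batch_norm,
                )
            )
            c_in = c_out
        self.pool = GlobalAvgPool2d()
        self.fc = Dense(c_in, 1, rng=rng)
        self.stage_activations: list[np.ndarray] = []

    def parameters(self) -> list:
        params = [p for st in self.stages for p in st.parameters()]
        return params + self.fc.parameters()

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, 1, n, n) -> logits (N,).  Stage outputs are cached."""
        self.stage_activations = []
        h = np.asarray(x, dtype=np.float32)
        for st in self.stages:
            h = st.forward(h, training)
            self.stage_activations.append(h)
        h = self.pool.forward(h, training)
        return self.fc.forward(h, training)[:, 0]

    def backward_from_logits(
        self, dlogit: np.ndarray, to_stage: int | None = None
    ) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); must follow a forward pass.

        If ``to_stage`` is given, stop once the gradient with respect to that
        stage's *output* is available and return it; otherwise return the
        gradient with respect to the network input.
        """
        g = self.fc.backward(dlogit[:, None])
        g = self.pool.backward(g)
        for i in range(len(self.stages) - 1, -1, -1):
            if to_stage is not None and i == to_stage:
                return g
            g = self.stages[i].backward(g)
        return g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, training=False))

    def _batch_norms(self):
        for st in self.stages:
            for bn in (st.bn1, st.bn2, st.bn3, getattr(st, "bn_skip", None)):
                if bn is not None:
                    yield bn

    def recalibrate_batch_norm(self, x: np.ndarray, batch_size: int = 256) -> None:
        """Recompute batch-norm running statistics at the current weights.

        Running statistics trail the weights during optimization; one pass
        over the data with momentum 1 (averaged across batches) replaces them
        with the statistics the final weights actually produce, so that
        eval-mode inference matches the trained network.
        """
        momenta = [bn.momentum for bn in self._batch_norms()]
        for bn in self._batch_norms():
            bn.momentum = 1.0
        n = x.shape[0]
        n_batches = 0
        means = [np.zeros_like(bn.running_mean) for bn in self._batch_norms()]
        variances = [np.zeros_like(bn.running_var) for bn in self._batch_norms()]
        for start in range(0, n, batch_size):
            self.forward_logits(x[start : start + batch_size], training=True)
            for k, bn in enumerate(self._batch_norms()):
                means[k] += bn.running_mean
                variances[k] += bn.running_var
            n_batches += 1
        for k, (bn, mom) in enumerate(zip(self._batch_norms(), momenta)):
            bn.running_mean[...] = means[k] / n_batches
            bn.running_var[...] = variances[k] / n_batches
            bn.momentum = mom

    def get_state(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for st in self.stages:
            for bn in (st.bn1, st.bn2, st.bn3, getattr(st, "bn_skip", None)):
                if bn is not None:
                    state.append(bn.running_mean.copy())
                    state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p.data[...] = s
        i = len(params)
        for st in self.stages:
            for bn in (st.bn1, st.bn2, st.bn3, getattr(st, "bn_skip", None)):
                if bn is not None:
                    bn.running_mean[...] = state[i]
                    bn.running_var[...] = state[i + 1]
                    i += 2
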