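"""Multi-modal late-fusion residual network for tabular genomic regression.

Each input modality (environment one-hot, genomic features, interaction
features) is processed by its own stack of residual blocks; the last hidden
representations are concatenated and passed through a fusion stack of the
same block design, ending in a single linear output neuron.  A residual block
is

    dense(L2) -> batch-norm -> ReLU -> dense(L2) -> batch-norm
    -> (+ skip, linear projection when widths differ) -> ReLU -> dropout

with batch normalization applied before each activation.  Hidden widths halve
from the first layer onwards, N(l) = floor(N(1) / 2**(l-1)), clamped to >= 1.

Training minimizes mean-squared error plus L2 penalties with Adam, batches of
32, at most 48 epochs, a learning rate decaying as lr0 * exp(-wd * epoch),
and early stopping when the monitored loss (training loss by default) fails
to improve for ``patience`` consecutive epochs.  Responses are standardized
to zero mean and unit variance on the training set and de-standardized at
prediction.  Everything is implemented in numpy with explicit forward and
backward passes, so fixed-seed runs are bit-reproducible on one device.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "MultiModalNet",
    "derive_layer_widths",
    "build_network",
    "train",
    "predict",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def derive_layer_widths(N1: int, L: int) -> list[int]:
    """Halving width schedule: [floor(N1 / 2**(l-1)) for l in 1..L], clamped to >= 1."""
    if N1 < 1 or L < 1:
        raise ValueError("N1 and L must be >= 1")
    return [max(1, N1 >> (l - 1)) for l in range(1, L + 1)]


@dataclasses.dataclass
class ArchitectureSpec:
    """Shape of the multi-modal network.

    ``modality_depths[q]`` residual blocks for modality q, the first with
    ``modality_first_widths[q]`` units and later blocks following the halving
    rule; likewise ``fusion_depth`` / ``fusion_first_width`` for the stack
    after concatenation.  ``fusion_depth = 0`` feeds the concatenated modality
    outputs straight into the output neuron.
    """

    modality_depths: list[int]
    modality_first_widths: list[int]
    fusion_depth: int = 0
    fusion_first_width: int = 0

    def __post_init__(self) -> None:
        if len(self.modality_depths) != len(self.modality_first_widths):
            raise ValueError("per-modality depth and width lists must align")
        if any(d < 1 for d in self.modality_depths):
            raise ValueError("modality depths must be >= 1")
        if any(w < 1 for w in self.modality_first_widths):
            raise ValueError("modality first-layer widths must be >= 1")
        if self.fusion_depth < 0:
            raise ValueError("fusion depth must be >= 0")
        if self.fusion_depth > 0 and self.fusion_first_width < 1:
            raise ValueError("fusion width must be >= 1 when fusion_depth > 0")

    @property
    def Q(self) -> int:
        return len(self.modality_depths)

    def modality_widths(self, q: int) -> list[int]:
        return derive_layer_widths(self.modality_first_widths[q], self.modality_depths[q])

    def fusion_widths(self) -> list[int]:
        if self.fusion_depth == 0:
            return []
        return derive_layer_widths(self.fusion_first_width, self.fusion_depth)


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings for :func:`train`."""

    lambda_l2: float = 1e-6
    dropout: float = 0.0
    lr0: float = 1e-3
    weight_decay_rate: float = 0.0  # wd in lr(epoch) = lr0 * exp(-wd * epoch)
    patience: int = 48
    batch_size: int = 32
    epochs: int = 48
    seed: int = 0
    monitor: str = "train"  # early stopping monitors train loss by default

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0 or self.lr0 < 0 or self.weight_decay_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.patience < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("patience, batch_size and epochs must be >= 1")
        if self.monitor not in ("train", "val"):
            raise ValueError("monitor must be 'train' or 'val'")


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, suited to ReLU stacks
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        yield self, "W", True  # True: L2-penalized
        yield self, "b", False


class _BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * inv_std
        if training:
            self._xhat = xhat
            self._inv_std = inv_std
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.dgamma = (grad * xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        g = grad * self.gamma * self._inv_std
        return g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)

    def params(self):
        yield self, "gamma", False
        yield self, "beta", False


class _ResidualBlock:
    """dense-BN-ReLU-dense-BN + skip -> ReLU -> dropout."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.d1 = _Dense(n_in, n_out, rng)
        self.bn1 = _BatchNorm(n_out)
        self.d2 = _Dense(n_out, n_out, rng)
        self.bn2 = _BatchNorm(n_out)
        self.proj = _Dense(n_in, n_out, rng) if n_in != n_out else None
        self._h1 = None
        self._pre = None
        self._drop_mask = None

    def forward(self, x, training: bool, dropout: float, rng: np.random.Generator):
        a1 = self.bn1.forward(self.d1.forward(x, training), training)
        h1 = np.maximum(a1, 0.0)
        a2 = self.bn2.forward(self.d2.forward(h1, training), training)
        skip = self.proj.forward(x, training) if self.proj is not None else x
        pre = a2 + skip
        out = np.maximum(pre, 0.0)
        if training:
            self._h1 = h1
            self._pre = pre
            if dropout > 0.0:
                mask = (rng.random(out.shape) >= dropout) / (1.0 - dropout)
                self._drop_mask = mask
                out = out * mask
            else:
                self._drop_mask = None
        return out

    def backward(self, grad):
        if self._drop_mask is not None:
            grad = grad * self._drop_mask
        dpre = grad * (self._pre > 0)
        dh1 = self.d2.backward(self.bn2.backward(dpre))
        da1 = dh1 * (self._h1 > 0)
        dx = self.d1.backward(self.bn1.backward(da1))
        if self.proj is not None:
            dx = dx + self.proj.backward(dpre)
        else:
            dx = dx + dpre
        return dx

    def layers(self):
        out = [self.d1, self.bn1, self.d2, self.bn2]
        if self.proj is not None:
            out.append(self.proj)
        return out


class MultiModalNet:
    """Weights, shapes and normalization state of the fused network."""

    def __init__(self, arch: ArchitectureSpec, input_widths: list[int], seed: int = 0):
        if len(input_widths) != arch.Q:
            raise ValueError(
                f"expected {arch.Q} input widths, received {len(input_widths)}"
            )
        if any(w < 1 for w in input_widths):
            raise ValueError("every modality must have at least one input feature")
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.input_widths = list(input_widths)
        self.modality_stacks: list[list[_ResidualBlock]] = []
        for q in range(arch.Q):
            widths = arch.modality_widths(q)
            stack, w_in = [], input_widths[q]
            for w in widths:
                stack.append(_ResidualBlock(w_in, w, rng))
                w_in = w
            self.modality_stacks.append(stack)
        concat_w = sum(arch.modality_widths(q)[-1] for q in range(arch.Q))
        self.fusion_stack: list[_ResidualBlock] = []
        w_in = concat_w
        for w in arch.fusion_widths():
            self.fusion_stack.append(_ResidualBlock(w_in, w, rng))
            w_in = w
        self.out = _Dense(w_in, 1, rng)
        self._concat_splits = np.cumsum(
            [arch.modality_widths(q)[-1] for q in range(arch.Q)]
        )[:-1]
        self.y_mean = 0.0
        self.y_std = 1.0

    # --- plumbing -----------------------------------------------------------
    def _all_layers(self):
        for stack in self.modality_stacks:
            for block in stack:
                yield from block.layers()
        for block in self.fusion_stack:
            yield from block.layers()
        yield self.out

    def parameters(self):
        for layer in self._all_layers():
            yield from layer.params()

    def n_parameters(self) -> int:
        return sum(getattr(obj, name).size for obj, name, _ in self.parameters())

    def l2_penalty(self, lam: float) -> float:
        return lam * sum(
            float(np.sum(getattr(obj, name) ** 2))
            for obj, name, penalized in self.parameters()
            if penalized
        )

    # --- forward / backward -------------------------------------------------
    def forward(
        self,
        blocks: list[np.ndarray],
        training: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if len(blocks) != self.arch.Q:
            raise ValueError(f"expected {self.arch.Q} modality blocks, got {len(blocks)}")
        for q, (x, w) in enumerate(zip(blocks, self.input_widths)):
            if x.shape[1] != w:
                raise ValueError(
                    f"modality {q}: input width {x.shape[1]} != trained width {w}"
                )
        outs = []
        for stack, x in zip(self.modality_stacks, blocks):
            h = x
            for block in stack:
                h = block.forward(h, training, dropout, rng)
            outs.append(h)
        h = np.concatenate(outs, axis=1)
        for block in self.fusion_stack:
            h = block.forward(h, training, dropout, rng)
        return self.out.forward(h, training)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        grad = self.out.backward(dpred[:, np.newaxis])
        for block in reversed(self.fusion_stack):
            grad = block.backward(grad)
        parts = np.split(grad, self._concat_splits, axis=1)
        for stack, g in zip(self.modality_stacks, parts):
            for block in reversed(stack):
                g = block.backward(g)


def build_network(
    arch: ArchitectureSpec, input_widths: list[int], seed: int = 0
) -> MultiModalNet:
    """Deterministically initialized network; same seed gives identical weights."""
    return MultiModalNet(arch, input_widths, seed=seed)


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = [(obj, name, pen) for obj, name, pen in params]
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in self.entries]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in self.entries]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float, lam: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, (obj, name, penalized) in enumerate(self.entries):
            grad = getattr(obj, "d" + name)
            if penalized and lam > 0:
                grad = grad + 2.0 * lam * getattr(obj, name)
            self.m[k] = b1 * self.m[k] + (1 - b1) * grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            setattr(
                obj,
                name,
                getattr(obj, name) - lr * mhat / (np.sqrt(vhat) + self.eps),
            )


def train(
    net: MultiModalNet,
    blocks: list[np.ndarray],
    y: np.ndarray,
    cfg: TrainConfig,
    val_blocks: list[np.ndarray] | None = None,
    val_y: np.ndarray | None = None,
) -> tuple[MultiModalNet, pd.DataFrame]:
    """Adam/MSE training with exponential learning-rate decay and early stopping.

    Responses are standardized on the training data (mean/sd stored on the
    network).  The per-epoch training loss is the batch-weighted mean squared
    error on the standardized scale; early stopping triggers after
    ``cfg.patience`` consecutive epochs without improvement of the monitored
    loss.  Returns the trained network and a history table (epoch,
    train_loss, val_loss, lr).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("modality blocks and response length disagree")
    net.y_mean = float(np.mean(y))
    net.y_std = float(np.std(y))
    if net.y_std == 0.0:
        net.y_std = 1.0
    ys = (y - net.y_mean) / net.y_std
    ys_val = None
    if val_blocks is not None and val_y is not None:
        ys_val = (np.asarray(val_y, dtype=float) - net.y_mean) / net.y_std

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 57111]))
    adam = _Adam(net.parameters())
    best = np.inf
    stall = 0
    history = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr0 * np.exp(-cfg.weight_decay_rate * epoch)
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            # sorted within the batch: membership is shuffled, but a stable
            # row order keeps floating-point reductions reproducible
            idx = np.sort(order[start : start + cfg.batch_size])
            xb = [b[idx] for b in blocks]
            yb = ys[idx]
            pred = net.forward(xb, training=True, dropout=cfg.dropout, rng=rng)
            err = pred - yb
            batch_mse = float(np.mean(err**2))
            if not np.isfinite(batch_mse):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            sq_sum += float(np.sum(err**2))
            net.backward(2.0 * err / len(idx))
            adam.step(lr, cfg.lambda_l2)
        train_loss = sq_sum / n
        val_loss = np.nan
        if ys_val is not None:
            val_pred = net.forward(val_blocks, training=False)
            val_loss = float(np.mean((val_pred - ys_val) ** 2))
        history.append((epoch, train_loss, val_loss, lr))
        monitored = val_loss if (cfg.monitor == "val" and ys_val is not None) else train_loss
        if monitored < best:
            best = monitored
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss", "lr"])
    return net, hist


def predict(net: MultiModalNet, blocks: list[np.ndarray]) -> np.ndarray:
    """Deterministic inference pass (running batch-norm statistics, no dropout),
    de-standardized back to the response scale."""
    pred = net.forward(blocks, training=False)
    return pred * net.y_std + net.y_mean
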