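"""Cross-branch attention convolutional network.

Three 1-D convolutional branches with kernel sizes 3/5/7 process the same
(p+q) x m double-embedding matrix; the branches share depth (3 layers of 100
filters by default) but differ in kernel size, so they see the sequence at
different granularities.  After every layer each branch is globally
max-pooled to a fixed-length vector, and a per-layer attention module scores
the three branch vectors, softmaxes the scores into weights on the 3-simplex,
and returns their weighted average.  The three per-layer fused vectors are
concatenated and a fully connected softmax head yields the two class
probabilities (binding site present / absent).

Everything is implemented directly on NumPy arrays with hand-written
gradients; `forward` returns a trace exposing every intermediate, and
`backward` consumes it.  Convolutions are valid (no padding), stride 1, no
dilation, realized as im2col + GEMM in float32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .errors import ConfigError, ShapeError
from .encoding import DEFAULT_MAX_WORDS

CHECKPOINT_FORMAT_VERSION = 1

# name -> (fn, derivative expressed in terms of the *output*)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda out: (out > 0).astype(out.dtype)),
    "tanh": (np.tanh, lambda out: 1.0 - out**2),
    "identity": (lambda z: z, lambda out: np.ones_like(out)),
}


def _act(name: str):
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ConfigError(f"unknown activation {name!r}") from None


@dataclass
class ModelConfig:
    """Architecture and initialization hyperparameters.

    ``head_activation`` defaults to identity so the classifier logits are
    unbounded; a bounded head (e.g. tanh) is configurable but saturates the
    softmax probabilities.
    """

    input_dim: int
    kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    layers_per_branch: int = 3
    filters_per_layer: int = 100
    max_words: int = DEFAULT_MAX_WORDS
    conv_activation: str = "relu"
    attention_activation: str = "tanh"
    head_activation: str = "identity"
    num_classes: int = 2
    attention_init_std: float = 0.1
    masked_pooling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != 3:
            raise ConfigError("exactly 3 branch kernel sizes are required")
        if any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigError("kernel sizes must be odd and >= 1")
        if self.filters_per_layer < 1 or self.layers_per_branch < 1:
            raise ConfigError("filters and layers must be >= 1")
        if self.input_dim < 1:
            raise ConfigError("input_dim must be >= 1")
        for name in (self.conv_activation, self.attention_activation,
                     self.head_activation):
            _act(name)
        # A batch must stay wide enough for the deepest valid convolution.
        need = receptive_field(max(self.kernel_sizes), self.layers_per_branch)
        if self.max_words < need:
            raise ConfigError(
                f"max_words={self.max_words} smaller than the deepest "
                f"receptive field {need}"
            )


@dataclass
class CbanModel:
    """Parameter container: three conv branches, per-layer attention, FC head."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


@dataclass
class ForwardTrace:
    """All intermediates of one forward pass (used by backward and by tests)."""

    branch_maps: list[list[np.ndarray]]      # [branch][layer] -> (B, F, M')
    pooled: list[list[np.ndarray]]           # [branch][layer] -> (B, F)
    attention_weights: list[np.ndarray]      # [layer] -> (B, 3)
    fused: list[np.ndarray]                  # [layer] -> (B, F)
    y_out: np.ndarray                        # (B, 3F)
    logits: np.ndarray                       # (B, num_classes) pre-softmax g(z)
    probs: np.ndarray                        # (B, num_classes)
    _cache: dict = field(default_factory=dict, repr=False)


def receptive_field(kernel: int, layer: int) -> int:
    """Input span seen by one feature of layer ``layer`` (1-based).

    For stacked valid convolutions with stride 1 and no dilation the span
    grows by (kernel - 1) per layer: 1 + layer * (kernel - 1).
    """
    if kernel < 1 or layer < 1:
        raise ValueError("kernel and layer must be >= 1")
    return 1 + layer * (kernel - 1)


def init_model(config: ModelConfig) -> CbanModel:
    """Allocate parameters; identical seeds give bit-identical models.

    Convolution and FC weights use fan-in-scaled (He) normal initialization;
    attention vectors are drawn from N(0, attention_init_std^2).
    """
    rng = np.random.default_rng(config.seed)
    F = config.filters_per_layer
    params: dict[str, np.ndarray] = {}
    for j, k in enumerate(config.kernel_sizes):
        c_in = config.input_dim
        for i in range(config.layers_per_branch):
            std = np.sqrt(2.0 / (c_in * k))
            params[f"conv{j}_{i}_W"] = rng.normal(
                0.0, std, size=(F, c_in, k)
            ).astype(np.float32)
            params[f"conv{j}_{i}_b"] = np.zeros(F, dtype=np.float32)
            c_in = F
    for i in range(config.layers_per_branch):
        params[f"attn{i}_w"] = rng.normal(
            0.0, config.attention_init_std, size=F
        ).astype(np.float32)
    fan_in = config.layers_per_branch * F
    params["fc_W"] = rng.normal(
        0.0, np.sqrt(2.0 / fan_in), size=(config.num_classes, fan_in)
    ).astype(np.float32)
    params["fc_b"] = np.zeros(config.num_classes, dtype=np.float32)
    return CbanModel(config=config, params=params)


# ---------------------------------------------------------------------------
# primitive operations (each usable standalone; forward() composes them)
# ---------------------------------------------------------------------------

def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D cross-correlation along the word axis via im2col + GEMM."""
    B, C, M = x.shape
    F, Cw, K = W.shape
    if Cw != C:
        raise ShapeError(f"input has {C} channels, kernel expects {Cw}")
    if M < K:
        raise ShapeError(f"input width {M} narrower than kernel {K}")
    Mo = M - K + 1
    cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)  # (B,C,Mo,K)
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
        B * Mo, C * K
    )
    out = cols2 @ W.reshape(F, C * K).T
    out += b
    out = out.reshape(B, Mo, F).transpose(0, 2, 1)
    return out, cols2


def _conv1d_backward(dout, cols2, W, x_shape, need_dx=True):
    B, C, M = x_shape
    F, _, K = W.shape
    Mo = M - K + 1
    d2 = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(B * Mo, F)
    dW = (d2.T @ cols2).reshape(F, C, K)
    db = d2.sum(axis=0)
    dx = None
    if need_dx:
        dcols = (d2 @ W.reshape(F, C * K)).reshape(B, Mo, C, K)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, Mo, K)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for t in range(K):
            dx[:, :, t : t + Mo] += dcols[:, :, :, t]
    return dW, db, dx


def branch_layer(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One convolutional layer: f(W * x + b), valid, stride 1."""
    fn, _ = _act(activation)
    out, _ = _conv1d(x, W, b)
    return fn(out)


def pool(x: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
    """Global max over the word axis, per channel.

    ``lengths`` optionally restricts the max to the first ``lengths[b]``
    positions of each sample (masked pooling, neutralizing zero-padding
    artifacts); by default the whole map is pooled, so an all-negative map
    with a padded zero tail pools to 0.
    """
    if x.ndim == 2:
        x = x[None]
    if x.shape[2] < 1:
        raise ShapeError("cannot pool an empty feature map")
    if lengths is None:
        return x.max(axis=2)
    pos = np.arange(x.shape[2])
    invalid = pos[None, :] >= np.maximum(np.asarray(lengths), 1)[:, None]
    masked = np.where(invalid[:, None, :], -np.inf, x)
    return masked.max(axis=2)


def attention_fuse(
    y1: np.ndarray,
    y2: np.ndarray,
    y3: np.ndarray,
    w_a: np.ndarray,
    activation: str = "tanh",
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-weighted average of the three branch vectors.

    Scores are g(w_a . Y_j) per branch; their softmax lies on the 3-simplex
    and weights the branch vectors.  Returns ``(fused, weights)``.
    """
    ys = [np.atleast_2d(y) for y in (y1, y2, y3)]
    if not (ys[0].shape == ys[1].shape == ys[2].shape):
        raise ShapeError("branch vectors differ in shape")
    stack = np.stack(ys, axis=1)  # (B, 3, F)
    fn, _ = _act(activation)
    scores = fn(stack @ w_a)  # (B, 3)
    a = _softmax(scores)
    fused = np.einsum("bj,bjf->bf", a, stack)
    return fused, a


def fuse_levels(*fused_layers: np.ndarray) -> np.ndarray:
    """Concatenate the per-layer fused vectors in layer order."""
    if not fused_layers:
        raise ShapeError("no levels to fuse")
    mats = [np.atleast_2d(y) for y in fused_layers]
    if len({m.shape[0] for m in mats}) != 1:
        raise ShapeError("levels disagree on batch size")
    return np.concatenate(mats, axis=1)


def classify(
    y_out: np.ndarray,
    W_fc: np.ndarray,
    b_fc: np.ndarray,
    activation: str = "identity",
) -> np.ndarray:
    """Softmax(g(W_fc y_out + b_fc)) -> class probabilities."""
    y_out = np.atleast_2d(y_out)
    if y_out.shape[1] != W_fc.shape[1]:
        raise ShapeError(
            f"feature length {y_out.shape[1]} != FC fan-in {W_fc.shape[1]}"
        )
    fn, _ = _act(activation)
    logits = fn(y_out @ W_fc.T + b_fc)
    return _softmax(logits)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def forward(
    model: CbanModel, batch: np.ndarray, lengths: np.ndarray | None = None
) -> ForwardTrace:
    """Run the full network on a padded batch of shape (B, p+q, M).

    ``lengths`` gives the unpadded word count per sample and is only used
    when ``config.masked_pooling`` is on.
    """
    cfg = model.config
    if batch.ndim != 3 or batch.shape[1] != cfg.input_dim:
        raise ShapeError(
            f"batch shape {batch.shape} incompatible with input_dim "
            f"{cfg.input_dim}"
        )
    conv_fn, _ = _act(cfg.conv_activation)
    attn_fn, _ = _act(cfg.attention_activation)
    head_fn, _ = _act(cfg.head_activation)

    nb, nl = 3, cfg.layers_per_branch
    branch_maps: list[list[np.ndarray]] = [[] for _ in range(nb)]
    pooled: list[list[np.ndarray]] = [[] for _ in range(nb)]
    cache: dict = {"cols": [[None] * nl for _ in range(nb)],
                   "pool_idx": [[None] * nl for _ in range(nb)],
                   "x_shapes": [[None] * nl for _ in range(nb)]}

    for j in range(nb):
        x = batch
        cur_len = lengths
        for i in range(nl):
            W = model.params[f"conv{j}_{i}_W"]
            b = model.params[f"conv{j}_{i}_b"]
            cache["x_shapes"][j][i] = x.shape
            out, cols2 = _conv1d(x, W, b)
            out = conv_fn(out)
            cache["cols"][j][i] = cols2
            branch_maps[j].append(out)
            if cfg.masked_pooling and cur_len is not None:
                cur_len = cur_len - (cfg.kernel_sizes[j] - 1)
                idx = _masked_argmax(out, cur_len)
            else:
                idx = out.argmax(axis=2)
            cache["pool_idx"][j][i] = idx
            y = np.take_along_axis(out, idx[:, :, None], axis=2)[:, :, 0]
            pooled[j].append(y)
            x = out

    attention_weights: list[np.ndarray] = []
    fused: list[np.ndarray] = []
    cache["attn_stack"] = []
    cache["attn_scores"] = []
    for i in range(nl):
        w_a = model.params[f"attn{i}_w"]
        stack = np.stack([pooled[j][i] for j in range(nb)], axis=1)  # (B,3,F)
        scores = attn_fn(stack @ w_a)
        a = _softmax(scores)
        fused_i = np.einsum("bj,bjf->bf", a, stack)
        cache["attn_stack"].append(stack)
        cache["attn_scores"].append(scores)
        attention_weights.append(a)
        fused.append(fused_i)

    y_out = np.concatenate(fused, axis=1)
    z = y_out @ model.params["fc_W"].T + model.params["fc_b"]
    logits = head_fn(z)
    probs = _softmax(logits)
    cache["y_out"] = y_out
    cache["head_z"] = z
    return ForwardTrace(
        branch_maps=branch_maps,
        pooled=pooled,
        attention_weights=attention_weights,
        fused=fused,
        y_out=y_out,
        logits=logits,
        probs=probs,
        _cache=cache,
    )


def _masked_argmax(out: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    masked = out.copy()
    pos = np.arange(out.shape[2])
    invalid = pos[None, :] >= np.maximum(lengths, 1)[:, None]
    masked[np.broadcast_to(invalid[:, None, :], out.shape)] = -np.inf
    return masked.argmax(axis=2)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of softmax outputs against 0/1 labels."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.log(p).mean())


def backward(
    model: CbanModel, trace: ForwardTrace, labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    cfg = model.config
    cache = trace._cache
    _, conv_d = _act(cfg.conv_activation)
    _, attn_d = _act(cfg.attention_activation)
    _, head_d = _act(cfg.head_activation)
    nb, nl = 3, cfg.layers_per_branch
    B = trace.probs.shape[0]
    grads: dict[str, np.ndarray] = {}

    dlogits = trace.probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    dz = dlogits * head_d(trace.logits)
    grads["fc_W"] = dz.T @ cache["y_out"]
    grads["fc_b"] = dz.sum(axis=0)
    dy_out = dz @ model.params["fc_W"]

    F = cfg.filters_per_layer
    # gradient flowing into each branch's pooled vector at each layer
    dpooled = [[None] * nl for _ in range(nb)]
    for i in range(nl):
        w_a = model.params[f"attn{i}_w"]
        stack = cache["attn_stack"][i]          # (B, 3, F)
        scores = cache["attn_scores"][i]        # g output, (B, 3)
        a = trace.attention_weights[i]
        dfused = dy_out[:, i * F : (i + 1) * F]  # (B, F)
        dstack = a[:, :, None] * dfused[:, None, :]
        da = np.einsum("bf,bjf->bj", dfused, stack)
        ds = a * (da - (a * da).sum(axis=1, keepdims=True))  # softmax jac
        dz_score = ds * attn_d(scores)
        grads[f"attn{i}_w"] = np.einsum("bj,bjf->f", dz_score, stack)
        dstack += dz_score[:, :, None] * w_a[None, None, :]
        for j in range(nb):
            dpooled[j][i] = dstack[:, j, :]

    for j in range(nb):
        dmap = None  # gradient w.r.t. branch j's layer-i output map
        for i in reversed(range(nl)):
            out = trace.branch_maps[j][i]
            d = np.zeros_like(out)
            idx = cache["pool_idx"][j][i][:, :, None]
            np.put_along_axis(d, idx, dpooled[j][i][:, :, None], axis=2)
            if dmap is not None:
                d += dmap
            d *= conv_d(out)
            W = model.params[f"conv{j}_{i}_W"]
            dW, db, dx = _conv1d_backward(
                d, cache["cols"][j][i], W, cache["x_shapes"][j][i],
                need_dx=(i > 0),
            )
            grads[f"conv{j}_{i}_W"] = dW
            grads[f"conv{j}_{i}_b"] = db
            dmap = dx
    return grads


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: CbanModel, path) -> None:
    """Serialize parameters plus config into a single .npz checkpoint."""
    meta = json.dumps(
        {"format_version": CHECKPOINT_FORMAT_VERSION,
         "config": asdict(model.config)}
    )
    np.savez(path, __meta__=np.array(meta), **model.params)


def load_model(path) -> CbanModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ConfigError(
                f"checkpoint format version {meta.get('format_version')} "
                f"not supported (expected {CHECKPOINT_FORMAT_VERSION})"
            )
        cfg_dict = meta["config"]
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        config = ModelConfig(**cfg_dict)
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return CbanModel(config=config, params=params)
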