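"""The aneurysm detector: an improved 3D-UNet with deep supervision.

The network is a 3D encoder–decoder fully convolutional network in the
U-Net family: each encoder level holds a residual *context block* (two
3x3x3 convolutions with instance normalization and leaky ReLU wrapped
around an identity shortcut), levels are connected by 2x max pooling /
2x nearest upsampling, and a context aggregation pathway concatenates
encoder features into the decoder at every resolution.  Segmentation
heads (1x1x1 convolutions to 2 classes) sit on the lowest decoder
levels as well as the final one; the auxiliary heads are upsampled and
summed into the output so the auxiliary losses inject gradient signals
deep into the decoder (deep supervision).

Training follows the study protocol: batch size 1, Adam at 5e-4,
Glorot-uniform initialization, early stopping on a held-out validation
split, roughly 200 epochs at most.  The loss is an equally weighted sum
of voxelwise cross-entropy and soft Dice on the summed output.

At full scale the network ingests 128^3 blocks with 16 base filters;
for CPU-sized experiments the same topology runs at 32^3 with 4 base
filters (``NetworkConfig.test_scale()``).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .volume_io import Volume
from .segment import VOI

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ModelState",
    "build_network",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**depth``;
    ``deep_supervision_levels`` counts the auxiliary heads below the
    final one and must leave room in the decoder
    (``<= depth - 2`` and in particular ``< depth``).
    """

    input_size: int = 128
    depth: int = 4
    base_filters: int = 16
    deep_supervision_levels: int = 2
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if not 0 <= self.deep_supervision_levels <= self.depth - 2:
            raise ValueError("deep_supervision_levels must be in [0, depth-2]")
        if self.n_classes != 2:
            raise ValueError("the detector is a 2-class (vessel/aneurysm) network")

    @classmethod
    def test_scale(cls) -> "NetworkConfig":
        """CPU-sized topology: 32^3 blocks, 4 base filters, depth 3."""
        return cls(input_size=32, depth=3, base_filters=4, deep_supervision_levels=1)

    def channels(self, level: int) -> int:
        return self.base_filters * (2**level)


@dataclass
class TrainConfig:
    batch_size: int = 1
    learning_rate: float = 5e-4
    max_epochs: int = 200
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ModelState:
    """Weights + topology + training history of one detector model."""

    params: dict[str, Tensor]
    config: NetworkConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = weights[k].astype(np.float32).copy()


# --- construction -----------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot-uniform: U(-L, L), L = sqrt(6 / (fan_in + fan_out))."""
    if len(shape) == 5:  # (out, in, k, k, k)
        receptive = int(np.prod(shape[2:]))
        fan_in, fan_out = shape[1] * receptive, shape[0] * receptive
    else:
        fan_in = fan_out = int(np.prod(shape))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> ModelState:
    """Allocate and Glorot-initialize all network parameters."""
    c = config or NetworkConfig()
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}

    def conv_param(name: str, cout: int, cin: int, k: int) -> None:
        params[f"{name}_w"] = Tensor(_glorot(rng, (cout, cin, k, k, k)), requires_grad=True)
        params[f"{name}_b"] = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def norm_param(name: str, ch: int) -> None:
        params[f"{name}_g"] = Tensor(np.ones(ch, np.float32), requires_grad=True)
        params[f"{name}_be"] = Tensor(np.zeros(ch, np.float32), requires_grad=True)

    conv_param("enc_in", c.channels(0), 1, 3)
    for lvl in range(c.depth):
        ch = c.channels(lvl)
        conv_param(f"ctx{lvl}_c1", ch, ch, 3)
        norm_param(f"ctx{lvl}_n1", ch)
        conv_param(f"ctx{lvl}_c2", ch, ch, 3)
        norm_param(f"ctx{lvl}_n2", ch)
        if lvl < c.depth - 1:
            conv_param(f"down{lvl}", c.channels(lvl + 1), ch, 3)
    for lvl in range(c.depth - 2, -1, -1):
        ch = c.channels(lvl)
        conv_param(f"up{lvl}", ch, c.channels(lvl + 1), 3)
        conv_param(f"loc{lvl}_c1", ch, 2 * ch, 3)
        norm_param(f"loc{lvl}_n1", ch)
        conv_param(f"loc{lvl}_c2", ch, ch, 1)
    for lvl in range(c.deep_supervision_levels + 1):
        conv_param(f"seg{lvl}", c.n_classes, c.channels(lvl), 1)

    return ModelState(params=params, config=c)


def _context_block(m: ModelState, lvl: int, x: Tensor) -> Tensor:
    p = m.params
    h = ag.conv3d(x, p[f"ctx{lvl}_c1_w"], p[f"ctx{lvl}_c1_b"])
    h = ag.instance_norm(h, p[f"ctx{lvl}_n1_g"], p[f"ctx{lvl}_n1_be"])
    h = ag.leaky_relu(h)
    h = ag.conv3d(h, p[f"ctx{lvl}_c2_w"], p[f"ctx{lvl}_c2_b"])
    h = ag.instance_norm(h, p[f"ctx{lvl}_n2_g"], p[f"ctx{lvl}_n2_be"])
    return ag.leaky_relu(ag.add(h, x))


def forward(m: ModelState, x: np.ndarray, requires_grad: bool = False) -> Tensor:
    """Full forward pass; ``x`` is (Z, Y, X) or (1, Z, Y, X).

    Returns the summed deep-supervision logits, shape (2, Z, Y, X).
    """
    c = m.config
    p = m.params
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != (c.input_size,) * 3:
        raise ValueError(f"expected input {(c.input_size,) * 3}, got {x.shape[1:]}")
    h = Tensor(x.astype(np.float32))

    h = ag.leaky_relu(ag.conv3d(h, p["enc_in_w"], p["enc_in_b"]))
    skips = []
    for lvl in range(c.depth):
        h = _context_block(m, lvl, h)
        if lvl < c.depth - 1:
            skips.append(h)
            h = ag.maxpool2(h)
            h = ag.leaky_relu(ag.conv3d(h, p[f"down{lvl}_w"], p[f"down{lvl}_b"]))

    dec: dict[int, Tensor] = {}
    for lvl in range(c.depth - 2, -1, -1):
        h = ag.upsample2(h)
        h = ag.leaky_relu(ag.conv3d(h, p[f"up{lvl}_w"], p[f"up{lvl}_b"]))
        h = ag.concat(h, skips[lvl])
        h = ag.conv3d(h, p[f"loc{lvl}_c1_w"], p[f"loc{lvl}_c1_b"])
        h = ag.instance_norm(h, p[f"loc{lvl}_n1_g"], p[f"loc{lvl}_n1_be"])
        h = ag.leaky_relu(h)
        h = ag.leaky_relu(ag.conv3d(h, p[f"loc{lvl}_c2_w"], p[f"loc{lvl}_c2_b"]))
        dec[lvl] = h

    acc: Tensor | None = None
    for lvl in range(c.deep_supervision_levels, 0, -1):
        head = ag.conv3d(dec[lvl], p[f"seg{lvl}_w"], p[f"seg{lvl}_b"])
        acc = head if acc is None else ag.add(acc, head)
        acc = ag.upsample2(acc)
    logits = ag.conv3d(dec[0], p["seg0_w"], p["seg0_b"])
    if acc is not None:
        logits = ag.add(logits, acc)
    return logits


def deep_supervision_head_count(m: ModelState) -> int:
    """Number of auxiliary segmentation heads below the final one."""
    return sum(1 for k in m.params if k.startswith("seg") and k.endswith("_w")) - 1


# --- training ---------------------------------------------------------------


def make_input(data: np.ndarray, voi_mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize a block for the network.

    The block is masked to the VOI and z-scored with the statistics of
    the VOI voxels (the region the model actually reads), so vessel
    contrast is on a comparable scale across cases regardless of how
    much of the block the VOI occupies.
    """
    x = np.asarray(data, dtype=np.float32)
    if voi_mask is not None:
        m = np.asarray(voi_mask, dtype=bool)
        x = x * m
        vals = x[m]
    else:
        vals = x
    sd = float(vals.std()) if vals.size else 0.0
    mu = float(vals.mean()) if vals.size else 0.0
    return (x - mu) / (sd if sd > 0 else 1.0)


def train(
    m: ModelState,
    data: list[tuple[np.ndarray, np.ndarray]],
    t: TrainConfig | None = None,
    verbose: bool = False,
) -> ModelState:
    """Optimize the model on (input block, foreground mask) pairs.

    ``data`` items are (standardized image block, boolean aneurysm
    mask), both ``input_size^3``.  One Adam step per block (batch size
    1).  A validation split (10 % of blocks when there are at least 5)
    drives early stopping; the best-validation weights are restored.
    """
    t = t or TrainConfig()
    if not data:
        raise ValueError("empty training set")
    if not any(np.any(fg) for _, fg in data) or all(np.all(fg) for _, fg in data):
        raise ValueError("degenerate labels: need both classes in the data")

    rng = np.random.default_rng(t.rng_seed)
    n_val = int(round(t.validation_fraction * len(data))) if len(data) >= 5 else 0
    order = rng.permutation(len(data))
    val_idx = list(order[:n_val])
    train_idx = list(order[n_val:])
    # keep at least one foreground block in training
    if not any(np.any(data[i][1]) for i in train_idx):
        train_idx, val_idx = list(order), []

    opt = ag.Adam(m.params, lr=t.learning_rate)
    best_loss = np.inf
    best_weights = m.copy_weights()
    patience_left = t.early_stop_patience

    for epoch in range(t.max_epochs):
        rng.shuffle(train_idx)
        train_loss = 0.0
        for i in train_idx:
            x, fg = data[i]
            opt.zero_grad()
            logits = forward(m, x, requires_grad=True)
            loss = ag.softmax_ce_dice(logits, fg)
            ag.backward(loss)
            opt.step()
            train_loss += float(loss.data)
        train_loss /= max(1, len(train_idx))

        if val_idx:
            val_loss = 0.0
            for i in val_idx:
                x, fg = data[i]
                logits = forward(m, x, requires_grad=False)
                val_loss += float(ag.softmax_ce_dice(logits, fg).data)
            val_loss /= len(val_idx)
        else:
            val_loss = train_loss

        m.history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = m.copy_weights()
            m.best_epoch = epoch
            patience_left = t.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    m.load_weights(best_weights)
    return m


# --- inference --------------------------------------------------------------


def predict(m: ModelState, v: Volume, voi: VOI | None = None) -> Volume:
    """Per-voxel aneurysm likelihood on a block-shaped volume.

    The softmax foreground probability is returned on the input grid;
    voxels outside the VOI are forced to zero.
    """
    c = m.config
    if v.shape != (c.input_size,) * 3:
        raise ValueError(f"volume shape {v.shape} != network input {(c.input_size,) * 3}")
    voi_mask = None
    if voi is not None:
        if voi.mask.shape != v.shape:
            raise ValueError("VOI grid does not match the volume")
        voi_mask = voi.mask
    x = make_input(v.data, voi_mask)
    logits = forward(m, x, requires_grad=False)
    prob = ag.softmax_fg(logits.data)
    if voi_mask is not None:
        prob = prob * voi_mask
    return Volume(prob.astype(np.float32), v.spacing, v.origin)


# --- persistence ------------------------------------------------------------


def save_model(m: ModelState, path) -> None:
    """Single-file checkpoint: weights + config + history (npz)."""
    arrays = {k: p.data for k, p in m.params.items()}
    meta = json.dumps(
        {"config": asdict(m.config), "history": m.history, "best_epoch": m.best_epoch}
    )
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        m = build_network(NetworkConfig(**meta["config"]), seed=0)
        m.load_weights({k: npz[k] for k in npz.files if k != "__meta__"})
        m.history = meta["history"]
        m.best_epoch = meta["best_epoch"]
    return m
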