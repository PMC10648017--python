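"""The downscaled U-Net family with exact kernel and parameter accounting.

The family is parameterized by the first-encoder width ``b``: encoder
widths (b, 2b, 4b, 8b), a 16b bridge, decoder widths (8b, 4b, 2b, b), two
3×3 same-padded convolutions per block, 2×2 max-pooling between encoder
blocks, a 2×2 transposed-convolution upsampling that halves channels
before each decoder block, concatenation skip connections, and a 1×1
single-channel sigmoid output.  Six standard scenarios halve ``b`` from 64
down to 2.

``count_parameters`` derives a per-layer ledger analytically; building the
model asserts that the sum of its actual arrays equals the ledger, so the
accounting can never drift from the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dataset_builder import DatasetSplit, TileSample, stack_samples
from .nn import Adam, Conv2d, ConvTranspose2d, Dropout, MaxPool2x2, Param, ReLU, \
    Upsample2x, adam_reference_step, bce_loss, sigmoid

SCENARIO_BASE_WIDTHS = {1: 64, 2: 32, 3: 16, 4: 8, 5: 4, 6: 2}


class ConfigurationError(ValueError):
    pass


@dataclass
class UNetSpec:
    """Architecture descriptor of one family member."""

    base_width: int
    depth: int = 4
    in_channels: int = 4
    conv_kernel: int = 3
    up_kernel: int = 2
    upsample_mode: str = "transposed_halving"   # or "plain_upsample"
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.base_width < 1:
            raise ConfigurationError("base_width must be ≥ 1")
        if self.upsample_mode not in ("transposed_halving", "plain_upsample"):
            raise ConfigurationError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def encoder_widths(self) -> List[int]:
        return [self.base_width * 2**i for i in range(self.depth)]

    @property
    def bridge_width(self) -> int:
        return self.base_width * 2**self.depth

    @property
    def decoder_widths(self) -> List[int]:
        return list(reversed(self.encoder_widths))


@dataclass
class LayerLedger:
    """Per-layer kernel and parameter accounting."""

    rows: List[Tuple[str, int, int]]  # (layer name, kernel count, parameter count)

    @property
    def total_parameters(self) -> int:
        return sum(r[2] for r in self.rows)

    @property
    def total_kernels(self) -> int:
        return sum(r[1] for r in self.rows)

    def to_csv(self) -> str:
        lines = ["layer,kernels,parameters"]
        lines += [f"{name},{k},{p}" for name, k, p in self.rows]
        lines.append(f"total,{self.total_kernels},{self.total_parameters}")
        return "\n".join(lines) + "\n"


def make_spec(scenario: Optional[int] = None,
              base_width: Optional[int] = None, **kwargs) -> UNetSpec:
    """Build a spec from a scenario number (1–6) or an explicit base width."""
    if (scenario is None) == (base_width is None):
        raise ConfigurationError("give exactly one of scenario or base_width")
    if scenario is not None:
        if scenario not in SCENARIO_BASE_WIDTHS:
            raise ConfigurationError(f"scenario must be 1..6, got {scenario}")
        base_width = SCENARIO_BASE_WIDTHS[scenario]
    return UNetSpec(base_width=base_width, **kwargs)


def count_kernels(spec: UNetSpec) -> int:
    """Feature-map count: two convs per block plus one up-conv per decoder.

    The 1×1 output layer is excluded by convention.
    """
    widths = spec.encoder_widths + [spec.bridge_width] + spec.decoder_widths
    return 2 * sum(widths) + sum(spec.decoder_widths)


def count_parameters(spec: UNetSpec) -> LayerLedger:
    """Analytic layer ledger of trainable parameters.

    A k×k convolution c_in→c_out holds k²·c_in·c_out weights + c_out
    biases.  Under ``transposed_halving`` each decoder starts with a 2×2
    transposed convolution c→c/2 (4·c·(c/2) weights + c/2 biases);
    concatenating the skip restores c channels before the block's two
    convolutions.  Under ``plain_upsample`` the upsampling is parameter-free
    and the first decoder convolution sees c + skip channels.
    """
    k2 = spec.conv_kernel**2
    rows: List[Tuple[str, int, int]] = []

    def conv(name: str, cin: int, cout: int, ksq: int = k2) -> None:
        rows.append((name, cout, ksq * cin * cout + cout))

    cin = spec.in_channels
    for i, w in enumerate(spec.encoder_widths, 1):
        conv(f"encoder{i}.conv1", cin, w)
        conv(f"encoder{i}.conv2", w, w)
        cin = w
    bw = spec.bridge_width
    conv("bridge.conv1", cin, bw)
    conv("bridge.conv2", bw, bw)
    c = bw
    for i, w in enumerate(spec.decoder_widths, 1):
        if spec.upsample_mode == "transposed_halving":
            rows.append((f"decoder{i}.upconv", w,
                         spec.up_kernel**2 * c * w + w))
            concat = w + w  # upsampled half + skip half
        else:
            rows.append((f"decoder{i}.upsample", 0, 0))
            concat = c + w  # full channels + skip
        conv(f"decoder{i}.conv1", concat, w)
        conv(f"decoder{i}.conv2", w, w)
        c = w
    rows.append(("output.conv1x1", 1, c * 1 + 1))
    return LayerLedger(rows=rows)


# ---------------------------------------------------------------------------
# model


class UNet:
    """A trainable U-Net built from a :class:`UNetSpec`.

    Construction asserts that the model's actual trainable-parameter count
    equals the analytic ledger total.
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoders: List[Tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        self.pools: List[MaxPool2x2] = []
        cin = spec.in_channels
        for i, w in enumerate(spec.encoder_widths, 1):
            self.encoders.append((
                Conv2d(cin, w, spec.conv_kernel, rng, f"encoder{i}.conv1"), ReLU(),
                Conv2d(w, w, spec.conv_kernel, rng, f"encoder{i}.conv2"), ReLU(),
            ))
            self.pools.append(MaxPool2x2())
            cin = w
        self.dropout = Dropout(spec.dropout_rate, rng)
        bw = spec.bridge_width
        self.bridge = (
            Conv2d(cin, bw, spec.conv_kernel, rng, "bridge.conv1"), ReLU(),
            Conv2d(bw, bw, spec.conv_kernel, rng, "bridge.conv2"), ReLU(),
        )
        self.decoders = []
        c = bw
        for i, w in enumerate(spec.decoder_widths, 1):
            if spec.upsample_mode == "transposed_halving":
                up = ConvTranspose2d(c, w, rng, f"decoder{i}.upconv")
                concat = w + w
            else:
                up = Upsample2x()
                concat = c + w
            self.decoders.append((
                up,
                Conv2d(concat, w, spec.conv_kernel, rng, f"decoder{i}.conv1"), ReLU(),
                Conv2d(w, w, spec.conv_kernel, rng, f"decoder{i}.conv2"), ReLU(),
            ))
            c = w
        self.out_conv = Conv2d(c, 1, 1, rng, "output.conv1x1")
        ledger_total = count_parameters(spec).total_parameters
        actual = self.parameter_count()
        if actual != ledger_total:
            raise AssertionError(
                f"model parameter count {actual} != ledger {ledger_total}"
            )

    # -- parameters -----------------------------------------------------
    def params(self) -> List[Param]:
        ps: List[Param] = []
        for c1, _, c2, _ in self.encoders:
            ps += c1.params() + c2.params()
        ps += self.bridge[0].params() + self.bridge[2].params()
        for up, c1, _, c2, _ in self.decoders:
            ps += up.params() + c1.params() + c2.params()
        ps += self.out_conv.params()
        return ps

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 4, H, W) float in [0, 1] → (N, 1, H, W) probabilities."""
        skips = []
        for (c1, r1, c2, r2), pool in zip(self.encoders, self.pools):
            x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train),
                                      train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.dropout.forward(x, train)
        b1, br1, b2, br2 = self.bridge
        x = br2.forward(b2.forward(br1.forward(b1.forward(x, train), train),
                                   train), train)
        self._skip_channels = []
        for (up, c1, r1, c2, r2), skip in zip(self.decoders, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train),
                                      train), train)
        z = self.out_conv.forward(x, train)
        self._z = z if train else None
        return sigmoid(z)

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from the gradient at the pre-sigmoid output."""
        d = self.out_conv.backward(dz)
        dskips = [None] * len(self.decoders)
        for i in range(len(self.decoders) - 1, -1, -1):
            up, c1, r1, c2, r2 = self.decoders[i]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
            n_up, _ = self._skip_channels[i]
            d_up, d_skip = d[:, :n_up], d[:, n_up:]
            dskips[i] = d_skip
            d = up.backward(d_up)
        b1, br1, b2, br2 = self.bridge
        d = b1.backward(br1.backward(b2.backward(br2.backward(d))))
        d = self.dropout.backward(d)
        for i in range(len(self.encoders) - 1, -1, -1):
            c1, r1, c2, r2 = self.encoders[i]
            d = self.pools[i].backward(d)
            d = d + dskips[len(self.decoders) - 1 - i]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))

    def predict_proba(self, patches: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Probability maps for (N, H, W, 4) uint8 patches → (N, H, W)."""
        x = _to_nchw(patches)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], train=False)[:, 0])
        return np.concatenate(outs, axis=0)

    # -- persistence -----------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]

    def save(self, path: str) -> None:
        meta = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez(path, __base_width=self.spec.base_width,
                 __depth=self.spec.depth, __in_channels=self.spec.in_channels,
                 __upsample_mode=self.spec.upsample_mode, **meta)

    @classmethod
    def load(cls, path: str) -> "UNet":
        data = np.load(path, allow_pickle=False)
        spec = UNetSpec(base_width=int(data["__base_width"]),
                        depth=int(data["__depth"]),
                        in_channels=int(data["__in_channels"]),
                        upsample_mode=str(data["__upsample_mode"]))
        model = cls(spec)
        model.load_state_dict({k[len("param/"):]: data[k] for k in data.files
                               if k.startswith("param/")})
        return model


def build_model(spec: UNetSpec, seed: int = 0) -> UNet:
    return UNet(spec, seed=seed)


def _to_nchw(patches: np.ndarray) -> np.ndarray:
    """(N, H, W, 4) uint8 → (N, 4, H, W) float64 scaled to [0, 1]."""
    return patches.astype(np.float64).transpose(0, 3, 1, 2) / 255.0


# ---------------------------------------------------------------------------
# training and evaluation


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigurationError("decay rates must lie in [0, 1)")
        if self.eps <= 0:
            raise ConfigurationError("eps must be positive")


@dataclass
class EvalResult:
    pixel_accuracy: float
    f1_score: float
    mean_bce_loss: float
    threshold: float = 0.5


@dataclass
class TrainingHistory:
    epochs: List[Dict[str, float]] = field(default_factory=list)

    def to_csv(self) -> str:
        cols = ["epoch", "train_loss", "train_accuracy",
                "val_loss", "val_accuracy"]
        lines = [",".join(cols)]
        for row in self.epochs:
            lines.append(",".join(
                "" if row.get(c) is None else f"{row[c]:.6f}" for c in cols))
        return "\n".join(lines) + "\n"


class DivergenceError(RuntimeError):
    pass


def train(model: UNet, split: DatasetSplit, config: TrainConfig) -> TrainingHistory:
    """Train with Adam on binary cross-entropy; record per-epoch metrics.

    Batch order is reshuffled each epoch from the config seed; with a fixed
    seed, data, and initialization the history is reproducible.
    """
    if not split.train:
        raise ConfigurationError("training set is empty")
    x_train, y_train = stack_samples(split.train)
    x_val, y_val = (stack_samples(split.validation) if split.validation
                    else (None, None))
    return train_arrays(model, x_train, y_train, config, x_val, y_val)


def train_arrays(model: UNet, patches: np.ndarray, labels: np.ndarray,
                 config: TrainConfig,
                 val_patches: Optional[np.ndarray] = None,
                 val_labels: Optional[np.ndarray] = None) -> TrainingHistory:
    """Array-level training loop: (N,H,W,4) patches, (N,H,W) binary labels."""
    x = _to_nchw(patches)
    y = labels.astype(np.float64)
    opt = Adam(model.params(), alpha=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x[idx], y[idx][:, None]
            p = model.forward(xb, train=True)
            loss = bce_loss(yb, p)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}")
            # d(mean BCE)/dz for sigmoid output: (p − y)/npixels
            dz = (p - yb) / yb.size
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
            accs.append(float(np.mean((p >= 0.5) == (yb >= 0.5))))
        row: Dict[str, float] = {
            "epoch": float(epoch + 1),
            "train_loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(accs)),
            "val_loss": None,
            "val_accuracy": None,
        }
        if val_patches is not None and len(val_patches):
            val = evaluate_arrays(model, val_patches, val_labels)
            row["val_loss"] = val.mean_bce_loss
            row["val_accuracy"] = val.pixel_accuracy
        history.epochs.append(row)
    return history


def evaluate(model: UNet, samples: Sequence[TileSample],
             threshold: float = 0.5) -> EvalResult:
    """Pixel accuracy, forest-positive F1, and mean BCE over samples."""
    if not samples:
        raise ConfigurationError("no samples to evaluate")
    patches, labels = stack_samples(samples)
    return evaluate_arrays(model, patches, labels, threshold)


def evaluate_arrays(model: UNet, patches: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> EvalResult:
    p = model.predict_proba(patches)
    y = labels.astype(bool)
    pred = p >= threshold
    accuracy = float(np.mean(pred == y))
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return EvalResult(pixel_accuracy=accuracy, f1_score=float(f1),
                      mean_bce_loss=bce_loss(y.astype(float), p),
                      threshold=threshold)
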