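"""3D U-net mapping (b0 + first-half MPG volumes) to the second-half volumes.

Encoder-decoder with stride-2 convolutional downsampling, transposed-conv
upsampling, concatenation skip connections, ReLU activations, and a final
1x1x1 linear projection; trained with Adam on the mean-squared error
between prediction and the measured second-half volumes.  The
implementation is a compact NumPy network with hand-derived gradients,
sized for whole-volume training on desk-scale phantom grids.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import numpy as np

from ._nnops import Conv1, Conv3, ConvT3, relu, relu_grad
from .dwi_io import DWIVolume
from .gradients import GradientScheme

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingState",
    "UNet3D",
    "build_model",
    "train",
    "predict",
    "predict_volume",
    "assemble_arms",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    input_channels: int = 33
    output_channels: int = 32
    levels: int = 3
    base_filters: int = 16
    kernel_size: int = 3
    downsample_stride: int = 2
    activation: str = "relu"
    input_skip: bool = True  # concatenate the input before the output head
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if min(self.input_channels, self.output_channels, self.base_filters) < 1:
            raise ValueError("channel counts must be >= 1")
        if self.activation != "relu":
            raise ValueError("only the rectified linear unit is supported")
        if self.downsample_stride != 2:
            raise ValueError("downsample_stride must be 2")


@dataclasses.dataclass
class TrainConfig:
    minibatch_size: int = 15
    epochs: int = 300
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to lr_final_fraction)
    lr_final_fraction: float = 0.02
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1 or self.minibatch_size < 1:
            raise ValueError("epochs and minibatch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only Adam is supported")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        if self.lr_schedule == "constant" or self.epochs == 1:
            return self.learning_rate
        import math

        frac = self.lr_final_fraction
        cos = 0.5 * (1.0 + math.cos(math.pi * epoch / (self.epochs - 1)))
        return self.learning_rate * (frac + (1.0 - frac) * cos)


@dataclasses.dataclass
class TrainingState:
    train_mse: list[float]
    val_mse: list[float]
    best_epoch: int  # index into the lists (0-based)

    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write("epoch,train_mse,val_mse\n")
            for i, (t, v) in enumerate(zip(self.train_mse, self.val_mse), start=1):
                f.write(f"{i},{t!r},{v!r}\n")


class UNet3D:
    """Encoder-decoder; levels L means L spatial resolutions (L-1 halvings)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, L, k = config.base_filters, config.levels, config.kernel_size
        self.enc = []  # per level: same-resolution conv
        self.down = []  # per level except deepest: stride-2 conv
        cin = config.input_channels
        for i in range(L):
            ch = f * 2**i
            self.enc.append(Conv3(cin, ch, k, 1, rng))
            if i < L - 1:
                self.down.append(Conv3(ch, f * 2 ** (i + 1), k, 2, rng))
                cin = f * 2 ** (i + 1)
        self.up = []  # deepest-first
        self.dec = []
        for i in range(L - 2, -1, -1):
            ch = f * 2**i
            self.up.append(ConvT3(f * 2 ** (i + 1), ch, k, 2, rng))
            self.dec.append(Conv3(2 * ch, ch, k, 1, rng))
        head_in = f + (config.input_channels if config.input_skip else 0)
        self.out = Conv1(head_in, config.output_channels, rng)

    def _layers(self):
        return [*self.enc, *self.down, *self.up, *self.dec, self.out]

    @property
    def n_parameters(self) -> int:
        return sum(l.n_params for l in self._layers())

    def _check_shape(self, spatial) -> None:
        divisor = 2 ** (self.config.levels - 1)
        for ax, s in enumerate(spatial):
            if s % divisor:
                raise ValueError(
                    f"spatial axis {ax} has size {s}, not divisible by 2^(levels-1)={divisor}"
                )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (input_channels, D, H, W) -> (output_channels, D, H, W)."""
        if x.shape[0] != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} input channels, got {x.shape[0]}"
            )
        self._check_shape(x.shape[1:])
        L = self.config.levels
        skips = []
        h = x.astype(np.float32)
        acts_enc = []
        for i in range(L):
            h = relu(self.enc[i].forward(h))
            acts_enc.append(h)
            if i < L - 1:
                skips.append(h)
                h = relu(self.down[i].forward(h))
                acts_enc.append(h)
        acts_up, acts_dec, concat_splits = [], [], []
        for j in range(L - 1):
            h = relu(self.up[j].forward(h))
            acts_up.append(h)
            skip = skips[L - 2 - j]
            concat_splits.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            h = relu(self.dec[j].forward(h))
            acts_dec.append(h)
        if self.config.input_skip:
            h = np.concatenate([h, x.astype(np.float32)], axis=0)
        y = self.out.forward(h)
        self._acts = (acts_enc, acts_up, acts_dec, concat_splits)
        return y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for one sample (after forward)."""
        acts_enc, acts_up, acts_dec, concat_splits = self._acts
        L = self.config.levels
        g = self.out.backward(dy)
        if self.config.input_skip:
            g = g[: g.shape[0] - self.config.input_channels]  # input needs no grad
        skip_grads = [None] * (L - 1)
        for j in range(L - 2, -1, -1):
            g = relu_grad(g, acts_dec[j])
            g = self.dec[j].backward(g)
            nskip = concat_splits[j]
            skip_grads[L - 2 - j] = g[:nskip]
            g = g[nskip:]
            g = relu_grad(g, acts_up[j])
            g = self.up[j].backward(g)
        # encoder activations stored in forward order: enc0, down0, enc1, ...
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                g = relu_grad(g, acts_enc[2 * i + 1])
                g = self.down[i].backward(g)
                g = g + skip_grads[i]
            g = relu_grad(g, acts_enc[2 * i])
            g = self.enc[i].backward(g, need_dx=i > 0)
        self._acts = None

    def zero_grad(self) -> None:
        for layer in self._layers():
            for _, dp in layer.params():
                dp[...] = 0.0

    def parameters(self):
        for layer in self._layers():
            yield from layer.params()

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]


def build_model(config: ModelConfig) -> UNet3D:
    return UNet3D(config)


class _Adam:
    def __init__(self, model: UNet3D, cfg: TrainConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]
        self.t = 0

    def step(self, model: UNet3D, lr: float) -> None:
        self.t += 1
        c = self.cfg
        bc1 = 1 - c.beta1**self.t
        bc2 = 1 - c.beta2**self.t
        for (p, g), m, v in zip(model.parameters(), self.m, self.v):
            m[...] = c.beta1 * m + (1 - c.beta1) * g
            v[...] = c.beta2 * v + (1 - c.beta2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(
    model: UNet3D,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    validation_set: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> TrainingState:
    """Minimize MSE with Adam; deterministic for a fixed seed.

    ``train_set``/``validation_set`` are lists of (input, target) arrays
    shaped (channels, D, H, W).  Gradients are averaged over each
    minibatch; the best-validation-epoch weights are restored at the end.
    """
    for x, y in list(train_set) + list(validation_set):
        if x.shape[1:] != y.shape[1:]:
            raise ValueError("input/target spatial shapes differ")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model, config)
    train_curve: list[float] = []
    val_curve: list[float] = []
    best = (np.inf, -1, None)
    n = len(train_set)
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.minibatch_size):
            batch = order[start : start + config.minibatch_size]
            model.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                x, y = train_set[idx]
                pred = model.forward(x)
                err = (pred - y.astype(np.float32)) / (pred.size * len(batch))
                model.backward(2.0 * err.astype(np.float32))
                batch_loss += _mse(pred, y)
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(epoch + 1)
            opt.step(model, lr)
            losses.append(batch_loss)
        train_curve.append(float(np.mean(losses)))
        if validation_set:
            val = float(np.mean([_mse(model.forward(x), y) for x, y in validation_set]))
        else:
            val = train_curve[-1]
        if not np.isfinite(val):
            raise TrainingDivergedError(epoch + 1)
        val_curve.append(val)
        if val < best[0]:
            best = (val, epoch, [p.copy() for p, _ in model.parameters()])
    if best[2] is not None:
        for (p, _), saved in zip(model.parameters(), best[2]):
            p[...] = saved
    return TrainingState(train_curve, val_curve, best_epoch=best[1])


def predict(model: UNet3D, x: np.ndarray) -> np.ndarray:
    """Inference with the non-negativity clamp (DWI signals are magnitudes)."""
    y = model.forward(np.asarray(x, dtype=np.float32))
    model._acts = None
    return np.clip(y, 0.0, None)


def predict_volume(model: UNet3D, volume: DWIVolume, second_scheme: GradientScheme) -> DWIVolume:
    """Predict the second-half MPG volumes from a (b0 + first-half) volume.

    The input volume must carry the training-time normalization; the output
    inherits it so it can be inverted before metric computation.
    """
    if volume.data.shape[-1] != model.config.input_channels:
        raise ValueError(
            f"volume has {volume.data.shape[-1]} channels; model expects "
            f"{model.config.input_channels}"
        )
    x = np.moveaxis(volume.data, -1, 0)
    y = predict(model, x)
    data = np.moveaxis(y, 0, -1)
    if data.shape[-1] != len(second_scheme):
        raise ValueError("output channel count does not match the second-half scheme")
    return DWIVolume(data, volume.affine, second_scheme, volume.normalization)


def _concat_volumes(a: DWIVolume, b: DWIVolume) -> DWIVolume:
    scheme = GradientScheme(
        np.vstack([a.scheme.directions, b.scheme.directions]),
        np.concatenate([a.scheme.bvalues, b.scheme.bvalues]),
        a.scheme.labels + b.scheme.labels,
        a.scheme.meta,
    )
    return DWIVolume(
        np.concatenate([a.data, b.data], axis=-1), a.affine, scheme, a.normalization
    )


def assemble_arms(
    input_dwi: DWIVolume, predicted: DWIVolume, reference: DWIVolume
) -> dict[str, DWIVolume]:
    """The three evaluation arms: (a) measured input only; (b) input plus
    predicted second half; (c) input plus measured second half."""
    for other in (predicted, reference):
        if other.spatial_shape != input_dwi.spatial_shape:
            raise ValueError("arm volumes must share one grid")
        if len(other.scheme) != len(predicted.scheme):
            raise ValueError("predicted and reference schemes must match in length")
    return {
        "a": input_dwi,
        "b": _concat_volumes(input_dwi, predicted),
        "c": _concat_volumes(input_dwi, reference),
    }


def save_model(model: UNet3D, path) -> None:
    """Checkpoint: .npz weights + JSON sidecar with the configuration."""
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.parameters())}
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(
        json.dumps(dataclasses.asdict(model.config), sort_keys=True)
    )


def load_model(path) -> UNet3D:
    cfg = ModelConfig(**json.loads(Path(str(path) + ".json").read_text()))
    model = UNet3D(cfg)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        for i, (p, _) in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
    return model
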