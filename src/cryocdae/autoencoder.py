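"""One convolutional denoising autoencoder block, as a sklearn-style estimator.

The encoder is three modules of (two stride-1 convolutions + 2x2 max
pooling); the decoder is three stride-2 transposed convolutions followed by a
final convolution that collapses the 32 feature channels back to one output
channel. Dropout (rate 0.5) follows each pooling and each transposed
convolution and is active only during training, so inference is
deterministic and shape-preserving: an ``H x W`` image in, an ``H x W``
image out, with ``H`` and ``W`` divisible by ``pool_factor ** encoder_modules``
(8 by default).

Trained by minimizing the mean reconstruction error
``(1/n) sum_i L(y_i, DC(EC(x_i)))`` with RMSProp; ``fit(X, y)`` takes the
corrupted stack as ``X`` and the (cleaner) target stack as ``y``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .stack import ImageStack

__all__ = [
    "BlockSpec",
    "TrainConfig",
    "ConvDenoisingAutoencoder",
    "build_block",
    "train_block",
    "apply_block",
    "expected_n_params",
]


@dataclass(frozen=True)
class BlockSpec:
    """Architecture hyper-parameters of one block."""

    channels: int = 32
    encoder_modules: int = 3
    convs_per_module: int = 2
    kernel_side: int = 3
    pool_factor: int = 2
    dropout_rate: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters shared by pre-training and fine-tuning."""

    optimizer_name: str = "rmsprop"
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 3e-3
    loss_name: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer_name != "rmsprop":
            raise ValueError("only the rmsprop optimizer is implemented")
        if self.loss_name != "mse":
            raise ValueError("only mean-square-error loss is implemented")


def expected_n_params(spec: BlockSpec) -> int:
    """Closed-form trainable-parameter count implied by a :class:`BlockSpec`."""
    k2, c = spec.kernel_side**2, spec.channels
    n = 0
    c_in = 1
    for _ in range(spec.encoder_modules):
        for _ in range(spec.convs_per_module):
            n += k2 * c_in * c + c
            c_in = c
    n += spec.encoder_modules * (4 * c * c + c)  # 2x2 stride-2 transposed convs
    n += k2 * c * 1 + 1  # channel-collapsing output convolution
    return n


class ConvDenoisingAutoencoder(BaseEstimator, TransformerMixin):
    """Denoising autoencoder: ``fit(noisy, cleaner)`` then ``transform(noisy)``.

    Parameters mirror :class:`BlockSpec` and :class:`TrainConfig`. With
    ``warm_start=True`` a further ``fit`` continues from the current weights
    (this is how pseudo-supervised fine-tuning re-uses pre-trained blocks).

    Attributes
    ----------
    net_ : the layer stack with learned parameters
    loss_history_ : per-epoch mean training loss, appended across warm starts
    n_params_ : trainable parameter count
    """

    def __init__(
        self,
        channels: int = 32,
        encoder_modules: int = 3,
        convs_per_module: int = 2,
        kernel_side: int = 3,
        pool_factor: int = 2,
        dropout_rate: float = 0.5,
        activation: str = "relu",
        optimizer_name: str = "rmsprop",
        epochs: int = 20,
        batch_size: int = 4,
        learning_rate: float = 3e-3,
        loss_name: str = "mse",
        warm_start: bool = False,
        random_state: int = 0,
    ):
        self.channels = channels
        self.encoder_modules = encoder_modules
        self.convs_per_module = convs_per_module
        self.kernel_side = kernel_side
        self.pool_factor = pool_factor
        self.dropout_rate = dropout_rate
        self.activation = activation
        self.optimizer_name = optimizer_name
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss_name = loss_name
        self.warm_start = warm_start
        self.random_state = random_state

    # ------------------------------------------------------------------ spec
    def spec(self) -> BlockSpec:
        return BlockSpec(
            channels=self.channels,
            encoder_modules=self.encoder_modules,
            convs_per_module=self.convs_per_module,
            kernel_side=self.kernel_side,
            pool_factor=self.pool_factor,
            dropout_rate=self.dropout_rate,
            activation=self.activation,
        )

    @property
    def side_divisor(self) -> int:
        return self.pool_factor**self.encoder_modules

    def _check_images(self, X: np.ndarray, name: str = "X") -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"{name} must be a (n, H, W) image stack; got shape {X.shape}")
        h, w = X.shape[1:]
        d = self.side_divisor
        if h % d or w % d:
            raise nn.ShapeError(
                f"image sides {h}x{w} must be divisible by {d} "
                f"(= pool_factor ** encoder_modules)"
            )
        return X

    def initialize(self) -> "ConvDenoisingAutoencoder":
        """Build the untrained network with seeded weight initialization."""
        spec = self.spec()
        if spec.activation != "relu":
            raise ValueError("only the relu activation is implemented")
        if spec.pool_factor != 2:
            raise ValueError("only pool_factor=2 is implemented")
        rng = np.random.default_rng(self.random_state)
        layers: list[nn.Layer] = []
        c_in = 1
        for _ in range(spec.encoder_modules):
            for _ in range(spec.convs_per_module):
                layers.append(nn.Conv2D(c_in, spec.channels, spec.kernel_side, rng, relu=True))
                c_in = spec.channels
            layers.append(nn.MaxPool2D(spec.pool_factor))
            layers.append(nn.Dropout(spec.dropout_rate))
        for _ in range(spec.encoder_modules):
            layers.append(nn.TransposedConv2x2(spec.channels, spec.channels, rng, relu=True))
            layers.append(nn.Dropout(spec.dropout_rate))
        layers.append(nn.Conv2D(spec.channels, 1, spec.kernel_side, rng))
        self.net_ = nn.Sequential(layers)
        self.n_params_ = self.net_.n_params
        self.loss_history_ = []
        return self

    # ------------------------------------------------------------- estimator
    def fit(self, X, y=None):
        """Train on (corrupted, target) image pairs; ``y`` defaults to ``X``."""
        X = self._check_images(X, "X")
        y = X if y is None else self._check_images(np.asarray(y), "y")
        if len(X) != len(y) or X.shape != y.shape:
            raise ValueError(f"input/target stacks differ in shape: {X.shape} vs {y.shape}")
        if not (self.warm_start and hasattr(self, "net_")):
            self.initialize()
        TrainConfig(  # validate optimization params
            optimizer_name=self.optimizer_name,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            loss_name=self.loss_name,
            seed=self.random_state,
        )
        rng = np.random.default_rng((self.random_state, len(self.loss_history_)))
        opt = nn.RMSProp(self.net_, self.learning_rate)
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][..., None]
                yb = y[idx][..., None]
                out = self.net_.forward(xb, train=True, rng=rng)
                diff = out - yb
                total += float(np.sum(diff * diff, dtype=np.float64))
                self.net_.backward((2.0 / diff.size) * diff)
                opt.step()
            self.loss_history_.append(total / (n * X.shape[1] * X.shape[2]))
        return self

    def transform(self, X, batch_size: int = 32) -> np.ndarray:
        """Denoise a stack; deterministic (dropout disabled)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("block is not initialized; call fit() or initialize() first")
        X = self._check_images(X, "X")
        out = np.empty_like(X)
        for start in range(0, len(X), batch_size):
            xb = X[start : start + batch_size][..., None]
            out[start : start + batch_size] = self.net_.forward(xb, train=False)[..., 0]
        return out

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Serialize spec + weights; loading restores bit-identical inference."""
        if not hasattr(self, "net_"):
            raise RuntimeError("nothing to save: block is not initialized")
        state = {f"param_{i:03d}": arr for i, arr in enumerate(self.net_.state())}
        np.savez(
            path,
            spec_json=np.array(repr(asdict(self.spec()))),
            random_state=np.array(self.random_state),
            loss_history=np.array(self.loss_history_, dtype=np.float64),
            **state,
        )

    @classmethod
    def load(cls, path) -> "ConvDenoisingAutoencoder":
        import ast

        with np.load(path, allow_pickle=False) as data:
            try:
                spec_dict = ast.literal_eval(str(data["spec_json"]))
                est = cls(random_state=int(data["random_state"]), **spec_dict)
                est.initialize()
                est.loss_history_ = list(data["loss_history"])
                params = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
                est.net_.load_state(params)
            except (KeyError, ValueError, SyntaxError) as exc:
                raise ValueError(f"corrupted or incompatible block weights file: {path}") from exc
        return est


# ------------------------------------------------------- functional wrappers
def build_block(spec: BlockSpec, seed: int) -> ConvDenoisingAutoencoder:
    """An untrained block with deterministically initialized parameters."""
    return ConvDenoisingAutoencoder(**asdict(spec), random_state=seed).initialize()


def train_block(
    block: ConvDenoisingAutoencoder,
    inputs: ImageStack,
    targets: ImageStack,
    cfg: TrainConfig,
) -> ConvDenoisingAutoencoder:
    """Continue training ``block`` on index-aligned (input, target) stacks."""
    if len(inputs) != len(targets):
        raise ValueError("input and target stacks must have equal length")
    block.set_params(
        optimizer_name=cfg.optimizer_name,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        loss_name=cfg.loss_name,
        warm_start=True,
    )
    return block.fit(inputs.pixels, targets.pixels)


def apply_block(block: ConvDenoisingAutoencoder, images: ImageStack) -> ImageStack:
    """Apply the block to a stack, passing labels and references through."""
    return images.with_pixels(block.transform(images.pixels))


def clone_block(block: ConvDenoisingAutoencoder) -> ConvDenoisingAutoencoder:
    """Deep copy including weights (sklearn ``clone`` drops the fitted state)."""
    return copy.deepcopy(block)
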