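"""The cascaded denoiser: pre-training, sequential fine-tuning, inference.

Three identical convolutional autoencoder blocks reduce noise progressively:
block 1 is pre-trained to map the low-SNR tier to the mid tier, block 2 mid
to high, block 3 high to clean (the tiers are index-aligned, so pairs form
by position; the blocks are mutually independent and could be trained in
parallel). On a target stack with no ground truth, the blocks are then
fine-tuned sequentially: each block starts from its pre-trained weights and
trains against the neighborhood-mean images of its own pre-trained outputs
(pseudo-supervision), after which its fine-tuned outputs feed the next
block. The final output is histogram-equalized by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .autoencoder import ConvDenoisingAutoencoder, clone_block
from .metrics import EqualizeConfig, equalize_stack
from .neighbors import NeighborConfig, neighbor_mean_stack
from .stack import ImageStack

__all__ = ["CascadeDenoiser", "CascadeRunRecord", "pretrain", "finetune", "denoise"]

TARGET_MODES = ("per_block", "block1_fixed")


@dataclass
class CascadeRunRecord:
    """Bookkeeping of one fine-tuning run: stage stacks and loss curves.

    ``stages[0]`` is the input test stack X^1; ``stages[j]`` is the output of
    fine-tuned block j; ``final`` is the (optionally equalized) cascade
    output. ``loss_histories[j]`` holds block j's fine-tuning losses.
    """

    stages: list[np.ndarray] = field(default_factory=list)
    final: Optional[np.ndarray] = None
    loss_histories: list[list[float]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)


class CascadeDenoiser(BaseEstimator, TransformerMixin):
    """Sklearn-style cascade estimator.

    ``fit(tiers)`` pre-trains the blocks on a list of 4 index-aligned stacks
    ordered low / mid / high / clean; ``fine_tune(X)`` adapts the blocks to a
    target stack with neighborhood-mean pseudo-targets; ``transform(X)``
    denoises (using fine-tuned blocks when present).

    Parameters
    ----------
    block : prototype ConvDenoisingAutoencoder, cloned per cascade position
        (None means the default 32-channel block).
    n_blocks : number of blocks; 3 is the canonical design and requires
        ``len(tiers) == n_blocks + 1``.
    k_neighbors, neighbor_metric, include_self : neighborhood-mean target
        construction (defaults k=30, euclidean, self included).
    target_mode : "block1_fixed" (default) fine-tunes every block against
        block 1's neighborhood-mean target stack; "per_block" rebuilds
        targets from each block's own pre-trained outputs. The fixed anchor
        is the safer rule: later blocks see already-denoised inputs far from
        their pre-training distribution, and targets built from their own
        degraded outputs lock that degradation in.
    enhance : histogram-equalize the final output.
    finetune_epochs : epoch budget for fine-tuning (None = same as the
        block's pre-training epochs).
    finetune_dropout : keep dropout active during fine-tuning. Off by
        default: dropout regularizes pre-training, but against smooth
        neighborhood-mean targets the train/inference mismatch of heavy
        dropout collapses the deterministic output toward a constant.
    """

    def __init__(
        self,
        block: Optional[ConvDenoisingAutoencoder] = None,
        n_blocks: int = 3,
        k_neighbors: int = 30,
        neighbor_metric: str = "euclidean",
        include_self: bool = True,
        target_mode: str = "block1_fixed",
        enhance: bool = True,
        n_bins: int = 256,
        finetune_epochs: Optional[int] = None,
        finetune_dropout: bool = False,
        random_state: int = 0,
    ):
        self.block = block
        self.n_blocks = n_blocks
        self.k_neighbors = k_neighbors
        self.neighbor_metric = neighbor_metric
        self.include_self = include_self
        self.target_mode = target_mode
        self.enhance = enhance
        self.n_bins = n_bins
        self.finetune_epochs = finetune_epochs
        self.finetune_dropout = finetune_dropout
        self.random_state = random_state

    # -------------------------------------------------------------- helpers
    def _neighbor_cfg(self) -> NeighborConfig:
        return NeighborConfig(
            k=self.k_neighbors, metric=self.neighbor_metric, include_self=self.include_self
        )

    def _prototype(self) -> ConvDenoisingAutoencoder:
        proto = self.block if self.block is not None else ConvDenoisingAutoencoder()
        return clone_block(proto)

    @staticmethod
    def _pixels(X) -> np.ndarray:
        return X.pixels if isinstance(X, ImageStack) else np.asarray(X, dtype=np.float32)

    def _equalize(self, pixels: np.ndarray) -> np.ndarray:
        cfg = EqualizeConfig(n_bins=self.n_bins, per_image=True)
        return equalize_stack(ImageStack(pixels), cfg).pixels

    # ------------------------------------------------------------------ fit
    def fit(self, tiers: Sequence, y=None):
        """Pre-train block j on (tier j -> tier j+1) pairs, j = 1..n_blocks."""
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"target_mode must be one of {TARGET_MODES}")
        if len(tiers) != self.n_blocks + 1:
            raise ValueError(
                f"need {self.n_blocks + 1} index-aligned tiers for {self.n_blocks} blocks; "
                f"got {len(tiers)}"
            )
        stacks = [self._pixels(t) for t in tiers]
        if any(s.shape != stacks[0].shape for s in stacks):
            raise ValueError("tiers are misaligned: all tiers must share shape and order")
        self.blocks_ = []
        for j in range(self.n_blocks):
            blk = self._prototype()
            blk.set_params(random_state=self.random_state * 1000 + j, warm_start=False)
            blk.fit(stacks[j], stacks[j + 1])
            self.blocks_.append(blk)
        self.finetuned_blocks_ = None
        return self

    # ------------------------------------------------------------ fine-tune
    def fine_tune(self, X) -> CascadeRunRecord:
        """Sequentially adapt each block to the target stack (Phase 2).

        Block j is initialized from its pre-trained weights and trained with
        inputs X^j and neighborhood-mean targets; then X^{j+1} = f_j'(X^j).
        """
        if not hasattr(self, "blocks_") or not self.blocks_:
            raise RuntimeError("cascade must be pre-trained (fit) before fine-tuning")
        X = self._pixels(X)
        cfg = self._neighbor_cfg()
        record = CascadeRunRecord(stages=[X])
        self.finetuned_blocks_ = []
        block1_targets = None
        cur = X
        for j, pre_block in enumerate(self.blocks_):
            pre_out = pre_block.transform(cur)
            if self.target_mode == "per_block" or j == 0:
                targets = neighbor_mean_stack(ImageStack(pre_out), cfg).pixels
                if j == 0:
                    block1_targets = targets
            else:
                targets = block1_targets
            ft = clone_block(pre_block)
            epochs = self.finetune_epochs if self.finetune_epochs is not None else ft.epochs
            ft.set_params(epochs=epochs, warm_start=True)
            if not self.finetune_dropout:
                from . import nn

                for layer in ft.net_.layers:
                    if isinstance(layer, nn.Dropout):
                        layer.rate = 0.0
            history_before = len(ft.loss_history_)
            ft.fit(cur, targets)
            record.loss_histories.append(list(ft.loss_history_[history_before:]))
            record.seeds.append(ft.random_state)
            cur = ft.transform(cur)
            record.stages.append(cur)
            self.finetuned_blocks_.append(ft)
        record.final = self._equalize(cur) if self.enhance else cur
        return record

    # ------------------------------------------------------------ inference
    def transform(self, X) -> np.ndarray:
        """Apply the cascade (fine-tuned blocks when available), then enhance."""
        if not hasattr(self, "blocks_"):
            raise RuntimeError("cascade must be pre-trained (fit) before denoising")
        blocks = self.finetuned_blocks_ if getattr(self, "finetuned_blocks_", None) else self.blocks_
        cur = self._pixels(X)
        for blk in blocks:
            cur = blk.transform(cur)
        return self._equalize(cur) if self.enhance else cur

    def denoise(self, images: ImageStack) -> ImageStack:
        return images.with_pixels(self.transform(images.pixels))


# ------------------------------------------------------- functional wrappers
def pretrain(training_sets: Sequence[ImageStack], spec=None, cfg=None, seed: int = 0) -> CascadeDenoiser:
    """Pre-train a 3-block cascade on the four aligned SNR tiers."""
    from dataclasses import asdict

    proto = ConvDenoisingAutoencoder()
    if spec is not None:
        proto.set_params(**asdict(spec))
    if cfg is not None:
        proto.set_params(
            optimizer_name=cfg.optimizer_name,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            loss_name=cfg.loss_name,
        )
    model = CascadeDenoiser(block=proto, random_state=seed)
    return model.fit(training_sets)


def finetune(model: CascadeDenoiser, test: ImageStack, cfg=None):
    """Fine-tune a pre-trained cascade on a test stack; returns (model, record)."""
    if cfg is not None:
        model.set_params(finetune_epochs=cfg.epochs)
    record = model.fine_tune(test)
    return model, record


def denoise(model: CascadeDenoiser, images: ImageStack) -> ImageStack:
    return model.denoise(images)
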