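"""Ordered stacks of same-sized 2D grayscale particle images.

The :class:`ImageStack` is the package's canonical in-memory container: a
``(n, H, W)`` float32 pixel array, optionally carrying per-image orientation
class labels, the signal-to-noise tier the stack was simulated at, and a
parallel stack of noise-free counterparts (``clean_ref``) when ground truth
exists. Pixel values are nominally in ``[0, 1]`` after dataset-level
normalization; noisy stacks may excurse outside that range and are stored
unclipped (clipping happens only on 8-bit export).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ImageStack", "SNRLevel"]


@dataclass(frozen=True)
class SNRLevel:
    """A signal-to-noise tier: ``value`` = var(signal) / var(noise).

    ``tier`` is one of ``{"low", "mid", "high", "clean"}``; the clean tier
    carries no noise and its ``value`` is ``inf`` by convention.
    """

    value: float
    tier: str

    _TIERS = ("low", "mid", "high", "clean")

    def __post_init__(self) -> None:
        if self.tier not in self._TIERS:
            raise ValueError(f"unknown SNR tier {self.tier!r}; expected one of {self._TIERS}")
        if self.tier != "clean" and not (np.isfinite(self.value) and self.value > 0):
            raise ValueError("SNR value must be a positive finite number for noisy tiers")

    @property
    def is_clean(self) -> bool:
        return self.tier == "clean"

    @classmethod
    def clean(cls) -> "SNRLevel":
        return cls(value=float("inf"), tier="clean")


@dataclass
class ImageStack:
    pixels: np.ndarray
    labels: Optional[np.ndarray] = None
    snr_tag: Optional[SNRLevel] = None
    clean_ref: Optional["ImageStack"] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (n, H, W); got shape {self.pixels.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match stack size {len(self)}"
                )

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray) -> "ImageStack":
        """A copy of this stack with new pixel data and metadata carried over."""
        return replace(self, pixels=np.ascontiguousarray(pixels, dtype=np.float32))

    def subset(self, indices) -> "ImageStack":
        idx = np.asarray(indices)
        return ImageStack(
            pixels=self.pixels[idx],
            labels=None if self.labels is None else self.labels[idx],
            snr_tag=self.snr_tag,
            clean_ref=None if self.clean_ref is None else self.clean_ref.subset(idx),
            meta=dict(self.meta),
        )
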