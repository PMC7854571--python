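"""SNR-calibrated synthetic single-particle datasets.

Emulates the standard simulation protocol for benchmarking particle-image
denoisers: project a 3D density at a small set of fixed orientations,
replicate each projection many times, and corrupt the replicas with additive
i.i.d. Gaussian noise calibrated so that

    SNR = var(signal) / var(noise)

with the signal variance pooled over all pixels of the clean stack. The
default tiers are SNR 0.1 (low), 0.4 (mid) and 0.6 (high) plus a clean tier,
with 1,000 replicas per orientation class — the regime where cryo-EM
particles live and progressive denoising is trained. Training tiers share the
same underlying clean projections in the same order, so (input, target) pairs
for tier-to-tier learning are formed by index; the test stack comes from a
*different* phantom, corrupted at the low tier only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .phantoms import Orientation, PhantomVolume, make_phantom, project
from .stack import ImageStack, SNRLevel

__all__ = [
    "DEFAULT_SNR_TIERS",
    "SimulationPlan",
    "default_orientations",
    "calibrate_noise_sigma",
    "add_noise",
    "build_datasets",
]

DEFAULT_SNR_TIERS = (
    SNRLevel(0.1, "low"),
    SNRLevel(0.4, "mid"),
    SNRLevel(0.6, "high"),
    SNRLevel.clean(),
)


def default_orientations() -> list[Orientation]:
    """Four well-separated viewing directions (ZYZ Euler, degrees)."""
    return [
        Orientation((0.0, 0.0, 0.0)),
        Orientation((0.0, 90.0, 0.0)),
        Orientation((90.0, 45.0, 0.0)),
        Orientation((30.0, 120.0, 60.0)),
    ]


@dataclass
class SimulationPlan:
    phantom: PhantomVolume
    orientations: Sequence[Orientation]
    n_per_class: int = 1000
    snr_tiers: Sequence[SNRLevel] = DEFAULT_SNR_TIERS
    image_side: Optional[int] = None
    seed: int = 0
    test_phantom: Optional[PhantomVolume] = None

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if len(self.orientations) < 1:
            raise ValueError("need at least one orientation")
        eulers = {tuple(o.euler) for o in self.orientations}
        if len(eulers) != len(self.orientations):
            raise ValueError("orientations must be pairwise distinct")
        if self.image_side is None:
            self.image_side = self.phantom.side
        if self.image_side != self.phantom.side:
            raise ValueError("image_side must equal the phantom side")


def _pooled_variance(pixels: np.ndarray) -> float:
    return float(np.var(np.asarray(pixels, dtype=np.float64)))


def calibrate_noise_sigma(clean_images: ImageStack, snr: SNRLevel) -> float:
    """Noise std-dev achieving ``var(signal)/var(noise) = snr.value``.

    ``sigma = sqrt(pooled_pixel_variance(clean) / snr.value)``.
    """
    if snr.is_clean:
        raise ValueError("clean tier has no noise sigma")
    if len(clean_images) == 0:
        raise ValueError("clean stack is empty")
    var = _pooled_variance(clean_images.pixels)
    if var <= 0:
        raise ValueError("degenerate signal: clean stack has zero pixel variance")
    return float(np.sqrt(var / snr.value))


def add_noise(clean: ImageStack, snr: SNRLevel, seed: int) -> ImageStack:
    """Corrupt a clean stack with i.i.d. zero-mean Gaussian pixel noise.

    Values are stored unclipped (clipping would bias every variance-based
    metric; it is applied only on 8-bit export). The returned stack keeps the
    input as ``clean_ref`` and records the tier.
    """
    sigma = calibrate_noise_sigma(clean, snr)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=clean.pixels.shape).astype(np.float32)
    return ImageStack(
        pixels=clean.pixels + noise,
        labels=None if clean.labels is None else clean.labels.copy(),
        snr_tag=snr,
        clean_ref=clean,
        meta={**clean.meta, "noise_sigma": sigma, "noise_seed": int(seed)},
    )


def _clean_projection_stack(
    phantom: PhantomVolume, orientations: Sequence[Orientation], n_per_class: int
) -> ImageStack:
    """Replicated clean projections, min-max normalized over the whole stack."""
    views = [project(phantom, o, normalize=False) for o in orientations]
    pixels = np.concatenate([np.repeat(v[None], n_per_class, axis=0) for v in views])
    labels = np.repeat(np.arange(len(orientations)), n_per_class)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise ValueError("degenerate projections: constant images")
    pixels = (pixels - lo) / (hi - lo)
    return ImageStack(pixels=pixels, labels=labels, snr_tag=SNRLevel.clean())


def build_datasets(plan: SimulationPlan) -> tuple[list[ImageStack], ImageStack]:
    """Build the tiered training stacks and the low-SNR test stack.

    Returns ``(train_tiers, test)`` where ``train_tiers[j]`` for the default
    tier list holds the same clean projections corrupted at SNR low/mid/high
    and, last, the clean tier itself — index-aligned so image ``i`` shares its
    clean source across tiers. The test stack is drawn from ``test_phantom``
    (derived deterministically from ``seed`` when not given), corrupted at the
    lowest noisy tier, and carries labels and clean references.
    """
    clean = _clean_projection_stack(plan.phantom, plan.orientations, plan.n_per_class)
    tiers: list[ImageStack] = []
    for t, snr in enumerate(plan.snr_tiers):
        if snr.is_clean:
            tiers.append(clean)
        else:
            tiers.append(add_noise(clean, snr, seed=plan.seed * 1000 + t))

    test_phantom = plan.test_phantom
    if test_phantom is None:
        test_phantom = make_phantom(
            plan.phantom.side, n_components=max(1, len(plan.phantom.spec)), seed=plan.seed + 1
        )
    noisy_tiers = [s for s in plan.snr_tiers if not s.is_clean]
    low = min(noisy_tiers, key=lambda s: s.value) if noisy_tiers else None
    test_clean = _clean_projection_stack(test_phantom, plan.orientations, plan.n_per_class)
    test = add_noise(test_clean, low, seed=plan.seed * 1000 + 99) if low else test_clean
    return tiers, test
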