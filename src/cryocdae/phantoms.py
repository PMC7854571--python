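"""Synthetic 3D density phantoms and their 2D projections.

A :class:`PhantomVolume` is a sum of randomly placed anisotropic Gaussian
blobs and solid ellipsoids on a cubic voxel grid — a stand-in for a
macromolecular density map. Projection images are line integrals (axis sums)
of the rotated volume, the same geometry a transmission electron microscope
realizes for a vitrified particle at a given orientation.

Rotation convention: intrinsic ZYZ Euler angles in degrees, applied about the
volume center with trilinear interpolation; the viewing (integration) axis is
the array's first axis (z). ``project(v, Orientation(0, 0, 0))`` is therefore
exactly ``v.grid.sum(axis=0)`` before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = ["Component", "PhantomVolume", "Orientation", "make_phantom", "project"]


@dataclass(frozen=True)
class Component:
    """One primitive: an anisotropic Gaussian blob or a solid ellipsoid."""

    kind: str  # "gaussian" | "ellipsoid"
    center: tuple[float, float, float]  # voxel coordinates, (z, y, x)
    axes: tuple[float, float, float]  # std-devs (gaussian) or semi-axes (ellipsoid)
    amplitude: float

    def rasterize(self, side: int) -> np.ndarray:
        """Evaluate this component alone on a ``side**3`` grid (the mass oracle path)."""
        zz, yy, xx = np.meshgrid(*(np.arange(side),) * 3, indexing="ij")
        dz = (zz - self.center[0]) / self.axes[0]
        dy = (yy - self.center[1]) / self.axes[1]
        dx = (xx - self.center[2]) / self.axes[2]
        r2 = dz * dz + dy * dy + dx * dx
        if self.kind == "gaussian":
            return self.amplitude * np.exp(-0.5 * r2)
        if self.kind == "ellipsoid":
            return np.where(r2 <= 1.0, self.amplitude, 0.0)
        raise ValueError(f"unknown component kind {self.kind!r}")


@dataclass
class PhantomVolume:
    grid: np.ndarray
    side: int
    spec: list[Component] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.side < 16:
            raise ValueError("phantom side must be >= 16 voxels")
        if self.grid.shape != (self.side,) * 3:
            raise ValueError(f"grid shape {self.grid.shape} does not match side {self.side}")
        if np.any(self.grid < 0):
            raise ValueError("phantom densities must be non-negative")


@dataclass(frozen=True)
class Orientation:
    """Intrinsic ZYZ Euler angles in degrees."""

    euler: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.euler) != 3 or not np.all(np.isfinite(self.euler)):
            raise ValueError("orientation needs three finite Euler angles")

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.euler, degrees=True).as_matrix()


def make_phantom(side: int, n_components: int, seed: int) -> PhantomVolume:
    """Build a random multi-component phantom, density normalized to max 1.

    Deterministic given ``seed``. Components are placed in the central half of
    the cube so projections keep the particle inside the field of view at any
    orientation; axes are drawn between 6% and 16% of the side.
    """
    if side < 16:
        raise ValueError("phantom side must be >= 16 voxels")
    if n_components < 1:
        raise ValueError("need at least one phantom component")
    rng = np.random.default_rng(seed)
    components: list[Component] = []
    lo, hi = 0.30 * side, 0.70 * side
    for _ in range(n_components):
        kind = "gaussian" if rng.random() < 0.7 else "ellipsoid"
        center = tuple(rng.uniform(lo, hi, size=3))
        axes = tuple(rng.uniform(0.06 * side, 0.16 * side, size=3))
        amplitude = float(rng.uniform(0.5, 1.0))
        components.append(Component(kind, center, axes, amplitude))
    grid = np.zeros((side,) * 3)
    for comp in components:
        grid += comp.rasterize(side)
    peak = grid.max()
    if peak <= 0:
        raise ValueError("phantom has no positive density")
    grid /= peak
    return PhantomVolume(grid=grid, side=side, spec=components)


def _rotate_volume(volume: PhantomVolume, orientation: Orientation) -> np.ndarray:
    """Rotate the density about its center (trilinear, zero fill)."""
    rot = orientation.matrix()
    # Array axes are (z, y, x); the rotation acts on (x, y, z) coordinates.
    flip = rot[::-1, ::-1]
    # affine_transform maps output index i to input index A @ i + offset,
    # so A is the inverse rotation expressed in index order.
    a = flip.T
    center = (np.array(volume.grid.shape) - 1) / 2.0
    offset = center - a @ center
    return ndimage.affine_transform(volume.grid, a, offset=offset, order=1, mode="constant")


def project(volume: PhantomVolume, orientation: Orientation, normalize: bool = True) -> np.ndarray:
    """Project the rotated volume along the viewing axis.

    With ``normalize`` the image is scaled by its own maximum into [0, 1]
    (dataset-level normalization is handled by the simulator, which uses the
    clean tier's range instead).
    """
    image = _rotate_volume(volume, orientation).sum(axis=0)
    if normalize:
        peak = image.max()
        if peak > 0:
            image = image / peak
    return image
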