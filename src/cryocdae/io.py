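"""Stack I/O: MRC (mode 2), a lossless NPZ container, PNG export, manifests.

MRC is the canonical interchange format for particle stacks. The writer
emits a minimal MRC2014 header (1024 bytes, mode 2 = float32, little
endian), data stored as ``(nz, ny, nx) = (n_images, H, W)``; the reader
accepts mode-2 files with an optional extended header. Labels, SNR metadata
and clean references do not fit MRC, so the NPZ container is the lossless
round-trip format; PNG export is 8-bit with clipping to [0, 1] and is meant
for inspection, never for metrics.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .stack import ImageStack, SNRLevel

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_stack_npz",
    "read_stack_npz",
    "write_png_dir",
    "read_png_dir",
    "write_manifest",
    "read_manifest",
]

_MRC_HEADER_WORDS = 256
_MRC_MODE_FLOAT32 = 2


def write_mrc(path, stack) -> None:
    """Write a float32 image stack as an MRC2014 mode-2 file."""
    pixels = stack.pixels if isinstance(stack, ImageStack) else np.asarray(stack, np.float32)
    if pixels.ndim != 3:
        raise ValueError("expected a (n, H, W) stack")
    data = np.ascontiguousarray(pixels, dtype="<f4")
    nz, ny, nx = data.shape
    header = np.zeros(_MRC_HEADER_WORDS, dtype="<i4")
    fheader = header.view("<f4")
    header[0:3] = (nx, ny, nz)
    header[3] = _MRC_MODE_FLOAT32
    header[7:10] = (nx, ny, nz)  # sampling grid
    fheader[10:13] = (float(nx), float(ny), float(nz))  # cell in angstrom (1 A/px)
    fheader[13:16] = (90.0, 90.0, 90.0)
    header[16:19] = (1, 2, 3)  # column/row/section axes
    fheader[19:22] = (float(data.min()), float(data.max()), float(data.mean()))
    header[23] = 0  # no extended header
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x44, 0x00, 0x00]), "little")  # little-endian stamp
    fheader[54] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(data.tobytes())


def read_mrc(path) -> ImageStack:
    """Read a mode-2 MRC stack (float32)."""
    with open(path, "rb") as fh:
        raw = fh.read(_MRC_HEADER_WORDS * 4)
        if len(raw) < _MRC_HEADER_WORDS * 4:
            raise ValueError(f"{path}: truncated MRC header")
        header = np.frombuffer(raw, dtype="<i4")
        nx, ny, nz, mode = (int(v) for v in header[:4])
        if mode != _MRC_MODE_FLOAT32:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2 float32)")
        nsymbt = int(header[23])
        fh.seek(_MRC_HEADER_WORDS * 4 + nsymbt)
        data = np.frombuffer(fh.read(nx * ny * nz * 4), dtype="<f4")
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    return ImageStack(pixels=data.reshape(nz, ny, nx).copy())


def write_stack_npz(path, stack: ImageStack) -> None:
    """Lossless container: pixels + labels + SNR tag + clean reference."""
    payload = {"pixels": stack.pixels}
    if stack.labels is not None:
        payload["labels"] = stack.labels
    if stack.snr_tag is not None:
        payload["snr_value"] = np.array(stack.snr_tag.value)
        payload["snr_tier"] = np.array(stack.snr_tag.tier)
    if stack.clean_ref is not None:
        payload["clean_pixels"] = stack.clean_ref.pixels
    np.savez(path, **payload)


def read_stack_npz(path) -> ImageStack:
    with np.load(path, allow_pickle=False) as data:
        if "pixels" not in data.files:
            raise ValueError(f"{path}: not a stack container (no 'pixels' array)")
        snr = None
        if "snr_tier" in data.files:
            snr = SNRLevel(value=float(data["snr_value"]), tier=str(data["snr_tier"]))
        clean = None
        if "clean_pixels" in data.files:
            clean = ImageStack(pixels=data["clean_pixels"])
        return ImageStack(
            pixels=data["pixels"],
            labels=data["labels"] if "labels" in data.files else None,
            snr_tag=snr,
            clean_ref=clean,
        )


def write_png_dir(directory, stack: ImageStack, prefix: str = "img") -> list[Path]:
    """8-bit PNG export; values clipped to [0, 1]. For inspection only."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, image in enumerate(stack.pixels):
        as8 = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, as8)
        paths.append(p)
    return paths


def read_png_dir(directory, prefix: str = "img") -> ImageStack:
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob(f"{prefix}_*.png"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}_*.png images under {directory}")
    pixels = np.stack([iio.imread(p).astype(np.float32) / 255.0 for p in paths])
    return ImageStack(pixels=pixels)


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
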