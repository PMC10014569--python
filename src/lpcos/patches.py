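"""Random 64x64 patch sampling and the positional train/validation split.

Patches are drawn uniformly over the full image grid — the field of view
is deliberately *not* required, so the network also sees the FOV rim and
learns to tell it from vessels.  Out-of-bounds regions are zero-padded.
Patch sets are resampled every epoch (seed + epoch) and split 90/10 by
position: the first 90% train, the last 10% validate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, ChannelStack

__all__ = ["PatchSet", "sample_patches", "split_train_val"]


@dataclass
class PatchSet:
    """Channel-stack crops with label crops and their provenance."""

    x: np.ndarray  # (N, C, P, P) float
    y: np.ndarray  # (N, P, P) bool
    provenance: list[tuple[int, int, int]]  # (image index, row, col) of top-left
    seed: int
    patch_size: int

    def __len__(self) -> int:
        return self.x.shape[0]


def _crop_padded(arr: np.ndarray, r: int, c: int, size: int) -> np.ndarray:
    """Crop with zero padding outside the array bounds; leading axes kept."""
    h, w = arr.shape[-2:]
    out = np.zeros(arr.shape[:-2] + (size, size), dtype=arr.dtype)
    r0, c0 = max(r, 0), max(c, 0)
    r1, c1 = min(r + size, h), min(c + size, w)
    if r1 > r0 and c1 > c0:
        out[..., r0 - r : r1 - r, c0 - c : c1 - c] = arr[..., r0:r1, c0:c1]
    return out


def sample_patches(
    stacks: list[ChannelStack],
    gts: list[BinaryMask | np.ndarray],
    n_per_image: int,
    patch_size: int = 64,
    seed: int = 0,
) -> PatchSet:
    """Draw ``n_per_image`` random patches from every image.

    Top-left corners are sampled uniformly on
    [-pad, side - patch_size + pad] with pad = patch_size // 2, so
    patches partially or entirely outside the image/FOV occur naturally
    (zero-padded).  Deterministic for a fixed seed; resample per epoch by
    passing ``seed + epoch``.
    """
    if n_per_image <= 0:
        raise ValueError("n_per_image must be positive")
    if len(stacks) != len(gts):
        raise ValueError("need one ground truth per channel stack")
    rng = np.random.default_rng(seed)
    pad = patch_size // 2
    xs, ys, prov = [], [], []
    for i, (stack, gt) in enumerate(zip(stacks, gts)):
        h, w = stack.shape
        if patch_size > min(h, w):
            raise ValueError("patch size exceeds the smallest image side")
        gt_arr = gt.pixels if isinstance(gt, BinaryMask) else np.asarray(gt, bool)
        if gt_arr.shape != (h, w):
            raise ValueError("ground-truth shape does not match the stack")
        rows = rng.integers(-pad, h - patch_size + pad + 1, size=n_per_image)
        cols = rng.integers(-pad, w - patch_size + pad + 1, size=n_per_image)
        for r, c in zip(rows, cols):
            xs.append(_crop_padded(stack.channels, int(r), int(c), patch_size))
            ys.append(_crop_padded(gt_arr, int(r), int(c), patch_size))
            prov.append((i, int(r), int(c)))
    return PatchSet(
        np.stack(xs), np.stack(ys).astype(bool), prov, seed, patch_size
    )


def split_train_val(
    ps: PatchSet, train_fraction: float = 0.9
) -> tuple[PatchSet, PatchSet]:
    """Positional split: first ``train_fraction`` of patches train."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(len(ps) * train_fraction)
    a = PatchSet(ps.x[:n_train], ps.y[:n_train], ps.provenance[:n_train], ps.seed, ps.patch_size)
    b = PatchSet(ps.x[n_train:], ps.y[n_train:], ps.provenance[n_train:], ps.seed, ps.patch_size)
    return a, b
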