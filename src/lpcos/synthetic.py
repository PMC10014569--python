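"""Seeded generator of fundus-like test images with paired masks.

Emulates the features of fundus photographs that drive the design of the
enhancement and segmentation stages: dark curvilinear vessels of varying
width on a brighter background, low vessel/background contrast, crossings
and bifurcations, a slowly varying multiplicative illumination field, a
circular field of view, mild background texture, and additive noise.

Vessel trees are grown as branching random walks with bounded curvature.
Branch widths are bimodal — wide trunks and thin distal twigs at or below
``small_width_max_px`` — so the generative "small vessel" label and the
morphological-opening definition used by the metrics agree: every twig is
removed by the opening disk while trunks survive it.  Cross-sections are
Gaussian (blurred boundaries, as in real small vessels); the ground truth
is the rendered profile at half maximum, so a branch of nominal width w
produces a ~w px wide mask.

It does NOT emulate the optic disc, fovea, lesions, vessel reflexes or
photoreceptor texture; conclusions from these fixtures transfer to the
geometry and contrast regime only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    BinaryMask,
    DatasetLayout,
    FundusImage,
    write_image_png,
    write_mask_png,
)

__all__ = ["SyntheticConfig", "generate_fundus", "generate_dataset"]

DEFAULT_PIXEL_SIZE_UM = 8.0  # 65 um kernel -> 9 px disk at this scale


@dataclass
class SyntheticConfig:
    size: tuple[int, int] = (256, 256)
    n_trees: int = 3
    width_range_px: tuple[float, float] = (1.5, 13.0)
    small_width_max_px: float = 3.0
    contrast: float = 0.3
    illumination_gradient: float = 0.2
    noise_sigma: float = 0.02
    background_level: float = 0.72
    texture_amplitude: float = 0.015
    fov_radius_fraction: float = 0.46  # of min(h, w); disk covers >= 60%
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if min(h, w) < 64:
            raise ValueError("synthetic frames must be at least 64 px per side")
        wmin, wmax = self.width_range_px
        if wmin < 1:
            raise ValueError("minimum vessel width must be >= 1 px")
        if wmax > min(h, w) / 4:
            raise ValueError("maximum vessel width exceeds the frame")
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must lie in [0, 1]")
        area = np.pi * (self.fov_radius_fraction * min(h, w)) ** 2 / (h * w)
        if area < 0.6:
            raise ValueError("FOV disk must cover at least 60% of the frame")


@dataclass
class _Branch:
    points: np.ndarray  # (n, 2) row, col
    widths: np.ndarray  # (n,)
    small: bool


def _grow_branch(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    width0: float,
    length: float,
    center: np.ndarray,
    fov_r: float,
    curvature: float = 0.08,
) -> _Branch:
    step = 1.0
    n = int(length / step)
    pts = np.empty((n, 2))
    widths = np.empty(n)
    pos = start.astype(float).copy()
    for i in range(n):
        pts[i] = pos
        widths[i] = width0 * (1.0 - 0.15 * i / max(n - 1, 1))  # mild taper
        heading += float(np.clip(rng.normal(0.0, curvature), -0.25, 0.25))
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if np.linalg.norm(pos - center) > fov_r + 4:
            return _Branch(pts[: i + 1], widths[: i + 1], small=False)
    return _Branch(pts, widths, small=False)


def _grow_tree(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    center: np.ndarray,
    fov_r: float,
    through_center: bool,
) -> list[_Branch]:
    h, w = cfg.size
    wmin, wmax = cfg.width_range_px
    angle = rng.uniform(0, 2 * np.pi)
    start = center + (0.92 * fov_r) * np.array([np.sin(angle), np.cos(angle)])
    if through_center:
        target = center + rng.normal(0, 3, size=2)
    else:
        target = center + rng.uniform(-0.4, 0.4, size=2) * fov_r
    d = target - start
    heading = float(np.arctan2(d[0], d[1]))
    trunk_w = rng.uniform(0.8 * wmax, wmax)
    trunk = _grow_branch(
        rng, start, heading, trunk_w, length=2.2 * fov_r, center=center, fov_r=fov_r
    )
    branches = [trunk]
    # thin distal twigs off the trunk
    n_twigs = rng.integers(2, 5)
    n_pts = len(trunk.points)
    for _ in range(int(n_twigs)):
        if n_pts < 10:
            break
        j = int(rng.integers(n_pts // 4, n_pts))
        p = trunk.points[j]
        base_heading = heading if j == 0 else float(
            np.arctan2(*(trunk.points[min(j + 1, n_pts - 1)] - trunk.points[j - 1]))
        )
        side = rng.choice([-1.0, 1.0])
        tw = rng.uniform(max(wmin, 1.2), cfg.small_width_max_px)
        twig = _grow_branch(
            rng,
            p,
            base_heading + side * rng.uniform(0.5, 1.1),
            tw,
            length=rng.uniform(0.3, 0.7) * fov_r,
            center=center,
            fov_r=fov_r,
            curvature=0.12,
        )
        twig.small = True
        branches.append(twig)
    return branches


def _render(branches: list[_Branch], shape: tuple[int, int]):
    """Max-combined Gaussian-profile rendering.

    Returns (all, small, thick) profiles; the small/thick split follows
    the per-branch label.
    """
    h, w = shape
    prof_all = np.zeros(shape)
    prof_small = np.zeros(shape)
    prof_thick = np.zeros(shape)
    for br in branches:
        for (r, c), width in zip(br.points, br.widths):
            sigma = width / 2.355  # FWHM = nominal width
            rad = max(int(np.ceil(3 * sigma)), 2)
            r0, r1 = int(np.floor(r)) - rad, int(np.floor(r)) + rad + 1
            c0, c1 = int(np.floor(c)) - rad, int(np.floor(c)) + rad + 1
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1, cc1 = min(r1, h), min(c1, w)
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            ys = np.arange(rr0, rr1)[:, None] - r
            xs = np.arange(cc0, cc1)[None, :] - c
            g = np.exp(-(ys**2 + xs**2) / (2 * sigma**2))
            np.maximum(prof_all[rr0:rr1, cc0:cc1], g, out=prof_all[rr0:rr1, cc0:cc1])
            target = prof_small if br.small else prof_thick
            np.maximum(target[rr0:rr1, cc0:cc1], g, out=target[rr0:rr1, cc0:cc1])
    return prof_all, prof_small, prof_thick


def _generate_with_meta(cfg: SyntheticConfig):
    h, w = cfg.size
    center = np.array([h / 2, w / 2])
    fov_r = cfg.fov_radius_fraction * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= fov_r**2

    for attempt in range(8):
        rng = np.random.default_rng(cfg.seed + 1_000_003 * attempt)
        branches: list[_Branch] = []
        tree_trunks: list[_Branch] = []
        for t in range(cfg.n_trees):
            tree = _grow_tree(rng, cfg, center, fov_r, through_center=(t < 2))
            tree_trunks.append(tree[0])
            branches.extend(tree)
        if cfg.n_trees < 2:
            break
        # require the first two trunks to intersect (a crossing)
        m0 = np.zeros((h, w), bool)
        m1 = np.zeros((h, w), bool)
        for mask, trunk in ((m0, tree_trunks[0]), (m1, tree_trunks[1])):
            idx = np.round(trunk.points).astype(int)
            ok = (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
            mask[idx[ok, 0], idx[ok, 1]] = True
        if (ndimage.binary_dilation(m0, iterations=2) & m1).any():
            break

    prof_all, prof_small, prof_thick = _render(branches, (h, w))
    gt = (prof_all >= 0.5) & fov
    # a twig pixel inside a trunk's own footprint is trunk, not small vessel
    small_gt = (prof_small >= 0.5) & gt & ~(prof_thick >= 0.5)

    # multiplicative illumination: smooth ramp in a random direction
    direction = rng.uniform(0, 2 * np.pi)
    ramp = (
        (yy - center[0]) * np.sin(direction) + (xx - center[1]) * np.cos(direction)
    ) / max(h, w)
    gain = 1.0 + cfg.illumination_gradient * ramp

    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
    texture *= cfg.texture_amplitude / max(texture.std(), 1e-12)

    img = cfg.background_level * gain - cfg.contrast * prof_all + texture
    img += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    img[~fov] *= 0.05  # dark rim outside the aperture
    img = np.clip(img, 0.0, 1.0)

    fov_mask = BinaryMask(fov, role="fov")
    fimg = FundusImage(
        img, pixel_size_um=cfg.pixel_size_um, source_channel="gray-as-is", fov=fov_mask
    )
    out = (
        fimg,
        BinaryMask(gt, role="vessel_gt"),
        BinaryMask(small_gt, role="vessel_gt"),
        fov_mask,
    )
    widths = [float(br.widths[0]) for br in branches]
    return out, widths


def generate_fundus(
    cfg: SyntheticConfig | None = None,
) -> tuple[FundusImage, BinaryMask, BinaryMask, BinaryMask]:
    """One synthetic fundus image with (gt, small_gt, fov) masks.

    Fully reproducible from ``cfg.seed``.  With ``n_trees >= 2`` the
    first two trees are routed through the frame centre so at least one
    vessel crossing exists.
    """
    return _generate_with_meta(cfg or SyntheticConfig())[0]


def generate_dataset(
    cfg: SyntheticConfig,
    n_images: int,
    out_dir: str | Path,
    force: bool = False,
) -> DatasetLayout:
    """Write ``n_images`` image/fov/gt triples in the standard layout.

    Per-image seeds are ``cfg.seed + i`` and recorded in the manifest
    together with per-branch widths and the small-vessel pixel counts, so
    any image can be regenerated bit-identically.
    """
    layout = DatasetLayout(Path(out_dir))
    if layout.root.exists() and any(layout.root.iterdir()) and not force:
        raise FileExistsError(
            f"{layout.root} exists and is not empty; pass force=True to overwrite"
        )
    layout.make_dirs()
    records = []
    for i in range(n_images):
        icfg = SyntheticConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        (img, gt, small_gt, fov), widths = _generate_with_meta(icfg)
        stem = f"img_{i:03d}"
        write_image_png(layout.images_dir / f"{stem}.png", img.pixels)
        write_mask_png(layout.gt_dir / f"{stem}.png", gt)
        write_mask_png(layout.fov_dir / f"{stem}.png", fov)
        write_mask_png(layout.gt_dir / f"{stem}_small.png", small_gt)
        records.append(
            {
                "stem": stem,
                "seed": icfg.seed,
                "branch_widths_px": widths,
                "small_vessel_pixels": int(small_gt.pixels.sum()),
                "vessel_pixels": int(gt.pixels.sum()),
            }
        )
    layout.write_manifest(
        {
            "config": {**cfg.__dict__, "size": list(cfg.size),
                       "width_range_px": list(cfg.width_range_px)},
            "pixel_size_um": cfg.pixel_size_um,
            "images": records,
        }
    )
    return layout
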