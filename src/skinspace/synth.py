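"""Seeded synthetic fixtures: skin-like scenes with exact masks, and planted
feature matrices for feature-selection experiments.

Scenes consist of hard-edged elliptical "skin" regions whose colors are drawn
from a compact Gaussian cluster in the (Cb, Cr) chroma plane (centered in the
classic skin locus) over a heterogeneous background.  The default background
rejects colors that fall inside the skin chroma cluster, so scenes are
separable by pixel color; the ``skin_like_distractor`` mode deliberately
plants near-cluster background colors to exercise false positives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import ellipse

from .colorspaces import PixelFeatureMatrix, RgbImage, SkinMask

__all__ = [
    "SceneConfig",
    "PlantedMatrixConfig",
    "generate_scene",
    "generate_dataset",
    "planted_matrix",
]

BACKGROUND_MODES = ("uniform_noise", "textured", "skin_like_distractor")

# Classic skin locus in full-range (Cb, Cr) with gray at 0.5.
_SKIN_CBCR_MEAN = (0.40, 0.60)
_SKIN_CBCR_SD = 0.02
_LUMA_RANGE = (0.35, 0.85)


@dataclass(frozen=True)
class SceneConfig:
    height: int = 64
    width: int = 64
    n_regions: int = 3
    skin_chroma_mean: tuple[float, float] = _SKIN_CBCR_MEAN
    skin_chroma_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (_SKIN_CBCR_SD**2, 0.0),
        (0.0, _SKIN_CBCR_SD**2),
    )
    background_mode: str = "uniform_noise"
    skin_fraction_target: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene dimensions must be at least 16 px")
        if not 0.0 < self.skin_fraction_target < 0.9:
            raise ValueError("skin_fraction_target must be in (0, 0.9)")
        if self.background_mode not in BACKGROUND_MODES:
            raise ValueError(
                f"unknown background_mode {self.background_mode!r}; "
                f"valid: {BACKGROUND_MODES}"
            )
        if self.n_regions < 0:
            raise ValueError("n_regions must be >= 0")


@dataclass(frozen=True)
class PlantedMatrixConfig:
    n: int = 2000
    m: int = 32
    informative: tuple[int, ...] = (0, 1, 2)
    separation: float = 6.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= i < self.m for i in self.informative):
            raise ValueError("informative indices must lie in [0, m)")
        if self.separation < 0.0:
            raise ValueError("separation must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")


def _ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse of the full-range BT.601 transform used by the color module."""
    r = y + 1.402 * (cr - 0.5)
    b = y + 1.772 * (cb - 0.5)
    g = (y - 0.299 * r - 0.114 * b) / 0.587
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


def _sample_skin_colors(config: SceneConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    cbcr = rng.multivariate_normal(
        config.skin_chroma_mean, np.asarray(config.skin_chroma_cov), size=n
    )
    y = rng.uniform(*_LUMA_RANGE, size=n)
    return _ycbcr_to_rgb(y, cbcr[:, 0], cbcr[:, 1])


def _in_skin_cluster(colors: np.ndarray, config: SceneConfig, margin: float = 4.0) -> np.ndarray:
    """Mahalanobis test of RGB colors against the skin chroma cluster."""
    y = 0.299 * colors[..., 0] + 0.587 * colors[..., 1] + 0.114 * colors[..., 2]
    cb = (colors[..., 2] - y) / 1.772 + 0.5
    cr = (colors[..., 0] - y) / 1.402 + 0.5
    delta = np.stack([cb, cr], axis=-1) - np.asarray(config.skin_chroma_mean)
    inv = np.linalg.inv(np.asarray(config.skin_chroma_cov))
    d2 = np.einsum("...i,ij,...j->...", delta, inv, delta)
    return d2 <= margin**2


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    if config.background_mode == "textured":
        yy, xx = np.mgrid[0:h, 0:w]
        phase = rng.uniform(0, 2 * np.pi, size=3)
        freq = rng.uniform(0.05, 0.25, size=3)
        base = np.stack(
            [0.5 + 0.45 * np.sin(freq[c] * (xx + yy) + phase[c]) for c in range(3)],
            axis=-1,
        )
        colors = np.clip(base + rng.normal(0, 0.02, size=base.shape), 0.0, 1.0)
    else:
        colors = rng.random((h, w, 3))
    if config.background_mode == "skin_like_distractor":
        # plant a patch of near-cluster colors to provoke false positives
        n_dist = max(1, int(0.05 * h * w))
        idx = rng.choice(h * w, size=n_dist, replace=False)
        flat = colors.reshape(-1, 3)
        flat[idx] = _sample_skin_colors(config, n_dist, rng)
        return flat.reshape(h, w, 3)
    # separable default: push background colors out of the skin chroma cluster
    for _ in range(20):
        inside = _in_skin_cluster(colors, config)
        if not inside.any():
            break
        colors[inside] = rng.random((int(inside.sum()), 3))
    else:
        # rejection failed to converge; shift remaining offenders to gray
        colors[_in_skin_cluster(colors, config)] = 0.5
    return colors


def _paint_regions(
    config: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize hard-edged ellipses totalling roughly the target area."""
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=bool)
    if config.n_regions == 0:
        return mask, np.zeros((0, 2), dtype=int)
    target_px = config.skin_fraction_target * h * w
    area_each = target_px / config.n_regions
    coords = []
    for _ in range(config.n_regions):
        ratio = rng.uniform(0.5, 2.0)
        r_axis = np.sqrt(area_each * ratio / np.pi)
        c_axis = area_each / (np.pi * r_axis)
        cy = rng.uniform(r_axis * 0.5, h - r_axis * 0.5)
        cx = rng.uniform(c_axis * 0.5, w - c_axis * 0.5)
        rr, cc = ellipse(cy, cx, r_axis, c_axis, shape=(h, w), rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
        coords.append((rr, cc))
    return mask, coords


def generate_scene(config: SceneConfig) -> tuple[RgbImage, SkinMask]:
    """Render one scene and its exact mask; deterministic under the seed.

    The achieved skin fraction is brought within +-0.1 of the target by
    re-drawing regions (bounded retries with fresh derived seeds).
    """
    last_err = None
    for attempt in range(30):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, attempt]))
        mask, _ = _paint_regions(config, rng)
        achieved = mask.mean()
        if config.n_regions == 0 or abs(achieved - config.skin_fraction_target) <= 0.1:
            image = _background(config, rng)
            n_skin = int(mask.sum())
            if n_skin:
                image[mask] = _sample_skin_colors(config, n_skin, rng)
            return RgbImage(image), SkinMask(mask.astype(np.uint8))
        last_err = (
            f"achieved skin fraction {achieved:.3f} vs target "
            f"{config.skin_fraction_target:.3f}"
        )
    raise RuntimeError(f"could not satisfy skin fraction after 30 attempts: {last_err}")


def generate_dataset(
    n_images: int,
    config: SceneConfig,
    seed: int | None = None,
    out_dir: str | Path = "synthetic",
) -> Path:
    """Write n scenes (PNG image + PNG mask) and a manifest CSV.

    Per-image seeds are derived from the master seed so that images are
    independent of generation order.  Returns the manifest path.
    """
    import imageio.v3 as iio

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    master = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValueError(f"cannot create output directory {out_dir}: {e}") from e
    rows = []
    for i in range(n_images):
        child = int(
            np.random.SeedSequence([master, i]).generate_state(1, dtype=np.uint64)[0]
            % (2**31 - 1)
        )
        cfg = SceneConfig(
            height=config.height,
            width=config.width,
            n_regions=config.n_regions,
            skin_chroma_mean=config.skin_chroma_mean,
            skin_chroma_cov=config.skin_chroma_cov,
            background_mode=config.background_mode,
            skin_fraction_target=config.skin_fraction_target,
            seed=child,
        )
        image, mask = generate_scene(cfg)
        img_path = out_dir / f"scene_{i:04d}.png"
        mask_path = out_dir / f"scene_{i:04d}_mask.png"
        iio.imwrite(img_path, np.round(image.pixels * 255).astype(np.uint8))
        iio.imwrite(mask_path, (mask.labels * 255).astype(np.uint8))
        rows.append((str(img_path), str(mask_path)))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "split"])
        for img, msk in rows:
            writer.writerow([img, msk, ""])
    return manifest


def planted_matrix(config: PlantedMatrixConfig) -> PixelFeatureMatrix:
    """Feature matrix with class-separated informative columns among noise.

    ``separation`` is the joint standardized mean difference of the
    informative block: each informative column is shifted by
    ``separation * noise_sd / sqrt(n_informative)``, so the full block is
    needed to realize the stated effect size and every informative column
    carries incremental signal.  All other columns are label-independent.
    """
    rng = np.random.default_rng(config.seed)
    labels = (rng.random(config.n) < config.class_balance).astype(np.uint8)
    values = rng.normal(0.0, config.noise_sd, size=(config.n, config.m))
    n_inf = max(1, len(config.informative))
    shift = config.separation * config.noise_sd / np.sqrt(n_inf)
    for j in config.informative:
        values[labels == 1, j] += shift
    return PixelFeatureMatrix(
        values=values,
        labels=labels,
        column_ids=tuple(f"col_{j}" for j in range(config.m)),
    )
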