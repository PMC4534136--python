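"""The built-in SKN hybrid color space and generic hybrid-space projection.

SKN is a fixed 3-D space whose coordinates are affine in (R, G, B) plus the
green chromaticity g = G/(R+G+B):

    S = 0.088 g - 58.89 G - 30.014 R - 11.952 B - 7.24
    K = 2.122 B + 14.859 G + 6.921 R + 0.62 g + 1.744
    N = 0.342 g - 3.698 G - 2.25 R - 0.103 B - 0.464

Channels are expected in [0, 1]; g of a black pixel is 1/3 by convention.

A :class:`HybridSpace` is the generic product of the derivation pipeline
(feature selection + PCA): an ordered component subset, per-component means
and a k x d loading matrix.  ``apply_hybrid`` projects an image through it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .colorspaces import ComponentRegistry, RgbImage

__all__ = [
    "SknPixel",
    "HybridSpace",
    "rgb_to_skn",
    "rgb_image_to_skn",
    "apply_hybrid",
    "skn_hybrid_space",
    "SKN_COEFFS",
]

# Rows: S, K, N.  Columns: g = G/(R+G+B), R, G, B, constant.
SKN_COEFFS = np.array(
    [
        [0.088, -30.014, -58.89, -11.952, -7.24],
        [0.620, 6.921, 14.859, 2.122, 1.744],
        [0.342, -2.250, -3.698, -0.103, -0.464],
    ]
)


class SknPixel(NamedTuple):
    S: float
    K: float
    N: float


def _skn_from_channels(r, g, b):
    """Shared arithmetic for the scalar and vectorized paths.

    Both public entry points funnel through this function so that their
    floating-point operation order is identical (bit-identical results).
    """
    total = r + g + b
    gc = np.where(total == 0.0, 1.0 / 3.0, g / np.where(total == 0.0, 1.0, total))
    s = 0.088 * gc - 58.89 * g - 30.014 * r - 11.952 * b - 7.24
    k = 2.122 * b + 14.859 * g + 6.921 * r + 0.62 * gc + 1.744
    n = 0.342 * gc - 3.698 * g - 2.25 * r - 0.103 * b - 0.464
    return s, k, n


def rgb_to_skn(r: float, g: float, b: float) -> SknPixel:
    """Transform one RGB pixel (channels in [0, 1]) to SKN coordinates."""
    for name, v in (("R", r), ("G", g), ("B", b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"channel {name}={v} outside [0, 1]")
    s, k, n = _skn_from_channels(np.float64(r), np.float64(g), np.float64(b))
    return SknPixel(float(s), float(k), float(n))


def rgb_image_to_skn(image: RgbImage | np.ndarray) -> np.ndarray:
    """Vectorized SKN transform; returns an H x W x 3 array of (S, K, N)."""
    px = image.pixels if isinstance(image, RgbImage) else RgbImage(np.asarray(image)).pixels
    s, k, n = _skn_from_channels(px[..., 0], px[..., 1], px[..., 2])
    return np.stack([s, k, n], axis=-1)


@dataclass(frozen=True)
class HybridSpace:
    """A linear color space over a subset of registry components.

    Output plane ``i`` at each pixel is ``loadings[i] . (values - means)``
    where ``values`` are the selected component planes.  Spaces produced by
    PCA have unit-norm loading rows (eigenvectors); hand-specified spaces
    such as the expanded SKN equations need not.
    """

    component_ids: tuple[str, ...]
    means: np.ndarray
    loadings: np.ndarray
    name: str = "hybrid"

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=np.float64)
        loadings = np.atleast_2d(np.asarray(self.loadings, dtype=np.float64))
        ids = tuple(self.component_ids)
        if means.shape != (len(ids),):
            raise ValueError("means length must equal the number of components")
        if loadings.shape[1] != len(ids):
            raise ValueError("loadings width must equal the number of components")
        object.__setattr__(self, "component_ids", ids)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "loadings", loadings)

    @property
    def n_outputs(self) -> int:
        return self.loadings.shape[0]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "component_ids": list(self.component_ids),
            "means": self.means.tolist(),
            "loadings": self.loadings.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HybridSpace":
        return cls(
            component_ids=tuple(d["component_ids"]),
            means=np.asarray(d["means"]),
            loadings=np.asarray(d["loadings"]),
            name=d.get("name", "hybrid"),
        )


def apply_hybrid(
    space: HybridSpace,
    image: RgbImage | np.ndarray,
    registry: ComponentRegistry | None = None,
) -> np.ndarray:
    """Project an image through a hybrid space; returns H x W x k planes."""
    registry = registry or ComponentRegistry.full()
    planes = registry.component_planes(image, ids=space.component_ids)
    stack = np.stack([planes[c] for c in space.component_ids], axis=-1)
    centered = stack - space.means
    return np.einsum("hwd,kd->hwk", centered, space.loadings)


def skn_hybrid_space() -> HybridSpace:
    """SKN expressed as a :class:`HybridSpace` over registry components.

    The components are (g, R, G, B) = (G_nRGB, R_RGB, G_RGB, B_RGB); the
    constant terms of the SKN equations are absorbed into the means, which
    solve ``loadings @ means = -constants`` exactly (3 equations, 4 unknowns,
    full row rank).
    """
    loadings = SKN_COEFFS[:, :4]
    constants = SKN_COEFFS[:, 4]
    means, *_ = np.linalg.lstsq(loadings, -constants, rcond=None)
    return HybridSpace(
        component_ids=("G_nRGB", "R_RGB", "G_RGB", "B_RGB"),
        means=means,
        loadings=loadings,
        name="skn",
    )
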