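"""Color space transforms and the pixel feature matrix.

Seventeen color spaces are supported; each transform maps an RGB image with
channels in [0, 1] to one real-valued plane per component.  A component
registry enumerates the unique components across all spaces and defines the
column order of the pixel feature matrix used for feature selection.

Dialect choices (all documented here, several overridable via keyword):

* Input scale: RGB in [0, 1]; 8-bit files are divided by 255 at load time.
* BT.601 luma (``Y = 0.299 R + 0.587 G + 0.114 B``) for the Y-family spaces.
* Full-range chroma planes offset so neutral gray sits at ``chroma_center``
  (default 0.5) for YCbCr, YCgCr, YUV, YIQ and YPbPr.
* XYZ/LAB/LUV: linear transform of the stored RGB values with sRGB primaries
  and D65 white (2 deg observer); no gamma linearization is applied.
* TSL follows Terrillon's definition; YES the Xerox definition; i1i2i3 Ohta's.
* RIQ = (R of RGB, I and Q of YIQ); YQCr = (Y, Q of YIQ, Cr of YCbCr).
* Normalized-RGB chromaticities of a black pixel are (1/3, 1/3, 1/3).
* Hue of an achromatic pixel is 0; hue-like angles are expressed in turns
  (range [0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "RgbImage",
    "SkinMask",
    "ComponentRegistry",
    "PixelFeatureMatrix",
    "SPACE_NAMES",
    "PRINTED_COMPONENTS",
    "transform",
    "to_normalized_rgb",
    "build_feature_matrix",
    "combination_space_size",
    "load_image",
    "load_mask",
]

# D65 reference white, 2 degree observer.
_XN, _YN, _ZN = 0.95047, 1.0, 1.08883
_UN_PRIME = 4.0 * _XN / (_XN + 15.0 * _YN + 3.0 * _ZN)
_VN_PRIME = 9.0 * _YN / (_XN + 15.0 * _YN + 3.0 * _ZN)

# sRGB primaries -> XYZ (D65), applied to the stored channel values directly.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RgbImage:
    """An H x W x 3 image, channel order (R, G, B), values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SkinMask:
    """Binary per-pixel labels; 1 = skin, 0 = non-skin."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"expected H x W label array, got shape {lab.shape}")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclass(frozen=True)
class PixelFeatureMatrix:
    """n x m component values plus per-pixel class labels."""

    values: np.ndarray
    labels: np.ndarray
    column_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if labels.shape != (values.shape[0],):
            raise ValueError("labels length must equal the row count")
        if values.shape[1] != len(self.column_ids):
            raise ValueError("column_ids length must equal the column count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        object.__setattr__(self, "column_ids", tuple(self.column_ids))

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# per-space transforms
# ---------------------------------------------------------------------------


def _split(image: RgbImage | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    px = image.pixels if isinstance(image, RgbImage) else RgbImage(np.asarray(image)).pixels
    return px[..., 0], px[..., 1], px[..., 2]


def _luma601(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.299 * r + 0.587 * g + 0.114 * b


def _space_rgb(r, g, b, cc):
    return {"R": r.copy(), "G": g.copy(), "B": b.copy()}


def _space_nrgb(r, g, b, cc):
    total = r + g + b
    safe = np.where(total == 0.0, 1.0, total)
    rn = np.where(total == 0.0, 1.0 / 3.0, r / safe)
    gn = np.where(total == 0.0, 1.0 / 3.0, g / safe)
    bn = np.where(total == 0.0, 1.0 / 3.0, b / safe)
    return {"R": rn, "G": gn, "B": bn}


def _space_hsv(r, g, b, cc):
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    c = v - mn
    s = np.divide(c, v, out=np.zeros_like(v), where=v > 0)
    safe_c = np.where(c == 0.0, 1.0, c)
    hr = ((g - b) / safe_c) % 6.0
    hg = (b - r) / safe_c + 2.0
    hb = (r - g) / safe_c + 4.0
    h6 = np.select([c == 0.0, v == r, v == g], [0.0, hr, hg], default=hb)
    return {"H": h6 / 6.0, "S": s, "V": v}


def _space_hsi(r, g, b, cc):
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    s = np.where(i > 0.0, 1.0 - mn / np.where(i == 0.0, 1.0, i), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    cosang = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0)) / (2.0 * np.pi)  # turns
    h = np.where(b > g, 1.0 - theta, theta)
    h = np.where(den == 0.0, 0.0, h)
    return {"H": h, "S": s, "I": i}


def _xyz_planes(r, g, b):
    x = _RGB_TO_XYZ[0, 0] * r + _RGB_TO_XYZ[0, 1] * g + _RGB_TO_XYZ[0, 2] * b
    y = _RGB_TO_XYZ[1, 0] * r + _RGB_TO_XYZ[1, 1] * g + _RGB_TO_XYZ[1, 2] * b
    z = _RGB_TO_XYZ[2, 0] * r + _RGB_TO_XYZ[2, 1] * g + _RGB_TO_XYZ[2, 2] * b
    return x, y, z


def _space_xyz(r, g, b, cc):
    x, y, z = _xyz_planes(r, g, b)
    return {"X": x, "Y": y, "Z": z}


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0)


def _space_lab(r, g, b, cc):
    x, y, z = _xyz_planes(r, g, b)
    fx, fy, fz = _lab_f(x / _XN), _lab_f(y / _YN), _lab_f(z / _ZN)
    return {"L": 116.0 * fy - 16.0, "A": 500.0 * (fx - fy), "B": 200.0 * (fy - fz)}


def _space_luv(r, g, b, cc):
    x, y, z = _xyz_planes(r, g, b)
    lum = 116.0 * _lab_f(y / _YN) - 16.0
    den = x + 15.0 * y + 3.0 * z
    # Black maps to the white point chromaticity so that U = V = 0 there.
    up = np.where(den == 0.0, _UN_PRIME, 4.0 * x / np.where(den == 0.0, 1.0, den))
    vp = np.where(den == 0.0, _VN_PRIME, 9.0 * y / np.where(den == 0.0, 1.0, den))
    return {"L": lum, "U": 13.0 * lum * (up - _UN_PRIME), "V": 13.0 * lum * (vp - _VN_PRIME)}


def _space_tsl(r, g, b, cc):
    total = r + g + b
    safe = np.where(total == 0.0, 1.0, total)
    rp = np.where(total == 0.0, 0.0, r / safe - 1.0 / 3.0)
    gp = np.where(total == 0.0, 0.0, g / safe - 1.0 / 3.0)
    s = np.sqrt(9.0 / 5.0 * (rp**2 + gp**2))
    ang = np.arctan2(rp, np.where(gp == 0.0, 1.0, gp)) / (2.0 * np.pi)
    t = np.select([gp > 0.0, gp < 0.0], [ang + 0.25, ang + 0.75], default=0.0)
    return {"T": t, "S": s, "L": _luma601(r, g, b)}


def _space_ycbcr(r, g, b, cc):
    y = _luma601(r, g, b)
    return {"Y": y, "CB": (b - y) / 1.772 + cc, "CR": (r - y) / 1.402 + cc}


def _space_ycgcr(r, g, b, cc):
    # Cg is the G analogue of Cb/Cr: (G - Y) scaled to full range.
    y = _luma601(r, g, b)
    return {"Y": y, "CG": (g - y) / 0.826 + cc, "CR": (r - y) / 1.402 + cc}


def _space_yes(r, g, b, cc):
    return {
        "Y": 0.253 * r + 0.684 * g + 0.063 * b,
        "E": 0.5 * r - 0.5 * g,
        "S": 0.25 * r + 0.25 * g - 0.5 * b,
    }


def _space_yiq(r, g, b, cc):
    return {
        "Y": _luma601(r, g, b),
        "I": 0.595716 * r - 0.274453 * g - 0.321263 * b + cc,
        "Q": 0.211456 * r - 0.522591 * g + 0.311135 * b + cc,
    }


def _space_ypbpr(r, g, b, cc):
    y = _luma601(r, g, b)
    return {"Y": y, "PB": (b - y) / 1.772 + cc, "PR": (r - y) / 1.402 + cc}


def _space_yuv(r, g, b, cc):
    y = _luma601(r, g, b)
    return {"Y": y, "U": 0.492 * (b - y) + cc, "V": 0.877 * (r - y) + cc}


def _space_i1i2i3(r, g, b, cc):
    return {"I1": (r + g + b) / 3.0, "I2": (r - b) / 2.0, "I3": (2.0 * g - r - b) / 4.0}


def _space_riq(r, g, b, cc):
    yiq = _space_yiq(r, g, b, cc)
    return {"R": r.copy(), "I": yiq["I"], "Q": yiq["Q"]}


def _space_yqcr(r, g, b, cc):
    return {
        "Y": _luma601(r, g, b),
        "Q": _space_yiq(r, g, b, cc)["Q"],
        "CR": _space_ycbcr(r, g, b, cc)["CR"],
    }


_SPACE_FUNCS: dict[str, Callable] = {
    "HSI": _space_hsi,
    "HSV": _space_hsv,
    "LAB": _space_lab,
    "LUV": _space_luv,
    "nRGB": _space_nrgb,
    "RGB": _space_rgb,
    "TSL": _space_tsl,
    "XYZ": _space_xyz,
    "YCbCr": _space_ycbcr,
    "YCgCr": _space_ycgcr,
    "YES": _space_yes,
    "YIQ": _space_yiq,
    "YPbPr": _space_ypbpr,
    "YUV": _space_yuv,
    "i1i2i3": _space_i1i2i3,
    "RIQ": _space_riq,
    "YQCr": _space_yqcr,
}

SPACE_NAMES: tuple[str, ...] = tuple(_SPACE_FUNCS)


def transform(
    image: RgbImage | np.ndarray, space_id: str, *, chroma_center: float = 0.5
) -> dict[str, np.ndarray]:
    """Transform an RGB image into the named color space.

    Returns a mapping from component name (e.g. ``"CB"``) to an H x W plane.
    ``chroma_center`` sets the neutral-gray offset of the full-range chroma
    planes in the Y-family spaces.
    """
    if space_id not in _SPACE_FUNCS:
        raise ValueError(
            f"unknown color space {space_id!r}; valid names: {', '.join(SPACE_NAMES)}"
        )
    r, g, b = _split(image)
    return _SPACE_FUNCS[space_id](r, g, b, chroma_center)


def to_normalized_rgb(image: RgbImage | np.ndarray) -> dict[str, np.ndarray]:
    """Chromaticities R/(R+G+B), G/(R+G+B), B/(R+G+B); black maps to 1/3 each."""
    r, g, b = _split(image)
    return _space_nrgb(r, g, b, 0.5)


# ---------------------------------------------------------------------------
# component registry
# ---------------------------------------------------------------------------

# Component id -> (space, plane).  The default registry order is the canonical
# printed 32-name list; the remaining ids cover every plane of every space and
# are resolvable on request (V_HSV in particular).
_COMPONENT_MAP: dict[str, tuple[str, str]] = {
    "H_HSI": ("HSI", "H"),
    "S_HSI": ("HSI", "S"),
    "I_HSI": ("HSI", "I"),
    "L_LAB": ("LAB", "L"),
    "A_LAB": ("LAB", "A"),
    "B_LAB": ("LAB", "B"),
    "U_LUV": ("LUV", "U"),
    "V_LUV": ("LUV", "V"),
    "R_nRGB": ("nRGB", "R"),
    "G_nRGB": ("nRGB", "G"),
    "B_nRGB": ("nRGB", "B"),
    "R_RGB": ("RGB", "R"),
    "G_RGB": ("RGB", "G"),
    "B_RGB": ("RGB", "B"),
    "S_TSL": ("TSL", "S"),
    "L_TSL": ("TSL", "L"),
    "X_XYZ": ("XYZ", "X"),
    "Y_XYZ": ("XYZ", "Y"),
    "Z_XYZ": ("XYZ", "Z"),
    "Y_YCBCR": ("YCbCr", "Y"),
    "CB_YCBCR": ("YCbCr", "CB"),
    "CR_YCBCR": ("YCbCr", "CR"),
    "CG_YCGCR": ("YCgCr", "CG"),
    "CR_YCGCR": ("YCgCr", "CR"),
    "E_YES": ("YES", "E"),
    "S_YES": ("YES", "S"),
    "Q_YIQ": ("YIQ", "Q"),
    "PB_YPBPR": ("YPbPr", "PB"),
    "PR_YPBPR": ("YPbPr", "PR"),
    "i1_i1i2i3": ("i1i2i3", "I1"),
    "i2_i1i2i3": ("i1i2i3", "I2"),
    "i3_i1i2i3": ("i1i2i3", "I3"),
    # additional (non-default) components
    "H_HSV": ("HSV", "H"),
    "S_HSV": ("HSV", "S"),
    "V_HSV": ("HSV", "V"),
    "L_LUV": ("LUV", "L"),
    "T_TSL": ("TSL", "T"),
    "Y_YES": ("YES", "Y"),
    "Y_YIQ": ("YIQ", "Y"),
    "I_YIQ": ("YIQ", "I"),
    "Y_YPBPR": ("YPbPr", "Y"),
    "Y_YUV": ("YUV", "Y"),
    "U_YUV": ("YUV", "U"),
    "V_YUV": ("YUV", "V"),
    "R_RIQ": ("RIQ", "R"),
    "I_RIQ": ("RIQ", "I"),
    "Q_RIQ": ("RIQ", "Q"),
    "Y_YQCR": ("YQCr", "Y"),
    "Q_YQCR": ("YQCr", "Q"),
    "CR_YQCR": ("YQCr", "CR"),
}

PRINTED_COMPONENTS: tuple[str, ...] = tuple(list(_COMPONENT_MAP)[:32])


@dataclass(frozen=True)
class ComponentRegistry:
    """Ordered set of color component identifiers with transform bindings."""

    entries: tuple[str, ...] = field(default=PRINTED_COMPONENTS)

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        unknown = [e for e in entries if e not in _COMPONENT_MAP]
        if unknown:
            raise ValueError(f"unknown component ids: {unknown}")
        if len(set(entries)) != len(entries):
            raise ValueError("component ids must be unique")
        if not entries:
            raise ValueError("registry must not be empty")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def default(cls) -> "ComponentRegistry":
        """The canonical 32-component registry."""
        return cls(PRINTED_COMPONENTS)

    @classmethod
    def full(cls) -> "ComponentRegistry":
        """Every plane of every supported space (includes V_HSV etc.)."""
        return cls(tuple(_COMPONENT_MAP))

    @classmethod
    def deduplicated(cls, tol: float = 1e-9, n_probe: int = 512, seed: int = 0) -> "ComponentRegistry":
        """Full registry with numerically identical components collapsed.

        Components are probed on random in-range pixels; two components whose
        values agree to ``tol`` everywhere are treated as the same formula and
        only the first (in full-registry order) is kept.
        """
        rng = np.random.default_rng(seed)
        probe = RgbImage(rng.random((1, n_probe, 3)))
        full = cls.full()
        vectors = full.component_planes(probe)
        kept: list[str] = []
        for cid in full.entries:
            vec = vectors[cid].ravel()
            if not any(np.max(np.abs(vec - vectors[k].ravel())) <= tol for k in kept):
                kept.append(cid)
        return cls(tuple(kept))

    @property
    def size(self) -> int:
        """Number of registered components."""
        return len(self.entries)

    def resolve(self, component_id: str) -> tuple[str, str]:
        """Map a component id to its (space, plane) pair."""
        try:
            return _COMPONENT_MAP[component_id]
        except KeyError:
            raise KeyError(f"unresolvable component id {component_id!r}") from None

    def component_planes(
        self, image: RgbImage | np.ndarray, ids: Sequence[str] | None = None
    ) -> dict[str, np.ndarray]:
        """Compute the requested component planes, one transform per space."""
        ids = tuple(ids) if ids is not None else self.entries
        spaces_needed = {self.resolve(c)[0] for c in ids}
        cache = {s: transform(image, s) for s in spaces_needed}
        out = {}
        for cid in ids:
            space, plane = self.resolve(cid)
            out[cid] = cache[space][plane]
        return out


def build_feature_matrix(
    pairs: Iterable[tuple[RgbImage, SkinMask]],
    registry: ComponentRegistry | None = None,
) -> PixelFeatureMatrix:
    """Stack all pixels of the given image/mask pairs into an n x m matrix.

    Rows follow image order, then row-major pixel order within each image;
    columns follow registry order.
    """
    registry = registry or ComponentRegistry.default()
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for idx, (image, mask) in enumerate(pairs):
        if (image.height, image.width) != (mask.height, mask.width):
            raise ValueError(
                f"pair {idx}: image is {image.height}x{image.width} but mask is "
                f"{mask.height}x{mask.width}"
            )
        planes = registry.component_planes(image)
        blocks.append(
            np.column_stack([planes[c].reshape(-1) for c in registry.entries])
        )
        labels.append(mask.labels.reshape(-1))
    if not blocks:
        raise ValueError("no image/mask pairs supplied")
    return PixelFeatureMatrix(
        values=np.vstack(blocks),
        labels=np.concatenate(labels),
        column_ids=registry.entries,
    )


def combination_space_size(registry: ComponentRegistry | None = None, k: int = 3) -> int:
    """Number of k-component subsets of the registry (binomial coefficient)."""
    import math

    registry = registry or ComponentRegistry.default()
    if not 0 <= k <= registry.size:
        raise ValueError(f"k must be in [0, {registry.size}], got {k}")
    return math.comb(registry.size, k)


# ---------------------------------------------------------------------------
# image / mask IO
# ---------------------------------------------------------------------------


def load_image(path: str | Path) -> RgbImage:
    """Read a PNG/JPEG/PPM image; 8-bit values are divided by 255."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = 255.0 if arr.max() <= 255 else 65535.0
        arr = arr.astype(np.float64) / scale
    return RgbImage(np.clip(arr.astype(np.float64), 0.0, 1.0))


def load_mask(path: str | Path) -> SkinMask:
    """Read a single-channel PNG mask; 255 -> skin, 0 -> non-skin."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if not (arr == arr[..., :1]).all():
            raise ValueError(f"mask {path} is not single-channel")
        arr = arr[..., 0]
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"mask {path} contains values other than 0/255: {bad.tolist()}")
    return SkinMask((arr == 255).astype(np.uint8))
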