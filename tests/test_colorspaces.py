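"""Transform correctness against a straight-line scalar reference, plus
registry and feature-matrix contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinspace import (
    ComponentRegistry,
    RgbImage,
    SkinMask,
    SPACE_NAMES,
    build_feature_matrix,
    combination_space_size,
    to_normalized_rgb,
    transform,
)
from skinspace.colorspaces import PRINTED_COMPONENTS, load_image, load_mask

# ---------------------------------------------------------------------------
# scalar reference implementations (straight-line formula evaluation; kept
# deliberately independent of the vectorized package code)
# ---------------------------------------------------------------------------

XN, YN, ZN = 0.95047, 1.0, 1.08883
UN = 4 * XN / (XN + 15 * YN + 3 * ZN)
VN = 9 * YN / (XN + 15 * YN + 3 * ZN)


def ref_luma(r, g, b):
    return 0.299 * r + 0.587 * g + 0.114 * b


def ref_xyz(r, g, b):
    x = 0.4124564 * r + 0.3575761 * g + 0.1804375 * b
    y = 0.2126729 * r + 0.7151522 * g + 0.0721750 * b
    z = 0.0193339 * r + 0.1191920 * g + 0.9503041 * b
    return x, y, z


def ref_f(t):
    d = 6.0 / 29.0
    return t ** (1.0 / 3.0) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0


def scalar_reference(space, r, g, b):
    """Per-pixel evaluation of every transform, one formula at a time."""
    if space == "RGB":
        return {"R": r, "G": g, "B": b}
    if space == "nRGB":
        s = r + g + b
        if s == 0:
            return {"R": 1 / 3, "G": 1 / 3, "B": 1 / 3}
        return {"R": r / s, "G": g / s, "B": b / s}
    if space == "HSV":
        v = max(r, g, b)
        c = v - min(r, g, b)
        s = 0.0 if v == 0 else c / v
        if c == 0:
            h = 0.0
        elif v == r:
            h = ((g - b) / c) % 6 / 6
        elif v == g:
            h = ((b - r) / c + 2) / 6
        else:
            h = ((r - g) / c + 4) / 6
        return {"H": h, "S": s, "V": v}
    if space == "HSI":
        i = (r + g + b) / 3
        s = 0.0 if i == 0 else 1 - min(r, g, b) / i
        den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
        if den == 0:
            h = 0.0
        else:
            theta = math.acos(max(-1, min(1, 0.5 * ((r - g) + (r - b)) / den))) / (2 * math.pi)
            h = 1 - theta if b > g else theta
        return {"H": h, "S": s, "I": i}
    if space == "XYZ":
        x, y, z = ref_xyz(r, g, b)
        return {"X": x, "Y": y, "Z": z}
    if space == "LAB":
        x, y, z = ref_xyz(r, g, b)
        fx, fy, fz = ref_f(x / XN), ref_f(y / YN), ref_f(z / ZN)
        return {"L": 116 * fy - 16, "A": 500 * (fx - fy), "B": 200 * (fy - fz)}
    if space == "LUV":
        x, y, z = ref_xyz(r, g, b)
        lum = 116 * ref_f(y / YN) - 16
        den = x + 15 * y + 3 * z
        up = UN if den == 0 else 4 * x / den
        vp = VN if den == 0 else 9 * y / den
        return {"L": lum, "U": 13 * lum * (up - UN), "V": 13 * lum * (vp - VN)}
    if space == "TSL":
        tot = r + g + b
        rp = 0.0 if tot == 0 else r / tot - 1 / 3
        gp = 0.0 if tot == 0 else g / tot - 1 / 3
        s = math.sqrt(9 / 5 * (rp * rp + gp * gp))
        if gp > 0:
            t = math.atan2(rp, gp) / (2 * math.pi) + 0.25
        elif gp < 0:
            t = math.atan2(rp, gp) / (2 * math.pi) + 0.75
        else:
            t = 0.0
        return {"T": t, "S": s, "L": ref_luma(r, g, b)}
    if space == "YCbCr":
        y = ref_luma(r, g, b)
        return {"Y": y, "CB": (b - y) / 1.772 + 0.5, "CR": (r - y) / 1.402 + 0.5}
    if space == "YCgCr":
        y = ref_luma(r, g, b)
        return {"Y": y, "CG": (g - y) / 0.826 + 0.5, "CR": (r - y) / 1.402 + 0.5}
    if space == "YES":
        return {
            "Y": 0.253 * r + 0.684 * g + 0.063 * b,
            "E": 0.5 * r - 0.5 * g,
            "S": 0.25 * r + 0.25 * g - 0.5 * b,
        }
    if space == "YIQ":
        return {
            "Y": ref_luma(r, g, b),
            "I": 0.595716 * r - 0.274453 * g - 0.321263 * b + 0.5,
            "Q": 0.211456 * r - 0.522591 * g + 0.311135 * b + 0.5,
        }
    if space == "YPbPr":
        y = ref_luma(r, g, b)
        return {"Y": y, "PB": (b - y) / 1.772 + 0.5, "PR": (r - y) / 1.402 + 0.5}
    if space == "YUV":
        y = ref_luma(r, g, b)
        return {"Y": y, "U": 0.492 * (b - y) + 0.5, "V": 0.877 * (r - y) + 0.5}
    if space == "i1i2i3":
        return {"I1": (r + g + b) / 3, "I2": (r - b) / 2, "I3": (2 * g - r - b) / 4}
    if space == "RIQ":
        yiq = scalar_reference("YIQ", r, g, b)
        return {"R": r, "I": yiq["I"], "Q": yiq["Q"]}
    if space == "YQCr":
        return {
            "Y": ref_luma(r, g, b),
            "Q": scalar_reference("YIQ", r, g, b)["Q"],
            "CR": scalar_reference("YCbCr", r, g, b)["CR"],
        }
    raise AssertionError(space)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("space", SPACE_NAMES)
def test_transform_matches_scalar_reference(space, random_pixels):
    image = RgbImage(random_pixels.reshape(1, -1, 3))
    planes = transform(image, space)
    for i, (r, g, b) in enumerate(random_pixels):
        ref = scalar_reference(space, float(r), float(g), float(b))
        for name, expected in ref.items():
            assert planes[name][0, i] == pytest.approx(expected, abs=1e-9), (
                f"{space}.{name} at pixel {i} ({r},{g},{b})"
            )


@pytest.mark.parametrize("space", SPACE_NAMES)
def test_transform_finite_on_dense_grid(space):
    axis = np.linspace(0.0, 1.0, 7)
    rr, gg, bb = np.meshgrid(axis, axis, axis, indexing="ij")
    image = RgbImage(np.stack([rr, gg, bb], axis=-1).reshape(7, 49, 3))
    for name, plane in transform(image, space).items():
        assert np.isfinite(plane).all(), f"{space}.{name} produced non-finite values"


def test_gray_pixel_hsv():
    planes = transform(RgbImage(np.full((1, 1, 3), 0.5)), "HSV")
    assert planes["S"][0, 0] == 0.0
    assert planes["V"][0, 0] == 0.5
    assert planes["H"][0, 0] == 0.0


def test_gray_pixel_i1i2i3():
    planes = transform(RgbImage(np.full((1, 1, 3), 0.5)), "i1i2i3")
    assert planes["I1"][0, 0] == pytest.approx(0.5)
    assert planes["I2"][0, 0] == pytest.approx(0.0)
    assert planes["I3"][0, 0] == pytest.approx(0.0)


def test_white_pixel_ycbcr_full_range():
    planes = transform(RgbImage(np.ones((1, 1, 3))), "YCbCr")
    assert planes["Y"][0, 0] == pytest.approx(1.0)
    assert planes["CB"][0, 0] == pytest.approx(0.5)
    assert planes["CR"][0, 0] == pytest.approx(0.5)


def test_unknown_space_rejected_with_valid_names(random_image):
    with pytest.raises(ValueError, match="HSV"):
        transform(random_image, "CMYK")


def test_rgb_transform_is_identity(random_image):
    planes = transform(random_image, "RGB")
    for i, name in enumerate("RGB"):
        np.testing.assert_array_equal(planes[name], random_image.pixels[..., i])


class TestNormalizedRgb:
    def test_sum_one_pixel(self):
        planes = to_normalized_rgb(RgbImage(np.array([[[0.5, 0.25, 0.25]]])))
        assert planes["R"][0, 0] == pytest.approx(0.5)
        assert planes["G"][0, 0] == pytest.approx(0.25)
        assert planes["B"][0, 0] == pytest.approx(0.25)

    @pytest.mark.parametrize("pixel", [(0.0, 0.0, 0.0), (1.0, 1.0, 1.0)])
    def test_achromatic_convention(self, pixel):
        planes = to_normalized_rgb(RgbImage(np.array([[pixel]])))
        for name in "RGB":
            assert planes[name][0, 0] == pytest.approx(1 / 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_planes_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        planes = to_normalized_rgb(RgbImage(rng.random((4, 5, 3))))
        np.testing.assert_allclose(
            planes["R"] + planes["G"] + planes["B"], 1.0, atol=1e-12
        )


class TestRegistry:
    def test_default_is_printed_list(self):
        reg = ComponentRegistry.default()
        assert reg.size == 32
        assert reg.entries == PRINTED_COMPONENTS
        assert reg.entries[0] == "H_HSI"
        assert reg.entries[-1] == "i3_i1i2i3"

    def test_v_hsv_resolvable(self):
        reg = ComponentRegistry.full()
        assert "V_HSV" in reg.entries
        assert reg.resolve("V_HSV") == ("HSV", "V")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ComponentRegistry(("R_RGB", "R_RGB"))

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ComponentRegistry(("R_RGB", "NOPE"))

    def test_dedup_removes_formula_duplicates(self):
        dedup = ComponentRegistry.deduplicated()
        full = ComponentRegistry.full()
        assert dedup.size < full.size
        # PB duplicates CB under the shared full-range dialect
        assert "CB_YCBCR" in dedup.entries
        assert "PB_YPBPR" not in dedup.entries


class TestFeatureMatrix:
    def test_all_skin_2x2(self, rng):
        image = RgbImage(rng.random((2, 2, 3)))
        mask = SkinMask(np.ones((2, 2), dtype=np.uint8))
        fm = build_feature_matrix([(image, mask)])
        assert fm.n_pixels == 4
        np.testing.assert_array_equal(fm.labels, [1, 1, 1, 1])

    def test_default_column_count_is_32(self, scene_pair):
        fm = build_feature_matrix([scene_pair])
        assert fm.n_components == 32

    def test_deterministic(self, scene_pair):
        a = build_feature_matrix([scene_pair])
        b = build_feature_matrix([scene_pair])
        np.testing.assert_array_equal(a.values, b.values)

    def test_row_count_conservation(self, rng):
        pairs = []
        expected = 0
        for _ in range(4):
            h, w = rng.integers(1, 9, size=2)
            pairs.append(
                (
                    RgbImage(rng.random((h, w, 3))),
                    SkinMask(rng.integers(0, 2, size=(h, w)).astype(np.uint8)),
                )
            )
            expected += h * w
        assert build_feature_matrix(pairs).n_pixels == expected

    def test_row_major_order(self):
        px = np.zeros((2, 2, 3))
        px[0, 1, 0] = 1.0  # unique R value at (row 0, col 1) -> row index 1
        fm = build_feature_matrix(
            [(RgbImage(px), SkinMask(np.zeros((2, 2), dtype=np.uint8)))]
        )
        r_col = fm.column_ids.index("R_RGB")
        assert fm.values[1, r_col] == 1.0

    def test_dimension_mismatch_names_pair(self, rng):
        good = (RgbImage(rng.random((2, 2, 3))), SkinMask(np.zeros((2, 2), dtype=np.uint8)))
        bad = (RgbImage(rng.random((2, 3, 3))), SkinMask(np.zeros((2, 2), dtype=np.uint8)))
        with pytest.raises(ValueError, match="pair 1"):
            build_feature_matrix([good, bad])


class TestCombinationSpace:
    def test_default_registry_k3(self):
        assert combination_space_size(k=3) == 4960

    def test_k_zero(self):
        assert combination_space_size(k=0) == 1

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations

        reg = ComponentRegistry(PRINTED_COMPONENTS[:10])
        assert combination_space_size(reg, 4) == sum(
            1 for _ in combinations(range(10), 4)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combination_space_size(k=33)


class TestImageIO:
    def test_image_round_trip(self, tmp_path, rng):
        import imageio.v3 as iio

        arr = rng.integers(0, 256, size=(5, 4, 3), dtype=np.uint8)
        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        image = load_image(path)
        np.testing.assert_allclose(image.pixels, arr / 255.0, atol=1e-12)

    def test_mask_round_trip(self, tmp_path, rng):
        import imageio.v3 as iio

        arr = (rng.integers(0, 2, size=(5, 4)) * 255).astype(np.uint8)
        path = tmp_path / "mask.png"
        iio.imwrite(path, arr)
        mask = load_mask(path)
        np.testing.assert_array_equal(mask.labels, arr // 255)

    def test_mask_intermediate_values_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "bad.png"
        iio.imwrite(path, np.full((4, 4), 128, dtype=np.uint8))
        with pytest.raises(ValueError, match="0/255"):
            load_mask(path)


class TestRgbImageValidation:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            RgbImage(np.full((2, 2, 3), 1.5))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            RgbImage(np.zeros((2, 2)))

    def test_mask_values_restricted(self):
        with pytest.raises(ValueError):
            SkinMask(np.full((2, 2), 2))
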