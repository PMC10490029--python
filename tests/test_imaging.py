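"""Imaging chain: HSV conversion, orientation, resize, crop, equalization,
mean V, and the full photo → concentration composition."""

import colorsys
import io

import numpy as np
import pytest
from PIL import Image, ImageOps

from nitracolor import (
    PixelGrid,
    ROISpec,
    correct_orientation,
    crop_roi,
    equalize_histogram,
    load_image,
    mean_v,
    process_sample,
    resize_longest_edge,
    rgb_to_hsv,
)
from nitracolor.imaging import rgb_array_to_hsv

SUBSAMPLED_CUBE = range(0, 256, 17)  # {0, 17, ..., 255}: 16 levels per channel


# ---------------------------------------------------------------- rgb_to_hsv


def test_hsv_matches_colorsys_oracle_on_subsampled_cube():
    """The sector-rule HSV recipe agrees with the standard library
    conversion to 1e-9 over a 16^3 grid of RGB triplets."""
    worst = 0.0
    for r in SUBSAMPLED_CUBE:
        for g in SUBSAMPLED_CUBE:
            for b in SUBSAMPLED_CUBE:
                got = rgb_to_hsv(r, g, b)
                oh, os_, ov = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
                oh_deg = (oh * 360.0) % 360.0
                if not got.achromatic:
                    worst = max(worst, abs(got.h - oh_deg))
                worst = max(worst, abs(got.s - os_), abs(got.v - ov))
                assert 0 <= got.h < 360 and 0 <= got.s <= 1 and 0 <= got.v <= 1
                assert got.v == max(r, g, b) / 255  # V is exactly max/255
    assert worst < 1e-9


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((255, 0, 0), (0.0, 1.0, 1.0)),
        ((128, 128, 128), (0.0, 0.0, 128 / 255)),
        ((128, 64, 32), (20.0, 0.75, 128 / 255)),
    ],
)
def test_hsv_reference_points(rgb, expected):
    got = rgb_to_hsv(*rgb)
    assert got.h == pytest.approx(expected[0], abs=1e-12)
    assert got.s == pytest.approx(expected[1], abs=1e-12)
    assert got.v == pytest.approx(expected[2], abs=1e-12)


def test_hsv_achromatic_flag_and_channel_validation():
    assert rgb_to_hsv(10, 10, 10).achromatic
    with pytest.raises(ValueError):
        rgb_to_hsv(256, 0, 0)


def test_vectorized_hsv_matches_scalar():
    rng = np.random.default_rng(3)
    px = rng.integers(0, 256, size=(40, 3), dtype=np.uint8)
    hsv = rgb_array_to_hsv(px)
    for i, (r, g, b) in enumerate(px):
        t = rgb_to_hsv(int(r), int(g), int(b))
        np.testing.assert_allclose(hsv[i], [t.h, t.s, t.v], atol=1e-12)


# ------------------------------------------------------------- load_image


def test_load_image_white_png(save_image):
    path = save_image(np.full((2, 2, 3), 255, dtype=np.uint8))
    img = load_image(path)
    assert img.pixels.shape == (2, 2, 3)
    assert (img.pixels == 255).all()


def test_load_image_preserves_exif_orientation(tmp_path):
    pil = Image.fromarray(np.zeros((3, 2, 3), dtype=np.uint8))
    exif = Image.Exif()
    exif[0x0112] = 6
    path = tmp_path / "oriented.jpg"
    pil.save(path, exif=exif)
    assert load_image(path).exif_orientation == 6


def test_load_image_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_image(tmp_path / "missing.png")
    empty = tmp_path / "empty.png"
    empty.write_bytes(b"")
    with pytest.raises(ValueError):
        load_image(empty)


# ----------------------------------------------------- correct_orientation


def _oriented_roundtrip(arr: np.ndarray, code: int) -> np.ndarray:
    """Oracle: Pillow's EXIF transpose applied to the same pixels."""
    pil = Image.fromarray(arr)
    exif = Image.Exif()
    exif[0x0112] = code
    buf = io.BytesIO()
    pil.save(buf, format="PNG", exif=exif)
    buf.seek(0)
    with Image.open(buf) as im:
        upright = ImageOps.exif_transpose(im)
        return np.asarray(upright.convert("RGB"))


@pytest.mark.parametrize("code", range(1, 9))
def test_orientation_matches_pillow_oracle(code):
    rng = np.random.default_rng(code)
    arr = rng.integers(0, 256, size=(3, 2, 3), dtype=np.uint8)
    got = correct_orientation(PixelGrid(arr, exif_orientation=code))
    np.testing.assert_array_equal(got.pixels, _oriented_roundtrip(arr, code))
    assert got.exif_orientation == 1


def test_orientation_6_pixel_mapping_by_hand():
    """A 2-wide, 3-tall grid rotated 90° CW: the first output row is the
    former first column bottom-to-top."""
    labels = np.arange(6, dtype=np.uint8).reshape(3, 2)
    arr = np.stack([labels] * 3, axis=-1)
    out = correct_orientation(PixelGrid(arr, exif_orientation=6))
    assert out.pixels.shape == (2, 3, 3)
    np.testing.assert_array_equal(out.pixels[0, :, 0], [4, 2, 0])
    np.testing.assert_array_equal(out.pixels[1, :, 0], [5, 3, 1])


def test_orientation_noop_and_invalid_code():
    arr = np.arange(12, dtype=np.uint8).reshape(2, 2, 3)
    same = correct_orientation(PixelGrid(arr, exif_orientation=1))
    np.testing.assert_array_equal(same.pixels, arr)
    absent = correct_orientation(PixelGrid(arr, exif_orientation=None))
    np.testing.assert_array_equal(absent.pixels, arr)
    with pytest.warns(UserWarning):
        bad = correct_orientation(PixelGrid(arr, exif_orientation=9))
    np.testing.assert_array_equal(bad.pixels, arr)


# ------------------------------------------------------ resize_longest_edge


@pytest.mark.parametrize(
    "w, h, target, expected",
    [
        (2160, 1080, 1080, (1080, 540)),
        (800, 600, 1080, (800, 600)),  # never upscale
        (1920, 1080, 1080, (1080, 608)),  # round(1080*1080/1920)
    ],
)
def test_resize_dimensions(w, h, target, expected):
    img = PixelGrid(np.zeros((h, w, 3), dtype=np.uint8))
    out = resize_longest_edge(img, target)
    assert (out.width, out.height) == expected


def test_resize_rejects_bad_target():
    img = PixelGrid(np.zeros((4, 4, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        resize_longest_edge(img, 0)


# ---------------------------------------------------------------- crop_roi


def test_crop_manual_and_centered_fraction_agree():
    img = PixelGrid(np.arange(100 * 100 * 3, dtype=np.int64).reshape(100, 100, 3) % 256)
    manual = crop_roi(img, ROISpec("manual", 25, 25, 75, 75))
    centered = crop_roi(img, ROISpec("centered-fraction", fraction=0.5))
    assert manual.pixels.shape == (50, 50, 3)
    np.testing.assert_array_equal(manual.pixels, centered.pixels)


def test_crop_out_of_bounds():
    img = PixelGrid(np.zeros((100, 100, 3), dtype=np.uint8))
    with pytest.raises(ValueError, match="out of bounds"):
        crop_roi(img, ROISpec("manual", 90, 90, 120, 120))


# ------------------------------------------------------- equalize_histogram


def test_equalize_constant_image_is_unchanged():
    img = PixelGrid(np.full((8, 8, 3), 145, dtype=np.uint8))
    out = equalize_histogram(img)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_equalize_two_level_cdf_map():
    """Half the pixels at V=0.2 and half at V=0.8 map to CDF values
    {0.5, 1.0} (up to 8-bit quantization)."""
    arr = np.zeros((2, 4, 3), dtype=np.uint8)
    arr[:, :2] = 51  # V = 0.2
    arr[:, 2:] = 204  # V = 0.8
    out = equalize_histogram(PixelGrid(arr))
    v = np.unique(out.pixels.max(axis=-1)) / 255.0
    np.testing.assert_allclose(sorted(v), [0.5, 1.0], atol=1.0 / 255)


def test_equalize_moves_v_cdf_toward_uniform_and_is_monotone():
    rng = np.random.default_rng(11)
    arr = rng.integers(40, 120, size=(32, 32, 3)).astype(np.uint8)
    img = PixelGrid(arr)
    out = equalize_histogram(img)
    assert out.pixels.shape == img.pixels.shape

    def ks_to_uniform(v255):
        levels = np.sort(v255.ravel()) / 255.0
        emp = np.arange(1, levels.size + 1) / levels.size
        return np.max(np.abs(emp - levels))

    assert ks_to_uniform(out.pixels.max(axis=-1)) <= ks_to_uniform(
        img.pixels.max(axis=-1)
    ) + 1e-12
    # the V remap is monotone non-decreasing
    vin = img.pixels.max(axis=-1).ravel()
    vout = out.pixels.max(axis=-1).ravel()
    order = np.argsort(vin, kind="stable")
    assert (np.diff(vout[order].astype(int))[np.diff(vin[order]) > 0] >= 0).all()


# ------------------------------------------------------------------ mean_v


@pytest.mark.parametrize(
    "fill, expected",
    [(255, 100.0), (128, 128 / 255 * 100)],
)
def test_mean_v_constant(fill, expected):
    img = PixelGrid(np.full((4, 4, 3), fill, dtype=np.uint8))
    assert mean_v(img) == pytest.approx(expected)
    assert mean_v(img, scale="unit") == pytest.approx(expected / 100.0)


def test_mean_v_half_black_half_white():
    arr = np.zeros((2, 2, 3), dtype=np.uint8)
    arr[0] = 255
    assert mean_v(PixelGrid(arr)) == pytest.approx(50.0)


def test_mean_v_invariances():
    img = PixelGrid(np.full((10, 6, 3), 77, dtype=np.uint8), exif_orientation=6)
    m = mean_v(img)
    assert mean_v(correct_orientation(img)) == pytest.approx(m)
    assert mean_v(crop_roi(img, ROISpec(fraction=0.5))) == pytest.approx(m)


# ---------------------------------------------------------- process_sample


def test_process_sample_recovers_concentration(standard_images, printed_model):
    """Noise-free fixtures across 0-10 mg/L come back within 0.1 mg/L."""
    for conc, path in standard_images:
        res = process_sample(path, ROISpec(), printed_model)
        assert res.concentration == pytest.approx(conc, abs=0.1)
        assert 0 <= res.mean_v <= 100


def test_process_sample_invariant_to_resize_target(save_image, printed_model):
    arr = np.full((60, 40, 3), 150, dtype=np.uint8)
    path = save_image(arr)
    a = process_sample(path, ROISpec(), printed_model, resize_target=1080)
    b = process_sample(path, ROISpec(), printed_model, resize_target=540)
    assert a.concentration == pytest.approx(b.concentration, abs=1e-9)
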