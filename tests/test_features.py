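"""Shape, texture, color and fluorescence descriptors."""

import math

import numpy as np
import pytest

from phytoscope import features as ft
from phytoscope.segment import trace_contour

from conftest import disk_mask


def make_particle(mask, gray=None, rgb=None, fluor=None):
    h, w = mask.shape
    if rgb is None:
        g = np.full((h, w), 128, dtype=np.uint8) if gray is None \
            else np.asarray(gray, dtype=np.uint8)
        rgb = np.stack([g, g, g], axis=2)
    fl = {name: np.zeros((h, w), dtype=np.uint8) for name in ("chl", "pe", "pc")}
    if fluor:
        fl.update({k: np.asarray(v, dtype=np.uint8) for k, v in fluor.items()})
    return ft.ParticleData(mask=mask, brightfield=rgb, fluor=fl,
                           contour=trace_contour(mask))


def ellipse_mask(shape, center, a, b, angle_deg=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    th = math.radians(angle_deg)
    u = (xx - center[1]) * math.cos(th) + (yy - center[0]) * math.sin(th)
    v = -(xx - center[1]) * math.sin(th) + (yy - center[0]) * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


# ---------------------------------------------------------------------------
# rotation normalization

def test_axis_aligned_ellipse_angle_zero():
    mask = ellipse_mask((81, 81), (40, 40), 30, 12)
    data = make_particle(mask)
    rotated, angle = ft.normalize_rotation(data)
    assert angle == 0.0
    assert rotated is data


@pytest.mark.parametrize("true_angle", [15, 37, -60])
def test_rotated_ellipse_angle_recovered(true_angle):
    mask = ellipse_mask((101, 101), (50, 50), 30, 12, angle_deg=true_angle)
    rotated, angle = ft.normalize_rotation(make_particle(mask))
    # moment angle has period 180 and flips sign with the image y axis
    assert angle == pytest.approx(true_angle, abs=1.0)
    residual = ft.ellipse_axes(rotated.mask)[2]
    assert abs(residual) <= 1.0


def test_disk_degenerate_angle_zero():
    mask = disk_mask((61, 61), (30, 30), 20)
    _, angle = ft.normalize_rotation(make_particle(mask))
    assert angle == 0.0


# ---------------------------------------------------------------------------
# basic shape statistics

def test_square_shape_statistics():
    mask = np.zeros((50, 50), dtype=bool)
    mask[10:40, 10:40] = True               # 30 x 30 square
    s = ft.shape_basic(mask, trace_contour(mask))
    assert s["area"] == 900
    assert s["solidity"] == pytest.approx(1.0, abs=0.001)
    assert s["circularity"] == pytest.approx(math.pi / 4.0, abs=0.1)
    assert s["min_feret"] == pytest.approx(30.0, abs=0.5)
    assert s["aspect_ratio"] == pytest.approx(1.0, abs=0.02)


def test_disk_shape_statistics():
    mask = disk_mask((61, 61), (30, 30), 20.5)   # diameter 41
    s = ft.shape_basic(mask, trace_contour(mask))
    assert 0.85 <= s["circularity"] <= 1.0
    assert s["solidity"] >= 0.98
    assert s["roundness"] == pytest.approx(1.0, abs=0.05)
    assert s["min_feret"] == pytest.approx(41, abs=1.0)


def test_convex_mask_has_solidity_one():
    # staircase digitization wedges shrink with resolution; at this size a
    # convex body must sit within 2% of the ideal solidity of 1
    mask = ellipse_mask((161, 161), (80, 80), 64, 40)
    s = ft.shape_basic(mask, trace_contour(mask))
    assert s["solidity"] == pytest.approx(1.0, abs=0.02)
    rect = np.zeros((40, 60), dtype=bool)
    rect[5:35, 5:55] = True
    assert ft.shape_basic(rect, trace_contour(rect))["solidity"] == 1.0


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors

def efd_coefficients_oracle(contour, n_harmonics):
    """Independent direct-summation EFD (explicit per-segment loops)."""
    pts = np.asarray(contour, dtype=float)
    xy = [(p[1], p[0]) for p in pts]
    xy.append(xy[0])
    dxs, dys, dts = [], [], []
    for (x0, y0), (x1, y1) in zip(xy[:-1], xy[1:]):
        dt = math.hypot(x1 - x0, y1 - y0)
        if dt > 0:
            dxs.append(x1 - x0)
            dys.append(y1 - y0)
            dts.append(dt)
    T = sum(dts)
    coeffs = []
    for n in range(1, n_harmonics + 1):
        a = b = c = d = 0.0
        t_prev = 0.0
        for dx, dy, dt in zip(dxs, dys, dts):
            t_cur = t_prev + dt
            w = T / (2.0 * math.pi ** 2 * n ** 2)
            cos_d = math.cos(2 * math.pi * n * t_cur / T) - \
                math.cos(2 * math.pi * n * t_prev / T)
            sin_d = math.sin(2 * math.pi * n * t_cur / T) - \
                math.sin(2 * math.pi * n * t_prev / T)
            a += w * dx / dt * cos_d
            b += w * dx / dt * sin_d
            c += w * dy / dt * cos_d
            d += w * dy / dt * sin_d
            t_prev = t_cur
        coeffs.append((a, b, c, d))
    return np.array(coeffs)


def test_efd_matches_direct_summation_on_square():
    mask = np.zeros((40, 40), dtype=bool)
    mask[8:32, 8:32] = True
    contour = trace_contour(mask)
    amps = ft.elliptic_fourier(contour, n_harmonics=12)
    oracle = efd_coefficients_oracle(contour, 12)
    oracle_amps = ft._normalize_efd(oracle)
    np.testing.assert_allclose(amps, oracle_amps, atol=1e-9)


def test_efd_first_harmonic_normalized_to_one():
    t = np.linspace(0, 2 * math.pi, 200, endpoint=False)
    pts = np.stack([20 * np.sin(t), 22 * np.cos(t)], axis=1)
    amps = ft.elliptic_fourier(pts)
    assert amps[0] == 1.0
    # mild ellipse: arc-length parameterization leaves only tiny higher
    # harmonics (they grow with eccentricity)
    assert amps[1:].max() < 0.02


def test_efd_rotation_and_scale_invariance():
    t = np.linspace(0, 2 * math.pi, 300, endpoint=False)
    base = np.stack([18 * np.sin(t) + 4 * np.sin(3 * t),
                     40 * np.cos(t)], axis=1)
    amps1 = ft.elliptic_fourier(base)
    th = math.radians(60)
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    transformed = 2.0 * (base @ R.T)
    amps2 = ft.elliptic_fourier(transformed)
    np.testing.assert_allclose(amps1, amps2, atol=1e-3)


def test_efd_open_contour_rejected():
    pts = np.stack([np.arange(20.0), np.zeros(20)], axis=1)
    with pytest.raises(ValueError, match="closed"):
        ft.elliptic_fourier(pts)


# ---------------------------------------------------------------------------
# co-occurrence texture

def test_glcm_constant_crop():
    crop = np.full((12, 12), 99.0)
    s = ft.glcm_stats(crop, np.ones((12, 12), dtype=bool))
    assert s["energy"] == pytest.approx(1.0)
    assert s["contrast"] == 0.0
    assert s["entropy"] == pytest.approx(0.0)
    assert s["homogeneity"] == pytest.approx(1.0)


def test_glcm_checkerboard_contrast_hand_count():
    # checkerboard of quantized levels 0 and 31; horizontal pairs always
    # differ by 31 levels -> contrast (31)^2 at 0 degrees
    yy, xx = np.mgrid[0:10, 0:10]
    crop = np.where((yy + xx) % 2 == 0, 0.0, 248.0)   # 248 // 8 -> level 31
    s = ft.glcm_stats(crop, np.ones((10, 10), dtype=bool),
                      offsets=[(0, 1)])
    assert s["contrast"] == pytest.approx(31.0 ** 2)
    assert s["energy"] == pytest.approx(0.5)      # two equal cells
    assert s["entropy"] == pytest.approx(1.0)     # two cells at 1/2


def test_glcm_too_small_mask_returns_zeros():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    s = ft.glcm_stats(np.random.default_rng(0).uniform(0, 255, (5, 5)), mask)
    assert all(v == 0.0 for v in s.values())


# ---------------------------------------------------------------------------
# directionality

def test_directionality_vertical_stripes_horizontal_gradient():
    xx = np.tile(np.arange(16.0), (16, 1))
    crop = 100 + 50 * np.sin(xx * math.pi / 2.0)
    hist = ft.directionality_hist(crop, np.ones((16, 16), dtype=bool))
    assert hist.sum() == pytest.approx(1.0)
    # horizontal gradients -> orientation 0 (mod pi): first and last bin
    assert hist[0] + hist[-1] >= 0.9


def test_directionality_rotation_permutes_bins():
    rng = np.random.default_rng(1)
    crop = rng.uniform(0, 255, (20, 20))
    h1 = ft.directionality_hist(crop, np.ones((20, 20), dtype=bool))
    h2 = ft.directionality_hist(np.rot90(crop),
                                np.ones((20, 20), dtype=bool))
    np.testing.assert_allclose(h2, np.roll(h1, 8), atol=0.08)


def test_directionality_flat_crop_uniform():
    hist = ft.directionality_hist(np.full((10, 10), 7.0),
                                  np.ones((10, 10), dtype=bool))
    np.testing.assert_allclose(hist, 1.0 / 16.0)


# ---------------------------------------------------------------------------
# invariant moments

def test_hu1_of_disk_matches_analytic():
    mask = disk_mask((201, 201), (100, 100), 80)
    hu = ft.image_moments(mask)
    assert hu[0] == pytest.approx(1.0 / (2.0 * math.pi), abs=0.003)


def test_hu_translation_invariance():
    m1 = np.zeros((120, 120), dtype=bool)
    m1[20:50, 30:80] = ellipse_mask((30, 50), (15, 25), 24, 12)
    m2 = np.zeros((120, 120), dtype=bool)
    m2[60:90, 10:60] = ellipse_mask((30, 50), (15, 25), 24, 12)
    np.testing.assert_allclose(ft.image_moments(m1), ft.image_moments(m2),
                               atol=1e-9)


def test_hu_rotation_invariance_90deg():
    mask = ellipse_mask((101, 101), (50, 50), 35, 15)
    hu1 = ft.image_moments(mask)
    hu2 = ft.image_moments(np.rot90(mask))
    np.testing.assert_allclose(hu1[:6], hu2[:6], atol=1e-6)


# ---------------------------------------------------------------------------
# local binary patterns

def riu2_code_oracle(pattern_bits):
    """riu2 code of an 8-bit neighbor pattern by explicit enumeration."""
    bits = list(pattern_bits)
    transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    return sum(bits) if transitions <= 2 else 9


def test_lbp_constant_crop_all_flat_code():
    hist = ft.lbp_riu(np.full((12, 12), 80.0), np.ones((12, 12), dtype=bool))
    assert hist[8] == 1.0
    assert hist.sum() == pytest.approx(1.0)


def test_lbp_codes_match_exhaustive_oracle():
    """Codes agree with per-pixel pattern enumeration on an 8x8 crop."""
    rng = np.random.default_rng(3)
    crop = rng.integers(0, 256, (8, 8)).astype(np.float64)
    codes = ft.lbp_codes(crop)
    for r in range(1, 7):
        for c in range(1, 7):
            bits = []
            for k in range(8):
                ang = 2 * math.pi * k / 8
                rr = r - math.sin(ang)
                cc = c + math.cos(ang)
                r0, c0 = int(math.floor(rr)), int(math.floor(cc))
                fr, fc = rr - r0, cc - c0
                r1 = r0 + 1 if fr > 0 else r0
                c1 = c0 + 1 if fc > 0 else c0
                val = (crop[r0, c0] * (1 - fr) * (1 - fc)
                       + crop[r0, c1] * (1 - fr) * fc
                       + crop[r1, c0] * fr * (1 - fc)
                       + crop[r1, c1] * fr * fc)
                if abs(val - crop[r, c]) < 1e-7:
                    val = crop[r, c]
                bits.append(1 if val >= crop[r, c] else 0)
            assert codes[r, c] == riu2_code_oracle(bits)


def test_lbp_agrees_with_skimage_reference():
    from skimage.feature import local_binary_pattern
    rng = np.random.default_rng(4)
    crop = rng.integers(0, 256, (24, 24))
    mine = ft.lbp_codes(crop.astype(np.float64))
    ref = local_binary_pattern(crop, 8, 1, method="uniform")
    inner = (slice(1, -1), slice(1, -1))
    assert (mine[inner] == ref[inner].astype(int)).mean() == 1.0


def test_lbp_rotation_invariance():
    rng = np.random.default_rng(5)
    crop = np.asarray(np.clip(
        100 + 40 * np.cumsum(rng.standard_normal((30, 30)), axis=0) / 5,
        0, 255))
    mask = np.ones((30, 30), dtype=bool)
    h1 = ft.lbp_riu(crop, mask)
    h2 = ft.lbp_riu(np.rot90(crop), mask)
    assert np.abs(h1 - h2).sum() <= 0.02


def test_lbp_too_small_crop_rejected():
    with pytest.raises(ValueError, match="too small"):
        ft.lbp_riu(np.zeros((2, 8)), np.ones((2, 8), dtype=bool))


# ---------------------------------------------------------------------------
# symmetry

def test_symmetric_particle_scores_one():
    mask = ellipse_mask((41, 61), (20, 30), 25, 14)
    yy, xx = np.mgrid[0:41, 0:61]
    crop = 100 + 50 * np.exp(-((xx - 30) ** 2 + (yy - 20) ** 2) / 100.0)
    s = ft.symmetry_measure(crop, mask)
    assert s["sym_major"] == pytest.approx(1.0, abs=0.05)
    assert s["sym_minor"] == pytest.approx(1.0, abs=0.05)


def test_half_bright_half_dark_antisymmetric():
    mask = ellipse_mask((41, 61), (20, 30), 25, 14)
    crop = np.full((41, 61), 50.0)
    crop[:20] = 200.0               # bright above the major axis
    s = ft.symmetry_measure(crop, mask)
    assert s["sym_major"] < -0.9


def test_symmetry_invariant_to_intensity_offset():
    rng = np.random.default_rng(6)
    mask = ellipse_mask((31, 51), (15, 25), 22, 12)
    crop = rng.uniform(0, 200, (31, 51))
    s1 = ft.symmetry_measure(crop, mask)
    s2 = ft.symmetry_measure(crop + 30.0, mask)
    assert s1["sym_major"] == pytest.approx(s2["sym_major"], abs=1e-9)
    assert s1["sym_minor"] == pytest.approx(s2["sym_minor"], abs=1e-9)


def test_constant_crop_symmetry_one():
    mask = np.ones((11, 11), dtype=bool)
    s = ft.symmetry_measure(np.full((11, 11), 9.0), mask)
    assert s == {"sym_major": 1.0, "sym_minor": 1.0}


# ---------------------------------------------------------------------------
# color and fluorescence

def _rgb(h, w, color):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = color
    return img


def test_hue_histogram_pure_colors():
    mask = np.ones((10, 10), dtype=bool)
    red = ft.hue_histogram(_rgb(10, 10, (255, 0, 0)), mask)
    assert red[0] == 1.0
    green = ft.hue_histogram(_rgb(10, 10, (0, 255, 0)), mask)
    # hue 120 deg -> bin floor(120/360*16) = 5
    assert green[5] == 1.0


def test_hue_histogram_red_blue_split():
    img = _rgb(10, 10, (255, 0, 0))
    img[:, 5:] = (0, 0, 255)
    hist = ft.hue_histogram(img, np.ones((10, 10), dtype=bool))
    assert hist[0] == pytest.approx(0.5)
    # hue 240 deg -> bin floor(240/360*16) = 10
    assert hist[10] == pytest.approx(0.5)


def test_hue_histogram_gray_particle_uniform():
    hist = ft.hue_histogram(_rgb(10, 10, (128, 128, 128)),
                            np.ones((10, 10), dtype=bool))
    np.testing.assert_allclose(hist, 1.0 / 16.0)


def test_fluorescence_means():
    mask = disk_mask((30, 30), (15, 15), 8)
    chl = np.zeros((30, 30), dtype=np.uint8)
    chl[mask] = 100
    pe = np.zeros((30, 30), dtype=np.uint8)
    half = mask & (np.arange(30)[None, :] >= 15)
    pe[half] = 200
    data = make_particle(mask, fluor={"chl": chl, "pe": pe})
    means = ft.fluorescence_means(data)
    assert means["mean_chl"] == 100.0
    assert means["mean_pc"] == 0.0
    assert 0 < means["mean_pe"] < 200


# ---------------------------------------------------------------------------
# assembly

def test_feature_set_sizes_and_order():
    assert len(ft.STAGE1_FEATURES) == 21
    assert len(ft.STAGE2_FEATURES) == 48
    assert set(ft.STAGE1_FEATURES) < set(ft.FULL_FEATURES)
    assert set(ft.STAGE2_FEATURES) < set(ft.FULL_FEATURES)
    for name in ("circularity", "roundness", "solidity", "min_feret",
                 "perimeter", "area", "hu_1"):
        assert name in ft.STAGE2_FEATURES
    assert [n for n in ft.STAGE2_FEATURES if n.startswith("efd_")] == \
        [f"efd_{i:02d}" for i in range(2, 14)]


def test_assemble_matches_spec_order_and_determinism():
    mask = ellipse_mask((41, 61), (20, 30), 24, 12)
    data = make_particle(mask)
    for name, n_expected in (("stage1", 21), ("stage2", 48)):
        spec = ft.feature_set(name)
        vec = ft.assemble_features(data, spec)
        assert list(vec.index) == list(spec.feature_names)
        assert len(vec) == n_expected
        assert np.isfinite(vec.to_numpy()).all()
    v1 = ft.assemble_features(data, ft.feature_set("stage2"))
    v2 = ft.assemble_features(data, ft.feature_set("stage2"))
    assert (v1 == v2).all()


def test_unknown_feature_set_rejected():
    with pytest.raises(KeyError, match="unknown feature set"):
        ft.feature_set("stage3")


def test_histogram_features_normalized(rendered_scene):
    from phytoscope.preprocess import correct_frame
    from phytoscope import synthetic as syn
    _, frame, truth = rendered_scene
    crops = syn.crops_from_scene(frame, truth)
    vec = ft.assemble_features(crops[0], ft.feature_set("full"))
    for prefix in ("hue_", "lbp_", "dir_"):
        block = vec[[n for n in vec.index if n.startswith(prefix)]]
        assert block.min() >= 0
        assert block.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# cross-feature invariances

def _textured_ellipse(angle_deg):
    mask = ellipse_mask((121, 121), (60, 60), 40, 18, angle_deg=angle_deg)
    yy, xx = np.mgrid[0:121, 0:121]
    th = math.radians(angle_deg)
    u = (xx - 60) * math.cos(th) + (yy - 60) * math.sin(th)
    v = -(xx - 60) * math.sin(th) + (yy - 60) * math.cos(th)
    g = 120 + 60 * np.sin(u / 6.0) * np.cos(v / 5.0)
    g = np.clip(np.where(mask, g, 235), 0, 255)
    return make_particle(mask, gray=g)


def test_rotation_robustness_of_texture_and_shape_features():
    """Same particle rendered at 0 and 45 degrees: riu2 LBP, EFD amplitudes
    and Hu-1 must be stable within the stated tolerances."""
    d0 = _textured_ellipse(0)
    d45 = _textured_ellipse(45)
    spec = ft.feature_set("stage2")
    v0 = ft.assemble_features(d0, spec)
    v45 = ft.assemble_features(d45, spec)
    lbp = [n for n in spec.feature_names if n.startswith("lbp_")]
    assert np.abs(v0[lbp] - v45[lbp]).sum() <= 0.05
    efd = [n for n in spec.feature_names if n.startswith("efd_")]
    assert np.abs(v0[efd] - v45[efd]).max() <= 0.05 * max(v0[efd].max(), 1e-9) + 5e-3
    assert abs(v0["hu_1"] - v45["hu_1"]) / v0["hu_1"] <= 0.02


def test_scale_behavior():
    """Doubling the size doubles min_feret and quadruples area; normalized
    EFD amplitudes stay put."""
    m1 = ellipse_mask((101, 101), (50, 50), 24, 12)
    m2 = ellipse_mask((201, 201), (100, 100), 48, 24)
    s1 = ft.shape_basic(m1, trace_contour(m1))
    s2 = ft.shape_basic(m2, trace_contour(m2))
    assert s2["min_feret"] == pytest.approx(2 * s1["min_feret"], rel=0.05)
    assert s2["area"] == pytest.approx(4 * s1["area"], rel=0.05)
    a1 = ft.elliptic_fourier(trace_contour(m1))
    a2 = ft.elliptic_fourier(trace_contour(m2))
    assert np.abs(a1 - a2).max() <= 0.02
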