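"""Per-particle feature battery.

Each segmented particle is described by shape, texture, color and
fluorescence descriptors:

* basic shape statistics (area, perimeter, circularity, roundness, solidity,
  minimum Feret diameter, aspect ratio),
* normalized elliptic Fourier amplitudes of the closed contour,
* Hu invariant moments of the binary mask,
* rotation-invariant uniform local binary patterns (riu2),
* gray-level co-occurrence (Haralick) statistics,
* a gradient-direction histogram and mirror-symmetry scores,
* a saturation-weighted hue histogram,
* mean fluorescence intensity per channel inside the mask.

Intensity textures that are not rotation invariant by construction
(directionality, symmetry, co-occurrence) are computed after the particle is
rotated so the major axis of its fitted ellipse lies at angle zero; shape,
contour and mask descriptors are rotation invariant by construction and use
the original mask.  Two named sub-sets feed the classifiers: ``stage1``
(color + fluorescence + size, 21 values) gates plankton from non-plankton,
``stage2`` (48 values) separates the taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.color import rgb2hsv
from scipy.spatial import ConvexHull

from .frames import brightness
from .preprocess import CorrectedFrame
from .segment import ParticleROI, contour_perimeter

FLUOR_CHANNELS = ("chl", "pe", "pc")


# ---------------------------------------------------------------------------
# particle data bundle

@dataclass
class ParticleData:
    """Everything needed to compute features for one particle.

    ``brightfield`` is the corrected RGB crop, ``fluor`` maps channel name to
    the matching grayscale crop; all arrays share the mask's shape.
    """

    mask: np.ndarray
    brightfield: np.ndarray
    fluor: dict[str, np.ndarray]
    contour: np.ndarray
    frame_id: str = "frame"
    particle_id: int = 0
    class_label: str | None = None

    @classmethod
    def from_roi(cls, roi: ParticleROI, corrected: CorrectedFrame,
                 class_label: str | None = None) -> "ParticleData":
        return cls(
            mask=roi.mask,
            brightfield=roi.crop(corrected.brightfield),
            fluor={name: roi.crop(img)
                   for name, img in corrected.fluorescence().items()},
            contour=roi.contour,
            frame_id=roi.frame_id,
            particle_id=roi.particle_id,
            class_label=class_label,
        )


# ---------------------------------------------------------------------------
# rotation normalization

def ellipse_axes(mask: np.ndarray) -> tuple[float, float, float]:
    """Fitted-ellipse (major, minor, angle_deg) from mask second moments.

    The ellipse shares the mask's area-normalized second central moments;
    the angle is measured between the major axis and the x (column) axis.
    A degenerate (circular) mask gets angle 0 by convention.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    n = xs.size
    if n == 0:
        raise ValueError("empty mask")
    xc, yc = xs.mean(), ys.mean()
    mu20 = ((xs - xc) ** 2).mean()
    mu02 = ((ys - yc) ** 2).mean()
    mu11 = ((xs - xc) * (ys - yc)).mean()
    common = math.sqrt((mu20 - mu02) ** 2 + 4 * mu11 ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    if common < 1e-9:
        angle = 0.0
    else:
        angle = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    return major, minor, angle


def normalize_rotation(data: ParticleData) -> tuple[ParticleData, float]:
    """Rotate a particle so its fitted-ellipse major axis lies at angle 0.

    Intensity channels are resampled bilinearly, the mask with nearest
    neighbor.  Returns the rotated bundle and the applied angle in degrees
    (0 for degenerate, circular particles).
    """
    _, _, angle = ellipse_axes(data.mask)
    if abs(angle) < 1e-12:
        return data, 0.0
    # image y axis points down: a positive moment angle maps to scipy's
    # positive rotation angle when undoing it
    mask = ndi.rotate(data.mask.astype(np.uint8), angle, reshape=True,
                      order=0) > 0
    bf = np.stack([
        ndi.rotate(data.brightfield[:, :, c].astype(np.float64), angle,
                   reshape=True, order=1)
        for c in range(3)
    ], axis=2)
    bf = np.clip(np.rint(bf), 0, 255).astype(np.uint8)
    fluor = {
        name: np.clip(np.rint(
            ndi.rotate(img.astype(np.float64), angle, reshape=True,
                       order=1)), 0, 255).astype(np.uint8)
        for name, img in data.fluor.items()
    }
    from .segment import trace_contour
    contour = trace_contour(mask) if mask.any() else data.contour
    rotated = ParticleData(mask=mask, brightfield=bf, fluor=fluor,
                           contour=contour, frame_id=data.frame_id,
                           particle_id=data.particle_id,
                           class_label=data.class_label)
    return rotated, float(angle)


# ---------------------------------------------------------------------------
# shape

def min_feret(contour: np.ndarray, step_deg: float = 1.0) -> float:
    """Minimum caliper width of the contour's pixel squares over rotations."""
    pts = np.asarray(contour, dtype=np.float64)
    # pixel corners so width reflects pixel extent, not center distance
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.sin(angles), np.cos(angles)], axis=1)  # (row, col)
    proj = corners @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def _polygon_area(pts: np.ndarray) -> float:
    """Shoelace area of a closed (row, col) polygon."""
    y, x = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def shape_basic(mask: np.ndarray, contour: np.ndarray) -> dict[str, float]:
    """Basic shape statistics of a particle mask and its boundary chain.

    Solidity compares the outline polygon's area with its convex hull's
    area (both via the shoelace formula), so a digitally convex shape
    scores ~1 despite its staircase boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    perim = contour_perimeter(contour)
    circularity = min(1.0, 4.0 * math.pi * area / perim ** 2) if perim > 0 else 1.0
    major, minor, _ = ellipse_axes(mask)
    roundness = 4.0 * area / (math.pi * major ** 2) if major > 0 else 1.0
    pts = np.asarray(contour, dtype=np.float64)
    poly_area = _polygon_area(pts)
    if poly_area > 0 and len(pts) >= 3:
        hull = ConvexHull(pts)
        solidity = min(1.0, poly_area / hull.volume)
    else:
        solidity = 1.0
    aspect = major / minor if minor > 0 else 1.0
    return {
        "area": area,
        "perimeter": perim,
        "circularity": circularity,
        "roundness": roundness,
        "solidity": solidity,
        "min_feret": min_feret(contour),
        "aspect_ratio": aspect,
    }


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors

def elliptic_fourier(contour: np.ndarray, n_harmonics: int = 29) -> np.ndarray:
    """Normalized elliptic Fourier amplitudes of a closed boundary chain.

    The chain is decomposed into per-harmonic coefficients (a_n, b_n, c_n,
    d_n), normalized for starting point and rotation via the first harmonic's
    ellipse, and scaled so the first harmonic's amplitude is 1.  Returns
    amplitudes for harmonics 1..n_harmonics.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if len(pts) < 8:
        raise ValueError("contour must have at least 8 points")
    gap = np.abs(pts[-1] - pts[0]).max()
    if gap > 1.5:
        raise ValueError("contour is not closed")
    xy = np.stack([pts[:, 1], pts[:, 0]], axis=1)      # (x, y)
    d = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if len(d) < 4:
        raise ValueError("degenerate contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]          # (H, 1)
    phi = 2.0 * math.pi * t / T                          # (M+1,)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])   # (H, M)
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * math.pi ** 2 * n[:, 0] ** 2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = const * (cos_d @ dxdt)
    b = const * (sin_d @ dxdt)
    c = const * (cos_d @ dydt)
    e = const * (sin_d @ dydt)
    coeffs = np.stack([a, b, c, e], axis=1)              # (H, 4)
    return _normalize_efd(coeffs)


def _normalize_efd(coeffs: np.ndarray) -> np.ndarray:
    """Start-point, rotation and scale normalization; returns amplitudes."""
    a1, b1, c1, d1 = coeffs[0]
    # shift the starting point so the first harmonic phase vanishes
    theta = 0.5 * math.atan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 ** 2 - b1 ** 2 + c1 ** 2 - d1 ** 2)
    out = coeffs.copy()
    for i in range(len(coeffs)):
        n = i + 1
        ct, st = math.cos(n * theta), math.sin(n * theta)
        rot = np.array([[ct, -st], [st, ct]])
        ab = out[i, :2] @ rot
        cd = out[i, 2:] @ rot
        out[i, :2], out[i, 2:] = ab, cd
    # rotate the coordinate frame onto the first harmonic's major axis
    a1, b1, c1, d1 = out[0]
    psi = math.atan2(c1, a1)
    cp, sp = math.cos(psi), math.sin(psi)
    R = np.array([[cp, sp], [-sp, cp]])
    for i in range(len(out)):
        m = R @ out[i].reshape(2, 2)
        out[i] = m.ravel()
    amps = np.sqrt((out ** 2).sum(axis=1))
    if amps[0] <= 0:
        raise ValueError("degenerate contour: zero first-harmonic amplitude")
    return amps / amps[0]


# ---------------------------------------------------------------------------
# texture

def glcm_stats(crop: np.ndarray, mask: np.ndarray, levels: int = 32,
               offsets: list[tuple[int, int]] | None = None
               ) -> dict[str, float]:
    """Haralick statistics of a masked gray-level co-occurrence matrix.

    Symmetric, normalized co-occurrence at distance 1 averaged over the four
    principal directions (or the given ``offsets``); only pixel pairs fully
    inside the mask count.  Fewer than 2 valid pairs yields all-zero
    statistics.
    """
    crop = np.asarray(crop, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    q = np.clip((crop / 256.0 * levels).astype(np.int64), 0, levels - 1)
    glcm = np.zeros((levels, levels), dtype=np.float64)
    if offsets is None:
        offsets = [(0, 1), (1, 1), (1, 0), (1, -1)]
    h, w = mask.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src_m = mask[r0:r1, c0:c1]
        dst_m = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = src_m & dst_m
        if not valid.any():
            continue
        i = q[r0:r1, c0:c1][valid]
        j = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)      # symmetric
    total = glcm.sum()
    if total < 4:                          # fewer than 2 pairs counted twice
        return {k: 0.0 for k in
                ("contrast", "correlation", "energy", "homogeneity", "entropy")}
    p = glcm / total
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    pi = p.sum(axis=1)
    mu = float((idx * pi).sum())
    var = float(((idx - mu) ** 2 * pi).sum())
    if var > 1e-12:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 1.0
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"contrast": contrast, "correlation": correlation,
            "energy": energy, "homogeneity": homogeneity, "entropy": entropy}


def directionality_hist(crop: np.ndarray, mask: np.ndarray,
                        bins: int = 16) -> np.ndarray:
    """Magnitude-weighted histogram of Sobel gradient orientations.

    Orientations live in [0, 180) degrees; the histogram is normalized to
    sum 1 and falls back to uniform when the masked gradient vanishes.
    """
    crop = np.asarray(crop, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    gx = ndi.sobel(crop, axis=1, mode="nearest")
    gy = ndi.sobel(crop, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)[mask]
    ang = np.mod(np.arctan2(gy, gx)[mask], math.pi)
    if mag.sum() <= 1e-12:
        return np.full(bins, 1.0 / bins)
    hist, _ = np.histogram(ang, bins=bins, range=(0.0, math.pi), weights=mag)
    return hist / hist.sum()


def image_moments(mask: np.ndarray) -> np.ndarray:
    """The seven Hu invariant moments of a binary mask."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    mu = measure.moments_central(mask)
    nu = measure.moments_normalized(mu)
    return measure.moments_hu(nu)


def lbp_riu(crop: np.ndarray, mask: np.ndarray, P: int = 8,
            R: float = 1.0) -> np.ndarray:
    """Rotation-invariant uniform (riu2) local binary pattern histogram.

    Each interior masked pixel is compared against ``P`` circular neighbors
    at radius ``R`` (bilinear sampling).  Uniform patterns (at most two 0/1
    transitions around the circle) are coded by their number of set bits
    (0..P); everything else shares the non-uniform code ``P+1``, giving a
    ``P+2``-bin histogram normalized to sum 1.
    """
    crop = np.asarray(crop, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    h, w = crop.shape
    r_int = int(math.ceil(R))
    if h < 2 * r_int + 1 or w < 2 * r_int + 1:
        raise ValueError(f"crop {crop.shape} too small for radius {R}")
    codes = lbp_codes(crop, P, R)
    interior = np.zeros_like(mask)
    interior[r_int:h - r_int, r_int:w - r_int] = True
    sel = mask & interior
    nbins = P + 2
    if not sel.any():
        return np.full(nbins, 1.0 / nbins)
    hist = np.bincount(codes[sel], minlength=nbins).astype(np.float64)
    return hist / hist.sum()


def lbp_codes(crop: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Per-pixel riu2 codes (border pixels use replicated-edge sampling)."""
    crop = np.asarray(crop, dtype=np.float64)
    h, w = crop.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    signs = np.zeros((P, h, w), dtype=bool)
    for k in range(P):
        ang = 2.0 * math.pi * k / P
        dr = -R * math.sin(ang)
        dc = R * math.cos(ang)
        sampled = ndi.map_coordinates(crop, [rows + dr, cols + dc],
                                      order=1, mode="nearest")
        # kill interpolation round-off so exact-equal neighbors count as >=
        sampled = np.where(np.abs(sampled - crop) < 1e-7, crop, sampled)
        signs[k] = sampled >= crop
    bits = signs.astype(np.int8)
    transitions = np.abs(np.diff(bits, axis=0)).sum(axis=0) + \
        np.abs(bits[0] - bits[-1])
    ones = bits.sum(axis=0)
    codes = np.where(transitions <= 2, ones, P + 1)
    return codes.astype(np.int64)


def symmetry_measure(crop: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mirror-symmetry correlation across the major and minor axes.

    Assumes a rotation-normalized particle (major axis horizontal).  Each
    score is the Pearson correlation between masked intensities and their
    mirror image, evaluated where both the mask and its mirror overlap;
    a constant crop scores 1 by convention.
    """
    crop = np.asarray(crop, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)

    def _corr(flip):
        fcrop = flip(crop)
        fmask = flip(mask)
        sel = mask & fmask
        if sel.sum() < 2:
            return 1.0
        x = crop[sel]
        y = fcrop[sel]
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            return 1.0
        return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))

    return {"sym_major": _corr(np.flipud), "sym_minor": _corr(np.fliplr)}


# ---------------------------------------------------------------------------
# color and fluorescence

def hue_histogram(rgb_crop: np.ndarray, mask: np.ndarray,
                  bins: int = 16) -> np.ndarray:
    """Saturation-weighted hue histogram of the masked pixels.

    Gray pixels carry little saturation and therefore little weight; a fully
    unsaturated particle yields a uniform histogram.
    """
    mask = np.asarray(mask, dtype=bool)
    hsv = rgb2hsv(np.asarray(rgb_crop, dtype=np.uint8))
    hue = hsv[:, :, 0][mask]
    sat = hsv[:, :, 1][mask]
    if sat.sum() <= 1e-9:
        return np.full(bins, 1.0 / bins)
    hist, _ = np.histogram(hue, bins=bins, range=(0.0, 1.0), weights=sat)
    return hist / hist.sum()


def fluorescence_means(data: ParticleData) -> dict[str, float]:
    """Mean fluorescence intensity inside the mask, per channel."""
    mask = np.asarray(data.mask, dtype=bool)
    return {f"mean_{name}": float(data.fluor[name][mask].mean())
            for name in FLUOR_CHANNELS}


# ---------------------------------------------------------------------------
# feature sets and assembly

_HUE_NAMES = [f"hue_{i:02d}" for i in range(16)]
_LBP_NAMES = [f"lbp_{i:02d}" for i in range(10)]
_DIR_NAMES = [f"dir_{i:02d}" for i in range(16)]
_FLUOR_NAMES = [f"mean_{c}" for c in FLUOR_CHANNELS]

STAGE1_FEATURES = tuple(_HUE_NAMES + _FLUOR_NAMES + ["area", "circularity"])

STAGE2_FEATURES = tuple(
    _LBP_NAMES
    + ["hu_1"]
    + [f"efd_{i:02d}" for i in range(2, 14)]
    + ["circularity", "roundness", "solidity", "min_feret", "perimeter",
       "area"]
    + _HUE_NAMES
    + _FLUOR_NAMES
)

FULL_FEATURES = tuple(
    ["area", "perimeter", "circularity", "roundness", "solidity",
     "min_feret", "aspect_ratio"]
    + [f"efd_{i:02d}" for i in range(1, 30)]
    + [f"hu_{i}" for i in range(1, 8)]
    + _LBP_NAMES
    + ["glcm_contrast", "glcm_correlation", "glcm_energy",
       "glcm_homogeneity", "glcm_entropy"]
    + _DIR_NAMES
    + ["sym_major", "sym_minor"]
    + _HUE_NAMES
    + _FLUOR_NAMES
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named, ordered selection of feature columns."""

    name: str
    feature_names: tuple[str, ...]


_SETS = {
    "stage1": FeatureSetSpec("stage1", STAGE1_FEATURES),
    "stage2": FeatureSetSpec("stage2", STAGE2_FEATURES),
    "full": FeatureSetSpec("full", FULL_FEATURES),
}


def feature_set(name: str) -> FeatureSetSpec:
    try:
        return _SETS[name]
    except KeyError:
        raise KeyError(f"unknown feature set {name!r}; "
                       f"expected one of {sorted(_SETS)}") from None


def compute_all_features(data: ParticleData,
                         names: tuple[str, ...]) -> dict[str, float]:
    """Compute the named features for one particle (lazily per family)."""
    need = set(names)
    out: dict[str, float] = {}

    if need & {"area", "perimeter", "circularity", "roundness", "solidity",
               "min_feret", "aspect_ratio"}:
        out.update(shape_basic(data.mask, data.contour))
    if any(n.startswith("efd_") for n in need):
        amps = elliptic_fourier(data.contour)
        out.update({f"efd_{i + 1:02d}": float(a) for i, a in enumerate(amps)})
    if any(n.startswith("hu_") for n in need):
        hu = image_moments(data.mask)
        out.update({f"hu_{i + 1}": float(v) for i, v in enumerate(hu)})
    if any(n.startswith("hue_") for n in need):
        hh = hue_histogram(data.brightfield, data.mask)
        out.update({name: float(v) for name, v in zip(_HUE_NAMES, hh)})
    if any(n.startswith("mean_") for n in need):
        out.update(fluorescence_means(data))

    texture_needed = (any(n.startswith(("lbp_", "dir_", "glcm_")) for n in need)
                      or {"sym_major", "sym_minor"} & need)
    if texture_needed:
        rotated, _ = normalize_rotation(data)
        gray = brightness(rotated.brightfield)
        if any(n.startswith("lbp_") for n in need):
            lh = lbp_riu(gray, rotated.mask)
            out.update({name: float(v) for name, v in zip(_LBP_NAMES, lh)})
        if any(n.startswith("glcm_") for n in need):
            out.update({f"glcm_{k}": v
                        for k, v in glcm_stats(gray, rotated.mask).items()})
        if any(n.startswith("dir_") for n in need):
            dh = directionality_hist(gray, rotated.mask)
            out.update({name: float(v) for name, v in zip(_DIR_NAMES, dh)})
        if {"sym_major", "sym_minor"} & need:
            out.update(symmetry_measure(gray, rotated.mask))
    return out


def assemble_features(data: ParticleData, spec: FeatureSetSpec) -> pd.Series:
    """Ordered feature vector for one particle, matching ``spec`` exactly."""
    values = compute_all_features(data, spec.feature_names)
    missing = [n for n in spec.feature_names if n not in values]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")
    vec = pd.Series({n: values[n] for n in spec.feature_names},
                    index=list(spec.feature_names), dtype=np.float64)
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise ValueError(f"non-finite feature value(s): {bad}")
    return vec


def feature_table(particles: list[ParticleData],
                  spec: FeatureSetSpec) -> pd.DataFrame:
    """Feature table for a list of particles.

    Columns: ``particle_id``, ``frame_id``, ``class_label`` followed by the
    feature columns in spec order.
    """
    rows = []
    for p in particles:
        vec = assemble_features(p, spec)
        row = {"particle_id": p.particle_id, "frame_id": p.frame_id,
               "class_label": p.class_label}
        row.update(vec.to_dict())
        rows.append(row)
    cols = ["particle_id", "frame_id", "class_label"] + list(spec.feature_names)
    return pd.DataFrame(rows, columns=cols)
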