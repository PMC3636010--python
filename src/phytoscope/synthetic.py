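"""Synthetic micrograph generator with pixel-exact ground truth.

Generates the five-channel frame sets the analysis pipeline consumes —
bright-field, blank reference and three fluorescence channels — with known
particle masks and taxon labels, so segmentation, feature extraction and
classification can be exercised and scored without any microscope.

The generator emulates the statistical structure the pipeline assumes:

* a light background with a linear illumination gradient (shared by the
  blank reference, which carries neither particles nor noise),
* opaque or pigmented plankton bodies drawn from distinct shape families
  (single cells, chains, stars, colony plates, spiny cells),
* autofluorescence only inside plankton bodies, with a per-taxon pigment
  profile over the chlorophyll / phycoerythrin / phycocyanin channels,
* brown, non-fluorescent detritus particles,
* additive Gaussian sensor noise.

All particles are rendered fully in focus.  No optics are simulated (no
point-spread function, depth of field or photobleaching).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .features import ParticleData
from .frames import FrameSet
from .preprocess import correct_frame
from .segment import trace_contour

SHAPE_FAMILIES = ("disk", "ellipse", "cell_chain", "star", "colony_grid",
                  "spiny_disk")


@dataclass(frozen=True)
class TaxonTemplate:
    """Rendering recipe for one particle class.

    ``size_range`` is the min/max equivalent diameter in pixels (min 12 px,
    so rendered particles clear the 100 px area filter by construction);
    ``pigment_profile`` gives the mean fluorescence gray level per channel
    (chlorophyll, phycoerythrin, phycocyanin) — all zero for detritus;
    ``texture_amplitude`` controls internal mottling of the body.
    """

    name: str
    shape_family: str
    size_range: tuple[float, float]
    body_color: tuple[int, int, int]
    pigment_profile: tuple[float, float, float]
    texture_amplitude: float = 15.0

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.size_range[0] < 12:
            raise ValueError("size_range minimum must be >= 12 px")
        if any(p < 0 for p in self.pigment_profile):
            raise ValueError("pigment_profile entries must be >= 0")


@dataclass
class SceneSpec:
    """Full description of one synthetic frame set.

    ``templates`` maps each TaxonTemplate to the number of particles to
    place.  Identical spec + seed render bit-identical images.
    """

    image_size: tuple[int, int] = (512, 512)          # (width, height)
    templates: list[tuple[TaxonTemplate, int]] = field(default_factory=list)
    background_level: tuple[int, int, int] = (230, 228, 225)
    gradient_amplitude: float = 12.0
    noise_sigma: float = 2.0
    rng_seed: int = 0
    allow_occlusion: bool = False
    frame_id: str = "synthetic"


@dataclass
class GroundTruth:
    """Label image (0 = background, k = particle id) and id -> taxon map."""

    label_image: np.ndarray
    particle_labels: dict[int, str]


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# shape rasterization

def _rot(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return points @ np.array([[c, -s], [s, c]]).T


def _fill_canvas(points_rc: np.ndarray, pad: int = 2) -> np.ndarray:
    """Solid polygon mask from (row, col) vertices, tightly cropped."""
    pts = points_rc - points_rc.min(axis=0) + pad
    h = int(math.ceil(pts[:, 0].max())) + pad + 1
    w = int(math.ceil(pts[:, 1].max())) + pad + 1
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=mask.shape)
    mask[rr, cc] = True
    return mask


def _disk_mask(radius: float, canvas: int | None = None) -> np.ndarray:
    n = canvas or (2 * int(math.ceil(radius)) + 3)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


def _stamp(canvas: np.ndarray, mask: np.ndarray, center_rc: tuple[int, int]):
    h, w = mask.shape
    H, W = canvas.shape
    r0 = center_rc[0] - h // 2
    c0 = center_rc[1] - w // 2
    rs, cs = max(0, r0), max(0, c0)
    re, ce = min(H, r0 + h), min(W, c0 + w)
    if re <= rs or ce <= cs:
        return
    canvas[rs:re, cs:ce] |= mask[rs - r0:re - r0, cs - c0:ce - c0]


def _enforce_4conn(mask: np.ndarray) -> np.ndarray:
    """Bridge diagonal-only junctions, then keep the largest 4-component.

    Rasterized thin structures (star points, spines) can connect only
    diagonally; a pixel is added at every diagonal-only junction so the
    ground-truth regions are genuinely 4-connected.
    """
    mask = mask.copy()
    for _ in range(8):
        a = mask[:-1, :-1] & mask[1:, 1:] & ~mask[:-1, 1:] & ~mask[1:, :-1]
        b = mask[:-1, 1:] & mask[1:, :-1] & ~mask[:-1, :-1] & ~mask[1:, 1:]
        if not (a.any() or b.any()):
            break
        mask[:-1, 1:] |= a
        mask[:-1, :-1] |= b
    lab, n = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1],
                                                 [0, 1, 0]], dtype=bool))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def render_shape(family: str, d_eq: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """Rasterize one particle body of roughly ``d_eq`` equivalent diameter."""
    return _enforce_4conn(_raw_shape(family, d_eq, rng))


def _raw_shape(family: str, d_eq: float, rng: np.random.Generator
               ) -> np.ndarray:
    r = d_eq / 2.0
    angle = rng.uniform(0, math.pi)
    if family == "disk":
        return _disk_mask(r)
    if family == "ellipse":
        q = rng.uniform(1.6, 2.4)
        a, b = r * math.sqrt(q), r / math.sqrt(q)
        t = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        pts = np.stack([b * np.sin(t), a * np.cos(t)], axis=1)
        return _fill_canvas(_rot(pts, angle))
    if family == "cell_chain":
        k = int(rng.integers(3, 6))
        rc = 1.05 * r / math.sqrt(k)
        span = 1.5 * rc * (k - 1)
        n = int(math.ceil(span + 2 * rc)) + 6
        canvas = np.zeros((n, n), dtype=bool)
        cell = _disk_mask(rc)
        direction = np.array([math.sin(angle), math.cos(angle)])
        for i in range(k):
            off = (i - (k - 1) / 2.0) * 1.5 * rc * direction
            wob = rng.uniform(-0.2, 0.2) * rc
            center = (int(round(n / 2 + off[0] + wob)),
                      int(round(n / 2 + off[1])))
            _stamp(canvas, cell, center)
        return canvas
    if family == "star":
        m = int(rng.integers(4, 7))
        t = np.linspace(0, 2 * math.pi, 2 * m, endpoint=False)
        radii = np.where(np.arange(2 * m) % 2 == 0, 1.35 * r, 0.55 * r)
        pts = np.stack([radii * np.sin(t), radii * np.cos(t)], axis=1)
        return _fill_canvas(_rot(pts, angle))
    if family == "colony_grid":
        rc = 0.62 * r
        spacing = 1.7 * rc
        n = int(math.ceil(spacing + 2 * rc)) + 8
        canvas = np.zeros((n, n), dtype=bool)
        cell = _disk_mask(rc)
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                off = _rot(np.array([[dr * spacing, dc * spacing]]), angle)[0]
                center = (int(round(n / 2 + off[0])),
                          int(round(n / 2 + off[1])))
                _stamp(canvas, cell, center)
        return canvas
    if family == "spiny_disk":
        body_r = 0.85 * r
        n_spikes = int(rng.integers(8, 13))
        n = 2 * int(math.ceil(1.45 * r)) + 5
        canvas = np.zeros((n, n), dtype=bool)
        canvas |= _disk_mask(body_r, canvas=n)
        c = (n - 1) / 2.0
        for i in range(n_spikes):
            a = angle + 2 * math.pi * i / n_spikes
            tip = np.array([c + 1.4 * r * math.sin(a),
                            c + 1.4 * r * math.cos(a)])
            base1 = np.array([c + body_r * math.sin(a + 0.18),
                              c + body_r * math.cos(a + 0.18)])
            base2 = np.array([c + body_r * math.sin(a - 0.18),
                              c + body_r * math.cos(a - 0.18)])
            rr, cc = draw_polygon([tip[0], base1[0], base2[0]],
                                  [tip[1], base1[1], base2[1]],
                                  shape=canvas.shape)
            canvas[rr, cc] = True
        return canvas
    raise ValueError(f"unknown shape family {family!r}")


# ---------------------------------------------------------------------------
# scene rendering

def _background(spec: SceneSpec) -> np.ndarray:
    """Blank reference: base color plus a linear left-to-right gradient."""
    w, h = spec.image_size
    ramp = np.linspace(0.0, spec.gradient_amplitude, w)[None, :]
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        img[:, :, c] = spec.background_level[c] + ramp
    return img


def render_scene(spec: SceneSpec) -> tuple[FrameSet, GroundTruth]:
    """Render a frame set and its pixel-exact ground truth.

    Particles are placed by rejection sampling with a 3 px clearance (unless
    ``allow_occlusion``) and never touch the frame border.  Raises
    :class:`PlacementError` naming the template when a particle cannot be
    placed within the retry budget.
    """
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.image_size
    blank = _background(spec)
    bf = blank.copy()
    fluor = {name: np.zeros((h, w), dtype=np.float64)
             for name in ("chl", "pe", "pc")}
    labels = np.zeros((h, w), dtype=np.int32)
    busy = np.zeros((h, w), dtype=bool)
    particle_labels: dict[int, str] = {}
    pid = 0
    clearance = 6      # min gap between particle bodies (keeps edge rings apart)
    margin = clearance + 1
    for template, count in spec.templates:
        for _ in range(count):
            mask = render_shape(template.shape_family,
                                rng.uniform(*template.size_range), rng)
            mh, mw = mask.shape
            if mh + 2 * margin >= h or mw + 2 * margin >= w:
                raise PlacementError(
                    f"template {template.name!r} too large for the image")
            dilated = ndi.binary_dilation(np.pad(mask, clearance),
                                          iterations=clearance)
            placed = False
            for _attempt in range(300):
                r0 = int(rng.integers(margin, h - mh - margin))
                c0 = int(rng.integers(margin, w - mw - margin))
                region = (slice(r0, r0 + mh), slice(c0, c0 + mw))
                wide = (slice(r0 - clearance, r0 + mh + clearance),
                        slice(c0 - clearance, c0 + mw + clearance))
                if not spec.allow_occlusion and (busy[wide] & dilated).any():
                    continue
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {template.name!r} particle after "
                    f"300 attempts; reduce counts or sizes")
            pid += 1
            particle_labels[pid] = template.name
            labels[region][mask] = pid
            busy[region] |= mask
            # bright-field body: base color plus smooth mottling
            mottle = ndi.gaussian_filter(
                rng.normal(0.0, 1.0, size=mask.shape), 1.2)
            mstd = mottle.std()
            if mstd > 0:
                mottle *= template.texture_amplitude / mstd
            for c in range(3):
                body = template.body_color[c] + mottle
                bf[region][..., c][mask] = body[mask]
            for channel, level in zip(("chl", "pe", "pc"),
                                      template.pigment_profile):
                if level > 0:
                    fluor[channel][region][mask] = level
    if spec.noise_sigma > 0:
        bf = bf + rng.normal(0.0, spec.noise_sigma, size=bf.shape)
        for name in fluor:
            fluor[name] = fluor[name] + rng.normal(
                0.0, spec.noise_sigma, size=fluor[name].shape)

    def _u8(img):
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    frame = FrameSet(
        brightfield=_u8(bf),
        blank=_u8(blank),
        fluor_chl=_u8(fluor["chl"]),
        fluor_pe=_u8(fluor["pe"]),
        fluor_pc=_u8(fluor["pc"]),
        frame_id=spec.frame_id,
    )
    return frame, GroundTruth(label_image=labels,
                              particle_labels=particle_labels)


# ---------------------------------------------------------------------------
# default taxon templates

def default_taxon_templates() -> list[TaxonTemplate]:
    """Five plankton morphotypes plus detritus.

    The plankton templates span the shape families and pigment mixes found
    in freshwater indicator taxa: a centric diatom-like disk, a cyanobacterial
    cell chain (chlorophyll + phycocyanin), a cryptophyte-like ellipse
    (chlorophyll + phycoerythrin), a star-shaped desmid and a four-cell
    colony plate.  Detritus is brown, irregular and non-fluorescent.
    """
    return [
        TaxonTemplate("centric_disk", "disk", (18, 28), (120, 140, 90),
                      (140, 0, 0), 22),
        TaxonTemplate("cell_chain", "cell_chain", (30, 46), (90, 130, 140),
                      (120, 0, 110), 14),
        TaxonTemplate("crypto_ellipse", "ellipse", (22, 34), (150, 110, 80),
                      (130, 90, 0), 18),
        TaxonTemplate("star_desmid", "star", (26, 40), (80, 150, 80),
                      (150, 0, 0), 20),
        TaxonTemplate("colony_plate", "colony_grid", (30, 46), (100, 160, 90),
                      (135, 0, 0), 20),
        TaxonTemplate("detritus", "ellipse", (16, 40), (172, 150, 116),
                      (0, 0, 0), 18),
    ]


def spiny_template() -> TaxonTemplate:
    """A spiny-cell taxon, available as a sixth plankton morphotype."""
    return TaxonTemplate("spiny_cell", "spiny_disk", (22, 32), (140, 120, 70),
                         (125, 0, 0), 15)


# ---------------------------------------------------------------------------
# labeled crop collections

def crops_from_scene(frame: FrameSet, truth: GroundTruth,
                     pad: int = 3) -> list[ParticleData]:
    """Particle crops from a rendered scene using its ground-truth masks.

    The frame is illumination-corrected first so crops match what the
    analysis pipeline extracts from segmented frames.
    """
    corrected = correct_frame(frame)
    crops = []
    for sl, pid in zip(ndi.find_objects(truth.label_image),
                       range(1, truth.label_image.max() + 1)):
        if sl is None:
            continue
        r0 = max(0, sl[0].start - pad)
        r1 = min(truth.label_image.shape[0], sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(truth.label_image.shape[1], sl[1].stop + pad)
        window = (slice(r0, r1), slice(c0, c1))
        mask = truth.label_image[window] == pid
        crops.append(ParticleData(
            mask=mask,
            brightfield=corrected.brightfield[window],
            fluor={name: img[window]
                   for name, img in corrected.fluorescence().items()},
            contour=trace_contour(mask),
            frame_id=frame.frame_id,
            particle_id=pid,
            class_label=truth.particle_labels[pid],
        ))
    return crops


def make_dataset(templates: list[TaxonTemplate], n_per_class: int = 600,
                 rng_seed: int = 0, tile: int = 96,
                 per_scene: int = 16) -> list[ParticleData]:
    """Labeled particle crops, ``n_per_class`` for every template.

    Particles are rendered onto small tiled scenes (several particles per
    scene for speed) and cropped out with their ground-truth masks, ready
    for feature extraction.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    crops: list[ParticleData] = []
    for template in templates:
        span = int(math.ceil(template.size_range[1] * 1.6)) + 12
        cols = max(1, int(math.isqrt(per_scene)))
        side = span * cols + 12
        remaining = n_per_class
        scene_idx = 0
        collected: list[ParticleData] = []
        while remaining > 0:
            count = min(per_scene, remaining)
            spec = SceneSpec(
                image_size=(side, side),
                templates=[(template, count)],
                rng_seed=int(rng.integers(0, 2 ** 31 - 1)),
                frame_id=f"{template.name}_{scene_idx:04d}",
            )
            frame, truth = render_scene(spec)
            collected.extend(crops_from_scene(frame, truth))
            remaining -= count
            scene_idx += 1
        crops.extend(collected[:n_per_class])
    return crops


def make_segmented_dataset(templates: list[TaxonTemplate],
                           n_per_class: int = 600, rng_seed: int = 0,
                           per_scene: int = 9) -> list[ParticleData]:
    """Labeled crops obtained through the *segmentation* pathway.

    Mirrors how training data is produced on a real microscope: mono-culture
    scenes are rendered, illumination-corrected and segmented, and every
    extracted particle inherits the scene's (single) class label.  Training
    on these crops keeps the training and analysis feature distributions
    identical, whereas :func:`make_dataset` uses the ground-truth masks
    directly.
    """
    from .segment import segment_frame
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    crops: list[ParticleData] = []
    for template in templates:
        span = int(math.ceil(template.size_range[1] * 1.6)) + 12
        cols = max(2, math.ceil(math.sqrt(per_scene)))
        side = span * cols + 16
        collected: list[ParticleData] = []
        scene_idx = 0
        while len(collected) < n_per_class:
            spec = SceneSpec(
                image_size=(side, side),
                templates=[(template, per_scene)],
                rng_seed=int(rng.integers(0, 2 ** 31 - 1)),
                frame_id=f"{template.name}_seg_{scene_idx:04d}",
            )
            frame, _ = render_scene(spec)
            corrected = correct_frame(frame)
            seg = segment_frame(corrected)
            for roi in seg.particles:
                collected.append(ParticleData(
                    mask=roi.mask,
                    brightfield=roi.crop(corrected.brightfield),
                    fluor={name: roi.crop(img) for name, img
                           in corrected.fluorescence().items()},
                    contour=roi.contour,
                    frame_id=spec.frame_id,
                    particle_id=roi.particle_id,
                    class_label=template.name,
                ))
            scene_idx += 1
            if scene_idx > 50 * (1 + n_per_class // per_scene):
                raise RuntimeError(
                    f"segmentation keeps losing {template.name!r} particles")
        crops.extend(collected[:n_per_class])
    return crops


def make_unknown_crops(templates: list[TaxonTemplate], n: int,
                       rng_seed: int = 0,
                       source: list[ParticleData] | None = None
                       ) -> list[ParticleData]:
    """Deliberately malformed crops labeled ``unknown``.

    Emulates wrongly segmented or occluded particles: each crop is either a
    particle truncated along a random chord (as if cut by a segmentation
    error) or two particles merged into one mask (as if aggregated).  Source
    particles are drawn from ``source`` when given, otherwise generated from
    the fluorescent templates.
    """
    rng = np.random.default_rng(rng_seed)
    if source is None:
        plankton = [t for t in templates
                    if any(p > 0 for p in t.pigment_profile)]
        if not plankton:
            raise ValueError("need at least one fluorescent template")
        source = make_dataset(
            plankton, n_per_class=max(2, 2 * n // len(plankton) + 2),
            rng_seed=rng_seed + 1)
    else:
        source = list(source)
    rng.shuffle(source)
    out: list[ParticleData] = []
    i = 0
    while len(out) < n and i < len(source):
        crop = source[i]
        if rng.random() < 0.5 or i + 1 >= len(source):
            mutated = _truncate_crop(crop, rng)
            i += 1
        else:
            mutated = _merge_crops(crop, source[i + 1], rng)
            i += 2
        if mutated is not None:
            mutated.class_label = "unknown"
            mutated.particle_id = len(out) + 1
            out.append(mutated)
    if len(out) < n:
        raise RuntimeError("could not synthesize enough unknown crops")
    return out


def _truncate_crop(crop: ParticleData, rng: np.random.Generator
                   ) -> ParticleData | None:
    """Cut the particle along a random chord through its centroid side."""
    mask = crop.mask
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    theta = rng.uniform(0, 2 * math.pi)
    nr, nc = math.sin(theta), math.cos(theta)
    rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    # cut close to the centroid so roughly half the body is lost and the
    # remnant is visibly malformed (not just a shaved cap)
    offset = rng.uniform(-0.02, 0.12) * max(mask.shape)
    keep = ((rr - cy) * nr + (cc - cx) * nc) <= offset
    new_mask = mask & keep
    lab, nlab = ndi.label(new_mask)
    if nlab == 0:
        return None
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, nlab + 1))
    new_mask = lab == (1 + int(np.argmax(sizes)))
    if new_mask.sum() < 100:
        return None
    return ParticleData(
        mask=new_mask,
        brightfield=crop.brightfield.copy(),
        fluor={k: v.copy() for k, v in crop.fluor.items()},
        contour=trace_contour(new_mask),
        frame_id=crop.frame_id + "_trunc",
    )


def _merge_crops(a: ParticleData, b: ParticleData,
                 rng: np.random.Generator) -> ParticleData | None:
    """Overlay two particles with a random overlapping offset."""
    ha, wa = a.mask.shape
    hb, wb = b.mask.shape
    # offset b so the bodies touch/overlap
    lo, hi = -hb // 3, ha - 2 * hb // 3 + 1
    if hi <= lo:
        hi = lo + 1
    dr = int(rng.integers(lo, hi))
    dc = int(rng.integers(wa // 3, 3 * wa // 4 + 1))
    h = max(ha, dr + hb) - min(0, dr)
    w = max(wa, dc + wb) - min(0, dc)
    ra, ca = -min(0, dr), -min(0, dc)
    rb, cb = ra + dr, ca + dc
    mask = np.zeros((h, w), dtype=bool)
    mask[ra:ra + ha, ca:ca + wa] |= a.mask
    mask[rb:rb + hb, cb:cb + wb] |= b.mask
    lab, nlab = ndi.label(mask)
    if nlab != 1:
        return None
    bf = np.full((h, w, 3), 230, dtype=np.float64)
    bf[ra:ra + ha, ca:ca + wa] = np.minimum(
        bf[ra:ra + ha, ca:ca + wa], a.brightfield.astype(np.float64))
    bf[rb:rb + hb, cb:cb + wb] = np.minimum(
        bf[rb:rb + hb, cb:cb + wb], b.brightfield.astype(np.float64))
    fluor = {}
    for name in a.fluor:
        ch = np.zeros((h, w), dtype=np.float64)
        ch[ra:ra + ha, ca:ca + wa] = np.maximum(
            ch[ra:ra + ha, ca:ca + wa], a.fluor[name].astype(np.float64))
        ch[rb:rb + hb, cb:cb + wb] = np.maximum(
            ch[rb:rb + hb, cb:cb + wb], b.fluor[name].astype(np.float64))
        fluor[name] = ch.astype(np.uint8)
    return ParticleData(
        mask=mask,
        brightfield=bf.astype(np.uint8),
        fluor=fluor,
        contour=trace_contour(mask),
        frame_id=a.frame_id + "_merged",
    )
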