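"""Particle segmentation by edge-enhanced, seeded region growing.

Organisms are separated from the background of the corrected bright-field
image in four steps:

1. Sobel edge magnitude of the brightness channel, contrast-stretched, is
   added to the brightness itself to form the *working image*.  Edges act as
   barriers so transparent organisms with sharp outlines do not merge into
   the background.
2. A rough partition of the working image into catchment basins of its local
   maxima (marker-based watershed), mimicking a maximum-finder "segmented
   particles" output.
3. The background is identified as the mode gray value whose basins cover the
   largest summed area; pixels at that value inside those basins become seed
   points.
4. Breadth-first region growing from the seeds over 4-neighbors.  A frontier
   pixel joins the background while its deviation from the running background
   mean stays within ``k * max(std, sigma_floor)`` with ``k = 10``; the
   running statistics are updated after every frontier sweep.

The complement of the grown background, hole-filled, yields particle regions
of interest.  Particles smaller than 100 px or touching the frame border are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .frames import brightness
from .preprocess import CorrectedFrame

#: growing criterion multiplier on the running background deviation
K_MULTIPLIER = 10.0
#: lower bound on the running std so the criterion never collapses to zero
SIGMA_FLOOR = 1.0
#: strict minimum particle area in pixels
MIN_AREA = 100

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BackgroundModel:
    """Seed pixels and running statistics for the background region."""

    seed_mask: np.ndarray
    background_mode: int
    running_mean: float
    running_std: float
    k_multiplier: float = K_MULTIPLIER
    sigma_floor: float = SIGMA_FLOOR


@dataclass
class ParticleROI:
    """One segmented particle.

    ``bbox`` is ``(x0, y0, width, height)``, 0-based and half-open; ``mask``
    and ``contour`` use bounding-box-local ``(row, col)`` coordinates.  The
    contour is a closed, 8-connected boundary chain.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area_px: int
    contour: np.ndarray
    frame_id: str = "frame"
    particle_id: int = 0

    def global_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Particle mask placed into a full-frame canvas of ``shape``."""
        out = np.zeros(shape, dtype=bool)
        x0, y0, w, h = self.bbox
        out[y0:y0 + h, x0:x0 + w] = self.mask
        return out

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Bounding-box crop of ``image`` (2-d or 3-d)."""
        x0, y0, w, h = self.bbox
        return image[y0:y0 + h, x0:x0 + w]


@dataclass
class SegmentationResult:
    particles: list[ParticleROI]
    background_mask: np.ndarray
    working: np.ndarray
    model: BackgroundModel


def edge_enhance(img: np.ndarray) -> np.ndarray:
    """Sobel edge magnitude of a grayscale image, rescaled to 8-bit.

    Uses the standard 3x3 Sobel kernels with border replication; the
    magnitude ``sqrt(Gx^2 + Gy^2)`` is linearly rescaled so its maximum maps
    to 255 (a constant image stays all-zero).
    """
    img = np.asarray(img, dtype=np.float64)
    gx = ndi.sobel(img, axis=1, mode="nearest")
    gy = ndi.sobel(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return np.rint(mag).astype(np.uint8)


def stretch_contrast(img: np.ndarray,
                     saturated_fraction: float = 0.004) -> np.ndarray:
    """Linear histogram stretch saturating ``saturated_fraction`` of pixels.

    Half of the saturated fraction is clipped in each tail: the lower and
    upper percentiles (0.2% / 99.8% at the default) map to 0 and 255.  A
    constant image is returned unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    tail = 100.0 * saturated_fraction / 2.0
    lo, hi = np.percentile(img, [tail, 100.0 - tail])
    if hi <= lo:
        return np.rint(img).astype(np.uint8)
    out = (img - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def make_working_image(corrected: CorrectedFrame) -> np.ndarray:
    """Working image for segmentation: contrast-stretched Sobel edges.

    Region growing operates on the edge magnitude of the brightness channel:
    the background is the large, edge-free area, and every particle —
    opaque or transparent — is enclosed by its own edge ring, which blocks
    the growth regardless of the body's interior intensity.  Organisms
    without sharp outlines (out of focus) consequently merge into the
    background, which is the intended behavior: their features would be
    unreliable anyway.
    """
    bright = brightness(corrected.brightfield)
    return stretch_contrast(edge_enhance(bright))


def rough_partition(working: np.ndarray, noise_tolerance: float = 10) -> np.ndarray:
    """Partition the image into catchment basins of its local maxima.

    Maxima with prominence exceeding ``noise_tolerance`` seed a marker-based
    watershed on the inverted working image, so every pixel is assigned to
    exactly one region.  Labels start at 1.
    """
    working = np.asarray(working)
    if working.size == 0:
        raise ValueError("empty image")
    peaks = h_maxima(working, noise_tolerance)
    markers, n = ndi.label(peaks, structure=np.ones((3, 3), dtype=bool))
    if n <= 1:
        return np.ones(working.shape, dtype=np.int32)
    return watershed(-working.astype(np.int16), markers).astype(np.int32)


def find_background_seeds(labels: np.ndarray,
                          working: np.ndarray) -> BackgroundModel:
    """Select background seed pixels from a rough partition.

    For every region the mode gray value is computed on a 256-bin histogram;
    regions sharing a mode are grouped and the mode whose group covers the
    largest summed area is declared the background value (area ties break
    toward the lower gray value, as does the per-region histogram argmax).
    Seeds are the pixels carrying that value inside those regions.
    """
    labels = np.asarray(labels)
    working = np.asarray(working)
    if labels.size == 0:
        raise ValueError("empty image")
    n_labels = int(labels.max())
    flat = labels.ravel().astype(np.int64) * 256 + working.ravel()
    hist = np.bincount(flat, minlength=(n_labels + 1) * 256)
    hist = hist.reshape(n_labels + 1, 256)
    region_mode = hist.argmax(axis=1)          # ties -> lower gray value
    region_area = hist.sum(axis=1)
    area_by_mode = np.zeros(256, dtype=np.int64)
    for lab in range(1, n_labels + 1):
        if region_area[lab] > 0:
            area_by_mode[region_mode[lab]] += region_area[lab]
    background_mode = int(area_by_mode.argmax())  # ties -> lower gray value
    chosen = np.zeros(n_labels + 1, dtype=bool)
    chosen[1:] = (region_mode[1:] == background_mode) & (region_area[1:] > 0)
    seed_mask = chosen[labels] & (working == background_mode)
    seeds = working[seed_mask].astype(np.float64)
    return BackgroundModel(
        seed_mask=seed_mask,
        background_mode=background_mode,
        running_mean=float(seeds.mean()),
        running_std=float(seeds.std()),
    )


def region_grow(working: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Grow the background from seed pixels by breadth-first sweeps.

    In each sweep every 4-neighbor of the current background is tested
    against ``|v - mean| <= k * max(std, sigma_floor)`` where mean/std are the
    running statistics of all pixels accepted so far; the statistics are
    refreshed once per sweep.  Terminates when no frontier pixel qualifies.
    """
    working = np.asarray(working, dtype=np.float64)
    mask = model.seed_mask.copy()
    if not mask.any():
        raise ValueError("background model has no seed pixels")
    n = int(mask.sum())
    s = float(working[mask].sum())
    ss = float((working[mask] ** 2).sum())
    while True:
        mean = s / n
        var = max(ss / n - mean * mean, 0.0)
        thr = model.k_multiplier * max(np.sqrt(var), model.sigma_floor)
        frontier = ndi.binary_dilation(mask, structure=_CROSS) & ~mask
        accept = frontier & (np.abs(working - mean) <= thr)
        if not accept.any():
            return mask
        vals = working[accept]
        n += vals.size
        s += float(vals.sum())
        ss += float((vals ** 2).sum())
        mask |= accept


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Closed 8-connected boundary chain of a connected binary region.

    Moore-neighbor tracing with Jacob's stopping criterion; returns an
    (N, 2) array of (row, col) coordinates whose last point neighbors the
    first (the chain is closed implicitly).
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    if rows.size == 0:
        raise ValueError("empty mask")
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    if rows.size == 1:
        return np.array([[start[0] - 1, start[1] - 1]])
    # clockwise ring of neighbor offsets starting west
    ring = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
            (0, 1), (1, 1), (1, 0), (1, -1)]
    contour = [start]
    cur = start
    prev = (start[0], start[1] - 1)    # background backtrack pixel (west)
    first_move = None
    limit = 4 * int(mask.sum()) + 8    # safety bound; never hit in practice
    while len(contour) <= limit:
        b = ring.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = (b + k) % 8
            cand = (cur[0] + ring[d][0], cur[1] + ring[d][1])
            if padded[cand]:
                nxt = cand
                dprev = (d - 1) % 8
                prev = (cur[0] + ring[dprev][0], cur[1] + ring[dprev][1])
                break
        if nxt is None:            # isolated pixel
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif cur == start and move == first_move:
            break                  # start revisited, leaving the same way
        cur = nxt
        if cur != start:
            contour.append(cur)
    pts = np.array(contour, dtype=np.int64)
    return pts - 1                 # un-pad


def contour_perimeter(contour: np.ndarray) -> float:
    """Chain length of a closed contour, diagonal steps weighted sqrt(2)."""
    if len(contour) < 2:
        return 0.0
    closed = np.vstack([contour, contour[:1]])
    steps = np.abs(np.diff(closed, axis=0))
    diag = (steps[:, 0] == 1) & (steps[:, 1] == 1)
    straight = steps.sum(axis=1) == 1
    return float(straight.sum() + np.sqrt(2.0) * diag.sum())


def extract_particles(background_mask: np.ndarray,
                      min_area: int = MIN_AREA,
                      exclude_edge: bool = True,
                      frame_id: str = "frame") -> list[ParticleROI]:
    """Particle ROIs from the complement of the background mask.

    The complement is labeled with 4-connectivity, holes are filled per
    component (transparent interiors count as particle), components with
    fewer than ``min_area`` pixels are dropped, and components whose bounding
    box touches the frame border are excluded.
    """
    bg = np.asarray(background_mask, dtype=bool)
    particles_mask = ~bg
    labels, n = ndi.label(particles_mask, structure=_CROSS)
    rois: list[ParticleROI] = []
    h_img, w_img = bg.shape
    pid = 0
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        local = ndi.binary_fill_holes(labels[sl] == lab)
        area = int(local.sum())
        if area < min_area:
            continue
        y0, x0 = sl[0].start, sl[1].start
        h, w = local.shape
        if exclude_edge and (x0 == 0 or y0 == 0 or x0 + w == w_img
                             or y0 + h == h_img):
            continue
        pid += 1
        rois.append(ParticleROI(
            mask=local,
            bbox=(x0, y0, w, h),
            area_px=area,
            contour=trace_contour(local),
            frame_id=frame_id,
            particle_id=pid,
        ))
    return rois


def _reclaim_edge_halo(bg: np.ndarray, bright: np.ndarray,
                       sweeps: int = 2) -> np.ndarray:
    """Re-examine the edge barrier against the intensity criterion.

    The Sobel barrier in the working image stops background growth about one
    pixel outside the true particle boundary.  Once growth has converged,
    frontier pixels whose *brightness* still satisfies the background
    criterion are reclaimed for a bounded number of sweeps, so the barrier's
    outer half does not ring every particle.  Reclaiming uses a tight
    3-sigma rule (only pixels statistically indistinguishable from the
    background belong to it), and the sweep bound keeps transparent organism
    interiors (background-like brightness behind a closed edge) from being
    eaten.
    """
    bg = bg.copy()
    vals = bright[bg]
    mean = float(vals.mean())
    thr = 3.0 * max(float(vals.std()), SIGMA_FLOOR)
    for _ in range(sweeps):
        frontier = ndi.binary_dilation(bg, structure=_CROSS) & ~bg
        accept = frontier & (np.abs(bright - mean) <= thr)
        if not accept.any():
            break
        bg |= accept
    return bg


def segment_frame(corrected: CorrectedFrame,
                  noise_tolerance: float = 10,
                  min_area: int = MIN_AREA) -> SegmentationResult:
    """Full segmentation of a corrected frame into particle ROIs."""
    working = make_working_image(corrected)
    labels = rough_partition(working, noise_tolerance)
    model = find_background_seeds(labels, working)
    bg = region_grow(working, model)
    bg = _reclaim_edge_halo(bg, brightness(corrected.brightfield))
    particles = extract_particles(bg, min_area=min_area,
                                  frame_id=corrected.frame_id)
    return SegmentationResult(particles=particles, background_mask=bg,
                              working=working, model=model)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
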