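"""End-to-end analysis and training workflows.

Analysis of a frame runs: illumination correction -> segmentation ->
stage-1 gate (plankton vs non-plankton on color/fluorescence/size features)
-> stage-2 taxon network (winner-take-all over detritus, unknown and the
taxa) -> optional per-class crop export.  Particles gated as non-plankton
are finalized as detritus without consulting the stage-2 network.

Training builds both classifiers from a labeled crop collection: the
stage-1 table folds every class except detritus into "plankton", the
stage-2 table keeps all classes (detritus and unknown included, so the
taxon network can also run stand-alone for confusion-matrix evaluation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import features as feat
from . import nnet
from .frames import FrameSet
from .preprocess import CorrectedFrame, correct_frame
from .segment import ParticleROI, SegmentationResult, segment_frame

STAGE1_CLASSES = ("plankton", "non_plankton")
NON_PLANKTON_LABEL = "detritus"
UNKNOWN_LABEL = "unknown"


@dataclass
class ClassifiedParticle:
    """Final classification of one segmented particle."""

    roi_ref: int
    stage1_label: str
    final_label: str
    stage2_activations: np.ndarray | None = None


@dataclass
class AnalysisResult:
    """Classified particles plus the artifacts needed to export them."""

    classified: list[ClassifiedParticle]
    rois: list[ParticleROI]
    corrected: CorrectedFrame
    segmentation: SegmentationResult


def _check_model(model: nnet.NetworkModel, expected: tuple[str, ...],
                 which: str) -> None:
    if tuple(model.feature_names) != expected:
        raise ValueError(
            f"{which} model feature set does not match the {which} "
            f"feature specification")


def analyze_frame(frame: FrameSet, stage1: nnet.NetworkModel,
                  stage2: nnet.NetworkModel, noise_tolerance: float = 10,
                  min_area: int = 100) -> AnalysisResult:
    """Segment and classify every particle of one frame set.

    The stage-1 network must be trained on the ``stage1`` feature set and
    the stage-2 network on ``stage2``; a mismatch raises before any particle
    is processed.
    """
    _check_model(stage1, feat.STAGE1_FEATURES, "stage1")
    _check_model(stage2, feat.STAGE2_FEATURES, "stage2")
    corrected = correct_frame(frame)
    seg = segment_frame(corrected, noise_tolerance=noise_tolerance,
                        min_area=min_area)
    spec1 = feat.feature_set("stage1")
    spec2 = feat.feature_set("stage2")
    out: list[ClassifiedParticle] = []
    for roi in seg.particles:
        data = feat.ParticleData.from_roi(roi, corrected)
        vec1 = feat.assemble_features(data, spec1)
        label1, _ = nnet.predict_class(stage1, vec1)
        if label1 == "non_plankton":
            out.append(ClassifiedParticle(
                roi_ref=roi.particle_id, stage1_label=label1,
                final_label=NON_PLANKTON_LABEL))
            continue
        vec2 = feat.assemble_features(data, spec2)
        label2, acts = nnet.predict_class(stage2, vec2)
        out.append(ClassifiedParticle(
            roi_ref=roi.particle_id, stage1_label=label1,
            final_label=label2, stage2_activations=acts))
    return AnalysisResult(classified=out, rois=seg.particles,
                          corrected=corrected, segmentation=seg)


def stage_tables(crops: list[feat.ParticleData]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-1 and stage-2 feature tables from labeled crops.

    Stage-1 labels: detritus -> non_plankton, everything else (unknown
    included) -> plankton.  Stage-2 keeps the crop labels as-is.
    """
    labels = {c.class_label for c in crops}
    if None in labels:
        raise ValueError("every crop needs a class_label")
    if NON_PLANKTON_LABEL not in labels:
        raise ValueError(f"missing class: {NON_PLANKTON_LABEL!r}")
    plankton_classes = sorted(labels - {NON_PLANKTON_LABEL})
    if len(plankton_classes) < 1:
        raise ValueError("need at least one plankton class")
    t1 = feat.feature_table(crops, feat.feature_set("stage1"))
    t1["class_label"] = [
        "non_plankton" if c.class_label == NON_PLANKTON_LABEL else "plankton"
        for c in crops]
    t2 = feat.feature_table(crops, feat.feature_set("stage2"))
    return t1, t2


def stage2_class_order(labels) -> list[str]:
    """Canonical class order: detritus, unknown, then taxa alphabetically."""
    labels = set(labels)
    order = []
    for special in (NON_PLANKTON_LABEL, UNKNOWN_LABEL):
        if special in labels:
            order.append(special)
            labels.discard(special)
    return order + sorted(labels)


def train_pipeline(crops: list[feat.ParticleData],
                   config: nnet.TrainingConfig | None = None,
                   hidden1: tuple[int, ...] = (10,),
                   hidden2: tuple[int, ...] = (50, 30)):
    """Train the stage-1 gate and the stage-2 taxon network.

    Returns (stage1_model, stage2_model, history1, history2).  Requires
    detritus plus at least two further classes in the crop labels.
    """
    config = config or nnet.TrainingConfig()
    t1, t2 = stage_tables(crops)
    classes2 = stage2_class_order(t2["class_label"])
    if len(classes2) < 3:
        raise ValueError(
            f"need detritus plus >= 2 further classes, got {classes2}")
    m1, h1 = nnet.fit_classifier(
        t1, list(feat.STAGE1_FEATURES), list(STAGE1_CLASSES),
        hidden=hidden1, config=config)
    m2, h2 = nnet.fit_classifier(
        t2, list(feat.STAGE2_FEATURES), classes2,
        hidden=hidden2, config=config)
    return m1, m2, h1, h2


def export_crops(result: AnalysisResult, out_dir: str) -> pd.DataFrame:
    """Write each particle's bright-field crop into a per-class folder.

    Files are named ``<frame_id>_<particle_id>.png``; name collisions get a
    numeric suffix instead of overwriting.  Returns the manifest (also
    written as ``manifest.csv`` when any particle was exported).
    """
    rois = {r.particle_id: r for r in result.rois}
    rows = []
    for cp in result.classified:
        roi = rois[cp.roi_ref]
        folder = os.path.join(out_dir, cp.final_label)
        os.makedirs(folder, exist_ok=True)
        base = f"{roi.frame_id}_{roi.particle_id}"
        path = os.path.join(folder, base + ".png")
        k = 1
        while os.path.exists(path):
            path = os.path.join(folder, f"{base}_{k}.png")
            k += 1
        iio.imwrite(path, roi.crop(result.corrected.brightfield))
        x0, y0, w, h = roi.bbox
        rows.append({"frame_id": roi.frame_id, "particle_id": roi.particle_id,
                     "final_label": cp.final_label,
                     "stage1_label": cp.stage1_label,
                     "x0": x0, "y0": y0, "width": w, "height": h,
                     "area_px": roi.area_px, "path": path})
    manifest = pd.DataFrame(rows, columns=[
        "frame_id", "particle_id", "final_label", "stage1_label",
        "x0", "y0", "width", "height", "area_px", "path"])
    if rows:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
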