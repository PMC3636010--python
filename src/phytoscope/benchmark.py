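"""Reproducible synthetic end-to-end benchmark.

Trains the two-stage pipeline on synthetic crops (five plankton morphotypes,
detritus and an "unknown" class of deliberately malformed particles) and
scores it on independently seeded test scenes, reporting per-class
recognition and the non-plankton exclusion error.  Training crops are
produced through the segmentation pathway — mono-class scenes are corrected
and segmented — exactly as the analysis pathway sees particles.
"""

from __future__ import annotations

import numpy as np

from . import nnet, pipeline, synthetic
from .evaluate import confusion_matrix, summarize


def synthetic_recognition_benchmark(n_per_class: int = 200,
                                    rng_seed: int = 0,
                                    n_scenes: int = 12,
                                    per_template: int = 3) -> dict:
    """Train on synthetic crops, test on fresh scenes; return the scores.

    Returns a dict with ``per_class_recognition_pct``,
    ``mean_recognition_pct``, ``exclusion_error_pct`` (detritus particles
    that pass the plankton gate), counts, and the training histories.
    """
    templates = synthetic.default_taxon_templates()
    seed = int(rng_seed) % (2 ** 31 - 1)
    crops = synthetic.make_segmented_dataset(
        templates, n_per_class=n_per_class, rng_seed=seed)
    plankton = [t for t in templates if t.name != "detritus"]
    unk_source = synthetic.make_segmented_dataset(
        plankton, n_per_class=max(2, n_per_class // 2), rng_seed=seed + 2)
    crops += synthetic.make_unknown_crops(
        templates, n_per_class, rng_seed=seed + 1, source=unk_source)
    config = nnet.TrainingConfig(rng_seed=seed)
    stage1, stage2, hist1, hist2 = pipeline.train_pipeline(crops,
                                                           config=config)

    truth_labels: list[str] = []
    pred_labels: list[str] = []
    excluded = 0
    detritus_total = 0
    for k in range(n_scenes):
        spec = synthetic.SceneSpec(
            image_size=(640, 640),
            templates=[(t, per_template) for t in templates],
            rng_seed=seed + 10_000 + k,
            frame_id=f"test_{k:03d}")
        frame, truth = synthetic.render_scene(spec)
        result = pipeline.analyze_frame(frame, stage1, stage2)
        for cp, roi in zip(result.classified, result.rois):
            gm = roi.global_mask(truth.label_image.shape)
            ids, counts = np.unique(truth.label_image[gm],
                                    return_counts=True)
            sel = ids > 0
            if not sel.any():
                continue
            gt = truth.particle_labels[ids[sel][np.argmax(counts[sel])]]
            truth_labels.append(gt)
            pred_labels.append(cp.final_label)
            if gt == "detritus":
                detritus_total += 1
                excluded += cp.stage1_label == "non_plankton"

    class_order = pipeline.stage2_class_order(
        set(truth_labels) | set(pred_labels))
    matrix = confusion_matrix(truth_labels, pred_labels, class_order)
    present = [c for c in class_order if c in set(truth_labels)]
    per_class = {}
    for c in present:
        i = matrix.index(c)
        per_class[c] = 100.0 * matrix.counts[i, i] / matrix.counts[i].sum()
    exclusion_error = (100.0 * (detritus_total - excluded) / detritus_total
                       if detritus_total else 0.0)
    return {
        "per_class_recognition_pct": per_class,
        "mean_recognition_pct": float(np.mean(list(per_class.values()))),
        "exclusion_error_pct": float(exclusion_error),
        "n_train_crops": len(crops),
        "n_test_particles": len(truth_labels),
        "n_detritus": detritus_total,
        "stage1_iterations": len(hist1),
        "stage2_iterations": len(hist2),
        "stage1_final_error": hist1[-1],
        "stage2_final_error": hist2[-1],
        "confusion": matrix,
    }
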