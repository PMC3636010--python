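# phytoscope

Automated recognition of phytoplankton in multichannel micrographs.

Routine monitoring of freshwater quality relies on counting indicator
phytoplankton taxa under the microscope — slow, expensive work whose
results vary between (and even within) analysts. `phytoscope` implements
the full image-analysis side of an automated counting system: particles are
segmented from bright-field images, described by shape, texture, color and
autofluorescence features, and classified by a two-stage neural network
into taxa, detritus, or unknown particles. Because the microscope front-end
is out of scope, the package ships a synthetic micrograph generator with
pixel-exact ground truth, so every stage is testable end to end without any
image downloads.

Intended users: aquatic ecologists and bioimage analysts building or
evaluating automated plankton counters, and anyone needing a tested,
scriptable reference implementation of the underlying methods.

## The method

For every stage position a *frame set* is analyzed: a bright-field RGB
image I_s, a blank reference I_lc taken without sample, and three
fluorescence channels (chlorophyll, phycoerythrin, phycocyanin).

1. **Illumination correction** — each bright-field channel is corrected as
   I_cor = I_s / I_lc · mean(I_lc), removing lamp drift and vignetting.
2. **Segmentation** — region growing from background seeds on the
   contrast-stretched Sobel edge magnitude of the brightness channel. A
   watershed rough partition locates the background as the largest area
   sharing a mode gray value; all pixels at that mode are seeds; a frontier
   pixel joins the background while |v − μ_bg| ≤ 10·σ_bg (running
   statistics over the grown background). Particles are the hole-filled
   complement; bodies under 100 px or touching the frame border are
   discarded.
3. **Features** — per particle: area, perimeter, circularity, roundness,
   solidity, minimum Feret diameter; normalized elliptic Fourier amplitudes
   of the contour (harmonics 2–13 feed the classifier); Hu moment 1 of the
   mask; a rotation-invariant uniform local binary pattern histogram
   (P=8, R=1); a saturation-weighted 16-bin hue histogram; and the mean
   fluorescence per channel inside the mask. Haralick (GLCM) statistics,
   a gradient directionality histogram, mirror-symmetry scores and the
   remaining EFD/Hu terms are computed and exported for feature-selection
   experiments but excluded from the default classifier inputs.
4. **Classification** — feed-forward networks with the Elliott activation
   x/(1+|x|), inputs min-max normalized to [−1, 1] (rules persisted with
   the model), trained full-batch with resilient propagation (RPROP) to 0%
   training misclassification or 3000 iterations. A small stage-1 net
   gates plankton from non-plankton (non-fluorescent, brown particles);
   survivors go to a 50+30-hidden-neuron stage-2 net with one output per
   class (ten taxa, detritus, unknown in the full setting) and
   winner-take-all decision.
5. **Evaluation** — confusion matrices with per-class recognition
   (diagonal / row sum) and false-positive rate (off-diagonal column sum /
   diagonal), the conventions of the published reference evaluation whose
   counts ship with the package.

## Worked example

Train both stages on synthetic crops and analyze a fresh scene:

```python
from collections import Counter
from phytoscope import (SceneSpec, analyze_frame, default_taxon_templates,
                        make_segmented_dataset, make_unknown_crops,
                        render_scene, train_pipeline)
from phytoscope.nnet import TrainingConfig

templates = default_taxon_templates()          # 5 morphotypes + detritus
crops = make_segmented_dataset(templates, n_per_class=60, rng_seed=0)
plankton = [t for t in templates if t.name != "detritus"]
crops += make_unknown_crops(templates, 60, rng_seed=1,
                            source=make_segmented_dataset(plankton, 30,
                                                          rng_seed=2))
stage1, stage2, h1, h2 = train_pipeline(crops,
                                        config=TrainingConfig(rng_seed=0))
print(f"stage 1 trained to {h1[-1]:.0%} error in {len(h1)} iterations")
print(f"stage 2 trained to {h2[-1]:.0%} error in {len(h2)} iterations")

frame, truth = render_scene(SceneSpec(templates=[(t, 2) for t in templates],
                                      rng_seed=99))
result = analyze_frame(frame, stage1, stage2)
print("true:     ", dict(Counter(truth.particle_labels.values())))
print("predicted:", dict(Counter(c.final_label for c in result.classified)))
```

Output:

```
stage 1 trained to 0% error in 6 iterations
stage 2 trained to 0% error in 41 iterations
true:      {'centric_disk': 2, 'cell_chain': 2, 'crypto_ellipse': 2, 'star_desmid': 2, 'colony_plate': 2, 'detritus': 2}
predicted: {'crypto_ellipse': 2, 'cell_chain': 2, 'centric_disk': 2, 'star_desmid': 2, 'colony_plate': 2, 'detritus': 2}
```

Both networks reach 0% training error quickly on this small set; on the
unseen scene all twelve particles are recovered by the segmentation and
classified correctly, with the two detritus particles excluded by the
stage-1 fluorescence gate.

The same workflow is available from the shell: `pv-simulate` renders frame
sets, `pv-preprocess`, `pv-segment` and `pv-features` run the individual
stages, `pv-trainall` trains both networks on synthetic crops, `pv-analyze`
classifies frame directories, and `pv-eval` computes confusion-matrix
metrics from truth/prediction CSVs.

## Layout

```
src/phytoscope/
  frames.py      five-channel frame-set container and TIFF I/O
  synthetic.py   scene generator, taxon templates, crop collections
  preprocess.py  blank-reference illumination correction
  segment.py     edge enhancement, watershed partition, region growing
  features.py    feature battery and named feature sets
  nnet.py        Elliott network, RPROP, normalization, persistence
  pipeline.py    two-stage analysis and training workflows
  benchmark.py   end-to-end synthetic recognition benchmark
  evaluate.py    confusion matrices and recognition statistics
  cli.py         pv-* console commands
docs/methods.md  model assumptions, parameters, numerical conventions
```
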