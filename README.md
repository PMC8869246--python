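# phaseseg

Fully automated foreground–background segmentation for **phase-contrast
microscopy** images of adherent cell cultures.

Checking confluence (the fraction of the culture surface covered by cells)
is a daily task in any cell-culture lab, but manual outlining of cell
regions is slow, subjective, and infeasible on blurry or dark images, while
deep-learning segmenters need large labeled training sets.  `phaseseg`
implements a classical, training-free pipeline whose only input is the
image itself: cellular edges are extracted with *grayscale morphology*
instead of a conventional gradient detector, binarized automatically with
Otsu's method, and turned into a cell mask by contour filling and cluster
detection.  The package also ships the evaluation metrics, three
robustness-perturbation protocols (blur, image size, illumination), and a
seeded synthetic scene generator with exact ground truth, so every stage is
testable without access to restricted microscope data.

## Method

For an input image `f` (resized to an 800×600 working frame and lightly
Gaussian-smoothed), with a 3×3 structuring element `D`:

```
Edge_external = (f ⊕ D) − f          dilation minus image
Edge_internal = f − (f ⊖ D)          image minus erosion
Edge_middle   = (f ⊕ D) − (f ⊖ D)    morphological gradient
Edge_all      = Edge_external + Edge_middle + Edge_internal   (saturating)
```

The combined edge image is smoothed, sharpened with a 3×3 Laplacian kernel,
and binarized at the threshold `t*` minimizing the weighted within-class
variance

```
t* = argmin_t  W_bg(t)·σ²_bg(t) + W_fg(t)·σ²_fg(t)
```

(equivalently, maximizing the between-class variance).  Two mask branches
follow: (A) external contours of the binarized edges are filled solid and
sub-debris components dropped, capturing small individual cells; (B) the
edge image is closed/opened with a 9×9 rectangle to locate cell clusters,
and each tiny interior gap is kept open as background exactly when its mean
intensity is closer to the background mean than to the foreground mean.
The union of the branches is the final mask, which splits the input into an
exact foreground/background partition; confluence is the mask's area
fraction.  Accuracy is reported as the dice coefficient
`2|X∩Y|/(|X|+|Y|)`, IoU `|X∩Y|/|X∪Y|`, and the relative error of the
measured growth area `|measured − actual|/actual`.

## Worked example

```python
from phaseseg import (PipelineConfig, SceneSpec, dice, iou,
                      generate_scene, segment)

scene = generate_scene(SceneSpec(seed=7))          # 400x300 synthetic frame
res = segment(scene.image, PipelineConfig(resize_target=None))
print(res.otsu_threshold, res.area_fraction, res.blob_count)
print(dice(res.final_mask, scene.truth_mask), iou(res.final_mask, scene.truth_mask))
```

prints

```
otsu_threshold   = 67
area_fraction    = 0.3742   (true 0.3572)
blob_count       = 5
dice vs truth    = 0.8715
iou vs truth     = 0.7722
```

i.e. the automatically chosen edge-image threshold was 67; the pipeline
measured 37.4% confluence against a true 35.7% (4.8% relative area error)
and overlapped the exact ground-truth mask with dice 0.87.  The same
pipeline is available from the shell — an input image is the only human
input:

```bash
phaseseg synth --n 10 --seed 1 --out scenes/        # paired image/mask PNGs
phaseseg segment scenes/image_0000.png --out-dir seg/ --no-resize
phaseseg eval --pred seg_masks/ --truth scenes_masks/ --out report
phaseseg sweep --axis blur_gaussian --images scenes/ --truth scenes/ --out sweep
```

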