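# vesseltrack

Probabilistic tracking-based segmentation of blood vessels in retinal
(fundus) images.

Rather than classifying every pixel, `vesseltrack` finds a sparse set of seed
points on the vessels and follows each vessel iteratively. At every step it
estimates the two edge points of the local cross-section by a Bayesian maximum
a posteriori (MAP) decision over an intensity profile sampled across the
vessel, modeling the cross-section as an inverted Gaussian dip on a constant
background. A gradient-symmetry test predicts upcoming bifurcations and
crossings; when it fires, the search window switches from a line to a
semicircle and the MAP decision selects among *normal*, *bifurcation* and
*crossing* edge configurations, so the tracker resolves junction topology
explicitly instead of smearing over it. The result is a vessel *tree* —
ordered edge-point pairs with widths, directions and parent/child links —
from which a binary segmentation mask is rasterized.

The pipeline:

1. **Seeds** — grey-level minima on a 30 px grid, validated by 12 oriented
   matched filters against a locally adaptive threshold (`docs/methods.md`,
   "Seed selection").
2. **Directions** — Sobel gradient field; the dominant local gradient
   orientation (closed form) is normal to the vessel axis.
3. **Tracking** — iterative MAP edge detection with a Gibbs smoothness prior
   on linear windows; exact vectorized search over all feasible
   configurations.
4. **Branches** — semicircle windows at predicted branch points; bifurcations
   spawn two daughter tracks, crossings are tracked through.

The full model, parameter meanings, numerical choices and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic Y-junction phantom (trunk width 8 px, branches 6 and
5 px, contrast 60, Gaussian noise σ = 5), track it, and compare the rasterized
mask to the ground truth:

```python
import numpy as np

from vesseltrack import evaluation, image_model, phantom, tracker

img, truth = phantom.generate_phantom(phantom.y_junction_spec(seed=0))
tree, seeds = tracker.track_all(img)
mask = image_model.rasterize_tree(tree, img.shape)
metrics = evaluation.confusion_metrics(mask, truth.mask)

print(f"seeds validated:   {len(seeds)}")
print(f"segments tracked:  {len(tree.segments)}")
branched = sum("branched" in s.stop_reasons for s in tree.segments)
print(f"bifurcations:      {branched}")
widths = [step.diameter for seg in tree.segments for step in seg.steps]
print(f"mean tracked width: {np.mean(widths):.2f} px")
print(f"sensitivity:       {metrics.sensitivity:.3f}")
print(f"specificity:       {metrics.specificity:.3f}")
```

Output:

```
seeds validated:   13
segments tracked:  4
bifurcations:      1
mean tracked width: 6.03 px
sensitivity:       0.926
specificity:       0.997
```

The trunk is tracked up to the junction, flagged as a bifurcation, and the
daughter branches are tracked from there — one trunk segment with a
"branched" stop plus three child segments, with widths averaging near the
true 5–8 px range.

## Command line

The `vesseltrack` entry point has four subcommands:

```sh
vesseltrack segment IMAGE --out DIR [--config cfg.yaml] [--fov mask.png]
vesseltrack phantom --out DIR [--spec spec.yaml]
vesseltrack evaluate PRED TRUTH [--fov mask.png] [--out metrics.json]
vesseltrack seeds IMAGE --out seeds.csv [--config cfg.yaml]
```

`segment` writes the segmentation mask (PNG), the vessel tree (JSON), the
per-step track table and seed list (CSV), and a run log echoing the effective
configuration. `phantom` renders a synthetic image with its ground-truth mask
and centerline table. All outputs are deterministic: identical inputs and
configuration reproduce byte-identical files.

## Reproduction

Run the test suite (unit tests plus the acceptance tests for MAP-oracle
equivalence, width/direction recovery, branch prediction, structure
identification, benchmark segmentation quality, seed coverage and
determinism):

```sh
python -m pytest -q tests/
```

Recompute the headline quantities on the synthetic study conditions
(straight vessels of widths 3/5/8/12 px at contrast 60 with σ = 5 noise,
Y-junction, crossing and 512² benchmark-tree phantoms, 10 seeded trials
each):

```sh
python scripts/acceptance.py --seed 0 --out results.json
```

With seed 0 this reports, among others: MAP search equal to exhaustive
enumeration on 200/200 random profiles; mean absolute width error
0.37–0.57 px on noisy phantoms (0.18–0.31 px noise-free); 100% of edge
directions within 5°; 3.9% branch false-trigger rate with all 10 Y-junctions
triggered promptly; benchmark sensitivity 0.964 / specificity 0.998. The
`--seed` flag offsets every trial seed, so any value reruns the same protocol
on fresh noise realizations.
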