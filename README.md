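# voxelseg

Voxel-wise semantic segmentation of large 3D greyscale (tomography-style)
volumes with classical machine learning:

- **Features per voxel**: the voxel intensity, a short-range k-bin
  neighbourhood intensity histogram at scale 0, a long-range histogram at a
  configurable pyramid scale, and uniform rotation-invariant local binary
  pattern histograms on three orthogonal planes (10 codes per plane,
  30 features).
- **Multi-scale pyramid**: Gaussian blur of the original volume followed by
  decimation by 2^s.
- **Incremental histograms**: the neighbourhood histogram of each successive
  voxel along z is obtained from its predecessor by subtracting the outgoing
  `z − r` plane and adding the incoming `z + r + 1` plane — an O(r²) update
  instead of an O(r³) recount, verified voxel-for-voxel against the naive
  path.
- **Classifiers**: a random forest (Gini, depth ≤ 16, sqrt features, 16/32/64
  trees) and a compact two-hidden-layer feedforward net (leaky ReLU, Adam,
  dropout, early stopping, normal weight init).
- **Hyperparameter optimisation**: a two-stage random search (uniform global
  sampling, then single-variable stochastic hill climbing) over the joint
  feature + classifier space, with a visited-set and a novelty timeout.
- **Out-of-core processing**: volumes are segmented in z-slabs with halos, so
  peak memory is bounded by the slab, not the volume.
- **Synthetic fixtures**: labelled multi-texture volumes (regions differing
  in intensity distribution and in spatial texture) so the entire pipeline is
  testable without any external scan.

## Test

```sh
python -m pytest -q tests/
```

The suite includes a dedicated `tests/test_acceptance.py` with one test per
acceptance criterion (LBP code cardinality and rotation invariance,
incremental-vs-naive histogram equivalence, count conservation,
slab-invariance of segmentation, synthetic recovery accuracy,
histogram-vs-LBP separation, and the search contracts).

## CLI

```sh
# generate a labelled synthetic volume (TIFF stack + per-slice label PNGs)
voxelseg synth --preset three-region --shape 64 --seed 1 --out data/

# train with a named preset (60/20/20 slice split happens internally)
voxelseg train --volume data/volume --labels-dir data/labels \
    --labelmap data/labelmap.json --preset synthetic-rf --seed 1 --out model/

# segment the whole volume slab by slab
voxelseg segment --volume data/volume --model model/ --slab-thickness 8 \
    --out seg/

# score against withheld annotated slices (per-label IoU, accuracy, confusion)
voxelseg evaluate --pred seg/labels --labels-dir data/labels \
    --labelmap data/labelmap.json --slices 51,58,60 --out report.json

# two-stage random hyperparameter search
voxelseg optimise --volume data/volume --labels-dir data/labels \
    --labelmap data/labelmap.json --classifier rf \
    --global-iters 20 --local-iters 30 --train-samples 500 --val-samples 500 \
    --seed 1 --out search.json

# list shipped presets (per-specimen optimised configs + synthetic presets)
voxelseg presets
```

Volumes are read from a directory of equally shaped 2D TIFF slices, a
multi-page TIFF, or an HDF5 dataset (`--format`/dataset name configurable in
the API). Label slices are integer-coded PNG/TIFF images named
`labels_z<index>.png`; code 255 means "no annotation" (ignored), and every
other code must be a label id.

## Library sketch

```python
import numpy as np
from voxelseg import (
    build_pyramid, segment_volume, train_pipeline, evaluate,
)
from voxelseg.presets import get_preset
from voxelseg.synth import (
    make_three_region_volume, annotations_from_labels, evenly_spaced_slices,
)

volume, labels, label_map = make_three_region_volume((64, 64, 64), seed=1)
annotations = annotations_from_labels(labels, evenly_spaced_slices(64, 20))
preset = get_preset("synthetic-rf", seed=1)
model = train_pipeline(
    volume, annotations, label_map,
    (preset.feature_config, preset.classifier_spec), seed=1,
)
predicted = segment_volume(model, volume, slab_thickness=8)
test_slices = [a for a in annotations
               if a.slice_index in model.metadata["split"]["test"]]
report = evaluate(predicted, test_slices, label_map)
print(report.overall_accuracy, report.per_label_iou)
```
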