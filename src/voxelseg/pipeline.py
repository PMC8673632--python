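"""End-to-end orchestration: slice split, sampling, training, blocked
segmentation of whole volumes, and IoU evaluation on withheld slices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from voxelseg.features import FeatureConfig, FeatureExtractor
from voxelseg.hpo import (
    SearchBudget,
    SearchSpace,
    VoxelSet,
    config_to_classifier_spec,
    config_to_feature_config,
    two_stage_search,
)
from voxelseg.models import TrainedModel, train_classifier
from voxelseg.pyramid import build_pyramid
from voxelseg.volume import AnnotatedSlice, LabelMap, Volume, iter_slabs


@dataclass(frozen=True)
class SliceSplit:
    """Disjoint train/validation/test slice indices covering all annotated
    slices, assigned randomly by slice (never by voxel)."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split sets overlap")

    def to_dict(self) -> dict:
        return {
            "train": list(self.train),
            "validation": list(self.validation),
            "test": list(self.test),
            "fractions": list(self.fractions),
            "seed": self.seed,
        }


def split_slices(
    annotated: Sequence[int] | Sequence[AnnotatedSlice],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SliceSplit:
    """Randomly split annotated slice indices into train/val/test.

    Set sizes follow largest-remainder apportionment of the fractions,
    with remainder ties resolved toward the earlier set (train before
    validation before test).
    """
    indices = [
        s.slice_index if isinstance(s, AnnotatedSlice) else int(s)
        for s in annotated
    ]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate annotated slice indices")
    n = len(indices)
    if n < 3:
        raise ValueError(f"need at least 3 annotated slices to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    quotas = [f * n for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    leftover = n - sum(sizes)
    # largest remainder first; ties to the earlier set
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(sorted(indices)))
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0]: sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return SliceSplit(
        train=tuple(sorted(int(i) for i in train)),
        validation=tuple(sorted(int(i) for i in val)),
        test=tuple(sorted(int(i) for i in test)),
        fractions=tuple(fractions),
        seed=seed,
    )


def sample_voxels(
    annotated_slices: Sequence[AnnotatedSlice],
    per_label_n: int,
    label_map: LabelMap,
    seed: int = 0,
    require_all_labels: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform per-label voxel sample without replacement.

    Returns ``(coords, labels)`` with at most ``per_label_n`` voxels per
    label (all of them when fewer are available).  Ignore-coded voxels
    are never sampled.  Labels absent from every slice raise an error
    naming them (unless ``require_all_labels`` is off).
    """
    if per_label_n < 1:
        raise ValueError("per_label_n must be >= 1")
    coords_all = []
    labels_all = []
    for sl in annotated_slices:
        yy, xx = np.nonzero(sl.labels != label_map.ignore_id)
        coords_all.append(
            np.column_stack([np.full(len(yy), sl.slice_index), yy, xx])
        )
        labels_all.append(sl.labels[yy, xx].astype(np.int64))
    coords = (
        np.concatenate(coords_all) if coords_all
        else np.empty((0, 3), dtype=np.int64)
    )
    labels = (
        np.concatenate(labels_all) if labels_all
        else np.empty(0, dtype=np.int64)
    )
    present = set(np.unique(labels).tolist())
    missing = [lid for lid in label_map.ids if lid not in present]
    if missing and require_all_labels:
        names = [label_map.names[m] for m in missing]
        raise ValueError(
            f"labels absent from every annotated slice: {names} (ids {missing})"
        )
    rng = np.random.default_rng(seed)
    pick = []
    for lid in sorted(present):
        idx = np.flatnonzero(labels == lid)
        n = min(per_label_n, len(idx))
        pick.append(rng.choice(idx, size=n, replace=False))
    pick = np.concatenate(pick)
    return coords[pick].astype(np.int64), labels[pick]


def _slices_by_index(
    annotations: Sequence[AnnotatedSlice], indices: Sequence[int]
) -> list[AnnotatedSlice]:
    wanted = set(indices)
    return [s for s in annotations if s.slice_index in wanted]


def train_pipeline(
    volume: Volume,
    annotations: Sequence[AnnotatedSlice],
    label_map: LabelMap,
    config_or_search,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    per_label_n: int = 16000,
    n_jobs: int = 1,
) -> TrainedModel:
    """Split slices, optionally search, then train on the full training set.

    ``config_or_search`` is either ``(FeatureConfig, classifier_spec)``
    (a preset) or ``(SearchSpace, SearchBudget)``; in the latter case
    the two-stage search runs on the train/validation slices first and
    the final model is trained with the optimised variables.  The slice
    split and any search trace summary are recorded in the model
    metadata.
    """
    split = split_slices(annotations, fractions, seed)
    train_slices = _slices_by_index(annotations, split.train)
    val_slices = _slices_by_index(annotations, split.validation)

    first, second = config_or_search
    search_summary = None
    if isinstance(first, SearchSpace):
        space, budget = first, second
        s_max = space.max_scale
        pyr = build_pyramid(volume, s_max)
        tr_coords, tr_labels = sample_voxels(
            train_slices, per_label_n * 4, label_map, seed=seed
        )
        val_coords, val_labels = sample_voxels(
            val_slices, per_label_n * 4, label_map, seed=seed + 1,
            require_all_labels=False,
        )
        result = two_stage_search(
            VoxelSet(pyr, tr_coords, tr_labels),
            VoxelSet(pyr, val_coords, val_labels),
            space,
            budget,
            n_jobs=n_jobs,
        )
        feature_config = config_to_feature_config(result.best_config)
        classifier_spec = config_to_classifier_spec(
            result.best_config, space.classifier, seed=seed
        )
        search_summary = {
            "best_config": result.best_config,
            "best_accuracy": result.best_accuracy,
            "n_evaluated": len(result.trace),
        }
    else:
        feature_config, classifier_spec = first, second
        s_max = feature_config.max_scale
        pyr = build_pyramid(volume, s_max)

    coords, labels = sample_voxels(train_slices, per_label_n, label_map, seed=seed)
    ext = FeatureExtractor(pyr)
    X = ext.features_for_coords(coords, feature_config)
    model = train_classifier(
        classifier_spec,
        X,
        labels,
        feature_config=feature_config,
        label_map=label_map,
        intensity_bounds=(volume.intensity_min, volume.intensity_max),
        n_jobs=n_jobs,
    )
    model.metadata.update(
        {
            "split": split.to_dict(),
            "per_label_n": per_label_n,
            "pipeline_seed": seed,
        }
    )
    if search_summary is not None:
        model.metadata["search"] = search_summary
    return model


def segment_volume(
    model: TrainedModel,
    volume: Volume,
    slab_thickness: int = 8,
    n_jobs: int = 1,
) -> np.ndarray:
    """Predict a label id for every voxel, slab by slab.

    The output is identical for any slab thickness; per-slab feature
    matrices bound peak memory by the slab, not the volume.  Histogram
    binning uses the *model's* stored intensity bounds so inference
    matches training.
    """
    if model.feature_config is None:
        raise ValueError("model carries no feature config; cannot segment")
    fc = model.feature_config
    pyr = build_pyramid(volume, fc.max_scale)
    bounds = model.intensity_bounds or (volume.intensity_min, volume.intensity_max)
    ext = FeatureExtractor(pyr, bounds=bounds)
    nz, ny, nx = volume.shape
    out = np.empty((nz, ny, nx), dtype=np.uint8)
    for slab in iter_slabs(volume, slab_thickness, halo=fc.required_halo()):
        z0, z1 = slab.z_range
        X = ext.block_features(z0, z1, fc)
        pred = model.predict(X)
        out[z0:z1] = pred.reshape(z1 - z0, ny, nx).astype(np.uint8)
    return out


@dataclass
class EvaluationReport:
    """Per-label IoU (percent, None where a label is absent from both
    truth and prediction), overall voxel accuracy, micro-averaged IoU,
    confusion counts (rows = truth) and per-label voxel shares."""

    per_label_iou: dict[int, float | None]
    overall_accuracy: float
    micro_iou: float
    confusion: np.ndarray
    label_share: dict[int, float]
    n_voxels: int

    def to_dict(self, label_map: LabelMap | None = None) -> dict:
        def name(lid: int) -> str:
            return label_map.names[lid] if label_map else str(lid)

        return {
            "per_label_iou_percent": {
                name(k): v for k, v in self.per_label_iou.items()
            },
            "overall_accuracy_percent": self.overall_accuracy,
            "micro_iou_percent": self.micro_iou,
            "confusion": self.confusion.tolist(),
            "label_share": {name(k): v for k, v in self.label_share.items()},
            "n_voxels": self.n_voxels,
        }


def evaluate(
    predicted: np.ndarray,
    truth_slices: Sequence[AnnotatedSlice],
    label_map: LabelMap,
) -> EvaluationReport:
    """Score a predicted label volume against annotated truth slices.

    Only non-ignore voxels on the truth slices count.  Per-label IoU is
    ``|pred ∩ truth| / |pred ∪ truth|`` as a percentage; overall
    accuracy is the fraction of correctly labelled voxels.  Micro IoU
    (intersection and union pooled over labels) is reported alongside.
    """
    predicted = np.asarray(predicted)
    truths = []
    preds = []
    for sl in truth_slices:
        if not 0 <= sl.slice_index < predicted.shape[0]:
            raise ValueError(
                f"truth slice z={sl.slice_index} outside predicted volume"
            )
        mask = sl.labels != label_map.ignore_id
        truths.append(sl.labels[mask].astype(np.int64))
        preds.append(predicted[sl.slice_index][mask].astype(np.int64))
    if not truths or sum(len(t) for t in truths) == 0:
        raise ValueError("no labelled voxels to evaluate")
    truth = np.concatenate(truths)
    pred = np.concatenate(preds)

    n = label_map.n_labels
    confusion = np.zeros((n, n), dtype=np.int64)
    np.add.at(confusion, (truth, pred), 1)

    per_label: dict[int, float | None] = {}
    inter_sum = 0
    union_sum = 0
    for lid in label_map.ids:
        inter = int(confusion[lid, lid])
        union = int(confusion[lid, :].sum() + confusion[:, lid].sum() - inter)
        if union == 0:
            per_label[lid] = None
        else:
            per_label[lid] = 100.0 * inter / union
            inter_sum += inter
            union_sum += union

    total = len(truth)
    overall = 100.0 * float(np.mean(pred == truth))
    micro = 100.0 * inter_sum / union_sum if union_sum else 100.0
    share = {
        lid: float(confusion[lid, :].sum()) / total for lid in label_map.ids
    }
    return EvaluationReport(
        per_label_iou=per_label,
        overall_accuracy=overall,
        micro_iou=micro,
        confusion=confusion,
        label_share=share,
        n_voxels=total,
    )
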