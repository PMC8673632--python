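"""Two-stage random hyperparameter search over features + classifier.

Stage one samples the whole joint space uniformly; stage two is a
stochastic hill climb that repeatedly mutates a single variable of the
best configuration found so far.  Previously visited configurations are
never re-evaluated; a phase exits early when ``t`` seconds pass inside
the resampling loop without producing a novel configuration.

Continuous variables (dropout, init stddev) are discretised onto fixed
grids — dropout in steps of 0.05, init stddev on a 16-point log grid —
so that the visited-set equality test is meaningful; the stddev grid is
log-spaced because its range spans four decades.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from voxelseg.features import FeatureConfig, HistogramSpec, LBPSpec, FeatureExtractor
from voxelseg.models import (
    NeuralNetSpec,
    RandomForestSpec,
    train_classifier,
)
from voxelseg.pyramid import Pyramid

Config = dict[str, "int | float"]


@dataclass(frozen=True)
class Choice:
    """A variable drawn uniformly from a finite set of values."""

    values: tuple

    def sample(self, rng: np.random.Generator):
        return self.values[int(rng.integers(len(self.values)))]

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, v) -> bool:
        return v in self.values


def int_range(lo: int, hi: int) -> Choice:
    """Uniform integer variable on the inclusive range [lo, hi]."""
    return Choice(tuple(range(lo, hi + 1)))


DROPOUT_GRID = tuple(round(0.05 * i, 2) for i in range(11))          # 0.0 .. 0.5
INIT_STDDEV_GRID = tuple(
    float(f"{v:.6g}") for v in np.geomspace(0.0001, 1.0, 16)
)

FEATURE_VARIABLES: dict[str, Choice] = {
    "hist1_radius": int_range(1, 8),
    "hist1_bins": Choice((8, 16, 32)),
    "hist2_scale": int_range(0, 2),
    "hist2_radius": int_range(1, 32),
    "hist2_bins": Choice((8, 16, 32)),
    "lbp_scale": int_range(0, 2),
    "lbp_radius": int_range(1, 32),
}

RF_VARIABLES: dict[str, Choice] = {
    "rf_n_trees": Choice((16, 32, 64)),
}

NN_VARIABLES: dict[str, Choice] = {
    "nn_layer1": Choice((32, 64, 128, 256)),
    "nn_layer2": Choice((32, 64, 128, 256)),
    "nn_dropout": Choice(DROPOUT_GRID),
    "nn_init_stddev": Choice(INIT_STDDEV_GRID),
    "nn_minibatch": Choice((4, 8, 16, 32, 64)),
}


@dataclass(frozen=True)
class SearchSpace:
    """Named variables, each with a finite uniform domain."""

    variables: Mapping[str, Choice]
    classifier: str = "random_forest"

    @classmethod
    def random_forest(cls, overrides: Mapping[str, Choice] | None = None) -> "SearchSpace":
        v = {**FEATURE_VARIABLES, **RF_VARIABLES, **(overrides or {})}
        return cls(variables=v, classifier="random_forest")

    @classmethod
    def neural_net(cls, overrides: Mapping[str, Choice] | None = None) -> "SearchSpace":
        v = {**FEATURE_VARIABLES, **NN_VARIABLES, **(overrides or {})}
        return cls(variables=v, classifier="neural_net")

    def validate(self, config: Config) -> None:
        if set(config) != set(self.variables):
            raise ValueError(
                f"config variables {sorted(config)} do not match the space "
                f"{sorted(self.variables)}"
            )
        for name, value in config.items():
            if value not in self.variables[name]:
                raise ValueError(f"value {value!r} out of range for {name}")

    @property
    def max_scale(self) -> int:
        hi = 0
        for name in ("hist2_scale", "lbp_scale"):
            if name in self.variables:
                hi = max(hi, max(self.variables[name].values))
        return hi


@dataclass(frozen=True)
class SearchBudget:
    """Iteration counts, per-label sample sizes and the novelty timeout."""

    I_g: int = 1000
    I_l: int = 10000
    S_t: int = 16000
    S_v: int = 16000
    t: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("I_g", "I_l", "S_t", "S_v"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.t <= 0:
            raise ValueError("timeout t must be positive")


@dataclass
class TraceEntry:
    iteration: int
    phase: str
    config: Config
    accuracy: float


@dataclass
class SearchResult:
    best_config: Config
    best_accuracy: float
    trace: list[TraceEntry]
    n_visited: int

    def best_so_far(self) -> list[float]:
        out, best = [], 0.0
        for e in self.trace:
            best = max(best, e.accuracy)
            out.append(best)
        return out

    def write_trace_csv(self, path: str | Path) -> None:
        path = Path(path)
        if not self.trace:
            path.write_text("")
            return
        names = sorted(self.trace[0].config)
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["iteration", "phase", *names, "accuracy"])
            for e in self.trace:
                w.writerow(
                    [e.iteration, e.phase, *[e.config[n] for n in names], e.accuracy]
                )


# --------------------------------------------------------------------------
# Sampling / mutation
# --------------------------------------------------------------------------

def sample_config(space: SearchSpace, rng: np.random.Generator) -> Config:
    """Draw every variable independently and uniformly from its domain."""
    return {name: dom.sample(rng) for name, dom in space.variables.items()}


def mutate_config(
    config: Config, space: SearchSpace, rng: np.random.Generator
) -> Config:
    """Replace exactly one variable with a fresh uniform value.

    The variable is chosen uniformly among those with more than one
    possible value; its new value is resampled until it differs.  With a
    fully degenerate space the config is returned unchanged.
    """
    space.validate(config)
    mutable = [n for n, dom in space.variables.items() if len(dom) > 1]
    out = dict(config)
    if not mutable:
        return out
    name = mutable[int(rng.integers(len(mutable)))]
    dom = space.variables[name]
    new = dom.sample(rng)
    while new == config[name]:
        new = dom.sample(rng)
    out[name] = new
    return out


def _config_key(config: Config) -> tuple:
    return tuple(sorted(config.items()))


def config_to_feature_config(config: Config) -> FeatureConfig:
    return FeatureConfig(
        hist1=HistogramSpec(r=int(config["hist1_radius"]), s=0,
                            k=int(config["hist1_bins"])),
        hist2=HistogramSpec(r=int(config["hist2_radius"]),
                            s=int(config["hist2_scale"]),
                            k=int(config["hist2_bins"])),
        lbp=LBPSpec(s=int(config["lbp_scale"]), r=int(config["lbp_radius"])),
    )


def config_to_classifier_spec(
    config: Config, classifier: str, seed: int = 0
) -> RandomForestSpec | NeuralNetSpec:
    if classifier == "random_forest":
        return RandomForestSpec(n_trees=int(config["rf_n_trees"]), seed=seed)
    if classifier == "neural_net":
        return NeuralNetSpec(
            layer1=int(config["nn_layer1"]),
            layer2=int(config["nn_layer2"]),
            dropout=float(config["nn_dropout"]),
            init_stddev=float(config["nn_init_stddev"]),
            minibatch=int(config["nn_minibatch"]),
            seed=seed,
        )
    raise ValueError(f"unknown classifier {classifier!r}")


# --------------------------------------------------------------------------
# The search itself
# --------------------------------------------------------------------------

@dataclass
class VoxelSet:
    """Labelled voxel coordinates against one pyramid."""

    pyramid: Pyramid
    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.coords) != len(self.labels):
            raise ValueError("coords and labels disagree in length")


def _balanced_sample(
    coords: np.ndarray, labels: np.ndarray, per_label: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of min(per_label, available) voxels per label, drawn
    uniformly without replacement."""
    picks = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n = min(per_label, len(idx))
        picks.append(rng.choice(idx, size=n, replace=False))
    return np.concatenate(picks)


def two_stage_search(
    train_set: VoxelSet,
    val_set: VoxelSet,
    space: SearchSpace,
    budget: SearchBudget,
    clock: Callable[[], float] = time.monotonic,
    n_jobs: int = 1,
    evaluate_fn: Callable[[Config], float] | None = None,
) -> SearchResult:
    """Run the global + local random search and return the best config.

    ``evaluate_fn`` replaces the default train-and-score evaluation
    (used by tests to plant a known objective); it receives a config and
    returns an accuracy in [0, 1].
    """
    labels_present = np.unique(train_set.labels)
    if len(labels_present) == 0:
        raise ValueError("training set carries no labelled voxels")
    missing = [
        int(l) for l in np.unique(val_set.labels) if l not in labels_present
    ]
    if missing:
        raise ValueError(
            f"labels {missing} present in validation but absent from training"
        )

    rng = np.random.default_rng(budget.seed)
    sub_tr = _balanced_sample(train_set.coords, train_set.labels, budget.S_t, rng)
    sub_val = _balanced_sample(val_set.coords, val_set.labels, budget.S_v, rng)
    tr_coords, tr_labels = train_set.coords[sub_tr], train_set.labels[sub_tr]
    val_coords, val_labels = val_set.coords[sub_val], val_set.labels[sub_val]

    if evaluate_fn is None:
        tr_ext = FeatureExtractor(train_set.pyramid)
        val_ext = (
            tr_ext if val_set.pyramid is train_set.pyramid
            else FeatureExtractor(val_set.pyramid, bounds=(tr_ext.lo, tr_ext.hi))
        )

    def default_evaluate(config: Config) -> float:
        fc = config_to_feature_config(config)
        spec = config_to_classifier_spec(config, space.classifier, seed=budget.seed)
        Xtr = tr_ext.features_for_coords(tr_coords, fc)
        Xval = val_ext.features_for_coords(val_coords, fc)
        model = train_classifier(spec, Xtr, tr_labels, n_jobs=n_jobs)
        pred = model.predict(Xval)
        return float(np.mean(pred == val_labels))

    evaluate = evaluate_fn or default_evaluate

    known: set[tuple] = set()
    best_config: Config | None = None
    best_accuracy = 0.0
    trace: list[TraceEntry] = []
    iteration = 0

    def run_phase(phase: str, n_iter: int, proposer: Callable[[], Config]) -> bool:
        nonlocal best_config, best_accuracy, iteration
        for _ in range(n_iter):
            start = clock()
            while True:
                config = proposer()
                if clock() - start > budget.t:
                    return False  # novelty timeout: exit phase
                if _config_key(config) not in known:
                    break
            known.add(_config_key(config))
            acc = evaluate(config)
            iteration += 1
            trace.append(TraceEntry(iteration, phase, dict(config), acc))
            # strict ">" per the hill-climb rule: ties keep the earlier config
            if acc > best_accuracy:
                best_accuracy = acc
                best_config = dict(config)
            elif best_config is None:
                best_config = dict(config)
        return True

    run_phase("global", budget.I_g, lambda: sample_config(space, rng))
    if best_config is None:
        raise RuntimeError("global phase evaluated no configuration")
    run_phase("local", budget.I_l, lambda: mutate_config(best_config, space, rng))

    return SearchResult(
        best_config=best_config,
        best_accuracy=best_accuracy,
        trace=trace,
        n_visited=len(known),
    )
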