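"""Named feature/classifier presets.

The four specimen presets per classifier are the optimised variable
sets found by the full-scale search on the original scans; the
``synthetic-*`` presets are small configurations sized for the bundled
synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from voxelseg.features import FeatureConfig, HistogramSpec, LBPSpec
from voxelseg.models import NeuralNetSpec, RandomForestSpec


@dataclass(frozen=True)
class Preset:
    name: str
    feature_config: FeatureConfig
    classifier_spec: "RandomForestSpec | NeuralNetSpec"

    def with_seed(self, seed: int) -> "Preset":
        return replace(self, classifier_spec=replace(self.classifier_spec, seed=seed))


def _fc(h1r, h1k, h2s, h2r, h2k, lbps, lbpr) -> FeatureConfig:
    return FeatureConfig(
        hist1=HistogramSpec(r=h1r, s=0, k=h1k),
        hist2=HistogramSpec(r=h2r, s=h2s, k=h2k),
        lbp=LBPSpec(s=lbps, r=lbpr),
    )


PRESETS: dict[str, Preset] = {
    # specimen presets, random forest
    "dog-rf": Preset("dog-rf", _fc(3, 32, 0, 12, 16, 0, 15), RandomForestSpec(64)),
    "raptor-rf": Preset("raptor-rf", _fc(6, 8, 0, 27, 32, 1, 27), RandomForestSpec(64)),
    "ibis-rf": Preset("ibis-rf", _fc(5, 8, 0, 21, 32, 1, 20), RandomForestSpec(64)),
    "ibis-jar-rf": Preset("ibis-jar-rf", _fc(7, 32, 2, 24, 16, 0, 30), RandomForestSpec(64)),
    # specimen presets, neural network
    "dog-nn": Preset(
        "dog-nn", _fc(7, 16, 1, 6, 8, 1, 18),
        NeuralNetSpec(layer1=256, layer2=64, dropout=0.4,
                      init_stddev=0.0001, minibatch=32),
    ),
    "raptor-nn": Preset(
        "raptor-nn", _fc(8, 32, 2, 32, 32, 1, 28),
        NeuralNetSpec(layer1=256, layer2=64, dropout=0.45,
                      init_stddev=0.0251, minibatch=32),
    ),
    "ibis-nn": Preset(
        "ibis-nn", _fc(7, 8, 0, 27, 32, 1, 27),
        NeuralNetSpec(layer1=64, layer2=128, dropout=0.25,
                      init_stddev=0.1585, minibatch=32),
    ),
    "ibis-jar-nn": Preset(
        "ibis-jar-nn", _fc(7, 32, 2, 29, 16, 0, 28),
        NeuralNetSpec(layer1=256, layer2=64, dropout=0.25,
                      init_stddev=0.0016, minibatch=32),
    ),
    # desk-scale presets for the synthetic fixtures
    "synthetic-rf": Preset(
        "synthetic-rf", _fc(2, 16, 1, 4, 16, 0, 3), RandomForestSpec(32)
    ),
    "synthetic-nn": Preset(
        "synthetic-nn", _fc(2, 16, 1, 4, 16, 0, 3),
        NeuralNetSpec(layer1=64, layer2=64, dropout=0.2,
                      init_stddev=0.05, minibatch=64),
    ),
}


def get_preset(name: str, seed: int = 0) -> Preset:
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return preset.with_seed(seed)
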