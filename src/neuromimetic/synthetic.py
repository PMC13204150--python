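"""Two-class imbalanced Gaussian-mixture feature tables.

The generator emulates the class structure of the motivating EEG study:
a small minority class (patients) against a large majority class (healthy
controls), with a handful of informative, mutually correlated features whose
class-conditional means differ by a configurable effect size, embedded in
class-independent Gaussian noise features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset, ValidationError, rng_stream


@dataclass
class GeneratorSpec:
    """Parameters of the two-class Gaussian-mixture generator.

    effect_size is the class-mean shift of each informative feature in units
    of its within-class standard deviation; correlation is the equicorrelation
    coefficient among informative features within a class.
    """

    n_class0: int = 1225
    n_class1: int = 325
    n_features: int = 64
    n_informative: int = 8
    effect_size: float = 1.0
    correlation: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "GeneratorSpec":
        if self.n_class0 <= 0 or self.n_class1 <= 0:
            raise ValidationError("class counts must be positive")
        if self.n_features <= 0:
            raise ValidationError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("n_informative must lie in [0, n_features]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValidationError("correlation must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        return self


_PRESETS = {
    # (healthy, patient) sample counts of the two visual-task experiments
    # the framework was designed around.
    "experiment1": (1225, 325),
    "experiment2": (1200, 350),
}


def preset(name: str, **overrides) -> GeneratorSpec:
    """Named generator spec reproducing a study experiment's class sizes."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset '{name}'; available: {sorted(_PRESETS)}")
    n0, n1 = _PRESETS[name]
    return GeneratorSpec(n_class0=n0, n_class1=n1, **overrides).validate()


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a labeled feature table from the generator spec.

    Informative features are equicorrelated unit-variance Gaussians whose
    means differ between classes by ``effect_size``; the remaining features
    are i.i.d. N(0, noise_sd^2) in both classes. Class-0 rows come first.
    """
    spec.validate()
    rng = rng_stream(spec.seed, "synthetic")
    n = spec.n_class0 + spec.n_class1
    p, k = spec.n_features, spec.n_informative

    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    if k > 0:
        # equicorrelated covariance (1-rho) I + rho J via its exact square root
        rho = spec.correlation
        z = rng.standard_normal((n, k))
        shared = rng.standard_normal((n, 1))
        informative = np.sqrt(1.0 - rho) * z + np.sqrt(rho) * shared
        informative[spec.n_class0:] += spec.effect_size
        X[:, :k] = informative

    labels = np.concatenate(
        [np.zeros(spec.n_class0, dtype=int), np.ones(spec.n_class1, dtype=int)])
    names = [f"f{j:03d}" for j in range(p)]
    ids = [f"s{i:04d}" for i in range(n)]
    return LabeledDataset(X, labels, names, ids)
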