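"""Synthetic ASV-like cohorts with a controllable age signal.

Emulates a saliva 16S cohort: a sparse non-negative integer count table over
a few hundred features and an age column spanning 6-78 years. The age signal
lives in *presence/absence* by default — each signal feature's probability
of being detected in a sample follows a logistic curve in age,

    P(present | age) = logistic( logit(baseline) + slope * (age - midrange) ),

with half the signal features increasing and half decreasing with age; noise
features are present at the baseline prevalence independent of age.
Conditional on presence, counts are negative-binomial. An optional
``abundance_signal`` mode instead scales the expected count with age (for
exercising the log2/CLR paths).

What this generator does *not* emulate: taxonomic or phylogenetic structure,
feature-feature correlation, compositional closure of real sequencing depth,
or the cohort's empirical age histogram (ages are uniform unless
``age_counts`` pins the histogram).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .io import FeatureTable, SampleMetadata


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults emulate the cohort scale this package targets: 150 samples aged
    6-78, a sparse table (here trimmed to 200 features for tractability),
    20 of which carry a presence/absence age signal of 0.08 logit units per
    year — strong enough to dominate a 30% baseline prevalence across the
    age span, as age-discriminative oral taxa do.
    """

    n_samples: int = 150
    n_features: int = 200
    n_signal_features: int = 20
    age_range: tuple[int, int] = (6, 78)
    presence_slope: float = 0.08  # logit units per year
    baseline_prevalence: float = 0.3
    count_dispersion: float = 0.5  # negative-binomial shape; smaller = noisier
    mean_depth: int = 20_000  # expected reads per sample
    seed: int = 8
    abundance_signal: bool = False
    age_counts: Optional[Mapping[int, int]] = field(default=None)
    with_sex: bool = True

    def validate(self) -> None:
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.n_signal_features > self.n_features:
            raise ValueError("n_signal_features exceeds n_features")
        if self.count_dispersion <= 0 or self.mean_depth <= 0:
            raise ValueError("count_dispersion and mean_depth must be positive")
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid age_range {self.age_range}")
        if self.age_counts is not None:
            if sum(self.age_counts.values()) != self.n_samples:
                raise ValueError("age_counts must sum to n_samples")
            if any(a < lo or a > hi for a in self.age_counts):
                raise ValueError("age_counts contains ages outside age_range")


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: SyntheticConfig) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Generate a (count FeatureTable, metadata) pair; fully seed-determined."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    if config.age_counts is not None:
        ages = np.repeat(
            list(config.age_counts.keys()), list(config.age_counts.values())
        )
        rng.shuffle(ages)
    else:
        ages = rng.integers(lo, hi + 1, size=config.n_samples)
    ages = ages.astype(int)

    n_sig = config.n_signal_features
    # half positive, half negative slope; odd counts favor positive
    slopes = np.zeros(config.n_features)
    slopes[: (n_sig + 1) // 2] = config.presence_slope
    slopes[(n_sig + 1) // 2 : n_sig] = -config.presence_slope

    midrange = (lo + hi) / 2.0
    base_logit = np.log(config.baseline_prevalence / (1 - config.baseline_prevalence))

    if config.abundance_signal:
        presence_p = np.full(
            (config.n_features, config.n_samples), config.baseline_prevalence
        )
    else:
        presence_p = _logistic(
            base_logit + slopes[:, None] * (ages[None, :] - midrange)
        )
    present = rng.random((config.n_features, config.n_samples)) < presence_p

    # per-feature mean count conditional on presence, scaled to mean_depth
    mu = config.mean_depth / (config.n_features * config.baseline_prevalence)
    mu_matrix = np.full((config.n_features, config.n_samples), mu)
    if config.abundance_signal:
        mu_matrix = mu_matrix * np.exp(
            slopes[:, None] * (ages[None, :] - midrange) / 4.0
        )
    r = config.count_dispersion
    p = r / (r + mu_matrix)
    counts = np.where(present, 1 + rng.negative_binomial(r, p), 0)

    feature_ids = [
        f"ASV_{i + 1:04d}{'_sig' if i < n_sig else ''}" for i in range(config.n_features)
    ]
    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    table = FeatureTable(feature_ids, sample_ids, counts.astype(float), "count")

    sexes = rng.choice(["female", "male"], size=config.n_samples) if config.with_sex else None
    meta = [
        SampleMetadata(
            sample_ids[j],
            int(ages[j]),
            None if sexes is None else str(sexes[j]),
        )
        for j in range(config.n_samples)
    ]
    return table, meta


def signal_feature_ids(config: SyntheticConfig) -> list[str]:
    """The feature ids carrying the age signal under ``config``."""
    return [
        f"ASV_{i + 1:04d}_sig" for i in range(config.n_signal_features)
    ]
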