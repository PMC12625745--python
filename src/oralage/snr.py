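"""Per-feature signal-to-noise scoring across age groups.

For a feature x with k age groups of sizes n_i (n samples total), the score is

    SNR = [ sum_i n_i (xbar_i - xbar)^2 / (k - 1) ]
          / [ sum_i sum_j (x_ij - xbar_i)^2 / (n - k) ]

i.e. between-group mean square over within-group mean square — numerically
the one-way ANOVA F statistic. A feature constant within every group (for
instance an ASV present in all samples after binarization) has a zero
denominator and an undefined SNR, reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, SampleMetadata, ValidationError

#: Default age groups: young 0-29, middle-aged 30-64, old >= 65.
DEFAULT_AGE_GROUPS: dict[str, tuple[int, Optional[int]]] = {
    "young": (0, 29),
    "middle": (30, 64),
    "old": (65, None),
}


@dataclass
class SNRResult:
    feature_id: str
    snr: Optional[float]  # None when within-group variation is zero
    group_means: dict[str, float]
    overall_mean: float


def assign_age_groups(
    meta: Sequence[SampleMetadata],
    groups: Mapping[str, tuple[int, Optional[int]]] = DEFAULT_AGE_GROUPS,
) -> list[str]:
    """Map each sample's age to a group label. Bounds are inclusive; an upper
    bound of None means unbounded."""
    labels = []
    for m in meta:
        for name, (lo, hi) in groups.items():
            if m.age >= lo and (hi is None or m.age <= hi):
                labels.append(name)
                break
        else:
            raise ValidationError(
                f"sample {m.sample_id!r} (age {m.age}) matches no group"
            )
    return labels


def compute_snr(table: FeatureTable, group_labels: Sequence[str]) -> list[SNRResult]:
    """Score every feature; see the module docstring for the statistic."""
    labels = np.asarray(group_labels)
    if len(labels) != table.n_samples:
        raise ValidationError("one group label per sample required")
    names, inverse = np.unique(labels, return_inverse=True)
    k = len(names)
    n = table.n_samples
    if k < 2:
        raise ValidationError("need at least 2 groups")
    if n <= k:
        raise ValidationError(f"need more samples ({n}) than groups ({k})")

    X = table.values  # (features, samples)
    counts = np.bincount(inverse, minlength=k).astype(float)
    # group sums via one matmul: (features, k)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inverse] = 1.0
    group_sums = X @ onehot
    group_means = group_sums / counts
    overall_mean = X.mean(axis=1)

    between = (counts * (group_means - overall_mean[:, None]) ** 2).sum(axis=1) / (k - 1)
    within_ss = ((X**2) @ onehot - counts * group_means**2).sum(axis=1)
    within_ss = np.maximum(within_ss, 0.0)
    # a within-group sum of squares at rounding-noise level (relative to the
    # feature's own scale) is an exactly-constant-within-groups feature
    scale = np.abs(X).max(axis=1)
    undefined = within_ss <= n * (1e-9 * scale) ** 2
    within = within_ss / (n - k)

    out = []
    for i, fid in enumerate(table.feature_ids):
        gm = {name: float(group_means[i, g]) for g, name in enumerate(names)}
        if undefined[i] or within[i] == 0.0:
            snr: Optional[float] = None
        else:
            snr = float(between[i] / within[i])
        out.append(SNRResult(fid, snr, gm, float(overall_mean[i])))
    return out


def snr_results_frame(results: Sequence[SNRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "snr": [np.nan if r.snr is None else r.snr for r in results],
        }
    ).set_index("feature_id")


def snr_summary(
    results_by_transform: Mapping[str, Sequence[SNRResult]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize and compare SNR profiles across transforms.

    Returns ``(summary, pairwise)``:

    * ``summary`` — per transform: mean SNR over defined features, number of
      features with SNR > 1, number of undefined features.
    * ``pairwise`` — per ordered transform pair: how many features score
      strictly higher under the first transform, and a two-sided Wilcoxon
      signed-rank p-value over features defined in both (identical profiles
      give p = 1 by convention).

    Features undefined under a transform are excluded from that transform's
    mean and, pairwise, only from comparisons involving it.
    """
    frames = {name: snr_results_frame(res) for name, res in results_by_transform.items()}
    names = list(frames)
    feature_sets = {name: tuple(f.index) for name, f in frames.items()}
    if len(set(feature_sets.values())) != 1:
        raise ValidationError("all transforms must score the same feature set")

    summary = pd.DataFrame(
        {
            "mean_snr": [frames[n]["snr"].mean() for n in names],
            "n_snr_gt_1": [(frames[n]["snr"] > 1).sum() for n in names],
            "n_undefined": [frames[n]["snr"].isna().sum() for n in names],
        },
        index=pd.Index(names, name="transform"),
    )

    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            sa, sb = frames[a]["snr"], frames[b]["snr"]
            both = sa.notna() & sb.notna()
            da, db = sa[both].to_numpy(), sb[both].to_numpy()
            wins = int((da > db).sum())
            diffs = da - db
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(da, db).pvalue)
            rows.append(
                {"transform_a": a, "transform_b": b, "n_compared": int(both.sum()),
                 "wins_a": wins, "wilcoxon_p": p}
            )
    pairwise = pd.DataFrame(rows)
    return summary, pairwise
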