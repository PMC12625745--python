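"""Age regression by a voting ensemble of bin-shifted classifiers.

The target (integer age over a fixed range [lo, hi]) is discretized into
contiguous bins of width N. N different bin schemes are built by shifting the
bin boundaries one year at a time: scheme 1 starts a full bin at lo; scheme k
(k >= 2) opens with a partial bin [lo, lo+k-2], continues with full width-N
bins, and closes with whatever partial bin reaches hi. With N = 20 over ages
1-80 this yields the schemes

    #1:  1-20, 21-40, 41-60, 61-80
    #2:  1, 2-21, 22-41, 42-61, 62-80
    ...
    #20: 1-19, 20-39, 40-59, 60-79, 80

One classifier is trained per scheme on the same data, its labels being the
bins the training ages fall in. At prediction time each member predicts a
bin, every integer age inside that bin receives one vote, and the age with
the most votes is the point prediction; ties go to the youngest age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .learners import DEFAULT_SEED, LearnerSpec, make_classifier


class Bin(NamedTuple):
    """A contiguous inclusive interval of integer ages."""

    start: int
    end: int

    def __contains__(self, age: object) -> bool:  # type: ignore[override]
        return isinstance(age, (int, np.integer)) and self.start <= age <= self.end

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return str(self.start) if self.start == self.end else f"{self.start}-{self.end}"


class AgeRange(NamedTuple):
    lo: int
    hi: int

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def __str__(self) -> str:
        return f"{self.lo}-{self.hi}"


def _as_range(age_range) -> AgeRange:
    lo, hi = int(age_range[0]), int(age_range[1])
    if lo > hi:
        raise ValueError(f"invalid age range {lo}-{hi}")
    return AgeRange(lo, hi)


@dataclass
class BinScheme:
    """One classifier's ordered partition of the age range into bins."""

    classifier_index: int  # 1-based
    bins: list[Bin]

    def assign(self, age: int) -> Bin:
        """The unique bin containing ``age``."""
        for b in self.bins:
            if b.start <= age <= b.end:
                return b
        raise ValueError(
            f"age {age} outside scheme range "
            f"{self.bins[0].start}-{self.bins[-1].end}"
        )

    def assign_index(self, age: int) -> int:
        for i, b in enumerate(self.bins):
            if b.start <= age <= b.end:
                return i
        raise ValueError(f"age {age} outside scheme range")


def build_bin_schemes(N: int, age_range) -> list[BinScheme]:
    """All N one-year-shifted bin schemes of width ``N`` over ``age_range``."""
    rng = _as_range(age_range)
    span = rng.hi - rng.lo + 1
    if not 1 <= N <= span:
        raise ValueError(f"bin width {N} outside [1, {span}] for range {rng}")
    schemes = []
    for k in range(1, N + 1):
        bins: list[Bin] = []
        if k >= 2:
            bins.append(Bin(rng.lo, rng.lo + k - 2))
            start = rng.lo + k - 1
        else:
            start = rng.lo
        while start <= rng.hi:
            bins.append(Bin(start, min(start + N - 1, rng.hi)))
            start += N
        schemes.append(BinScheme(k, bins))
    return schemes


def assign_bin(age: int, scheme: BinScheme) -> Bin:
    """The bin of ``scheme`` containing integer ``age``."""
    return scheme.assign(int(age))


@dataclass
class VoteTally:
    """Per-integer-age vote counts over an age range."""

    age_range: AgeRange
    counts: np.ndarray  # aligned with age_range.ages

    def votes(self, age: int) -> int:
        if not self.age_range.lo <= age <= self.age_range.hi:
            raise ValueError(f"age {age} outside range {self.age_range}")
        return int(self.counts[age - self.age_range.lo])

    def as_dict(self) -> dict[int, int]:
        return {int(a): int(c) for a, c in zip(self.age_range.ages, self.counts)}

    @property
    def predicted_age(self) -> int:
        """Argmax of the votes; ties break toward the youngest age."""
        return int(self.age_range.lo + int(np.argmax(self.counts)))


def tally_votes(predicted_bins: Sequence[Bin], age_range) -> VoteTally:
    """One vote to every integer age inside each predicted bin."""
    rng = _as_range(age_range)
    counts = np.zeros(rng.hi - rng.lo + 1, dtype=int)
    for b in predicted_bins:
        if b.start < rng.lo or b.end > rng.hi:
            raise ValueError(f"bin {b} outside range {rng}")
        counts[b.start - rng.lo : b.end - rng.lo + 1] += 1
    return VoteTally(rng, counts)


class BinnedVotingAgeRegressor(RegressorMixin, BaseEstimator):
    """Integer-age regressor built from ``bin_width`` bin-shifted classifiers.

    Parameters
    ----------
    bin_width : int, default 32
        Width N of the interior age bins; also the number of ensemble
        members. 32 is the tuned default for presence/absence tables with
        XGBoost members.
    age_range : (int, int), default (1, 80)
        Inclusive integer age range. Must contain every training and
        prediction-target age; it may extend beyond the observed ages.
    base_learner : str or (str, dict), default "xgboost"
        Member classification algorithm (see :mod:`oralage.learners`). One
        shared hyperparameter set serves all members.
    random_state : int, default 8
        Seed passed to members that accept one.

    Attributes
    ----------
    schemes_ : list of BinScheme
    members_ : list of fitted classifiers, one per scheme. Each member is
        trained only on its occupied bins (bins containing at least one
        training sample), so a predicted bin always maps back to a valid
        age interval.
    member_bins_ : list of list of Bin — the occupied bins (class order) of
        each member.
    """

    def __init__(
        self,
        bin_width: int = 32,
        age_range: tuple[int, int] = (1, 80),
        base_learner: LearnerSpec = "xgboost",
        random_state: Optional[int] = DEFAULT_SEED,
    ):
        self.bin_width = bin_width
        self.age_range = age_range
        self.base_learner = base_learner
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y)
        if np.any(y != np.round(y)):
            raise ValueError("ages must be integers")
        y = y.astype(int)
        rng = _as_range(self.age_range)
        if np.any((y < rng.lo) | (y > rng.hi)):
            bad = y[(y < rng.lo) | (y > rng.hi)]
            raise ValueError(
                f"training ages {sorted(set(bad.tolist()))} outside the "
                f"configured age range {rng}; widen the range"
            )
        prototype = make_classifier(self.base_learner, self.random_state)
        self.schemes_ = build_bin_schemes(self.bin_width, rng)
        self.members_ = []
        self.member_bins_ = []
        for scheme in self.schemes_:
            bin_idx = np.array([scheme.assign_index(a) for a in y])
            occupied = sorted(set(bin_idx.tolist()))
            if len(occupied) < 2:
                raise ValueError(
                    f"scheme #{scheme.classifier_index} has a single occupied "
                    "age bin; cannot train a classifier"
                )
            remap = {b: c for c, b in enumerate(occupied)}
            labels = np.array([remap[b] for b in bin_idx])
            member = clone(prototype)
            member.fit(X, labels)
            self.members_.append(member)
            self.member_bins_.append([scheme.bins[b] for b in occupied])
        self.range_ = rng
        self.n_features_in_ = X.shape[1]
        return self

    def _member_bin_predictions(self, X) -> list[list[Bin]]:
        """Per sample, the bin predicted by each member."""
        check_is_fitted(self, "members_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        per_member = [
            [bins[int(c)] for c in member.predict(X)]
            for member, bins in zip(self.members_, self.member_bins_)
        ]
        # transpose to per-sample
        return [list(sample_bins) for sample_bins in zip(*per_member)]

    def predict_tally(self, X) -> list[VoteTally]:
        """Full per-age vote tallies, one per sample."""
        return [
            tally_votes(bins, self.range_) for bins in self._member_bin_predictions(X)
        ]

    def predict(self, X) -> np.ndarray:
        """Point age predictions (integer years)."""
        return np.array([t.predicted_age for t in self.predict_tally(X)])


def predict_age(model: BinnedVotingAgeRegressor, sample_features) -> tuple[int, VoteTally]:
    """Predict one sample's age and return its vote tally alongside."""
    x = np.asarray(sample_features, dtype=float).reshape(1, -1)
    tally = model.predict_tally(x)[0]
    return tally.predicted_age, tally


def fit_ensemble(
    X,
    ages,
    bin_width: int,
    age_range=(1, 80),
    base_learner: LearnerSpec = "xgboost",
    random_state: Optional[int] = DEFAULT_SEED,
) -> BinnedVotingAgeRegressor:
    """Functional wrapper over :class:`BinnedVotingAgeRegressor`."""
    return BinnedVotingAgeRegressor(
        bin_width=bin_width,
        age_range=age_range,
        base_learner=base_learner,
        random_state=random_state,
    ).fit(X, ages)
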