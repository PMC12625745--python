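"""Reading, writing, validation and alignment of ASV tables and sample metadata.

The central container is :class:`FeatureTable`, a features x samples matrix
with string identifiers and a declared ``value_kind`` (raw counts, relative
abundances, presence/absence, or a log-scale transform thereof). Downstream
stages check the kind so that, e.g., a CLR transform is never applied to raw
counts by accident.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("count", "relative_abundance", "binarized", "log2", "clr")


class ValidationError(ValueError):
    """A table or metadata file violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed at all."""


@dataclass
class FeatureTable:
    """A features-by-samples numeric matrix with identifiers.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (e.g. ASV ids).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_features, n_samples)
    value_kind : str
        One of ``count``, ``relative_abundance``, ``binarized``, ``log2``,
        ``clr``. Kind-specific invariants are checked on construction.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "count"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in table")
        if self.value_kind == "count":
            if np.any(self.values < 0):
                self._raise_at(self.values < 0, "negative count")
            if np.any(self.values != np.round(self.values)):
                self._raise_at(self.values != np.round(self.values), "non-integer count")
        elif self.value_kind == "binarized":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if np.any(bad):
                self._raise_at(bad, "non-binary entry")
        elif self.value_kind == "relative_abundance":
            sums = self.values.sum(axis=0)
            bad = (np.abs(sums - 1.0) > 1e-9) & (sums != 0.0)
            if np.any(bad):
                j = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"relative-abundance column {self.sample_ids[j]!r} sums to "
                    f"{sums[j]!r}, expected 1"
                )

    def _raise_at(self, mask: np.ndarray, what: str) -> None:
        i, j = (int(x[0]) for x in np.nonzero(mask))
        raise ValidationError(
            f"{what} at feature {self.feature_ids[i]!r}, sample "
            f"{self.sample_ids[j]!r}: {self.values[i, j]!r}"
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_kind: str = "count") -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), value_kind)

    def samples_array(self) -> np.ndarray:
        """Values as an (n_samples, n_features) array for estimator use."""
        return self.values.T.copy()

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return FeatureTable(
            list(self.feature_ids), list(sample_ids), self.values[:, cols], self.value_kind
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return FeatureTable(
            list(feature_ids), list(self.sample_ids), self.values[rows, :], self.value_kind
        )


@dataclass
class SampleMetadata:
    """Per-sample metadata: required integer age, optional sex and covariates."""

    sample_id: str
    age: int
    sex: Optional[str] = None  # "female" / "male" / None (missing or unknown)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"sample {self.sample_id!r}: age must be >= 0")


def _sep_for(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    return "," if fmt == "csv" else "\t"


def read_feature_table(
    path: str | Path,
    format: Optional[str] = None,
    value_kind: str = "count",
    transpose: bool = False,
) -> FeatureTable:
    """Read an ASV table (rows = features, header = sample ids).

    ``format`` is ``tsv``, ``csv`` or ``biom`` (BIOM 2.x HDF5); by default it
    is inferred from the file suffix. ``transpose=True`` handles
    samples-as-rows tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom" or (format is None and path.suffix.lower() == ".biom"):
        return _read_biom(path, value_kind)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, format), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    if transpose:
        df = df.T
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    for col in non_numeric:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValidationError(
            f"{path}: non-numeric entry at feature {bad.index[0]!r}, "
            f"sample {col!r}: {bad.iloc[0]!r}"
        )
    return FeatureTable.from_dataframe(df, value_kind)


def _read_biom(path: Path, value_kind: str = "count") -> FeatureTable:
    """Minimal BIOM 2.x (HDF5) reader: dense reconstruction of the CSR
    observation matrix. Suitable for the table sizes this package targets."""
    import h5py

    with h5py.File(path, "r") as h5:
        try:
            feature_ids = [x.decode() for x in h5["observation/ids"][:]]
            sample_ids = [x.decode() for x in h5["sample/ids"][:]]
            data = h5["observation/matrix/data"][:]
            indices = h5["observation/matrix/indices"][:]
            indptr = h5["observation/matrix/indptr"][:]
        except KeyError as exc:
            raise ParseError(f"{path}: not a BIOM 2.x file ({exc})") from exc
    from scipy.sparse import csr_matrix

    mat = csr_matrix(
        (data, indices, indptr), shape=(len(feature_ids), len(sample_ids))
    ).toarray()
    return FeatureTable(feature_ids, sample_ids, mat, value_kind)


def write_feature_table(table: FeatureTable, path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    df = table.to_dataframe()
    if table.value_kind in ("count", "binarized"):
        df = df.astype(int)
    df.to_csv(path, sep=_sep_for(path, format), index_label="feature_id")


def read_metadata(path: str | Path, format: Optional[str] = None) -> list[SampleMetadata]:
    """Read sample metadata (columns: sample_id, age, optional sex, extras).

    Ages must be integers; non-integer or missing ages are rejected. Sex
    values other than female/male (any case, f/m accepted) are treated as
    missing rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, format), dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("sample_id", "age"):
        if required not in df.columns:
            raise ValidationError(f"{path}: missing required column {required!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    out: list[SampleMetadata] = []
    extra_cols = [c for c in df.columns if c not in ("sample_id", "age", "sex")]
    for _, row in df.iterrows():
        sid = row["sample_id"]
        raw_age = row["age"]
        if pd.isna(raw_age) or str(raw_age).strip() == "":
            raise ValidationError(f"{path}: sample {sid!r}: missing age")
        try:
            age_f = float(raw_age)
        except ValueError as exc:
            raise ValidationError(f"{path}: sample {sid!r}: non-numeric age {raw_age!r}") from exc
        if age_f != int(age_f):
            raise ValidationError(
                f"{path}: sample {sid!r}: age must be an integer, got {raw_age!r}"
            )
        sex = None
        if "sex" in df.columns and not pd.isna(row["sex"]):
            s = str(row["sex"]).strip().lower()
            sex = {"f": "female", "m": "male", "female": "female", "male": "male"}.get(s)
        covs = {c: row[c] for c in extra_cols if not pd.isna(row[c])}
        out.append(SampleMetadata(sid, int(age_f), sex, covs))
    return out


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    rows = [
        {"sample_id": m.sample_id, "age": m.age, "sex": m.sex if m.sex else "", **m.covariates}
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, format), index=False)


def align(
    table: FeatureTable, meta: Sequence[SampleMetadata]
) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Restrict table and metadata to their common samples, in table order.

    Dropped ids are logged as a warning; an empty intersection is an error.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    shared = [s for s in table.sample_ids if s in meta_by_id]
    if not shared:
        raise ValidationError("no samples shared between table and metadata")
    dropped_table = [s for s in table.sample_ids if s not in meta_by_id]
    dropped_meta = [m.sample_id for m in meta if m.sample_id not in set(table.sample_ids)]
    if dropped_table or dropped_meta:
        msg = (
            f"align dropped {len(dropped_table)} table samples {dropped_table} and "
            f"{len(dropped_meta)} metadata samples {dropped_meta}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return table.select_samples(shared), [meta_by_id[s] for s in shared]


def ages_vector(meta: Sequence[SampleMetadata]) -> np.ndarray:
    return np.array([m.age for m in meta], dtype=int)
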