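"""Auto/cross-covariance (ACC) featurization of descriptor-encoded sequences.

ACC converts a variable-length n x 5 descriptor matrix into a fixed-length
vector of lagged products, so sequences of any length become comparable
inputs for ordinary classifiers.  For descriptor pair (j, k) and lag l the
default ("uncentered") dialect computes

    AC_jkl = 1/(n - l) * sum_{i=1..n-l} E[j, i] * E[k, i + l]

with j == k the auto-covariance terms and j != k the cross-covariance
terms.  With lags l = 1..L there are 25*L features (125 at the default
L = 5), named ``AC{j}{k}{l}`` and ordered lexicographically in (j, k, l).
Two alternative normalization dialects are exposed for sensitivity
analysis: "uncentered_n" divides by n instead of n - l, and "centered"
subtracts each descriptor's sequence mean before forming the products.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import EDescriptorTable, EncodedSequence, N_DESCRIPTORS, encode_sequence
from .io import SequenceDataset

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 5
ACC_DIALECTS = ("uncentered", "uncentered_n", "centered")
SHORT_SEQUENCE_POLICIES = ("error", "drop")


class ShortSequenceError(ValueError):
    """A sequence is too short for the requested maximum lag."""


@dataclass(frozen=True)
class ACCFeatureVector:
    """The fixed-length ACC feature vector of one sequence."""

    record_id: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names must be parallel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite ACC features for record {self.record_id!r}")


@dataclass
class FeatureMatrix:
    """Row-per-sequence ACC features with optional parallel class labels."""

    values: np.ndarray
    ids: list[str]
    feature_names: tuple[str, ...]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        m, d = self.values.shape
        if len(self.ids) != m:
            raise ValueError("ids must parallel rows")
        if d != len(self.feature_names):
            raise ValueError("feature_names must parallel columns")
        if self.labels is not None and len(self.labels) != m:
            raise ValueError("labels must parallel rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[indices],
            ids=[self.ids[i] for i in indices],
            feature_names=self.feature_names,
            labels=None if self.labels is None else [self.labels[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame.insert(0, "id", self.ids)
        if self.labels is not None:
            frame.insert(1, "label", self.labels)
        return frame

    def to_tsv(self, path: str | os.PathLike) -> None:
        # repr-precision floats so the round-trip is bit-exact
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if "id" not in frame.columns:
            raise ValueError(f"{path}: missing 'id' column")
        labels = frame["label"].astype(str).tolist() if "label" in frame.columns else None
        feature_cols = [c for c in frame.columns if c not in ("id", "label")]
        return cls(
            values=frame[feature_cols].to_numpy(dtype=float),
            ids=frame["id"].astype(str).tolist(),
            feature_names=tuple(feature_cols),
            labels=labels,
        )


def feature_names(max_lag: int = DEFAULT_MAX_LAG) -> tuple[str, ...]:
    """Canonical ``AC{j}{k}{l}`` names, lexicographic in (j, k, l)."""
    if max_lag < 1:
        raise ValueError(f"max_lag must be >= 1, got {max_lag}")
    return tuple(
        f"AC{j}{k}{l}"
        for j in range(1, N_DESCRIPTORS + 1)
        for k in range(1, N_DESCRIPTORS + 1)
        for l in range(1, max_lag + 1)
    )


def acc_transform(encoded: EncodedSequence, max_lag: int = DEFAULT_MAX_LAG,
                  dialect: str = "uncentered") -> ACCFeatureVector:
    """Transform one encoded sequence into its 25*max_lag ACC feature vector."""
    if max_lag < 1:
        raise ValueError(f"max_lag must be >= 1, got {max_lag}")
    if dialect not in ACC_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {ACC_DIALECTS}")
    E = encoded.matrix
    n = E.shape[0]
    if n < max_lag + 1:
        raise ShortSequenceError(
            f"record {encoded.record_id!r} has length {n}; "
            f"ACC at max_lag={max_lag} needs at least {max_lag + 1} residues"
        )
    if dialect == "centered":
        E = E - E.mean(axis=0, keepdims=True)
    # blocks[l-1][j-1, k-1] = sum_i E[j,i] E[k,i+l] / norm
    blocks = np.empty((max_lag, N_DESCRIPTORS, N_DESCRIPTORS))
    for lag in range(1, max_lag + 1):
        norm = n if dialect == "uncentered_n" else n - lag
        blocks[lag - 1] = (E[:-lag].T @ E[lag:]) / norm
    # reorder to lexicographic (j, k, l)
    values = blocks.transpose(1, 2, 0).reshape(-1)
    return ACCFeatureVector(
        record_id=encoded.record_id,
        values=values,
        names=feature_names(max_lag),
    )


def featurize_dataset(dataset: SequenceDataset, table: EDescriptorTable,
                      max_lag: int = DEFAULT_MAX_LAG, dialect: str = "uncentered",
                      short_policy: str = "error") -> FeatureMatrix:
    """ACC-featurize every record, one row per surviving sequence in input order.

    Records shorter than max_lag + 1 either abort ("error", default) or are
    dropped with a warning ("drop"), with labels realigned to the survivors.
    """
    if short_policy not in SHORT_SEQUENCE_POLICIES:
        raise ValueError(
            f"unknown short-sequence policy {short_policy!r}; "
            f"choose from {SHORT_SEQUENCE_POLICIES}"
        )
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] | None = [] if dataset.labels is not None else None
    names = feature_names(max_lag)
    for idx, record in enumerate(dataset.records):
        try:
            vec = acc_transform(encode_sequence(record, table), max_lag=max_lag,
                                dialect=dialect)
        except ShortSequenceError:
            if short_policy == "error":
                raise
            logger.warning(
                "record %r dropped: length %d < required %d",
                record.id, record.length, max_lag + 1,
            )
            continue
        rows.append(vec.values)
        ids.append(record.id)
        if labels is not None:
            labels.append(dataset.labels[idx])
    if not rows:
        raise ShortSequenceError(
            f"all {len(dataset)} records are shorter than max_lag + 1 = {max_lag + 1}"
        )
    return FeatureMatrix(values=np.vstack(rows), ids=ids, feature_names=names,
                         labels=labels)
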