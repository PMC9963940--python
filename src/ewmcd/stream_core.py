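"""Core domain types for chunked binary-labeled streams, plus CSV I/O.

A stream arrives in fixed-size chunks of numeric feature vectors with a
binary label.  The rare (minority) class is the *positive* class and is
always declared explicitly by the caller — it is never inferred from
frequency, because early chunks of a stream may transiently invert the
imbalance.

Instances carry two pieces of provenance that the oversampling models
rely on:

``time_moment``
    The chunk index at which the instance (or, for a synthetic instance,
    its source) originally arrived.  Model B's bypass/filter split is
    driven entirely by this tag.
``is_synthetic``
    Whether the instance was generated by the oversampler rather than
    read from the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Instance",
    "Chunk",
    "AdaptedWindow",
    "read_chunks",
    "write_window",
    "TIME_MOMENT_COLUMN",
    "SYNTHETIC_COLUMN",
]

#: Provenance column names used on CSV output (and recognised on input).
TIME_MOMENT_COLUMN = "__time_moment"
SYNTHETIC_COLUMN = "__synthetic"

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class Instance:
    """One labeled feature vector with provenance tags.

    Parameters
    ----------
    features : numpy.ndarray
        1-D float vector of length ``d`` (the stream's dimensionality).
    label : int
        ``1`` for the rare/positive class, ``0`` for the majority class.
    time_moment : int
        Chunk index of origin.  For a real instance this equals the index
        of the chunk it arrived in; a synthetic instance inherits the tag
        of its source item.
    is_synthetic : bool
        True for oversampler-generated instances (always positive).
    """

    features: np.ndarray
    label: int
    time_moment: int
    is_synthetic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", np.asarray(self.features, dtype=float)
        )
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.time_moment < 0:
            raise ValueError("time_moment must be non-negative")
        if self.is_synthetic and self.label != POSITIVE:
            raise ValueError("synthetic instances must be positive-labeled")

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass(frozen=True)
class Chunk:
    """A raw stream chunk W(T): real instances that arrived at index T."""

    index: int
    instances: tuple[Instance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        for inst in self.instances:
            if inst.is_synthetic:
                raise ValueError("raw chunks contain real instances only")
            if inst.time_moment != self.index:
                raise ValueError(
                    "real instance time_moment must equal its chunk index"
                )

    def __len__(self) -> int:
        return len(self.instances)

    def positives(self) -> tuple[Instance, ...]:
        return tuple(i for i in self.instances if i.is_positive)

    def features_matrix(self) -> np.ndarray:
        return _stack_features(self.instances)

    def labels(self) -> np.ndarray:
        return np.array([i.label for i in self.instances], dtype=int)


@dataclass(frozen=True)
class AdaptedWindow:
    """The oversampled training window Ŵ(T).

    Holds the raw chunk's instances in their original order followed by
    the synthetic instances generated at step T.  Negative instances are
    never modified, removed or synthesized.
    """

    index: int
    instances: tuple[Instance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))

    def __len__(self) -> int:
        return len(self.instances)

    def positives(self) -> tuple[Instance, ...]:
        return tuple(i for i in self.instances if i.is_positive)

    def synthetic_instances(self) -> tuple[Instance, ...]:
        return tuple(i for i in self.instances if i.is_synthetic)

    def real_instances(self) -> tuple[Instance, ...]:
        return tuple(i for i in self.instances if not i.is_synthetic)

    def features_matrix(self) -> np.ndarray:
        return _stack_features(self.instances)

    def labels(self) -> np.ndarray:
        return np.array([i.label for i in self.instances], dtype=int)

    @classmethod
    def from_chunk(cls, chunk: Chunk) -> "AdaptedWindow":
        """Wrap a raw chunk as an adapted window with no synthetics."""
        return cls(index=chunk.index, instances=chunk.instances)


def _stack_features(instances: Sequence[Instance]) -> np.ndarray:
    if not instances:
        return np.empty((0, 0))
    return np.stack([i.features for i in instances])


def read_chunks(
    path: Union[str, Path],
    chunk_size: int,
    label_column: str,
    positive_label: object,
) -> Iterator[Chunk]:
    """Read a header-ed CSV as a sequence of :class:`Chunk` objects.

    All non-label, non-provenance columns are parsed as float features.
    The label column must contain exactly two distinct values, one of
    which is ``positive_label`` (compared after string conversion, so
    ``1`` and ``"1"`` match).  The last chunk may be smaller than
    ``chunk_size``; it is yielded like any other chunk.

    Raises
    ------
    ValueError
        If a feature cell is non-numeric (the error names row and
        column), the label column has more than two distinct values, or
        the declared positive label never occurs alongside exactly one
        other value.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be a positive integer")
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")

    feature_cols = [
        c
        for c in df.columns
        if c not in (label_column, TIME_MOMENT_COLUMN, SYNTHETIC_COLUMN)
    ]
    labels_raw = df[label_column].astype(str)
    distinct = set(labels_raw.unique())
    if len(distinct) > 2:
        raise ValueError(
            f"label column has {len(distinct)} distinct values "
            f"({sorted(distinct)}); exactly two are required"
        )
    pos = str(positive_label)
    if pos not in distinct and len(distinct) == 2:
        raise ValueError(
            f"declared positive label {positive_label!r} not among "
            f"observed labels {sorted(distinct)}"
        )

    features = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        try:
            features[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(
                dtype=float
            )
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna() & df[col].notna()].index[0])
            raise ValueError(
                f"non-numeric feature value in column {col!r}, row {row}"
            ) from None
        if np.isnan(features[:, j]).any():
            row = int(np.flatnonzero(np.isnan(features[:, j]))[0])
            raise ValueError(
                f"missing value in column {col!r}, row {row}; "
                "features must be complete"
            )

    labels = (labels_raw == pos).astype(int).to_numpy()

    for chunk_index, start in enumerate(range(0, len(df), chunk_size)):
        stop = min(start + chunk_size, len(df))
        instances = tuple(
            Instance(
                features=features[i],
                label=int(labels[i]),
                time_moment=chunk_index,
            )
            for i in range(start, stop)
        )
        yield Chunk(index=chunk_index, instances=instances)


def write_window(window: AdaptedWindow, path: Union[str, Path]) -> None:
    """Write an adapted window to CSV with provenance columns.

    Feature columns are named ``f0 .. f{d-1}``; the label column is
    ``label`` (1 = positive) and two provenance columns record each
    instance's ``time_moment`` and synthetic flag.  Reading the file
    back with :func:`read_chunks` round-trips all feature values.
    """
    if len(window) == 0:
        raise ValueError("cannot write an empty window")
    X = window.features_matrix()
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df["label"] = window.labels()
    df[TIME_MOMENT_COLUMN] = [i.time_moment for i in window.instances]
    df[SYNTHETIC_COLUMN] = [int(i.is_synthetic) for i in window.instances]
    df.to_csv(path, index=False, float_format="%.17g")
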