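"""Seeded generator of imbalanced Gaussian streams with abrupt drift.

Emulates the statistical shape of a feature-extracted biomedical
monitoring stream (e.g. EEG-derived seizure detection features): a heavy
minority class, numeric features with class-conditional structure, and
occasional abrupt changes in the minority-class distribution.  Each
instance's label is Bernoulli(positive_rate) and its features are drawn
from an isotropic Gaussian for that label; a drift event replaces the
positive-class mean from the given chunk onward.

Defaults mirror a 100-chunk stream of 1600 instances with 35 features
and a rare positive class; :func:`desk_scale_drift_spec` provides the
small drift fixture used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import yaml

from .stream_core import Chunk, Instance

__all__ = ["StreamSpec", "generate", "desk_scale_drift_spec", "spec_from_yaml"]


@dataclass(frozen=True)
class StreamSpec:
    """Configuration of a synthetic imbalanced stream.

    Parameters
    ----------
    n_chunks, chunk_size, d :
        Stream shape.  Defaults (100 chunks x 1600 instances, 35
        features) match the full-scale stream the method targets.
    positive_rate : float
        Expected per-chunk minority fraction; must be below 0.5 so the
        positive class is the minority by construction.
    negative_mean, positive_mean :
        Class-conditional Gaussian means (length ``d``).  Defaults put
        the negative class at the origin and the positive class at
        Euclidean distance 3 along the diagonal — separable but noisy
        at unit variance.
    negative_scale, positive_scale : float
        Isotropic standard deviations.
    drift_events :
        Sequence of ``(chunk_index, new_positive_mean)`` pairs with
        strictly increasing indices; from each index onward the positive
        class is drawn around the new mean (abrupt mean replacement).
    seed : int
        Full reproducibility: equal specs generate identical streams.
    """

    n_chunks: int = 100
    chunk_size: int = 1600
    d: int = 35
    positive_rate: float = 0.02
    negative_mean: Optional[np.ndarray] = None
    positive_mean: Optional[np.ndarray] = None
    negative_scale: float = 1.0
    positive_scale: float = 1.0
    drift_events: tuple[tuple[int, np.ndarray], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chunks < 1 or self.chunk_size < 1 or self.d < 1:
            raise ValueError("n_chunks, chunk_size and d must be positive")
        if not (0.0 < self.positive_rate < 0.5):
            raise ValueError("positive_rate must be in (0, 0.5)")
        if self.negative_scale <= 0 or self.positive_scale <= 0:
            raise ValueError("class scales must be positive")
        neg = (
            np.zeros(self.d)
            if self.negative_mean is None
            else np.asarray(self.negative_mean, dtype=float)
        )
        pos = (
            default_positive_mean(self.d)
            if self.positive_mean is None
            else np.asarray(self.positive_mean, dtype=float)
        )
        if neg.shape != (self.d,) or pos.shape != (self.d,):
            raise ValueError("class means must have length d")
        object.__setattr__(self, "negative_mean", neg)
        object.__setattr__(self, "positive_mean", pos)

        events = tuple(
            (int(idx), np.asarray(mean, dtype=float))
            for idx, mean in self.drift_events
        )
        indices = [idx for idx, _ in events]
        if indices != sorted(set(indices)):
            raise ValueError("drift event indices must be strictly increasing")
        if any(idx < 0 or idx >= self.n_chunks for idx in indices):
            raise ValueError("drift event indices must lie within the stream")
        if any(mean.shape != (self.d,) for _, mean in events):
            raise ValueError("drift means must have length d")
        object.__setattr__(self, "drift_events", events)


def default_positive_mean(d: int) -> np.ndarray:
    """Positive-class mean at Euclidean distance 3 from the origin."""
    return np.full(d, 3.0 / np.sqrt(d))


def generate(spec: StreamSpec) -> Iterator[Chunk]:
    """Yield the stream's chunks in order, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    drift = dict(
        (idx, mean) for idx, mean in spec.drift_events
    )
    pos_mean = spec.positive_mean
    for t in range(spec.n_chunks):
        if t in drift:
            pos_mean = drift[t]
        labels = rng.random(spec.chunk_size) < spec.positive_rate
        noise = rng.standard_normal((spec.chunk_size, spec.d))
        features = np.where(
            labels[:, None],
            pos_mean + spec.positive_scale * noise,
            spec.negative_mean + spec.negative_scale * noise,
        )
        yield Chunk(
            index=t,
            instances=tuple(
                Instance(
                    features=features[i],
                    label=int(labels[i]),
                    time_moment=t,
                )
                for i in range(spec.chunk_size)
            ),
        )


def desk_scale_drift_spec(seed: int = 0) -> StreamSpec:
    """Small drift fixture: 50 chunks x 200 instances, 2% positive, d=5.

    The feature count is scaled down along with the chunk size so the
    distortion filter keeps its full-scale operating point: a cluster of
    n same-distribution Gaussian positives accepts a fresh candidate
    with probability P((1 + 1/n) chi2_d <= chi2_{d(n-1)} / n), which is
    ~0.44 at the full scale (n ~ 32 positives per 1600-instance chunk,
    d = 35) but collapses to ~0.04 at n ~ 4 with d = 35.  At d = 5 the
    4-positive desk chunks accept at ~0.3, preserving the
    accumulate-then-collapse dynamics the fixture exists to exercise.

    One abrupt drift at the stream midpoint mirrors the positive-class
    mean through the origin.  The mirrored mean sits 6 standard
    deviations from the old one — far outside the old cluster's spread —
    so the distortion filter visibly collapses, and, because the new
    positives are *closer to the negative mean than to the old positive
    mean*, a stale classifier genuinely suffers until it re-adapts.
    """
    d = 5
    pos = default_positive_mean(d)
    return StreamSpec(
        n_chunks=50,
        chunk_size=200,
        d=d,
        positive_rate=0.02,
        drift_events=((25, -pos),),
        seed=seed,
    )


def spec_from_yaml(path: Union[str, Path]) -> StreamSpec:
    """Load a StreamSpec from a YAML (or JSON) mapping.

    Recognised keys mirror the dataclass fields; ``drift_events`` is a
    list of ``[chunk_index, mean_vector]`` pairs, where a scalar mean is
    broadcast across all features.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("stream spec file must contain a mapping")
    d = int(raw.get("d", 35))
    events = []
    for idx, mean in raw.get("drift_events", []):
        mean = np.asarray(mean, dtype=float)
        if mean.ndim == 0:
            mean = np.full(d, float(mean))
        events.append((int(idx), mean))
    kwargs = {
        k: raw[k]
        for k in (
            "n_chunks",
            "chunk_size",
            "positive_rate",
            "negative_scale",
            "positive_scale",
            "seed",
        )
        if k in raw
    }
    for key in ("negative_mean", "positive_mean"):
        if key in raw:
            mean = np.asarray(raw[key], dtype=float)
            if mean.ndim == 0:
                mean = np.full(d, float(mean))
            kwargs[key] = mean
    return StreamSpec(d=d, drift_events=tuple(events), **kwargs)
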