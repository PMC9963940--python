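"""Stage 2: SMOTE-style synthesis from the MCD itemset.

Each admitted item ``x`` yields exactly one synthetic point

    x_hat = x + (CW(T) - x) * RV

where ``RV`` is a vector of independent uniform draws (one per feature)
from a configurable sub-range of [0, 1].  With the default range [0, 1]
every synthetic coordinate is a convex combination of the source item
and the cluster centroid, so the point lies in the axis-aligned box
spanned by the two — the same segment-interpolation idea as classic
SMOTE, but paired with the centroid instead of a nearest neighbour.

Only the synthetic offspring are merged into the adapted window; the
real source items themselves are not copied forward.  Synthetic
instances inherit the ``time_moment`` of their source, which is what
lets provenance ages deeper than one chunk propagate through model B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcd_selection import MCDItemset
from .stream_core import AdaptedWindow, Chunk, Instance, POSITIVE

__all__ = ["RVRange", "random_vector", "synthesize_point", "oversample"]


@dataclass(frozen=True)
class RVRange:
    """Closed sub-range of [0, 1] for the random interpolation vector.

    The default [0, 1] matches original SMOTE.  [0, 0.5] keeps synthetic
    coordinates in the half of the segment adjacent to the source item;
    [0.5, 1] keeps them adjacent to the centroid.
    """

    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(
                f"require 0 <= lo < hi <= 1, got [{self.lo}, {self.hi}]"
            )


def random_vector(
    d: int, rv_range: RVRange, rng: np.random.Generator
) -> np.ndarray:
    """Vector of ``d`` independent uniform draws in [lo, hi]."""
    if d < 1:
        raise ValueError("d must be a positive integer")
    return rng.uniform(rv_range.lo, rv_range.hi, size=d)


def synthesize_point(
    x: Instance, centroid: np.ndarray, rv: np.ndarray
) -> Instance:
    """Interpolate one synthetic positive between ``x`` and the centroid.

    Features are ``x + (centroid - x) * rv`` element-wise; the result is
    positive-labeled, flagged synthetic, and inherits the source's
    ``time_moment``.
    """
    centroid = np.asarray(centroid, dtype=float)
    rv = np.asarray(rv, dtype=float)
    if centroid.shape != x.features.shape or rv.shape != x.features.shape:
        raise ValueError("x, centroid and rv must share dimensionality")
    dv = centroid - x.features
    return Instance(
        features=x.features + dv * rv,
        label=POSITIVE,
        time_moment=x.time_moment,
        is_synthetic=True,
    )


def oversample(
    chunk: Chunk,
    itemset: MCDItemset,
    centroid: np.ndarray | None,
    rv_range: RVRange,
    rng: np.random.Generator,
) -> AdaptedWindow:
    """Build the adapted window Ŵ(T) = W(T) followed by SYNTH(T).

    Exactly one synthetic instance is generated per itemset item, in
    itemset order (one RV draw each, so runs are reproducible under a
    seeded ``rng``).  The chunk's own instances are passed through
    unmodified; an empty itemset yields a window identical to the chunk.
    """
    if len(itemset) == 0:
        return AdaptedWindow.from_chunk(chunk)
    if centroid is None:
        raise ValueError("a centroid is required when the itemset is non-empty")
    centroid = np.asarray(centroid, dtype=float)
    d = centroid.shape[0]
    synth = tuple(
        synthesize_point(x, centroid, random_vector(d, rv_range, rng))
        for x in itemset.items
    )
    return AdaptedWindow(index=chunk.index, instances=chunk.instances + synth)
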