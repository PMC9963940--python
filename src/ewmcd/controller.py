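"""Per-chunk orchestration of the EWMCD models, with window telemetry.

The controller is the stateful wrapper a stream pipeline talks to: feed
it chunks in order and it returns the adapted training window for each,
remembering the previous adapted window between calls.  It takes *no*
window-size or age-cutoff parameter — the itemset size is determined
entirely by the data through the distortion criterion, which is the
method's self-adjusting property.

The controller never undersamples the majority class, and it places no
cap on how many positives accumulate; it records the positive fraction
in telemetry and logs a warning once positives dominate (> 50% of the
adapted window), but does not intervene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mcd_selection import select_mcd_a, select_mcd_b
from .oversampler import RVRange, oversample
from .stream_core import AdaptedWindow, Chunk

__all__ = ["Variant", "TelemetryRecord", "Controller"]

logger = logging.getLogger(__name__)


class Variant(str, Enum):
    """Which selection rule stage 1 applies."""

    EWMCD_A = "A"
    EWMCD_B = "B"


@dataclass(frozen=True)
class TelemetryRecord:
    """Per-chunk window diagnostics (the drift-tracking signal).

    ``max_age`` is the largest provenance age T − time_moment observed
    in the adapted window; it exceeds 1 only when old items survive
    re-acceptance chains (model A) or the bypass/filter split (model B).
    """

    chunk_index: int
    n_instances: int
    n_positives: int
    mcd_size: int
    bypass_count: int
    filtered_count: int
    n_synthetic: int
    window_size: int
    positive_fraction: float
    max_age: int
    mse: Optional[float]
    centroid: Optional[np.ndarray]


class Controller:
    """Stateful per-chunk driver for one model variant.

    Parameters
    ----------
    variant : Variant or str
        ``"A"`` (strict filter) or ``"B"`` (last-chunk bypass).
    rv_range : RVRange
        Interpolation range for the random vector; default [0, 1].
    seed : int
        Seeds the single RNG stream used for all RV draws in this run.
    """

    def __init__(
        self,
        variant: Variant | str = Variant.EWMCD_A,
        rv_range: RVRange | None = None,
        seed: int = 0,
    ) -> None:
        self.variant = Variant(variant)
        self.rv_range = rv_range if rv_range is not None else RVRange()
        self.rng = np.random.default_rng(seed)
        self.previous_window: Optional[AdaptedWindow] = None
        self.telemetry: list[TelemetryRecord] = []
        self._next_index: Optional[int] = None

    def process_chunk(self, chunk: Chunk) -> AdaptedWindow:
        """Select, synthesize, and return the adapted window for one chunk.

        Chunks must arrive in consecutive index order.  The first chunk
        is a cold start: with no previous window there is nothing to
        select from, so the adapted window equals the chunk.
        """
        if self._next_index is not None and chunk.index != self._next_index:
            raise ValueError(
                f"out-of-order chunk: expected index {self._next_index}, "
                f"got {chunk.index}"
            )

        if self.previous_window is None:
            window = AdaptedWindow.from_chunk(chunk)
            itemset_size = bypass = filtered = 0
            cluster_mse = None
            centroid = None
        else:
            select = (
                select_mcd_a if self.variant is Variant.EWMCD_A else select_mcd_b
            )
            itemset, centroid, cluster = select(chunk, self.previous_window)
            window = oversample(
                chunk, itemset, centroid, self.rv_range, self.rng
            )
            itemset_size = len(itemset)
            bypass = itemset.bypass_count
            filtered = itemset.filtered_count
            cluster_mse = cluster.mse if cluster is not None else None

        n_pos = sum(1 for i in window.instances if i.is_positive)
        pos_frac = n_pos / len(window) if len(window) else 0.0
        if pos_frac > 0.5:
            logger.warning(
                "chunk %d: positives are %.1f%% of the adapted window "
                "(rare class now dominates)",
                chunk.index,
                100 * pos_frac,
            )
        max_age = max(
            (chunk.index - i.time_moment for i in window.instances), default=0
        )
        self.telemetry.append(
            TelemetryRecord(
                chunk_index=chunk.index,
                n_instances=len(chunk),
                n_positives=len(chunk.positives()),
                mcd_size=itemset_size,
                bypass_count=bypass,
                filtered_count=filtered,
                n_synthetic=len(window) - len(chunk),
                window_size=len(window),
                positive_fraction=pos_frac,
                max_age=max_age,
                mse=cluster_mse,
                centroid=centroid,
            )
        )
        self.previous_window = window
        self._next_index = chunk.index + 1
        return window

    def telemetry_frame(self, normalize_centroid: bool = False) -> pd.DataFrame:
        """Telemetry as a DataFrame, one row per processed chunk.

        Centroid coordinates appear as ``centroid_0 .. centroid_{d-1}``
        (NaN for chunks where no cluster was formed).  With
        ``normalize_centroid=True`` each centroid feature is min-max
        scaled over the run, the form used for drift-tracking plots.
        """
        rows = []
        d = next(
            (r.centroid.shape[0] for r in self.telemetry if r.centroid is not None),
            0,
        )
        for r in self.telemetry:
            row = {
                "chunk_index": r.chunk_index,
                "n_instances": r.n_instances,
                "n_positives": r.n_positives,
                "mcd_size": r.mcd_size,
                "bypass_count": r.bypass_count,
                "filtered_count": r.filtered_count,
                "n_synthetic": r.n_synthetic,
                "window_size": r.window_size,
                "positive_fraction": r.positive_fraction,
                "max_age": r.max_age,
                "mse": np.nan if r.mse is None else r.mse,
            }
            for j in range(d):
                row[f"centroid_{j}"] = (
                    np.nan if r.centroid is None else r.centroid[j]
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        if normalize_centroid and d:
            for j in range(d):
                col = df[f"centroid_{j}"]
                span = col.max() - col.min()
                df[f"centroid_{j}"] = (
                    (col - col.min()) / span if span > 0 else 0.0
                )
        return df

    def write_telemetry(
        self, path: Union[str, Path], normalize_centroid: bool = False
    ) -> None:
        self.telemetry_frame(normalize_centroid).to_csv(
            path, index=False, float_format="%.17g"
        )
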