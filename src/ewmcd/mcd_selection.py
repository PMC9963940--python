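"""Stage 1: select the elementary MCD itemset from the previous window.

Both model variants scan the positive instances of the previous
*adapted* window Ŵ(T−1) — raw positives plus the synthetic positives
generated there, so provenance tags older than T−1 can flow forward —
and admit a subset as sources for synthesis:

* **Model A** builds the virtual cluster VC(T) from the current chunk's
  positives only and admits a previous positive iff the distortion test
  passes (its squared distance to CW(T) is at most the cluster MSE).

* **Model B** relaxes the filter for the freshest items: previous
  positives whose ``time_moment`` equals T−1 bypass the test entirely
  and are folded into VC(T) *before* the centroid and MSE are computed;
  only the older items (time moments T−2 … T−z) are filtered.  The
  rationale is that last-chunk items were themselves selected against
  a centroid one step ago, so re-filtering them against a centroid they
  helped define would be circular, while admitting them keeps the
  centroid anchored to the recent past.

Both selectors are pure functions of their inputs: stage 1 involves no
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .distortion import VirtualCluster, accepts
from .stream_core import AdaptedWindow, Chunk, Instance

__all__ = ["MCDItemset", "extract_positives", "select_mcd_a", "select_mcd_b"]


@dataclass(frozen=True)
class MCDItemset:
    """Previous-window positives admitted as synthesis sources.

    ``bypass_count`` counts items admitted without filtering (model B's
    last-chunk items; always 0 under model A); ``filtered_count`` counts
    items admitted by the distortion test.
    """

    items: tuple[Instance, ...]
    bypass_count: int = 0
    filtered_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if any(not i.is_positive for i in self.items):
            raise ValueError("MCD items must be positive-labeled")
        if self.bypass_count + self.filtered_count != len(self.items):
            raise ValueError("bypass_count + filtered_count must equal size")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def empty(cls) -> "MCDItemset":
        return cls(items=(), bypass_count=0, filtered_count=0)


SelectionResult = tuple[
    MCDItemset, Optional[np.ndarray], Optional[VirtualCluster]
]


def extract_positives(window: Chunk | AdaptedWindow) -> tuple[Instance, ...]:
    """All and only the positive-labeled instances, order preserved."""
    return tuple(i for i in window.instances if i.is_positive)


def _check_indices(current: Chunk, previous: AdaptedWindow) -> None:
    if current.index != previous.index + 1:
        raise ValueError(
            f"current chunk index {current.index} must follow previous "
            f"window index {previous.index}"
        )


def select_mcd_a(current: Chunk, previous: AdaptedWindow) -> SelectionResult:
    """Model A selection: every previous positive faces the filter.

    Returns ``(itemset, centroid, cluster)``.  If either the previous
    window or the current chunk has no positives, oversampling is
    skipped for this step: the itemset is empty and centroid/cluster are
    ``None`` (a centroid of an empty point set is undefined).
    """
    _check_indices(current, previous)
    prev_pos = extract_positives(previous)
    cur_pos = current.positives()
    if not prev_pos or not cur_pos:
        return MCDItemset.empty(), None, None

    cluster = VirtualCluster.from_points(
        np.stack([p.features for p in cur_pos])
    )
    items = tuple(x for x in prev_pos if accepts(x.features, cluster))
    itemset = MCDItemset(items=items, bypass_count=0, filtered_count=len(items))
    return itemset, cluster.centroid, cluster


def select_mcd_b(current: Chunk, previous: AdaptedWindow) -> SelectionResult:
    """Model B selection: last-chunk items bypass, older items are filtered.

    Previous-window positives with ``time_moment == previous.index`` are
    admitted unconditionally and joined with the current positives to
    form VC(T) before the centroid and MSE are computed; positives with
    older time moments are then screened by the distortion test against
    that cluster.  The returned itemset preserves previous-window order
    (bypass and filtered items interleaved as they appeared).

    If the current chunk has no positives, the bypass items alone can
    still seed VC(T); when both are empty, oversampling is skipped.
    """
    _check_indices(current, previous)
    prev_pos = extract_positives(previous)
    cur_pos = current.positives()

    last_chunk = [x for x in prev_pos if x.time_moment == previous.index]
    vc_members = [p.features for p in cur_pos] + [
        x.features for x in last_chunk
    ]
    if not prev_pos or not vc_members:
        return MCDItemset.empty(), None, None

    cluster = VirtualCluster.from_points(np.stack(vc_members))

    items: list[Instance] = []
    n_bypass = 0
    n_filtered = 0
    for x in prev_pos:
        if x.time_moment == previous.index:
            items.append(x)
            n_bypass += 1
        elif accepts(x.features, cluster):
            items.append(x)
            n_filtered += 1
    itemset = MCDItemset(
        items=tuple(items), bypass_count=n_bypass, filtered_count=n_filtered
    )
    return itemset, cluster.centroid, cluster
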