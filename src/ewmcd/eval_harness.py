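"""Prequential (test-then-train) evaluation with imbalance-aware metrics.

Each chunk is first scored with the model as trained on earlier chunks,
then used for training — optionally after adaptation by an oversampling
controller.  The first chunk is train-only, since an untrained model has
no defined predictions.  Six metrics are derived from the confusion
counts: sensitivity (TPR), specificity (TNR), accuracy, precision, F1
and the Matthews correlation coefficient, the last being the most
reliable single number under heavy class imbalance.

By default only *real* instances are scored; synthetic positives enter
training windows but never the confusion counts, because scoring points
the sampler itself created would inflate sensitivity.  Pass
``score_synthetic=True`` to also score the synthetic members of the
previous training window, for compatibility with protocols that test
every element of the adapted window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierAdapter
from .controller import Controller
from .stream_core import Chunk

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "metrics_from_counts",
    "PrequentialResult",
    "prequential_run",
    "repeat_and_average",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts with the rare class as positive."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def update(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        self.tp += int(np.sum((y_true == 1) & (y_pred == 1)))
        self.fp += int(np.sum((y_true == 0) & (y_pred == 1)))
        self.tn += int(np.sum((y_true == 0) & (y_pred == 0)))
        self.fn += int(np.sum((y_true == 1) & (y_pred == 0)))

    def copy(self) -> "ConfusionCounts":
        return ConfusionCounts(self.tp, self.fp, self.tn, self.fn)


@dataclass(frozen=True)
class MetricReport:
    """The six derived metrics for one scope (per-chunk or cumulative)."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    """Standard closed forms; any zero denominator yields metric = 0.

    MCC is the Pearson correlation between the binary prediction and
    truth indicator vectors; its denominator is the geometric mean of
    the four marginal products.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated instances")
    sens = _safe_div(c.tp, c.tp + c.fn)
    spec = _safe_div(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    prec = _safe_div(c.tp, c.tp + c.fp)
    f1 = _safe_div(2 * prec * sens, prec + sens)
    mcc_den = np.sqrt(
        float(c.tp + c.fp)
        * float(c.tp + c.fn)
        * float(c.tn + c.fp)
        * float(c.tn + c.fn)
    )
    mcc = _safe_div(float(c.tp) * c.tn - float(c.fp) * c.fn, mcc_den)
    return MetricReport(sens, spec, acc, prec, f1, mcc)


@dataclass
class PrequentialResult:
    """Outputs of one prequential pass over a stream."""

    per_chunk: list[MetricReport]
    per_chunk_index: list[int]
    cumulative: MetricReport
    counts: ConfusionCounts
    telemetry: Optional[pd.DataFrame]

    def per_chunk_frame(self) -> pd.DataFrame:
        rows = [
            {"chunk_index": idx, **rep.as_dict()}
            for idx, rep in zip(self.per_chunk_index, self.per_chunk)
        ]
        return pd.DataFrame(rows)


def prequential_run(
    stream: Iterable[Chunk],
    classifier: ClassifierAdapter,
    controller: Optional[Controller] = None,
    score_synthetic: bool = False,
) -> PrequentialResult:
    """Test-then-train over a chunked stream.

    For every chunk after the first: (1) predict on the chunk's real
    instances and update the confusion counts; (2) train on the adapted
    window from ``controller`` if one is supplied, otherwise on the raw
    chunk.  The first chunk is train-only, so counts start at the second
    chunk.  With ``score_synthetic=True``, the synthetic instances of
    the *previous* adapted window are scored alongside the current
    chunk's real instances.
    """
    per_chunk: list[MetricReport] = []
    per_chunk_index: list[int] = []
    cumulative = ConfusionCounts()
    prev_window = None
    first = True

    for chunk in stream:
        if not first:
            X = chunk.features_matrix()
            y = chunk.labels()
            if score_synthetic and prev_window is not None:
                synth = prev_window.synthetic_instances()
                if synth:
                    X = np.vstack([X] + [s.features[None, :] for s in synth])
                    y = np.concatenate(
                        [y, np.ones(len(synth), dtype=int)]
                    )
            try:
                y_pred = classifier.predict(X)
            except Exception as exc:  # adapter failures carry chunk context
                raise RuntimeError(
                    f"classifier predict failed at chunk {chunk.index}"
                ) from exc
            chunk_counts = ConfusionCounts()
            chunk_counts.update(y, y_pred)
            cumulative.update(y, y_pred)
            per_chunk.append(metrics_from_counts(chunk_counts))
            per_chunk_index.append(chunk.index)

        if controller is not None:
            window = controller.process_chunk(chunk)
            X_train = window.features_matrix()
            y_train = window.labels()
            prev_window = window
        else:
            X_train = chunk.features_matrix()
            y_train = chunk.labels()
        try:
            classifier.learn(X_train, y_train)
        except Exception as exc:
            raise RuntimeError(
                f"classifier learn failed at chunk {chunk.index}"
            ) from exc
        first = False

    if cumulative.total == 0:
        raise ValueError("stream must contain at least two chunks to score")
    telemetry = controller.telemetry_frame() if controller is not None else None
    return PrequentialResult(
        per_chunk=per_chunk,
        per_chunk_index=per_chunk_index,
        cumulative=metrics_from_counts(cumulative),
        counts=cumulative,
        telemetry=telemetry,
    )


def repeat_and_average(
    seeds: Sequence[int],
    run: Callable[[int], MetricReport],
) -> tuple[MetricReport, list[MetricReport]]:
    """Run once per seed and average each cumulative metric.

    ``run`` maps a seed to a cumulative :class:`MetricReport` (it is
    responsible for seeding every source of randomness in its pipeline).
    Per-run reports are returned alongside the unweighted mean so
    dispersion across repetitions can be inspected.  Duplicate seeds
    trigger a warning rather than an error.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds supplied; runs will repeat exactly")
    reports = [run(int(s)) for s in seeds]
    mean = MetricReport(
        **{
            k: float(np.mean([r.as_dict()[k] for r in reports]))
            for k in reports[0].as_dict()
        }
    )
    return mean, reports
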