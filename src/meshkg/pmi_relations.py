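"""Pointwise-mutual-information relation mining over MeSH co-occurrence.

For two keywords x and y with document counts N(x), N(y), pair count
N(x,y) and corpus size R,

    PMI(x, y) = log2( N(x,y) * R / (N(x) * N(y)) )      if N(x,y) > 0
    PMI(x, y) = -10  (sentinel)                          if N(x,y) = 0

in bits, with no smoothing. The sentinel marks pairs never co-mentioned in
the corpus and is excluded from threshold calibration and histograms — on
a sparse corpus it would otherwise dominate the mode.

The support threshold tau is calibrated as the mode of the floor-rounded
PMI values of an existing, trusted relation set; a relation is *supported*
iff its PMI >= tau (boundary inclusive). Candidate discovery returns
supported keyword pairs absent (in either orientation) from the existing
edge set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .publications import CorpusIndex

__all__ = [
    "PMI_SENTINEL",
    "CooccurrenceRecord",
    "PmiValue",
    "ThresholdCalibration",
    "SUPPORTED",
    "BELOW_THRESHOLD",
    "MISSING_IN_CORPUS",
    "pmi",
    "pmi_from_index",
    "floor_round",
    "calibrate_threshold",
    "classify_support",
    "discover_candidates",
    "floor_histogram_report",
]

#: Sentinel PMI assigned to pairs with zero co-occurrence.
PMI_SENTINEL = -10.0

MISSING_IN_CORPUS = "missing_in_corpus"
BELOW_THRESHOLD = "below_threshold"
SUPPORTED = "supported"


@dataclass(frozen=True)
class CooccurrenceRecord:
    """The counts feeding one PMI evaluation."""

    x: str
    y: str
    n_x: int
    n_y: int
    n_xy: int
    corpus_size: int

    def __post_init__(self) -> None:
        if self.corpus_size < 1:
            raise ValueError("corpus_size must be >= 1")
        if min(self.n_x, self.n_y, self.n_xy) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_xy > min(self.n_x, self.n_y):
            raise ValueError("N(x,y) cannot exceed min(N(x), N(y))")
        if max(self.n_x, self.n_y) > self.corpus_size:
            raise ValueError("marginal counts cannot exceed corpus size")


@dataclass(frozen=True)
class PmiValue:
    """A PMI in bits; ``is_sentinel`` marks the zero-co-occurrence case."""

    value: float
    is_sentinel: bool

    def __float__(self) -> float:
        return self.value


def pmi(record: CooccurrenceRecord) -> PmiValue:
    """Pointwise mutual information of one keyword pair, in bits."""
    if record.n_xy == 0:
        return PmiValue(PMI_SENTINEL, True)
    if record.n_x == 0 or record.n_y == 0:
        raise ValueError("N(x,y) > 0 requires positive marginal counts")
    value = (
        math.log2(record.n_xy)
        + math.log2(record.corpus_size)
        - math.log2(record.n_x)
        - math.log2(record.n_y)
    )
    return PmiValue(value, False)


def pmi_from_index(index: CorpusIndex, x: str, y: str) -> PmiValue:
    """PMI of a descriptor pair from exact corpus document counts."""
    record = CooccurrenceRecord(
        x=x,
        y=y,
        n_x=index.count(x),
        n_y=index.count(y),
        n_xy=index.pair_count(x, y),
        corpus_size=index.n_documents,
    )
    return pmi(record)


def floor_round(value: float) -> int:
    """Round down to the nearest whole number (floor(-0.2) == -1)."""
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    return math.floor(value)


@dataclass(frozen=True)
class ThresholdCalibration:
    """The floor-value histogram of a trusted relation set and its mode."""

    floor_histogram: Mapping[int, int]
    threshold: int


def floor_histogram_report(pmi_values: Iterable[PmiValue]) -> dict[int, int]:
    """Histogram of floor-rounded PMI values, sentinels excluded."""
    hist: Counter[int] = Counter(
        floor_round(v.value) for v in pmi_values if not v.is_sentinel
    )
    return dict(hist)


def calibrate_threshold(pmi_values: Sequence[PmiValue]) -> ThresholdCalibration:
    """Set the support threshold to the mode of the floored PMI values.

    Sentinels are excluded first; ties break toward the smallest integer.
    Raises if every value is the sentinel.
    """
    hist = floor_histogram_report(pmi_values)
    if not hist:
        raise ValueError("cannot calibrate: all PMI values are sentinels")
    threshold = min(
        hist, key=lambda k: (-hist[k], k)
    )  # max count, then smallest floor
    return ThresholdCalibration(floor_histogram=hist, threshold=threshold)


def classify_support(pmi_value: PmiValue, threshold: int) -> str:
    """Support status of one relation against an integer threshold."""
    if pmi_value.is_sentinel:
        return MISSING_IN_CORPUS
    if pmi_value.value >= threshold:
        return SUPPORTED
    return BELOW_THRESHOLD


def _unordered(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def discover_candidates(
    pair_records: Sequence[CooccurrenceRecord],
    threshold: int,
    existing_edges: Iterable[tuple[str, str]],
) -> list[tuple[tuple[str, str], PmiValue]]:
    """Supported keyword pairs not yet present in the edge set.

    Pairs are unordered: a record (a, b) is excluded if either (a, b) or
    (b, a) is an existing edge. Output is lexicographic on the pair.
    """
    existing = {_unordered(e) for e in existing_edges}
    out = []
    for rec in pair_records:
        key = _unordered((rec.x, rec.y))
        if key in existing:
            continue
        value = pmi(rec)
        if classify_support(value, threshold) == SUPPORTED:
            out.append((key, value))
    out.sort(key=lambda item: item[0])
    return out


def pmi_table(
    records: Sequence[CooccurrenceRecord], threshold: int | None = None
) -> pd.DataFrame:
    """Per-relation PMI table (x, y, counts, pmi, floor, status)."""
    rows = []
    for rec in records:
        v = pmi(rec)
        row = {
            "x": rec.x,
            "y": rec.y,
            "n_x": rec.n_x,
            "n_y": rec.n_y,
            "n_xy": rec.n_xy,
            "corpus_size": rec.corpus_size,
            "pmi": v.value,
            "floor": None if v.is_sentinel else floor_round(v.value),
        }
        if threshold is not None:
            row["status"] = classify_support(v, threshold)
        rows.append(row)
    return pd.DataFrame(rows)
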