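"""Accuracy metrics for age prediction: MAD, per-locus Pearson r, R².

MAD (mean absolute deviation) is the mean of |predicted − chronological| in
years, reported overall and within age strata (23–30, 31–40, 41–50, 51–60,
61–70 by default, inclusive endpoints). R² is the squared Pearson correlation
between predicted and chronological age — the R² of the fitted line in a
predicted-vs-chronological scatter, which can exceed the training value on a
test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .loci import LOCUS_ORDER
from .model import Cohort

Bin = Tuple[int, int]

#: Ages falling in no bin are accumulated under this key.
OTHER_BIN = "other"


class PairingError(ValueError):
    """Predicted and chronological vectors cannot be paired."""


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (empty, or zero variance)."""


@dataclass(frozen=True)
class AgeBinScheme:
    """Ordered, non-overlapping integer age strata with inclusive endpoints."""

    bins: Tuple[Bin, ...] = ((23, 30), (31, 40), (41, 50), (51, 60), (61, 70))

    def __post_init__(self) -> None:
        last_hi = -np.inf
        for lo, hi in self.bins:
            if lo > hi:
                raise ValueError(f"bin ({lo}, {hi}) has min > max")
            if lo <= last_hi:
                raise ValueError("bins must be ascending and non-overlapping")
            last_hi = hi

    def assign(self, age: float) -> Union[Bin, str]:
        for lo, hi in self.bins:
            if lo <= age <= hi:
                return (lo, hi)
        return OTHER_BIN


DEFAULT_BINS = AgeBinScheme()


@dataclass(frozen=True)
class BinStat:
    mad: Optional[float]
    n: int


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    mad_overall: float
    mad_by_bin: Mapping[Union[Bin, str], BinStat]
    pearson_by_locus: Mapping[str, Optional[float]]
    r_squared: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mad_overall": self.mad_overall,
            "mad_by_bin": {
                (f"{k[0]}-{k[1]}" if isinstance(k, tuple) else k): {
                    "mad": v.mad,
                    "n": v.n,
                }
                for k, v in self.mad_by_bin.items()
            },
            "pearson_by_locus": dict(self.pearson_by_locus),
            "r_squared": self.r_squared,
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _paired(predicted: Sequence[float], chronological: Sequence[float]):
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if pred.shape != chron.shape or pred.ndim != 1:
        raise PairingError(
            f"predicted and chronological must be equal-length vectors, "
            f"got shapes {pred.shape} and {chron.shape}"
        )
    if pred.size == 0:
        raise UndefinedMetricError("metric undefined on empty input")
    return pred, chron


def mad(predicted: Sequence[float], chronological: Sequence[float]) -> float:
    """Mean absolute deviation |predicted − chronological| in years."""
    pred, chron = _paired(predicted, chronological)
    return float(np.mean(np.abs(pred - chron)))


def mad_by_age_group(
    predicted: Sequence[float],
    chronological: Sequence[float],
    scheme: AgeBinScheme = DEFAULT_BINS,
) -> Dict[Union[Bin, str], BinStat]:
    """Per-stratum MAD, binned on chronological age (inclusive endpoints).

    Every bin in the scheme appears in the result; an empty bin carries
    ``mad=None, n=0``. Ages outside all bins are pooled under ``OTHER_BIN``
    (present only when non-empty).
    """
    pred, chron = _paired(predicted, chronological)
    buckets: Dict[Union[Bin, str], list] = {b: [] for b in scheme.bins}
    for p, c in zip(pred, chron):
        buckets.setdefault(scheme.assign(c), []).append(abs(p - c))
    result: Dict[Union[Bin, str], BinStat] = {}
    for key, devs in buckets.items():
        if key == OTHER_BIN and not devs:
            continue
        result[key] = BinStat(
            mad=float(np.mean(devs)) if devs else None, n=len(devs)
        )
    return result


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; raises on <3 points or zero variance."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise PairingError("vectors must have equal length")
    if xv.size < 3:
        raise UndefinedMetricError("correlation needs at least 3 points")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise UndefinedMetricError("correlation undefined for zero variance")
    r, _ = stats.pearsonr(xv, yv)
    if np.isnan(r):
        raise UndefinedMetricError("correlation undefined (degenerate input)")
    return float(r)


def pearson_per_locus(
    cohort: Cohort,
    loci: Sequence[str] = LOCUS_ORDER,
) -> Dict[str, Optional[float]]:
    """Pearson r of methylation level vs chronological age per locus.

    A locus with fewer than 3 present measurements or zero variance maps to
    ``None`` (undefined correlation).
    """
    result: Dict[str, Optional[float]] = {}
    for locus in loci:
        pairs = [
            (s.profile.level(locus), s.age_years)
            for s in cohort
            if s.profile.level(locus) is not None
        ]
        try:
            result[locus] = pearson([p[0] for p in pairs], [p[1] for p in pairs])
        except UndefinedMetricError:
            result[locus] = None
    return result


def r_squared(predicted: Sequence[float], chronological: Sequence[float]) -> float:
    """Squared Pearson correlation between predicted and chronological age."""
    return pearson(predicted, chronological) ** 2


def evaluate_predictions(
    predictions: pd.DataFrame,
    cohort: Optional[Cohort] = None,
    scheme: AgeBinScheme = DEFAULT_BINS,
) -> EvaluationReport:
    """Full evaluation of a prediction table.

    ``predictions`` needs columns ``age_years`` and ``predicted_age_years``
    (as produced by :func:`snapage.model.predict_cohort`). If a cohort is
    supplied, per-locus level-vs-age correlations are included.
    """
    pred = predictions["predicted_age_years"].to_numpy(dtype=float)
    chron = predictions["age_years"].to_numpy(dtype=float)
    try:
        r2: Optional[float] = r_squared(pred, chron)
    except UndefinedMetricError:
        r2 = None
    return EvaluationReport(
        n=len(pred),
        mad_overall=mad(pred, chron),
        mad_by_bin=mad_by_age_group(pred, chron, scheme),
        pearson_by_locus=pearson_per_locus(cohort) if cohort is not None else {},
        r_squared=r2,
    )


def locus_scatter_frame(cohort: Cohort, loci: Sequence[str] = LOCUS_ORDER) -> pd.DataFrame:
    """Tidy ``sample_id, age_years, locus, level`` table for scatterplots."""
    rows = []
    for s in cohort:
        for locus in loci:
            level = s.profile.level(locus)
            if level is not None:
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "age_years": s.age_years,
                        "locus": locus,
                        "level": level,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "age_years", "locus", "level"])
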