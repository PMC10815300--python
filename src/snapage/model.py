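"""Multivariate linear age models over five-locus methylation profiles.

An age model is an intercept plus one coefficient (years per unit methylation)
per locus, applied to a replicate-averaged profile:

    predicted age = b0 + sum_l  b_l * level_l

The published buccal-swab model trained on 30 volunteers ships as a built-in
(:func:`published_model`); new models are fitted by ordinary least squares on
a training cohort. Predictions are returned unclamped — implausible outputs
(negative, or far above the human range) are the caller's signal that the
model does not fit the material, so they must not be hidden.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .loci import LOCUS_ORDER
from .quantify import MethylationProfile

logger = logging.getLogger(__name__)


class MissingPredictorError(ValueError):
    """A profile lacks a locus the model needs."""


class InsufficientDataError(ValueError):
    """Too few complete samples to fit the model."""


class SingularFitError(ValueError):
    """The design matrix is rank-deficient."""


@dataclass(frozen=True)
class AgeModel:
    """Linear age model: intercept (years) + per-locus slopes (years/level)."""

    intercept: float
    coefficients: Mapping[str, float]
    locus_order: Tuple[str, ...] = LOCUS_ORDER
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.locus_order):
            raise ValueError(
                "coefficients must cover exactly the loci in locus_order; "
                f"got {sorted(self.coefficients)} vs {list(self.locus_order)}"
            )

    def coefficient(self, locus: str) -> float:
        return self.coefficients[locus]

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        """Serialize with decimal-string values (exact float round trip)."""
        payload = {
            "intercept": repr(float(self.intercept)),
            "coefficients": {
                locus: repr(float(self.coefficients[locus]))
                for locus in self.locus_order
            },
            "locus_order": list(self.locus_order),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "AgeModel":
        """Load a model from a JSON string or file path."""
        text = source
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            locus_order=tuple(payload["locus_order"]),
            provenance=payload.get("provenance", ""),
        )


# Printed constants of the published five-locus buccal-swab model.
_PUBLISHED = {
    "intercept": "13.96381427",
    "ELOVL2": "50.04231273",
    "FHL2": "-11.16979445",
    "KLF14": "73.87032325",
    "C1orf132": "-49.27304295",
    "TRIM59": "84.17900486",
}


def published_model() -> AgeModel:
    """The published five-locus buccal-swab age model, constants verbatim."""
    return AgeModel(
        intercept=float(_PUBLISHED["intercept"]),
        coefficients={locus: float(_PUBLISHED[locus]) for locus in LOCUS_ORDER},
        locus_order=LOCUS_ORDER,
        provenance="paper-published",
    )


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    age_years: float
    profile: MethylationProfile
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"{self.sample_id}: age must be positive")


@dataclass(frozen=True)
class Cohort:
    """Samples with chronological ages and averaged methylation profiles."""

    samples: Tuple[CohortSample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("cohort contains duplicate sample ids")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.samples], dtype=float)

    def complete_samples(
        self, loci: Sequence[str] = LOCUS_ORDER
    ) -> Tuple[CohortSample, ...]:
        return tuple(s for s in self.samples if s.profile.is_complete(loci))

    def to_frame(self, loci: Sequence[str] = LOCUS_ORDER) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "age_years": s.age_years, "sex": s.sex}
            for locus in loci:
                row[locus] = s.profile.level(locus)
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample_id", "age_years", "sex", *loci])


def predict_age(model: AgeModel, profile: MethylationProfile) -> float:
    """Apply the linear model to one averaged profile; output is unclamped."""
    total = model.intercept
    for locus in model.locus_order:
        level = profile.level(locus)
        if level is None:
            raise MissingPredictorError(
                f"profile {profile.sample_id} has no level for locus {locus}"
            )
        total += model.coefficients[locus] * level
    if total < 0 or total > 120:
        logger.warning(
            "implausible predicted age %.2f y for sample %s", total, profile.sample_id
        )
    return float(total)


def predict_cohort(model: AgeModel, cohort: Cohort) -> pd.DataFrame:
    """Predict every sample; returns ``sample_id, age_years, predicted_age_years``."""
    rows = [
        {
            "sample_id": s.sample_id,
            "age_years": s.age_years,
            "predicted_age_years": predict_age(model, s.profile),
        }
        for s in cohort
    ]
    return pd.DataFrame(rows, columns=["sample_id", "age_years", "predicted_age_years"])


def fit_age_model(
    training: Cohort,
    loci: Sequence[str] = LOCUS_ORDER,
    provenance: Optional[str] = None,
) -> AgeModel:
    """Ordinary least-squares fit of age on the five methylation levels.

    Samples with an incomplete profile are excluded (their count is logged).
    Requires at least ``len(loci) + 2`` complete samples — strictly more
    observations than the six free parameters — and a full-rank design. The
    solve uses an orthogonal (SVD-based) decomposition; no regularization.
    """
    complete = training.complete_samples(loci)
    excluded = len(training) - len(complete)
    if excluded:
        logger.info("excluded %d samples with incomplete profiles", excluded)
    n, p = len(complete), len(loci)
    if n < p + 2:
        raise InsufficientDataError(
            f"need at least {p + 2} complete samples to fit {p + 1} parameters, got {n}"
        )
    design = np.column_stack(
        [np.ones(n)]
        + [np.array([s.profile.level(l) for s in complete]) for l in loci]
    )
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularFitError("design matrix is rank-deficient")
    ages = np.array([s.age_years for s in complete])
    beta, *_ = np.linalg.lstsq(design, ages, rcond=None)
    return AgeModel(
        intercept=float(beta[0]),
        coefficients={locus: float(b) for locus, b in zip(loci, beta[1:])},
        locus_order=tuple(loci),
        provenance=provenance if provenance is not None else f"fitted:n={n}",
    )


def split_cohort(
    cohort: Cohort,
    train_fraction: float = 0.5,
    seed: int = 0,
    stratify_by_age: bool = False,
) -> Tuple[Cohort, Cohort]:
    """Random disjoint train/test partition, reproducible under ``seed``.

    The training set receives ``ceil(n * train_fraction)`` samples. With
    ``stratify_by_age`` the samples are first ordered by age and the split is
    taken within consecutive pairs, balancing the age distributions; the
    default is a simple random split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_train = math.ceil(n * train_fraction)
    if stratify_by_age:
        # shuffle within age-adjacent pairs so each pair contributes one
        # sample to each half (leftovers fill the training set first)
        order = sorted(range(n), key=lambda i: cohort.samples[i].age_years)
        first, second = [], []
        for start in range(0, n, 2):
            pair = list(order[start : start + 2])
            rng.shuffle(pair)
            first.append(pair[0])
            second.extend(pair[1:])
        candidates = first + second
    else:
        candidates = [int(i) for i in rng.permutation(n)]
    train_set = set(candidates[:n_train])
    train = Cohort(tuple(s for i, s in enumerate(cohort.samples) if i in train_set))
    test = Cohort(tuple(s for i, s in enumerate(cohort.samples) if i not in train_set))
    return train, test


def cohort_from_frames(
    metadata: pd.DataFrame,
    profiles: Sequence[MethylationProfile],
) -> Cohort:
    """Join cohort metadata with averaged profiles by sample id."""
    by_id: Dict[str, MethylationProfile] = {p.sample_id: p for p in profiles}
    samples = []
    for _, row in metadata.iterrows():
        sid = str(row["sample_id"])
        if sid not in by_id:
            continue
        samples.append(
            CohortSample(
                sample_id=sid,
                age_years=float(row["age_years"]),
                sex=row.get("sex"),
                profile=by_id[sid],
            )
        )
    return Cohort(tuple(samples))
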