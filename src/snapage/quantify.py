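"""Peak-ratio methylation quantification, replicate QC and averaging.

The methylation level of a locus is the intensity fraction of the
methylated-allele peak,

    level = I_meth / (I_meth + I_unmeth),

with I the peak height (or, optionally, area) of the C vs T channel for
ELOVL2/FHL2 and the G vs A channel for KLF14/C1orf132/TRIM59. Each sample is
measured four times (2 bisulfite conversions x 2 amplifications); a pooled
two-sample t-test checks that the two conversion batches agree before the
replicates are averaged into one profile per sample, and fully methylated /
fully unmethylated control DNAs verify the conversion itself.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .loci import LOCI, LOCUS_ORDER
from .peak_io import PeakPair, PeakRecord, select_locus_pair

ReplicateKey = Union[Tuple[int, int], str]


class InsufficientReplicatesError(ValueError):
    """A statistical check was asked for with fewer replicates than it needs."""


class AggregationError(ValueError):
    """Profiles from different samples were mixed in one aggregation."""


@dataclass(frozen=True)
class MethylationProfile:
    """Per-sample (or per-replicate) methylation levels.

    ``levels`` maps locus name to a fraction in [0, 1]; a locus with no
    quantifiable measurement is simply absent from the map. ``replicate_key``
    is ``(conversion, amplification)`` for a single replicate or the string
    ``"averaged"`` for a replicate-averaged profile.
    """

    sample_id: str
    replicate_key: ReplicateKey
    levels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, level in self.levels.items():
            if not 0.0 <= level <= 1.0:
                raise ValueError(
                    f"{self.sample_id}/{locus}: level {level} outside [0, 1]"
                )

    def level(self, locus: str) -> Optional[float]:
        return self.levels.get(locus)

    def is_complete(self, loci: Sequence[str] = LOCUS_ORDER) -> bool:
        return all(l in self.levels for l in loci)


@dataclass(frozen=True)
class HomogeneityResult:
    """Outcome of the between-conversion pooled-variance t-test for one locus."""

    locus: str
    t_statistic: float
    p_value: float
    df: int
    passed: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ControlCheck:
    """Per-locus pass/fail of one bisulfite-conversion control DNA.

    ``passed`` maps locus to True/False, or ``None`` when the locus could not
    be evaluated (absent in the control profile).
    """

    control_type: str  # "methylated" | "unmethylated"
    levels: Mapping[str, float]
    passed: Mapping[str, Optional[bool]]


@dataclass(frozen=True)
class ControlReport:
    methylated: ControlCheck
    unmethylated: ControlCheck
    batch_passed: bool
    unevaluable: Tuple[str, ...] = ()


def methylation_level(pair: PeakPair) -> Optional[float]:
    """Peak-ratio methylation level ``I_meth / (I_meth + I_unmeth)``.

    Returns ``None`` (undefined measurement) when both intensities are zero;
    0/0 arithmetic is never performed.
    """
    total = pair.i_meth + pair.i_unmeth
    if total == 0:
        return None
    return pair.i_meth / total


def profiles_from_records(
    records: Iterable[PeakRecord],
    intensity_mode: str = "height",
) -> List[MethylationProfile]:
    """Quantify every replicate present in a peak-record collection.

    Records are grouped by (sample, conversion, amplification, locus); each
    group is resolved to a peak pair and scored. Loci whose measurement is
    missing (no peak on either channel) are left out of the profile.
    """
    groups: Dict[Tuple[str, int, int, str], List[PeakRecord]] = defaultdict(list)
    for record in records:
        groups[(record.sample_id, record.conversion, record.amplification, record.locus)].append(record)

    by_replicate: Dict[Tuple[str, int, int], Dict[str, float]] = defaultdict(dict)
    for (sample_id, conv, amp, locus), group in groups.items():
        pair = select_locus_pair(group, LOCI[locus], intensity_mode)
        if pair is None:
            continue
        level = methylation_level(pair)
        if level is None:
            continue
        by_replicate[(sample_id, conv, amp)][locus] = level

    return [
        MethylationProfile(sample_id=sid, replicate_key=(conv, amp), levels=levels)
        for (sid, conv, amp), levels in sorted(by_replicate.items())
    ]


def conversion_homogeneity_test(
    levels_conv1: Sequence[float],
    levels_conv2: Sequence[float],
    alpha: float = 0.05,
    locus: str = "",
) -> HomogeneityResult:
    """Two-tailed pooled-variance (equal-variance) two-sample t-test.

    Compares methylation levels measured under the first vs the second
    bisulfite conversion; ``passed`` means no significant heterogeneity at
    ``alpha`` (p >= alpha). Degenerate inputs with zero pooled variance give
    t = 0, p = 1 when the group means agree and p = 0 (flagged ``degenerate``)
    when they do not.
    """
    x = np.asarray(levels_conv1, dtype=float)
    y = np.asarray(levels_conv2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientReplicatesError(
            f"t-test needs >=2 values per conversion, got {x.size} and {y.size}"
        )
    df = int(x.size + y.size - 2)
    pooled_ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    if pooled_ss == 0.0:
        if x.mean() == y.mean():
            return HomogeneityResult(locus, 0.0, 1.0, df, passed=(1.0 >= alpha))
        return HomogeneityResult(
            locus,
            float(np.inf if x.mean() > y.mean() else -np.inf),
            0.0,
            df,
            passed=False,
            degenerate=True,
        )
    t_stat, p_value = stats.ttest_ind(x, y, equal_var=True)
    return HomogeneityResult(
        locus,
        float(t_stat),
        float(p_value),
        df,
        passed=bool(p_value >= alpha),
    )


def conversion_homogeneity_by_locus(
    replicate_profiles: Sequence[MethylationProfile],
    alpha: float = 0.05,
    loci: Sequence[str] = LOCUS_ORDER,
) -> Dict[str, HomogeneityResult]:
    """Cohort-level between-conversion homogeneity test, one test per locus.

    For each locus, all levels measured under conversion 1 (both
    amplifications, all samples) form one group and those under conversion 2
    the other. This pooled, cohort-level comparison is the default; see
    :func:`conversion_homogeneity_by_sample` for a per-sample variant.
    """
    results: Dict[str, HomogeneityResult] = {}
    for locus in loci:
        group1 = [
            p.levels[locus]
            for p in replicate_profiles
            if locus in p.levels and p.replicate_key[0] == 1
        ]
        group2 = [
            p.levels[locus]
            for p in replicate_profiles
            if locus in p.levels and p.replicate_key[0] == 2
        ]
        results[locus] = conversion_homogeneity_test(group1, group2, alpha, locus)
    return results


def conversion_homogeneity_by_sample(
    replicate_profiles: Sequence[MethylationProfile],
    alpha: float = 0.05,
    loci: Sequence[str] = LOCUS_ORDER,
) -> Dict[Tuple[str, str], HomogeneityResult]:
    """Per-sample variant: one test per (sample, locus) with 2 values per group."""
    by_sample: Dict[str, List[MethylationProfile]] = defaultdict(list)
    for profile in replicate_profiles:
        by_sample[profile.sample_id].append(profile)
    results: Dict[Tuple[str, str], HomogeneityResult] = {}
    for sample_id, profiles in sorted(by_sample.items()):
        for locus in loci:
            group1 = [
                p.levels[locus]
                for p in profiles
                if locus in p.levels and p.replicate_key[0] == 1
            ]
            group2 = [
                p.levels[locus]
                for p in profiles
                if locus in p.levels and p.replicate_key[0] == 2
            ]
            if len(group1) < 2 or len(group2) < 2:
                continue
            results[(sample_id, locus)] = conversion_homogeneity_test(
                group1, group2, alpha, locus
            )
    return results


def average_replicates(
    profiles: Sequence[MethylationProfile],
) -> MethylationProfile:
    """Arithmetic per-locus mean of a sample's replicate profiles.

    Each locus is averaged over the replicates in which it is present; a locus
    absent from every replicate stays absent. All profiles must belong to the
    same sample.
    """
    if not profiles:
        raise AggregationError("no replicate profiles to average")
    sample_ids = {p.sample_id for p in profiles}
    if len(sample_ids) > 1:
        raise AggregationError(f"mixed sample ids in averaging: {sorted(sample_ids)}")

    pooled: Dict[str, List[float]] = defaultdict(list)
    for profile in profiles:
        for locus, level in profile.levels.items():
            pooled[locus].append(level)
    averaged = {locus: float(np.mean(vals)) for locus, vals in pooled.items()}
    return MethylationProfile(
        sample_id=profiles[0].sample_id,
        replicate_key="averaged",
        levels=averaged,
    )


def average_by_sample(
    replicate_profiles: Sequence[MethylationProfile],
) -> List[MethylationProfile]:
    """Average replicates sample-by-sample, returning one profile per sample."""
    by_sample: Dict[str, List[MethylationProfile]] = defaultdict(list)
    for profile in replicate_profiles:
        by_sample[profile.sample_id].append(profile)
    return [average_replicates(group) for _, group in sorted(by_sample.items())]


def check_controls(
    meth_control: MethylationProfile,
    unmeth_control: MethylationProfile,
    low_bound: float = 0.1,
    high_bound: float = 0.9,
    loci: Sequence[str] = LOCUS_ORDER,
) -> ControlReport:
    """Verify bisulfite conversion using the fully (un)methylated control DNAs.

    The methylated control must score at least ``high_bound`` and the
    unmethylated control at most ``low_bound`` at every locus. A locus absent
    from a control profile is marked unevaluable and triggers a warning; any
    outright failure fails the batch.
    """
    meth_passed: Dict[str, Optional[bool]] = {}
    unmeth_passed: Dict[str, Optional[bool]] = {}
    unevaluable: List[str] = []
    for locus in loci:
        level = meth_control.level(locus)
        meth_passed[locus] = None if level is None else bool(level >= high_bound)
        level = unmeth_control.level(locus)
        unmeth_passed[locus] = None if level is None else bool(level <= low_bound)
        if meth_passed[locus] is None or unmeth_passed[locus] is None:
            unevaluable.append(locus)

    if unevaluable:
        warnings.warn(
            f"control DNA unevaluable at loci: {', '.join(unevaluable)}",
            stacklevel=2,
        )
    batch_passed = all(
        flag is not False
        for flags in (meth_passed, unmeth_passed)
        for flag in flags.values()
    )
    return ControlReport(
        methylated=ControlCheck("methylated", dict(meth_control.levels), meth_passed),
        unmethylated=ControlCheck(
            "unmethylated", dict(unmeth_control.levels), unmeth_passed
        ),
        batch_passed=batch_passed,
        unevaluable=tuple(unevaluable),
    )


def profiles_from_wide_frame(
    frame: pd.DataFrame,
    loci: Sequence[str] = LOCUS_ORDER,
    replicate_key: ReplicateKey = "averaged",
) -> List[MethylationProfile]:
    """Inverse of :func:`averaged_profiles_frame`: wide CSV rows to profiles."""
    profiles = []
    for _, row in frame.iterrows():
        levels = {
            locus: float(row[locus])
            for locus in loci
            if locus in frame.columns and pd.notna(row[locus])
        }
        profiles.append(
            MethylationProfile(
                sample_id=str(row["sample_id"]),
                replicate_key=replicate_key,
                levels=levels,
            )
        )
    return profiles


def replicate_levels_frame(profiles: Sequence[MethylationProfile]) -> pd.DataFrame:
    """Tidy frame ``sample_id, conversion, amplification, locus, level``."""
    rows = []
    for profile in profiles:
        conv, amp = profile.replicate_key  # type: ignore[misc]
        for locus, level in profile.levels.items():
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "conversion": conv,
                    "amplification": amp,
                    "locus": locus,
                    "level": level,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "conversion", "amplification", "locus", "level"])


def averaged_profiles_frame(
    profiles: Sequence[MethylationProfile],
    loci: Sequence[str] = LOCUS_ORDER,
) -> pd.DataFrame:
    """Wide frame ``sample_id, <locus columns>`` of averaged profiles."""
    rows = []
    for profile in profiles:
        row = {"sample_id": profile.sample_id}
        for locus in loci:
            row[locus] = profile.level(locus)
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *loci])
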