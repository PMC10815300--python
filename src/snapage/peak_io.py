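"""Reading and writing SNaPshot peak tables and cohort metadata.

The pipeline starts from delimited peak tables of the kind exported by
capillary-electrophoresis genotyping software (one row per called peak with
sample, replicate, locus, base channel, height, area and fragment size), not
from raw electropherogram traces. The canonical dialect is comma-separated
UTF-8 with a header row and columns::

    sample_id, conversion, amplification, locus, base, height, area, size_nt

Other exports are adapted through a :class:`PeakTableDialect` column mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .loci import LOCI, VALID_BASES, LocusDefinition

REQUIRED_COLUMNS = ("sample_id", "conversion", "amplification", "locus", "base", "height")
OPTIONAL_COLUMNS = ("area", "size_nt")
CANONICAL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


class PeakTableFormatError(ValueError):
    """The peak table cannot be interpreted (missing column, bad row, unknown locus)."""


@dataclass(frozen=True)
class PeakTableDialect:
    """Delimiter plus mapping from canonical column names to file column names."""

    delimiter: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )

    def file_column(self, canonical: str) -> Optional[str]:
        return self.columns.get(canonical)


DEFAULT_DIALECT = PeakTableDialect()


@dataclass(frozen=True)
class PeakRecord:
    """One called fluorescence peak.

    ``conversion`` and ``amplification`` (each 1 or 2 in the standard design)
    together identify one of the up-to-four replicates of a sample: two
    bisulfite conversions, each amplified twice.
    """

    sample_id: str
    conversion: int
    amplification: int
    locus: str
    base: str
    height: float
    area: Optional[float] = None
    size_nt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak height must be nonnegative, got {self.height}")
        if self.area is not None and self.area < 0:
            raise ValueError(f"peak area must be nonnegative, got {self.area}")
        if self.base not in VALID_BASES:
            raise ValueError(f"invalid base channel {self.base!r}")


@dataclass(frozen=True)
class PeakPair:
    """Intensities of the methylated- and unmethylated-allele peaks (RFU)."""

    i_meth: float
    i_unmeth: float

    def __post_init__(self) -> None:
        if self.i_meth < 0 or self.i_unmeth < 0:
            raise ValueError("peak intensities must be nonnegative")


def _float_or_none(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def parse_peak_table(
    path: Union[str, Path],
    dialect: PeakTableDialect = DEFAULT_DIALECT,
    strict: bool = True,
) -> List[PeakRecord]:
    """Parse a delimited peak table into :class:`PeakRecord` objects.

    Parameters
    ----------
    path
        File to read.
    dialect
        Delimiter and column-name mapping; defaults to the canonical dialect.
    strict
        If True (default), any malformed row or unknown locus raises
        :class:`PeakTableFormatError`; if False, offending rows are skipped
        with a warning, so no row is ever dropped silently.

    Returns
    -------
    list of PeakRecord, in file row order.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"peak table {path} is empty", stacklevel=2)
        return []

    for canonical in REQUIRED_COLUMNS:
        col = dialect.file_column(canonical)
        if col is None or col not in frame.columns:
            raise PeakTableFormatError(
                f"peak table {path} is missing required column "
                f"{canonical!r} (mapped to {col!r})"
            )
    if frame.empty:
        warnings.warn(f"peak table {path} has a header but no rows", stacklevel=2)
        return []

    records: List[PeakRecord] = []
    rejected = 0
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            locus = str(row[dialect.file_column("locus")]).strip()
            if locus not in LOCI:
                raise PeakTableFormatError(f"unknown locus {locus!r}")
            area_col = dialect.file_column("area")
            size_col = dialect.file_column("size_nt")
            record = PeakRecord(
                sample_id=str(row[dialect.file_column("sample_id")]).strip(),
                conversion=int(row[dialect.file_column("conversion")]),
                amplification=int(row[dialect.file_column("amplification")]),
                locus=locus,
                base=str(row[dialect.file_column("base")]).strip().upper(),
                height=float(row[dialect.file_column("height")]),
                area=_float_or_none(row.get(area_col)) if area_col else None,
                size_nt=_float_or_none(row.get(size_col)) if size_col else None,
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise PeakTableFormatError(
                    f"peak table {path}, line {line_no}: {exc}"
                ) from exc
            rejected += 1
            warnings.warn(
                f"peak table {path}, line {line_no} skipped: {exc}", stacklevel=2
            )
            continue
        records.append(record)

    if rejected:
        warnings.warn(
            f"peak table {path}: skipped {rejected} of {len(frame)} rows",
            stacklevel=2,
        )
    return records


def write_peak_table(
    records: Iterable[PeakRecord],
    path: Union[str, Path],
    dialect: PeakTableDialect = DEFAULT_DIALECT,
) -> None:
    """Write records to a delimited peak table in the given dialect."""
    rows = [
        {
            dialect.file_column("sample_id"): r.sample_id,
            dialect.file_column("conversion"): r.conversion,
            dialect.file_column("amplification"): r.amplification,
            dialect.file_column("locus"): r.locus,
            dialect.file_column("base"): r.base,
            dialect.file_column("height"): r.height,
            dialect.file_column("area"): r.area,
            dialect.file_column("size_nt"): r.size_nt,
        }
        for r in records
    ]
    columns = [dialect.file_column(c) for c in CANONICAL_COLUMNS]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep=dialect.delimiter, index=False)


def read_cohort_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort metadata CSV with columns ``sample_id, age_years, sex``."""
    frame = pd.read_csv(path)
    for col in ("sample_id", "age_years"):
        if col not in frame.columns:
            raise PeakTableFormatError(f"cohort metadata is missing column {col!r}")
    if (frame["age_years"] <= 0).any():
        raise PeakTableFormatError("cohort metadata contains non-positive ages")
    if frame["sample_id"].duplicated().any():
        raise PeakTableFormatError("cohort metadata contains duplicate sample ids")
    return frame


def _intensity(record: PeakRecord, mode: str) -> float:
    if mode == "height":
        return record.height
    if mode == "area":
        if record.area is None:
            raise ValueError(
                f"intensity mode 'area' requested but peak for {record.locus} "
                f"({record.sample_id}) has no area"
            )
        return record.area
    raise ValueError(f"unknown intensity mode {mode!r}")


def _best_peak(
    candidates: Sequence[PeakRecord],
    locus_def: LocusDefinition,
    mode: str,
) -> Optional[PeakRecord]:
    """Pick the peak to quantify when a channel has 0, 1 or several calls.

    When more than one peak is called on the channel, peaks inside the locus'
    expected size window are preferred; among those the tallest wins, with
    ties broken toward the smaller fragment size (unsized peaks last).
    """
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    pool = list(candidates)
    if locus_def.expected_size_range is not None:
        lo, hi = locus_def.expected_size_range
        in_range = [
            r for r in pool if r.size_nt is not None and lo <= r.size_nt <= hi
        ]
        if in_range:
            pool = in_range
    return min(
        pool,
        key=lambda r: (
            -_intensity(r, mode),
            r.size_nt if r.size_nt is not None else float("inf"),
        ),
    )


def select_locus_pair(
    records: Sequence[PeakRecord],
    locus_def: LocusDefinition,
    intensity_mode: str = "height",
) -> Optional[PeakPair]:
    """Resolve the methylated/unmethylated peak pair for one replicate × locus.

    ``records`` must all belong to the same sample, replicate and locus. A
    missing channel contributes intensity 0 — single-base extension of a fully
    (un)methylated template legitimately produces only one peak. If both
    channels are absent the measurement is missing and ``None`` is returned.
    """
    keys = {(r.sample_id, r.conversion, r.amplification, r.locus) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple replicates/loci: {sorted(keys)}")

    meth = _best_peak(
        [r for r in records if r.base == locus_def.methylated_base],
        locus_def,
        intensity_mode,
    )
    unmeth = _best_peak(
        [r for r in records if r.base == locus_def.unmethylated_base],
        locus_def,
        intensity_mode,
    )
    if meth is None and unmeth is None:
        return None
    i_meth = _intensity(meth, intensity_mode) if meth is not None else 0.0
    i_unmeth = _intensity(unmeth, intensity_mode) if unmeth is not None else 0.0
    return PeakPair(i_meth, i_unmeth)
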