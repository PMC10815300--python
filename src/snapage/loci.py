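"""Locus definitions for the five-CpG buccal-swab methylation clock.

Each marker is interrogated by single-base extension (SBE) after bisulfite
conversion: the methylated template incorporates one dye-labelled terminator,
the unmethylated template another, so methylation is read out as the ratio of
two peak intensities in a capillary electropherogram. Which nucleotide channel
carries the methylated allele depends on which strand the SBE primer queries:
ELOVL2 and FHL2 are read as C (methylated) vs T (unmethylated), while KLF14,
C1orf132/MIR29B2C and TRIM59 are read on the opposite strand as G vs A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

#: Canonical locus order used everywhere a profile is treated as a vector.
LOCUS_ORDER: Tuple[str, ...] = ("ELOVL2", "FHL2", "KLF14", "C1orf132", "TRIM59")

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LocusDefinition:
    """Chemistry of one SBE marker.

    Parameters
    ----------
    name
        Locus identifier (gene symbol; ``C1orf132`` is also known as
        MIR29B2C).
    methylated_base
        Nucleotide channel whose intensity enters the numerator of the
        methylation ratio.
    unmethylated_base
        Nucleotide channel of the unmethylated allele (second denominator
        term).
    expected_size_range
        Optional (min, max) fragment size in nucleotides used to match peaks
        when an electropherogram contains more than one call per channel.
    """

    name: str
    methylated_base: str
    unmethylated_base: str
    expected_size_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.methylated_base not in VALID_BASES:
            raise ValueError(f"invalid methylated base {self.methylated_base!r}")
        if self.unmethylated_base not in VALID_BASES:
            raise ValueError(f"invalid unmethylated base {self.unmethylated_base!r}")
        if self.methylated_base == self.unmethylated_base:
            raise ValueError(
                f"{self.name}: methylated and unmethylated channels must differ"
            )
        if self.expected_size_range is not None:
            lo, hi = self.expected_size_range
            if not lo < hi:
                raise ValueError(f"{self.name}: size range must satisfy min < max")


# Size windows are nominal SBE product sizes within the 120-nt sizing standard;
# they only matter for disambiguating multiple peak calls on one channel.
LOCI = {
    "ELOVL2": LocusDefinition("ELOVL2", "C", "T", (24.0, 32.0)),
    "FHL2": LocusDefinition("FHL2", "C", "T", (32.0, 40.0)),
    "KLF14": LocusDefinition("KLF14", "G", "A", (40.0, 48.0)),
    "C1orf132": LocusDefinition("C1orf132", "G", "A", (48.0, 56.0)),
    "TRIM59": LocusDefinition("TRIM59", "G", "A", (56.0, 64.0)),
}


def get_locus(name: str) -> LocusDefinition:
    """Return the definition for ``name``, raising ``KeyError`` if unknown."""
    return LOCI[name]
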