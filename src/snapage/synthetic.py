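"""Synthetic cohorts and peak tables with the structure the pipeline assumes.

The generator emulates a buccal-swab methylation study end to end: ages drawn
uniformly over a range, per-locus methylation levels linear in age with
Gaussian biological scatter (clamped to [0, 1]), a 2-conversions ×
2-amplifications replicate design with optional between-conversion batch
shift, and capillary-electrophoresis peak heights obtained by splitting a
log-normal total intensity between the methylated and unmethylated channels
with multiplicative noise, integer rounding and detector saturation. Fully
methylated and fully unmethylated control samples ride along in every peak
table, as conversion controls do on a real plate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .loci import LOCI, LOCUS_ORDER
from .model import Cohort, CohortSample
from .peak_io import PeakRecord, write_peak_table
from .quantify import MethylationProfile

#: Reserved sample ids of the conversion-control samples in generated tables.
METH_CONTROL_ID = "CTRL_METH"
UNMETH_CONTROL_ID = "CTRL_UNMETH"
CONTROL_IDS = (METH_CONTROL_ID, UNMETH_CONTROL_ID)


@dataclass(frozen=True)
class LocusParams:
    """Linear age trend of one locus: level = baseline + slope·age + N(0, sd²)."""

    baseline: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 60
    age_range: Tuple[float, float] = (23.0, 70.0)
    integer_ages: bool = True
    locus_params: Mapping[str, LocusParams] = field(default_factory=dict)
    n_conversions: int = 2
    n_amplifications: int = 2
    replicate_noise_sd: float = 0.01
    conversion_shift: float = 0.0
    total_intensity_mean: float = 4000.0
    total_intensity_sd: float = 1200.0
    intensity_noise_cv: float = 0.05
    saturation_rfu: float = 30000.0
    meth_control_level: float = 0.98
    unmeth_control_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        for name in ("replicate_noise_sd", "intensity_noise_cv", "total_intensity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.locus_params) - set(LOCUS_ORDER):
            raise ValueError("locus_params contains unknown loci")


def default_config(**overrides) -> SyntheticConfig:
    """Load the packaged default parameter set, optionally overriding fields."""
    text = resources.files("snapage.data").joinpath("default_synthetic.yaml").read_text()
    return config_from_yaml_text(text, **overrides)


def config_from_yaml_text(text: str, **overrides) -> SyntheticConfig:
    raw = yaml.safe_load(text)
    raw["age_range"] = tuple(float(a) for a in raw["age_range"])
    raw["locus_params"] = {
        locus: LocusParams(**params) for locus, params in raw["locus_params"].items()
    }
    raw.update(overrides)
    return SyntheticConfig(**raw)


def config_from_yaml(path: Union[str, Path], **overrides) -> SyntheticConfig:
    return config_from_yaml_text(Path(path).read_text(), **overrides)


def config_to_yaml(config: SyntheticConfig, path: Union[str, Path, None] = None) -> str:
    raw = {
        "n_samples": config.n_samples,
        "age_range": list(config.age_range),
        "integer_ages": config.integer_ages,
        "locus_params": {
            locus: {
                "baseline": p.baseline,
                "slope": p.slope,
                "noise_sd": p.noise_sd,
            }
            for locus, p in config.locus_params.items()
        },
        "n_conversions": config.n_conversions,
        "n_amplifications": config.n_amplifications,
        "replicate_noise_sd": config.replicate_noise_sd,
        "conversion_shift": config.conversion_shift,
        "total_intensity_mean": config.total_intensity_mean,
        "total_intensity_sd": config.total_intensity_sd,
        "intensity_noise_cv": config.intensity_noise_cv,
        "saturation_rfu": config.saturation_rfu,
        "meth_control_level": config.meth_control_level,
        "unmeth_control_level": config.unmeth_control_level,
        "seed": config.seed,
    }
    text = yaml.safe_dump(raw, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _clamp01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort with true (noise-free of measurement error) profiles.

    Ages are uniform over ``age_range`` (whole years by default); each locus
    level is its linear age trend plus Gaussian scatter, clamped to [0, 1].
    A configuration whose trend clamps more than half the samples at any locus
    triggers a warning — realized correlations would no longer reflect the
    nominal slope/noise.
    """
    params = config.locus_params or default_config().locus_params
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.integer_ages and float(lo).is_integer() and float(hi).is_integer():
        ages = rng.integers(int(lo), int(hi) + 1, size=config.n_samples).astype(float)
    else:
        ages = rng.uniform(lo, hi, size=config.n_samples)
    sexes = rng.choice(["F", "M"], size=config.n_samples)

    raw_levels: Dict[str, np.ndarray] = {}
    for locus in LOCUS_ORDER:
        p = params[locus]
        raw = p.baseline + p.slope * ages + rng.normal(0.0, p.noise_sd, config.n_samples)
        clamped_frac = np.mean((raw < 0.0) | (raw > 1.0))
        if clamped_frac > 0.5:
            warnings.warn(
                f"{locus}: {clamped_frac:.0%} of generated levels clamped to [0,1]; "
                "the configured trend is inconsistent with the level scale",
                stacklevel=2,
            )
        raw_levels[locus] = _clamp01(raw)

    samples = []
    for i in range(config.n_samples):
        profile = MethylationProfile(
            sample_id=f"S{i + 1:03d}",
            replicate_key="truth",
            levels={locus: float(raw_levels[locus][i]) for locus in LOCUS_ORDER},
        )
        samples.append(
            CohortSample(
                sample_id=profile.sample_id,
                age_years=float(ages[i]),
                sex=str(sexes[i]),
                profile=profile,
            )
        )
    return Cohort(tuple(samples))


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and standard deviation."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_peak_table(
    cohort: Cohort,
    config: SyntheticConfig,
    include_controls: bool = True,
) -> List[PeakRecord]:
    """Render a cohort's true levels as SNaPshot peak records.

    For every sample × conversion × amplification × locus the replicate-level
    methylation is the true level plus a between-conversion shift of
    ``±conversion_shift`` (conversion 1 low, conversion 2 high) and Gaussian
    replicate noise, clamped to [0, 1]. A log-normal total intensity is then
    split between the methylated and unmethylated channels, each perturbed by
    multiplicative noise, rounded to integer RFU and capped at the detector
    saturation. Control samples are emitted with constant true levels.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    mu, sigma = _lognormal_params(config.total_intensity_mean, config.total_intensity_sd)

    entries: List[Tuple[str, Dict[str, float]]] = [
        (s.sample_id, dict(s.profile.levels)) for s in cohort
    ]
    if include_controls:
        entries.append(
            (METH_CONTROL_ID, {l: config.meth_control_level for l in LOCUS_ORDER})
        )
        entries.append(
            (UNMETH_CONTROL_ID, {l: config.unmeth_control_level for l in LOCUS_ORDER})
        )

    records: List[PeakRecord] = []
    for sample_id, true_levels in entries:
        for conv in range(1, config.n_conversions + 1):
            batch = config.conversion_shift * (conv - 1.5) * 2.0
            for amp in range(1, config.n_amplifications + 1):
                for locus in LOCUS_ORDER:
                    if locus not in true_levels:
                        continue
                    level = true_levels[locus] + batch
                    if config.replicate_noise_sd > 0:
                        level += rng.normal(0.0, config.replicate_noise_sd)
                    level = float(np.clip(level, 0.0, 1.0))
                    total = float(rng.lognormal(mu, sigma)) if sigma > 0 else config.total_intensity_mean
                    eta = (
                        rng.normal(0.0, config.intensity_noise_cv, size=2)
                        if config.intensity_noise_cv > 0
                        else np.zeros(2)
                    )
                    i_meth = round(min(config.saturation_rfu, max(0.0, level * total * (1 + eta[0]))))
                    i_unmeth = round(min(config.saturation_rfu, max(0.0, (1 - level) * total * (1 + eta[1]))))
                    locus_def = LOCI[locus]
                    size = (
                        float(np.mean(locus_def.expected_size_range))
                        if locus_def.expected_size_range
                        else None
                    )
                    for base, intensity in (
                        (locus_def.methylated_base, i_meth),
                        (locus_def.unmethylated_base, i_unmeth),
                    ):
                        if intensity <= 0:
                            continue  # no peak called for an absent allele
                        records.append(
                            PeakRecord(
                                sample_id=sample_id,
                                conversion=conv,
                                amplification=amp,
                                locus=locus,
                                base=base,
                                height=float(intensity),
                                area=None,
                                size_nt=size,
                            )
                        )
    return records


def simulate(
    config: SyntheticConfig,
    outdir: Union[str, Path],
) -> Dict[str, Path]:
    """Generate a full study and write its text artifacts to ``outdir``.

    Writes cohort metadata (``cohort.csv``), true per-sample levels
    (``truth.csv``), the peak table (``peaks.csv``) and the exact parameter
    set used (``config.yaml``). Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    records = generate_peak_table(cohort, config)

    paths = {
        "cohort": outdir / "cohort.csv",
        "truth": outdir / "truth.csv",
        "peaks": outdir / "peaks.csv",
        "config": outdir / "config.yaml",
    }
    meta = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "age_years": s.age_years, "sex": s.sex}
            for s in cohort
        ]
    )
    meta.to_csv(paths["cohort"], index=False)
    cohort.to_frame().drop(columns=["age_years", "sex"]).to_csv(
        paths["truth"], index=False
    )
    write_peak_table(records, paths["peaks"])
    config_to_yaml(config, paths["config"])
    return paths
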