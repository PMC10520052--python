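"""Synthetic literature-style concentration datasets with known truth.

Real concentration data for e-cigarette chemicals exist only as scattered
literature reports: right-skewed positive values with non-detect zeros,
published variously as individual results, means, min–max ranges, or
per-power-setting replicates.  This module draws concentrations from a
known ground-truth distribution and repackages them into exactly those
report shapes, so every pipeline stage (harmonization, fitting, Monte
Carlo, sensitivity) can be tested end to end without any download.

The default ground-truth family is lognormal: concentrations are
non-negative and strongly right-skewed (reported standard deviations exceed
means for most chemicals).  Report-shape conventions are fixed:
``mean_only`` reports the mean of 3 draws, ``range_only`` the min and max
of a 5-draw batch, ``per_power_series`` 3 within-study replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .concentrations import (
    CANONICAL_UNITS,
    MATRICES,
    REPORT_KINDS,
    RawLiteratureRecord,
    load_packaged_summaries,
)
from .registry import CHEMICALS

__all__ = [
    "GENERATOR_VERSION",
    "GeneratorConfig",
    "SyntheticStudySet",
    "lognormal_from_mean_sd",
    "analytic_mean",
    "generate",
    "generate_paper_like_study",
]

GENERATOR_VERSION = "1"

#: draws per study by report kind (min/max of the 5-draw batch for ranges)
_BATCH = {"individual": 1, "mean_only": 3, "range_only": 5, "per_power_series": 3}

_DEFAULT_MIX = {
    "individual": 0.5,
    "mean_only": 0.2,
    "range_only": 0.2,
    "per_power_series": 0.1,
}


def lognormal_from_mean_sd(mean: float, sd: float) -> dict[str, float]:
    """Moment-match lognormal parameters (µ, σ of log-concentration) to an
    arithmetic mean and standard deviation."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    cv = sd / mean
    sigma2 = math.log1p(cv**2)
    return {"mu": math.log(mean) - sigma2 / 2, "sigma": math.sqrt(max(sigma2, 1e-12))}


def _sampler(family: str, params: Mapping[str, float]):
    if family == "lognormal":
        return lambda rng, size: rng.lognormal(params["mu"], params["sigma"], size)
    if family == "normal":
        return lambda rng, size: rng.normal(params["mean"], params["sd"], size)
    if family == "gamma":
        return lambda rng, size: rng.gamma(params["shape"], params["scale"], size)
    if family == "weibull":
        return lambda rng, size: params["scale"] * rng.weibull(params["shape"], size)
    if family == "uniform":
        return lambda rng, size: rng.uniform(params["low"], params["high"], size)
    if family == "triangular":
        return lambda rng, size: rng.triangular(
            params["left"], params["mode"], params["right"], size
        )
    raise ValueError(f"unknown family {family!r}")


def analytic_mean(family: str, params: Mapping[str, float], zero_fraction: float = 0.0) -> float:
    """Expected value of a generated sample, zero inflation included."""
    if family == "lognormal":
        base = math.exp(params["mu"] + params["sigma"] ** 2 / 2)
    elif family == "normal":
        base = params["mean"]
    elif family == "gamma":
        base = params["shape"] * params["scale"]
    elif family == "weibull":
        base = params["scale"] * math.gamma(1 + 1 / params["shape"])
    elif family == "uniform":
        base = (params["low"] + params["high"]) / 2
    elif family == "triangular":
        base = (params["left"] + params["mode"] + params["right"]) / 3
    else:
        raise ValueError(f"unknown family {family!r}")
    return (1 - zero_fraction) * base


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth for one chemical/matrix synthetic study set."""

    chemical: str
    matrix: str
    family: str = "lognormal"
    params: Mapping[str, float] = field(default_factory=lambda: {"mu": 0.0, "sigma": 1.0})
    n_studies: int = 10
    zero_fraction: float = 0.0
    report_kind_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chemical not in CHEMICALS:
            raise ValueError(f"unknown chemical id {self.chemical!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0 <= self.zero_fraction <= 1:
            raise ValueError("zero_fraction must be in [0, 1]")
        if set(self.report_kind_mix) - set(REPORT_KINDS):
            raise ValueError("unknown report kind in mix")
        total = sum(self.report_kind_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"report_kind_mix must sum to 1, got {total}")
        _sampler(self.family, self.params)  # validates family
        analytic_mean(self.family, self.params)  # validates params

    @property
    def truth_mean(self) -> float:
        return analytic_mean(self.family, self.params, self.zero_fraction)


@dataclass(frozen=True)
class SyntheticStudySet:
    """Generated raw literature records plus the configuration that made them."""

    records: tuple[RawLiteratureRecord, ...]
    truth: GeneratorConfig
    generator_version: str = GENERATOR_VERSION


def generate(config: GeneratorConfig) -> SyntheticStudySet:
    """Draw a synthetic study set; deterministic for a given config/seed."""
    rng = np.random.default_rng(config.seed)
    sampler = _sampler(config.family, config.params)
    kinds = list(config.report_kind_mix)
    probs = np.asarray([config.report_kind_mix[k] for k in kinds], dtype=float)
    unit = CANONICAL_UNITS[config.matrix]

    records: list[RawLiteratureRecord] = []
    for i in range(config.n_studies):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        batch = np.maximum(sampler(rng, _BATCH[kind]), 0.0)
        if config.zero_fraction > 0:
            batch = np.where(rng.random(len(batch)) < config.zero_fraction, 0.0, batch)
        if kind == "individual":
            values = [float(batch[0])]
        elif kind == "mean_only":
            values = [float(np.mean(batch))]
        elif kind == "range_only":
            values = [float(np.min(batch)), float(np.max(batch))]
        else:
            values = [float(v) for v in batch]
        records.append(
            RawLiteratureRecord(
                chemical=config.chemical,
                matrix=config.matrix,
                report_kind=kind,
                values=values,
                unit=unit,
                study_id=f"synthetic:{config.chemical}:{config.matrix}:{i:03d}",
            )
        )
    return SyntheticStudySet(tuple(records), config)


def generate_paper_like_study(
    seed: int = 0, variant: str = "as_used"
) -> dict[tuple[str, str], SyntheticStudySet]:
    """Generate a full two-matrix dataset shaped like the published study.

    For each chemical × matrix, the lognormal ground truth is moment-matched
    so the expected sample mean equals the packaged summary mean and the
    study count equals the published number of source articles.  Where the
    published minimum is zero, 10 % of draws are non-detect zeros and the
    positive part is rescaled to preserve the overall mean.
    """
    summaries = load_packaged_summaries(variant)
    root = np.random.default_rng(seed)
    out: dict[tuple[str, str], SyntheticStudySet] = {}
    for key in sorted(summaries):
        s = summaries[key]
        zero_fraction = 0.1 if s.min == 0 else 0.0
        pos_mean = s.mean / (1 - zero_fraction)
        pos_sd = s.sd / (1 - zero_fraction) if s.sd > 0 else pos_mean * 0.1
        config = GeneratorConfig(
            chemical=s.chemical,
            matrix=s.matrix,
            family="lognormal",
            params=lognormal_from_mean_sd(pos_mean, pos_sd),
            n_studies=s.n_refs,
            zero_fraction=zero_fraction,
            seed=int(root.integers(2**31)),
        )
        out[key] = generate(config)
    return out
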