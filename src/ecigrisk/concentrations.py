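"""Ingestion and harmonization of literature concentration measurements.

Published measurements of chemicals in e-cigarette aerosols and e-liquids
come in heterogeneous shapes: individual sample results, a mean only, a
min–max range only, or replicate measurements of the same device at several
power settings.  The harmonization rules turn each of these into equivalent
"samples" on canonical units (aerosol: µg/puff; e-liquid: mg/ml):

* ``individual``       — one sample per reported value;
* ``mean_only``        — the reported mean counts as one sample;
* ``range_only``       — the reported minimum and maximum count as two
                         samples;
* ``per_power_series`` — the arithmetic mean across power settings counts
                         as one sample.

Non-detects are encoded as concentration 0 (no LOD/2 substitution; the
assessment assumes 100 % absorption of what is present).  Chromium samples
are flagged as hexavalent unconditionally, the more hazardous species.

The packaged per-chemical summaries carry a documented resolution: the
published aerosol summary rows for acetone and acrolein are transposed
relative to every downstream table, so the default ("as-used") variant
swaps them back (acrolein mean 0.373 µg/puff, acetone 0.242 µg/puff); the
as-printed variant remains loadable for comparison.
"""

from __future__ import annotations

import csv
import logging
import math
import statistics
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .registry import CHEMICALS

__all__ = [
    "MATRICES",
    "REPORT_KINDS",
    "CANONICAL_UNITS",
    "RawLiteratureRecord",
    "ConcentrationSample",
    "ConcentrationSummary",
    "NoData",
    "to_canonical",
    "from_canonical",
    "harmonize",
    "summarize",
    "load_samples_csv",
    "write_samples_csv",
    "load_packaged_summaries",
    "surrogate_samples",
]

logger = logging.getLogger(__name__)

MATRICES = ("aerosol", "e-liquid")
REPORT_KINDS = ("individual", "mean_only", "range_only", "per_power_series")

CANONICAL_UNITS = {"aerosol": "ug/puff", "e-liquid": "mg/ml"}

# multiplicative factor source-unit -> canonical unit
_UNIT_FACTORS = {
    "aerosol": {"ug/puff": 1.0, "ng/puff": 1e-3, "mg/puff": 1e3},
    # mg/g assumes e-liquid density 1 g/ml
    "e-liquid": {"mg/ml": 1.0, "ug/ml": 1e-3, "mg/g": 1.0},
}


class NoData(LookupError):
    """No samples available for the requested chemical/matrix."""


def _check_chem_matrix(chemical: str, matrix: str) -> None:
    if chemical not in CHEMICALS:
        raise ValueError(f"unknown chemical id: {chemical!r}")
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix: {matrix!r}")


@dataclass
class RawLiteratureRecord:
    """One reported result set from one source article, before harmonization."""

    chemical: str
    matrix: str
    report_kind: str
    values: list[float]
    unit: str
    study_id: str

    def __post_init__(self) -> None:
        _check_chem_matrix(self.chemical, self.matrix)
        if self.report_kind not in REPORT_KINDS:
            raise ValueError(f"unknown report kind: {self.report_kind!r}")
        if not self.values:
            raise ValueError("record has no values")
        for v in self.values:
            if not math.isfinite(v):
                raise ValueError(f"non-finite value in {self.study_id}")
            if v < 0:
                raise ValueError(f"negative concentration in {self.study_id}: {v}")
        if self.report_kind == "range_only":
            if len(self.values) != 2:
                raise ValueError("range_only record must have exactly 2 values")
            if self.values[0] > self.values[1]:
                raise ValueError("range_only record must be (min, max)")


@dataclass(frozen=True)
class ConcentrationSample:
    """One harmonized measurement in canonical units."""

    chemical: str
    matrix: str
    value: float
    study_id: str
    hexavalent: bool = False

    def __post_init__(self) -> None:
        _check_chem_matrix(self.chemical, self.matrix)
        if not (math.isfinite(self.value) and self.value >= 0):
            raise ValueError(f"invalid sample value {self.value!r}")


@dataclass(frozen=True)
class ConcentrationSummary:
    """Per-chemical summary of harmonized samples (canonical units)."""

    chemical: str
    matrix: str
    mean: float
    sd: float
    min: float
    max: float
    n_refs: int

    def __post_init__(self) -> None:
        _check_chem_matrix(self.chemical, self.matrix)
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"{self.chemical}/{self.matrix}: min <= mean <= max violated "
                f"({self.min}, {self.mean}, {self.max})"
            )
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_refs < 1:
            raise ValueError("n_refs must be >= 1")


def to_canonical(value: float, unit: str, matrix: str) -> float:
    """Convert a concentration to the matrix's canonical unit."""
    try:
        factor = _UNIT_FACTORS[matrix][unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r} for matrix {matrix!r}") from None
    return value * factor


def from_canonical(value: float, unit: str, matrix: str) -> float:
    """Inverse of :func:`to_canonical`."""
    try:
        factor = _UNIT_FACTORS[matrix][unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r} for matrix {matrix!r}") from None
    return value / factor


def harmonize(record: RawLiteratureRecord) -> list[ConcentrationSample]:
    """Apply the harmonization rules to one raw literature record."""
    canonical = [to_canonical(v, record.unit, record.matrix) for v in record.values]
    if record.report_kind == "individual":
        values = canonical
    elif record.report_kind == "mean_only":
        if len(canonical) != 1:
            raise ValueError("mean_only record must carry exactly one value")
        values = canonical
    elif record.report_kind == "range_only":
        values = [min(canonical), max(canonical)]
    else:  # per_power_series: the mean over power settings is one sample
        values = [sum(canonical) / len(canonical)]
    hexavalent = record.chemical == "Cr"
    return [
        ConcentrationSample(record.chemical, record.matrix, v, record.study_id, hexavalent)
        for v in values
    ]


def summarize(
    samples: Sequence[ConcentrationSample], chemical: str, matrix: str
) -> ConcentrationSummary:
    """Summarize harmonized samples for one chemical/matrix.

    ``sd`` is the sample (n−1) standard deviation, defined as 0 for a single
    sample so that summaries are total; ``n_refs`` counts distinct studies.
    """
    values = [s.value for s in samples if s.chemical == chemical and s.matrix == matrix]
    if not values:
        raise NoData(f"no samples for {chemical}/{matrix}")
    studies = {s.study_id for s in samples if s.chemical == chemical and s.matrix == matrix}
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return ConcentrationSummary(
        chemical=chemical,
        matrix=matrix,
        mean=sum(values) / len(values),
        sd=sd,
        min=min(values),
        max=max(values),
        n_refs=len(studies),
    )


_SAMPLES_HEADER = ("chemical", "matrix", "value", "unit", "study_id", "report_kind")


def load_samples_csv(path: str | Path) -> list[RawLiteratureRecord]:
    """Read sample-level records from CSV (one value per row).

    Rows sharing (chemical, matrix, study_id, report_kind) are combined into
    one record, so multi-value report kinds (ranges, power series) span
    several rows in file form.
    """
    path = Path(path)
    grouped: dict[tuple, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _SAMPLES_HEADER:
            raise ValueError(
                f"{path}: unexpected header {reader.fieldnames!r}; "
                f"expected {','.join(_SAMPLES_HEADER)}"
            )
        for row_no, row in enumerate(reader, start=2):
            key = (
                row["chemical"].strip(),
                row["matrix"].strip(),
                row["study_id"].strip(),
                row["report_kind"].strip(),
            )
            try:
                value = float(row["value"])
            except ValueError as exc:
                raise ValueError(f"{path} row {row_no}: bad value {row['value']!r}") from exc
            entry = grouped.setdefault(key, {"values": [], "unit": row["unit"].strip()})
            if entry["unit"] != row["unit"].strip():
                raise ValueError(f"{path} row {row_no}: mixed units within one record")
            entry["values"].append(value)
    records = []
    for (chemical, matrix, study_id, kind), entry in grouped.items():
        values = entry["values"]
        if kind == "range_only":
            values = sorted(values)
        records.append(
            RawLiteratureRecord(chemical, matrix, kind, values, entry["unit"], study_id)
        )
    if not records:
        logger.warning("%s: empty sample file", path)
    return records


def write_samples_csv(records: Iterable[RawLiteratureRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SAMPLES_HEADER)
        for rec in records:
            for v in rec.values:
                writer.writerow(
                    [rec.chemical, rec.matrix, repr(v), rec.unit, rec.study_id, rec.report_kind]
                )


def _load_summary_file(name: str, variant: str) -> list[ConcentrationSummary]:
    out = []
    with resources.as_file(resources.files("ecigrisk") / "tables" / name) as p:
        with Path(p).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                prefix = "" if variant == "as_used" else "printed_"
                out.append(
                    ConcentrationSummary(
                        chemical=row["chemical"],
                        matrix=row["matrix"],
                        mean=float(row[prefix + "mean"]),
                        sd=float(row[prefix + "sd"]),
                        min=float(row[prefix + "min"]),
                        max=float(row[prefix + "max"]),
                        n_refs=int(row["n_refs"]),
                    )
                )
    return out


def load_packaged_summaries(variant: str = "as_used") -> dict[tuple[str, str], ConcentrationSummary]:
    """Load the packaged per-chemical concentration summaries.

    ``variant="as_used"`` (default) applies the documented acetone/acrolein
    aerosol transposition fix; ``variant="as_printed"`` returns the summary
    rows exactly as published and warns, since the published aerosol rows
    for those two chemicals are inconsistent with every downstream result.
    """
    if variant not in ("as_used", "as_printed"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "as_printed":
        warnings.warn(
            "as-printed aerosol summaries transpose acetone and acrolein; "
            "downstream tables were computed from the as-used values",
            stacklevel=2,
        )
    summaries = _load_summary_file("aerosol_summary.csv", variant) + _load_summary_file(
        "eliquid_summary.csv", variant
    )
    return {(s.chemical, s.matrix): s for s in summaries}


def surrogate_samples(
    summary: ConcentrationSummary, n: int = 1000, seed: int = 0
) -> list[ConcentrationSample]:
    """Build a synthetic sample set matching a summary's moments.

    This is a fallback for distribution fitting when only summary statistics
    (mean, sd, min, max) are available: a lognormal is moment-matched to the
    positive part, a point mass at zero is added when the reported minimum
    is zero, and draws are clipped to the reported range.  The construction
    is a modelling device of this package, not a published procedure.
    """
    import numpy as np

    if summary.mean <= 0:
        return [
            ConcentrationSample(summary.chemical, summary.matrix, 0.0, f"surrogate:{i}")
            for i in range(n)
        ]
    rng = np.random.default_rng(seed)
    zero_frac = 0.1 if summary.min == 0 else 0.0
    pos_mean = summary.mean / (1 - zero_frac)
    cv = summary.sd / summary.mean if summary.mean > 0 else 1.0
    sigma2 = math.log1p(cv**2) if cv > 0 else 1e-6
    mu = math.log(pos_mean) - sigma2 / 2
    draws = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    draws = np.clip(draws, summary.min, summary.max)
    draws[rng.random(n) < zero_frac] = 0.0
    return [
        ConcentrationSample(
            summary.chemical, summary.matrix, float(v), f"surrogate:{i}",
            summary.chemical == "Cr",
        )
        for i, v in enumerate(draws)
    ]
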