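"""Chemical registry and route-specific toxicity reference values.

The study panel comprises four carbonyl/ketone compounds (formaldehyde,
acetaldehyde, acetone, acrolein) and seven heavy metals (As, Cd, Mn, Pb, Cu,
Ni, Cr).  Each chemical carries regulatory reference values by exposure
route: air-concentration thresholds (OEHHA REL, USEPA RfC, both µg/m³),
chronic dose thresholds (USEPA RfD, mg/kg·day), cancer potencies / slope
factors ((mg/kg·day)⁻¹) and acute lethal doses (LD50, mg/kg).

Non-cancer screening is deliberately conservative: where both an REL and an
RfC exist for the same chemical and route, the *smaller* of the two (after
conversion to a dose) is used as the reference dose.  Air-concentration
thresholds are converted to doses with the scenario's breathing volume and
body weight:  dose = c[µg/m³] × V[m³/day] / BW[kg] / 1000  (mg/kg·day).

A missing reference value ("–" in regulatory compilations) means the
corresponding risk is *not assessed* — it never silently becomes zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CHEMICAL_IDS",
    "CHEMICALS",
    "ROUTES",
    "Chemical",
    "ToxicityReference",
    "ReferenceDose",
    "NoReferenceAvailable",
    "load_reference_table",
    "write_reference_table",
    "merge_references",
    "load_packaged_references",
    "concentration_threshold_to_dose",
    "noncancer_reference_dose",
]

logger = logging.getLogger(__name__)

ROUTES = ("inhalation", "oral", "dermal")


@dataclass(frozen=True)
class Chemical:
    """One member of the study panel."""

    id: str
    display_name: str
    is_metal: bool
    notes: str = ""


CHEMICALS: Mapping[str, Chemical] = {
    c.id: c
    for c in (
        Chemical("formaldehyde", "Formaldehyde", False, "IARC group 1 carcinogen"),
        Chemical("acetaldehyde", "Acetaldehyde", False, "IARC group 2B carcinogen"),
        Chemical("acetone", "Acetone", False, "non-carcinogenic; no inhalation reference value"),
        Chemical("acrolein", "Acrolein", False, "IARC group 2A; assessed for non-cancer risk only"),
        Chemical("As", "Arsenic", True, ""),
        Chemical("Cd", "Cadmium", True, "IARC group 1 carcinogen (2017)"),
        Chemical("Mn", "Manganese", True, ""),
        Chemical("Pb", "Lead", True, "IARC group 2B carcinogen (2017)"),
        Chemical("Cu", "Copper", True, ""),
        Chemical("Ni", "Nickel", True, ""),
        Chemical("Cr", "Chromium", True, "treated as hexavalent throughout"),
    )
}

CHEMICAL_IDS = tuple(CHEMICALS)

_VALUE_FIELDS = (
    "rel_ug_m3",
    "rfc_ug_m3",
    "cpv_inh",
    "rfd_oral",
    "cpv_oral",
    "rfd_derm",
    "sf_derm",
    "ld50_oral",
    "ld50_derm",
)

CSV_HEADER = ("chemical",) + _VALUE_FIELDS + ("source",)


@dataclass
class ToxicityReference:
    """Per-chemical regulatory constants; ``None`` marks a value that does
    not exist (risk not assessable), never zero."""

    chemical: str
    rel_ug_m3: float | None = None
    rfc_ug_m3: float | None = None
    cpv_inh: float | None = None
    rfd_oral: float | None = None
    cpv_oral: float | None = None
    rfd_derm: float | None = None
    sf_derm: float | None = None
    ld50_oral: float | None = None
    ld50_derm: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.chemical not in CHEMICALS:
            raise ValueError(f"unknown chemical id: {self.chemical!r}")
        non_null = 0
        for name in _VALUE_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            non_null += 1
            if not v > 0:
                raise ValueError(
                    f"{self.chemical}: {name} must be strictly positive, got {v!r}"
                )
        if non_null == 0:
            raise ValueError(f"{self.chemical}: all reference values null")


@dataclass(frozen=True)
class ReferenceDose:
    """A non-cancer reference dose (mg/kg·day) with its provenance."""

    chemical: str
    route: str
    value: float
    provenance: str

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("reference dose must be positive")


class NoReferenceAvailable(LookupError):
    """No applicable threshold for this chemical/route; the hazard quotient
    cannot be computed and the cell is reported as not assessed."""


def _parse_field(raw: str, field: str, row_no: int) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValueError(f"row {row_no}: cannot parse {field}={raw!r}") from exc
    if value < 0:
        raise ValueError(f"row {row_no}: negative value {field}={value}")
    return value


def load_reference_table(path: str | Path) -> list[ToxicityReference]:
    """Read a toxicity-reference CSV in the documented dialect.

    Header ``chemical,rel_ug_m3,rfc_ug_m3,cpv_inh,rfd_oral,cpv_oral,
    rfd_derm,sf_derm,ld50_oral,ld50_derm,source``; empty field = null.
    Unknown chemical ids and negative values are hard errors naming the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_HEADER:
            raise ValueError(
                f"{path}: unexpected header {reader.fieldnames!r}; "
                f"expected {','.join(CSV_HEADER)}"
            )
        records: list[ToxicityReference] = []
        for row_no, row in enumerate(reader, start=2):
            chem = row["chemical"].strip()
            if chem not in CHEMICALS:
                raise ValueError(f"{path} row {row_no}: unknown chemical id {chem!r}")
            values = {
                f: _parse_field(row[f], f, row_no) for f in _VALUE_FIELDS
            }
            records.append(
                ToxicityReference(chemical=chem, source=row["source"].strip(), **values)
            )
    if not records:
        logger.warning("%s: empty reference table", path)
    return records


def write_reference_table(records: Iterable[ToxicityReference], path: str | Path) -> None:
    """Write records back to the CSV dialect (round-trips with the loader)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            row = [rec.chemical]
            for f in _VALUE_FIELDS:
                v = getattr(rec, f)
                row.append("" if v is None else repr(v))
            row.append(rec.source)
            writer.writerow(row)


def merge_references(tables: Iterable[Iterable[ToxicityReference]]) -> dict[str, ToxicityReference]:
    """Merge per-route tables into one record per chemical.

    A field may be set by at most one table; conflicting non-null values are
    a hard error (the packaged tables are disjoint by construction).
    """
    merged: dict[str, ToxicityReference] = {}
    for table in tables:
        for rec in table:
            if rec.chemical not in merged:
                merged[rec.chemical] = replace(rec)
                continue
            base = merged[rec.chemical]
            updates: dict[str, float] = {}
            for f in _VALUE_FIELDS:
                v = getattr(rec, f)
                if v is None:
                    continue
                existing = getattr(base, f)
                if existing is not None and existing != v:
                    raise ValueError(
                        f"{rec.chemical}: conflicting values for {f}: {existing} vs {v}"
                    )
                updates[f] = v
            source = base.source
            if rec.source and rec.source not in source:
                source = f"{source}; {rec.source}" if source else rec.source
            merged[rec.chemical] = replace(base, source=source, **updates)
    return merged


def _packaged(name: str):
    return resources.files("ecigrisk") / "tables" / name


def load_packaged_references() -> dict[str, ToxicityReference]:
    """Load and merge the packaged inhalation/dermal/oral reference tables."""
    tables = []
    for name in ("toxicity_inhalation.csv", "toxicity_dermal.csv", "toxicity_oral.csv"):
        with resources.as_file(_packaged(name)) as p:
            tables.append(load_reference_table(p))
    return merge_references(tables)


def concentration_threshold_to_dose(c_ug_m3: float, scenario) -> float:
    """Convert an air-concentration threshold (µg/m³) to a dose threshold
    (mg/kg·day) with the scenario's daily breathing volume and body weight."""
    return c_ug_m3 * scenario.breathing_volume / scenario.bw / 1000.0


def noncancer_reference_dose(
    chemical: str,
    route: str,
    ref: ToxicityReference,
    scenario,
) -> ReferenceDose:
    """Select the non-cancer reference dose for one chemical and route.

    Inhalation: every available air-concentration threshold (REL, RfC) is
    converted to a dose and the minimum is returned (conservative choice
    when agencies disagree).  Oral and dermal: the applicable RfD.

    Raises :class:`NoReferenceAvailable` when no threshold exists, which is
    distinct from a zero reference — callers must skip the hazard quotient.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route: {route!r}")
    if ref.chemical != chemical:
        raise ValueError("reference record does not match chemical")

    if route == "inhalation":
        candidates: list[tuple[float, str]] = []
        if ref.rel_ug_m3 is not None:
            candidates.append(
                (concentration_threshold_to_dose(ref.rel_ug_m3, scenario), "REL")
            )
        if ref.rfc_ug_m3 is not None:
            candidates.append(
                (concentration_threshold_to_dose(ref.rfc_ug_m3, scenario), "RfC")
            )
        if not candidates:
            raise NoReferenceAvailable(f"{chemical}/inhalation: no REL or RfC")
        value, provenance = min(candidates)
        return ReferenceDose(chemical, route, value, provenance)

    field = "rfd_oral" if route == "oral" else "rfd_derm"
    rfd = getattr(ref, field)
    if rfd is None:
        raise NoReferenceAvailable(f"{chemical}/{route}: no RfD")
    return ReferenceDose(chemical, route, rfd, "RfD")
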