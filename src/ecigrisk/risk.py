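"""Risk characterization: cancer risk, hazard quotients, acute risk, totals.

* Cancer risk        CR = potency × chronic dose; acceptable ≤ 1×10⁻⁶.
* Hazard quotient    HQ = chronic dose / reference dose; acceptable ≤ 1,
  adverse > 1, high concern > 10.
* Acute risk         AR = acute intake / LD50; unacceptable > 1.

Route totals add independent per-chemical risks with no interaction terms
(no synergy or antagonism is modelled): the hazard index HI is the sum of
HQs, and total CR / total AR are straight sums.  Chemicals lacking the
relevant reference value are excluded from the corresponding sum — they are
"not assessed", which is different from contributing zero.  Worst-case
totals combine every chemical's maximum concentration simultaneously, a
deliberately pessimistic co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .concentrations import ConcentrationSummary, load_packaged_summaries
from .exposure import (
    DoseResult,
    ExposureScenario,
    acute_intake,
    dd_dermal,
    dd_inhalation,
    dd_oral,
)
from .registry import (
    CHEMICAL_IDS,
    NoReferenceAvailable,
    ReferenceDose,
    ToxicityReference,
    load_packaged_references,
    noncancer_reference_dose,
)

__all__ = [
    "THRESHOLDS",
    "RiskResult",
    "AggregateReport",
    "cancer_risk",
    "hazard_quotient",
    "acute_risk",
    "aggregate",
    "assess_deterministic",
    "aggregate_frame",
]

#: Acceptability thresholds by risk kind.
THRESHOLDS = {"cancer": 1e-6, "noncancer": 1.0, "acute": 1.0}


@dataclass(frozen=True)
class RiskResult:
    """One chemical × route × kind risk value with its acceptability flag."""

    chemical: str
    route: str
    kind: str  # "cancer" | "noncancer" | "acute"
    value: float
    acceptable: bool
    reference_used: str = ""
    high_concern: bool = False  # noncancer only: HQ > 10

    def __post_init__(self) -> None:
        if self.kind not in THRESHOLDS:
            raise ValueError(f"unknown risk kind {self.kind!r}")
        if np.ndim(self.value) == 0 and self.value < 0:
            raise ValueError("risk value must be >= 0")


def _flag(kind: str, value: float) -> bool:
    return bool(value <= THRESHOLDS[kind])


def cancer_risk(dose: DoseResult, potency: float | None) -> RiskResult | None:
    """Excess lifetime cancer risk from a chronic dose and a cancer potency
    (slope factor), (mg/kg·day)⁻¹.  ``potency=None`` → not assessed."""
    if potency is None:
        return None
    if dose.regime != "chronic":
        raise ValueError("cancer risk requires a chronic dose")
    if not potency > 0:
        raise ValueError("potency must be positive")
    value = potency * dose.value
    return RiskResult(
        dose.chemical or "", dose.route, "cancer", value, _flag("cancer", np.max(value)),
        reference_used=f"potency={potency}",
    )


def hazard_quotient(dose: DoseResult, ref: ReferenceDose | None) -> RiskResult | None:
    """Non-cancer hazard quotient.  ``ref=None`` → not assessed."""
    if ref is None:
        return None
    if dose.regime != "chronic":
        raise ValueError("hazard quotient requires a chronic dose")
    value = dose.value / ref.value
    vmax = float(np.max(value))
    return RiskResult(
        dose.chemical or "", dose.route, "noncancer", value,
        _flag("noncancer", vmax), reference_used=ref.provenance,
        high_concern=vmax > 10,
    )


def acute_risk(intake: DoseResult, ld50: float | None) -> RiskResult | None:
    """Acute risk ratio against the route-specific LD50 (mg/kg)."""
    if ld50 is None:
        return None
    if intake.regime != "acute":
        raise ValueError("acute risk requires an acute intake")
    if not ld50 > 0:
        raise ValueError("LD50 must be positive")
    value = intake.value / ld50
    return RiskResult(
        intake.chemical or "", intake.route, "acute", value,
        _flag("acute", np.max(value)), reference_used=f"ld50={ld50}",
    )


@dataclass
class AggregateReport:
    """Totals for one route: hazard index, total cancer and acute risk, and
    each total's percentage share across routes."""

    route: str
    hi: float = 0.0
    total_cr: float = 0.0
    total_ar: float = 0.0
    n_assessed: Mapping[str, int] = field(default_factory=dict)
    shares: Mapping[str, float] = field(default_factory=dict)  # kind -> % of cross-route total
    notes: str = ""


_KIND_TOTAL = {"noncancer": "hi", "cancer": "total_cr", "acute": "total_ar"}


def aggregate(results: Iterable[RiskResult | None]) -> dict[str, AggregateReport]:
    """Sum assessed risks by route and kind; attach cross-route shares.

    ``None`` entries (not-assessed cells) are skipped.  Shares within a kind
    sum to 100 % across routes with a nonzero grand total.
    """
    reports: dict[str, AggregateReport] = {}
    counts: dict[str, dict[str, int]] = {}
    for res in results:
        if res is None:
            continue
        rep = reports.setdefault(res.route, AggregateReport(route=res.route))
        attr = _KIND_TOTAL[res.kind]
        setattr(rep, attr, getattr(rep, attr) + float(np.asarray(res.value)))
        counts.setdefault(res.route, {}).setdefault(res.kind, 0)
        counts[res.route][res.kind] += 1
    for route, rep in reports.items():
        rep.n_assessed = dict(counts.get(route, {}))
        if not rep.n_assessed:
            rep.notes = "no chemicals assessed"
    for kind, attr in _KIND_TOTAL.items():
        grand = sum(getattr(rep, attr) for rep in reports.values())
        for rep in reports.values():
            share = 100.0 * getattr(rep, attr) / grand if grand > 0 else 0.0
            rep.shares = {**rep.shares, kind: share}
    return reports


def _route_inputs(summary: ConcentrationSummary, stat: str) -> float:
    if stat not in ("mean", "max", "min"):
        raise ValueError(f"unknown statistic {stat!r}")
    return getattr(summary, stat)


def assess_deterministic(
    summaries: Mapping[tuple[str, str], ConcentrationSummary] | None = None,
    refs: Mapping[str, ToxicityReference] | None = None,
    scenario: ExposureScenario | None = None,
    mode: str = "paper_replication",
    stat: str = "mean",
    chemicals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Run the full deterministic pipeline on concentration summaries.

    Returns a tidy frame with one row per chemical × route × quantity:
    columns ``chemical, route, regime, kind, concentration, dose, value,
    acceptable, reference`` where ``kind`` is ``dose`` for exposure rows and
    ``cancer``/``noncancer``/``acute`` for risk rows.  Cells whose reference
    data do not exist are simply absent (not zero).

    ``stat="max"`` evaluates the worst-case: every chemical at its maximum
    reported concentration simultaneously.
    """
    if summaries is None:
        summaries = load_packaged_summaries()
    if refs is None:
        refs = load_packaged_references()
    if scenario is None:
        scenario = ExposureScenario.paper_default()
    if chemicals is None:
        chemicals = CHEMICAL_IDS

    rows: list[dict] = []

    def add_dose(chem: str, dose: DoseResult, conc: float) -> None:
        rows.append(
            {
                "chemical": chem, "route": dose.route, "regime": dose.regime,
                "kind": "dose", "concentration": conc, "dose": float(dose.value),
                "value": float(dose.value), "acceptable": None, "reference": "",
            }
        )

    def add_risk(res: RiskResult | None, dose: DoseResult, conc: float) -> None:
        if res is None:
            return
        rows.append(
            {
                "chemical": res.chemical, "route": res.route, "regime": dose.regime,
                "kind": res.kind, "concentration": conc, "dose": float(dose.value),
                "value": float(res.value), "acceptable": res.acceptable,
                "reference": res.reference_used,
            }
        )

    for chem in chemicals:
        ref = refs.get(chem)
        aero = summaries.get((chem, "aerosol"))
        liquid = summaries.get((chem, "e-liquid"))

        if aero is not None:
            p = _route_inputs(aero, stat)
            dose = dd_inhalation(p, scenario, chem)
            add_dose(chem, dose, p)
            if ref is not None:
                add_risk(cancer_risk(dose, ref.cpv_inh), dose, p)
                try:
                    rd = noncancer_reference_dose(chem, "inhalation", ref, scenario)
                except NoReferenceAvailable:
                    rd = None
                add_risk(hazard_quotient(dose, rd), dose, p)

        if liquid is not None:
            p = _route_inputs(liquid, stat)
            oral = dd_oral(p, scenario, chem)
            derm = dd_dermal(p, chem, scenario, mode)
            add_dose(chem, oral, p)
            add_dose(chem, derm, p)
            if ref is not None:
                add_risk(cancer_risk(oral, ref.cpv_oral), oral, p)
                add_risk(cancer_risk(derm, ref.sf_derm), derm, p)
                for route, rfd in (("oral", oral), ("dermal", derm)):
                    try:
                        rd = noncancer_reference_dose(chem, route, ref, scenario)
                    except NoReferenceAvailable:
                        rd = None
                    add_risk(hazard_quotient(rfd, rd), rfd, p)
                for route, ld50 in (("oral", ref.ld50_oral), ("dermal", ref.ld50_derm)):
                    intake = acute_intake(p, scenario, chem, route)
                    add_dose(chem, intake, p)
                    add_risk(acute_risk(intake, ld50), intake, p)

    return pd.DataFrame(
        rows,
        columns=[
            "chemical", "route", "regime", "kind", "concentration",
            "dose", "value", "acceptable", "reference",
        ],
    )


def aggregate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an :func:`assess_deterministic` frame into route totals."""
    results = [
        RiskResult(
            r.chemical, r.route, r.kind, r.value, bool(r.acceptable),
            reference_used=r.reference,
        )
        for r in frame.itertuples()
        if r.kind in THRESHOLDS
    ]
    reports = aggregate(results)
    out = []
    for route in ("inhalation", "dermal", "oral"):
        rep = reports.get(route)
        if rep is None:
            continue
        out.append(
            {
                "route": route,
                "hi": rep.hi, "hi_share_pct": rep.shares.get("noncancer", 0.0),
                "total_cr": rep.total_cr, "cr_share_pct": rep.shares.get("cancer", 0.0),
                "total_ar": rep.total_ar, "ar_share_pct": rep.shares.get("acute", 0.0),
                "notes": rep.notes,
            }
        )
    return pd.DataFrame(out)
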