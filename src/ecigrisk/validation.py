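"""Recompute published benchmark quantities from the packaged inputs.

Each check recomputes one published deterministic result — a mean dose, a
cancer risk, a hazard quotient, an acute risk, or the inhalation hazard
index — from the packaged concentration summaries, toxicity reference
tables and default exposure scenario, and compares it with the published
value at 1 % relative tolerance (absorbing the publication's own rounding
of intermediate values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .concentrations import load_packaged_summaries
from .exposure import ExposureScenario, acute_intake, dd_dermal, dd_inhalation
from .registry import load_packaged_references, noncancer_reference_dose
from .risk import (
    acute_risk,
    aggregate_frame,
    assess_deterministic,
    cancer_risk,
    hazard_quotient,
)

__all__ = ["ReferenceCheck", "reference_checks", "run_checks"]


@dataclass(frozen=True)
class ReferenceCheck:
    """One published value and the computation that should reproduce it."""

    name: str
    description: str
    expected: float
    units: str
    n_inputs: int  # number of source articles (or summed chemicals) behind the input
    rel_tol: float
    compute: Callable[[], float]


def _context():
    summaries = load_packaged_summaries()
    refs = load_packaged_references()
    scenario = ExposureScenario.paper_default()
    return summaries, refs, scenario


def reference_checks() -> list[ReferenceCheck]:
    summaries, refs, scenario = _context()

    def mean(chem: str, matrix: str) -> float:
        return summaries[(chem, matrix)].mean

    def inhalation_dose(chem: str) -> float:
        return dd_inhalation(mean(chem, "aerosol"), scenario, chem).value

    def inhalation_cr(chem: str) -> float:
        dose = dd_inhalation(mean(chem, "aerosol"), scenario, chem)
        return cancer_risk(dose, refs[chem].cpv_inh).value

    def inhalation_hq(chem: str) -> float:
        dose = dd_inhalation(mean(chem, "aerosol"), scenario, chem)
        rd = noncancer_reference_dose(chem, "inhalation", refs[chem], scenario)
        return hazard_quotient(dose, rd).value

    def inhalation_hi() -> float:
        frame = assess_deterministic(summaries, refs, scenario)
        agg = aggregate_frame(frame)
        return float(agg.loc[agg.route == "inhalation", "hi"].iloc[0])

    def oral_ar(chem: str) -> float:
        intake = acute_intake(mean(chem, "e-liquid"), scenario, chem, "oral")
        return acute_risk(intake, refs[chem].ld50_oral).value

    def dermal_ar(chem: str) -> float:
        intake = acute_intake(mean(chem, "e-liquid"), scenario, chem, "dermal")
        return acute_risk(intake, refs[chem].ld50_derm).value

    def dermal_cr(chem: str) -> float:
        dose = dd_dermal(mean(chem, "e-liquid"), chem, scenario, "paper_replication")
        return cancer_risk(dose, refs[chem].sf_derm).value

    n_refs = {
        (c, m): s.n_refs for (c, m), s in summaries.items()
    }

    return [
        ReferenceCheck(
            "formaldehyde_inhalation_dose",
            "mean chronic inhalation daily dose of formaldehyde",
            2.01e-3, "mg/kg day", n_refs[("formaldehyde", "aerosol")], 0.01,
            lambda: inhalation_dose("formaldehyde"),
        ),
        ReferenceCheck(
            "chromium_inhalation_cancer_risk",
            "mean inhalation cancer risk of hexavalent chromium",
            4.39e-4, "", n_refs[("Cr", "aerosol")], 0.01,
            lambda: inhalation_cr("Cr"),
        ),
        ReferenceCheck(
            "formaldehyde_inhalation_cancer_risk",
            "mean inhalation cancer risk of formaldehyde",
            4.22e-5, "", n_refs[("formaldehyde", "aerosol")], 0.01,
            lambda: inhalation_cr("formaldehyde"),
        ),
        ReferenceCheck(
            "nickel_inhalation_cancer_risk",
            "mean inhalation cancer risk of nickel",
            3.11e-5, "", n_refs[("Ni", "aerosol")], 0.01,
            lambda: inhalation_cr("Ni"),
        ),
        ReferenceCheck(
            "arsenic_inhalation_cancer_risk",
            "mean inhalation cancer risk of arsenic",
            6.74e-6, "", n_refs[("As", "aerosol")], 0.01,
            lambda: inhalation_cr("As"),
        ),
        ReferenceCheck(
            "acrolein_inhalation_hq",
            "mean inhalation hazard quotient of acrolein (min of REL/RfC doses)",
            151.97, "", n_refs[("acrolein", "aerosol")], 0.01,
            lambda: inhalation_hq("acrolein"),
        ),
        ReferenceCheck(
            "nickel_inhalation_hq",
            "mean inhalation hazard quotient of nickel",
            8.55, "", n_refs[("Ni", "aerosol")], 0.01,
            lambda: inhalation_hq("Ni"),
        ),
        ReferenceCheck(
            "formaldehyde_inhalation_hq",
            "mean inhalation hazard quotient of formaldehyde",
            0.78, "", n_refs[("formaldehyde", "aerosol")], 0.01,
            lambda: inhalation_hq("formaldehyde"),
        ),
        ReferenceCheck(
            "inhalation_hazard_index",
            "hazard index (sum of assessed HQs) for the inhalation route",
            170.63, "", 10, 0.01,
            inhalation_hi,
        ),
        ReferenceCheck(
            "formaldehyde_oral_acute_risk",
            "mean acute risk of formaldehyde by oral ingestion",
            9.65e-7, "", n_refs[("formaldehyde", "e-liquid")], 0.01,
            lambda: oral_ar("formaldehyde"),
        ),
        ReferenceCheck(
            "arsenic_dermal_acute_risk",
            "mean acute risk of arsenic by dermal contact",
            2.68e-8, "", n_refs[("As", "e-liquid")], 0.01,
            lambda: dermal_ar("As"),
        ),
        ReferenceCheck(
            "arsenic_dermal_cancer_risk",
            "mean dermal cancer risk of arsenic",
            2.43e-6, "", n_refs[("As", "e-liquid")], 0.01,
            lambda: dermal_cr("As"),
        ),
    ]


def run_checks() -> list[dict]:
    """Run every reference check; returns name, computed and published
    values, relative error and pass flag for each."""
    out = []
    for check in reference_checks():
        value = float(check.compute())
        rel_err = abs(value - check.expected) / abs(check.expected)
        out.append(
            {
                "name": check.name,
                "description": check.description,
                "computed": value,
                "published": check.expected,
                "units": check.units,
                "rel_err": rel_err,
                "passed": rel_err <= check.rel_tol,
                "n_inputs": check.n_inputs,
            }
        )
    return out
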