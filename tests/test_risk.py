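"""Risk characterization and route aggregation."""

import numpy as np
import pytest

from ecigrisk.exposure import DoseResult, acute_intake, dd_inhalation
from ecigrisk.registry import ReferenceDose, noncancer_reference_dose
from ecigrisk.risk import (
    RiskResult,
    acute_risk,
    aggregate,
    aggregate_frame,
    assess_deterministic,
    cancer_risk,
    hazard_quotient,
)


def chronic(value, chemical="Cr", route="inhalation"):
    return DoseResult(chemical, route, "chronic", value)


class TestCancerRisk:
    def test_published_chromium_value(self):
        res = cancer_risk(chronic(8.62e-7), 510.0)
        assert res.value == pytest.approx(4.39e-4, rel=2e-3)
        assert not res.acceptable  # far above 1e-6

    def test_published_arsenic_oral_value(self):
        res = cancer_risk(chronic(1.94e-8, "As", "oral"), 1.50)
        assert res.value == pytest.approx(2.91e-8, rel=2e-3)
        assert res.acceptable

    def test_zero_dose_zero_risk(self):
        res = cancer_risk(chronic(0.0), 510.0)
        assert res.value == 0.0 and res.acceptable

    def test_missing_potency_not_assessed(self):
        assert cancer_risk(chronic(1e-3), None) is None

    def test_rejects_acute_dose(self):
        with pytest.raises(ValueError, match="chronic"):
            cancer_risk(DoseResult("As", "oral", "acute", 1e-3), 1.5)


class TestHazardQuotient:
    def test_published_acrolein_value(self, refs, scenario):
        dose = chronic(8.685e-4, "acrolein")
        rd = noncancer_reference_dose("acrolein", "inhalation", refs["acrolein"], scenario)
        res = hazard_quotient(dose, rd)
        assert res.value == pytest.approx(151.97, rel=2e-3)
        assert not res.acceptable and res.high_concern

    def test_published_formaldehyde_value(self, refs, scenario):
        rd = noncancer_reference_dose(
            "formaldehyde", "inhalation", refs["formaldehyde"], scenario
        )
        res = hazard_quotient(chronic(2.01e-3, "formaldehyde"), rd)
        assert res.value == pytest.approx(0.78, rel=5e-3)
        assert res.acceptable and not res.high_concern

    def test_published_cadmium_dermal_value(self):
        rd = ReferenceDose("Cd", "dermal", 1e-5, "RfD")
        res = hazard_quotient(chronic(1.85e-6, "Cd", "dermal"), rd)
        assert res.value == pytest.approx(0.185, rel=1e-3)

    def test_missing_reference_not_assessed(self):
        assert hazard_quotient(chronic(1e-3), None) is None


class TestAcuteRisk:
    def test_published_formaldehyde_oral(self, scenario):
        intake = acute_intake(5.41e-3, scenario, "formaldehyde", "oral")
        res = acute_risk(intake, 800.0)
        assert res.value == pytest.approx(9.65e-7, rel=2e-3)
        assert res.acceptable

    def test_published_arsenic_dermal(self, scenario):
        intake = acute_intake(2.72e-5, scenario, "As", "dermal")
        res = acute_risk(intake, 145.0)
        assert res.value == pytest.approx(2.68e-8, rel=2e-3)

    def test_zero_intake(self, scenario):
        res = acute_risk(acute_intake(0.0, scenario), 46.0)
        assert res.value == 0.0

    def test_missing_ld50_not_assessed(self, scenario):
        assert acute_risk(acute_intake(1.0, scenario), None) is None


def risk(chemical, route, kind, value):
    return RiskResult(chemical, route, kind, value, acceptable=value <= 1)


class TestAggregate:
    def test_single_result_route(self):
        reports = aggregate([risk("Cu", "oral", "noncancer", 2.0)])
        assert reports["oral"].hi == 2.0
        assert reports["oral"].shares["noncancer"] == pytest.approx(100.0)

    def test_none_entries_skipped(self):
        reports = aggregate([None, risk("Cu", "oral", "noncancer", 1.0), None])
        assert reports["oral"].n_assessed == {"noncancer": 1}

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(11)
        chems = ["As", "Cd", "Cu", "Ni", "Cr"]
        results, expected = [], {}
        for route in ("inhalation", "oral", "dermal"):
            for kind in ("cancer", "noncancer", "acute"):
                if kind == "acute" and route == "inhalation":
                    continue
                for chem in chems:
                    v = float(rng.exponential(1.0))
                    results.append(risk(chem, route, kind, v))
                    expected[(route, kind)] = expected.get((route, kind), 0.0) + v
        reports = aggregate(results)
        for (route, kind), total in expected.items():
            attr = {"noncancer": "hi", "cancer": "total_cr", "acute": "total_ar"}[kind]
            assert getattr(reports[route], attr) == pytest.approx(total)
        for kind in ("noncancer", "cancer", "acute"):
            share_sum = sum(rep.shares[kind] for rep in reports.values())
            assert share_sum == pytest.approx(100.0, abs=0.1)

    def test_removing_a_chemical_never_increases_totals(self):
        results = [risk(c, "oral", "noncancer", v)
                   for c, v in [("As", 0.5), ("Cd", 1.5), ("Cu", 0.2)]]
        full = aggregate(results)["oral"].hi
        for i in range(len(results)):
            reduced = aggregate(results[:i] + results[i + 1:])["oral"].hi
            assert reduced <= full

    def test_hi_at_least_max_component(self):
        values = [0.4, 3.0, 0.1]
        reports = aggregate(
            [risk(c, "inhalation", "noncancer", v)
             for c, v in zip(["As", "Cd", "Cu"], values)]
        )
        assert reports["inhalation"].hi >= max(values)


class TestFullPipeline:
    def test_published_route_totals(self, summaries, refs, scenario):
        frame = assess_deterministic(summaries, refs, scenario)
        agg = aggregate_frame(frame).set_index("route")
        assert agg.loc["inhalation", "hi"] == pytest.approx(170.63, rel=0.01)
        assert agg.loc["inhalation", "total_cr"] == pytest.approx(5.35e-4, rel=0.01)
        assert agg.loc["inhalation", "hi_share_pct"] == pytest.approx(99.70, abs=0.1)
        assert agg.loc["inhalation", "cr_share_pct"] == pytest.approx(87.05, abs=0.5)
        # acute inhalation is not modelled at all
        assert agg.loc["inhalation", "total_ar"] == 0.0

    def test_acetone_inhalation_hq_absent(self, summaries, refs, scenario):
        frame = assess_deterministic(summaries, refs, scenario)
        sub = frame[(frame.chemical == "acetone") & (frame.route == "inhalation")]
        assert "noncancer" not in set(sub.kind)
        assert "cancer" not in set(sub.kind)

    def test_worst_case_totals_dominate_means(self, summaries, refs, scenario):
        mean_agg = aggregate_frame(
            assess_deterministic(summaries, refs, scenario, stat="mean")
        ).set_index("route")
        max_agg = aggregate_frame(
            assess_deterministic(summaries, refs, scenario, stat="max")
        ).set_index("route")
        for route in ("inhalation", "oral", "dermal"):
            for col in ("hi", "total_cr", "total_ar"):
                assert max_agg.loc[route, col] >= mean_agg.loc[route, col]

    def test_empty_chemical_list_gives_empty_tables(self, summaries, refs, scenario):
        frame = assess_deterministic(summaries, refs, scenario, chemicals=[])
        assert frame.empty
        assert aggregate_frame(frame).empty
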