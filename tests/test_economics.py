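"""Dosing, drug-cost bridging, SAE costs, discounting, accrual, ICER."""

import numpy as np
import pytest

from escc_cea.economics import (
    CEAResult,
    EconParams,
    Policies,
    accrue,
    ae_cost_one_time,
    chemo_dose_mg,
    compare,
    cost_per_administration,
    discount_factor,
    drug_cost_per_model_cycle,
    run_strategy,
)
from escc_cea.markov import MarkovTrace, RegimenComponent, StrategySpec

from conftest import CTP_OS, CTP_PFS

PACLITAXEL = RegimenComponent("paclitaxel", 108.26, 100, "per_m2", 175, 21, 6)
CISPLATIN = RegimenComponent("cisplatin", 10.97, 100, "per_m2", 75, 21, 6)
CAMRELIZUMAB = RegimenComponent("camrelizumab", 424.35, 200, "flat_mg", 200, 21, None)


def zero_econ(**kw):
    base = dict(
        unit_costs={k: 0.0 for k in (
            "followup_per_cycle", "labs_radiology", "salvage_per_cycle",
            "bsc_per_cycle", "terminal_care")},
        ae_unit_costs={},
        u_pfs=0.0, u_pd=0.0, discount_rate=0.0,
    )
    base.update(kw)
    return EconParams(**base)


class TestDosing:
    @pytest.mark.parametrize(
        "comp,expected",
        [(PACLITAXEL, 301.0), (CISPLATIN, 129.0), (CAMRELIZUMAB, 200.0)],
    )
    def test_dose_mg_at_reference_bsa(self, comp, expected):
        assert chemo_dose_mg(comp, 1.72) == pytest.approx(expected)

    def test_bsa_must_be_positive(self):
        with pytest.raises(ValueError):
            chemo_dose_mg(PACLITAXEL, 0.0)


class TestDrugCostPerCycle:
    def test_camrelizumab_monthly_cost(self):
        # (200/200) * 424.35 * (365.25/12)/21, frozen independent evaluation
        assert drug_cost_per_model_cycle(CAMRELIZUMAB, 1.72) == pytest.approx(
            615.0549107142857, abs=1e-9
        )

    def test_vial_rounding_charges_whole_vials(self):
        # 301 mg of paclitaxel -> 4 vials of 100 mg
        assert cost_per_administration(PACLITAXEL, 1.72, vial_rounding=True) == (
            pytest.approx(4 * 108.26)
        )
        assert cost_per_administration(PACLITAXEL, 1.72) == pytest.approx(3.01 * 108.26)

    def test_schedule_exhaustion(self):
        # 6 administrations at ~1.449/month are spent during cycle 5
        a = (365.25 / 12) / 21
        per_adm = cost_per_administration(PACLITAXEL, 1.72)
        for t in (1, 2, 3, 4):
            assert drug_cost_per_model_cycle(PACLITAXEL, 1.72, t) == pytest.approx(per_adm * a)
        assert drug_cost_per_model_cycle(PACLITAXEL, 1.72, 5) == pytest.approx(
            per_adm * (6 - 4 * a)
        )
        assert drug_cost_per_model_cycle(PACLITAXEL, 1.72, 6) == 0.0
        total = sum(drug_cost_per_model_cycle(PACLITAXEL, 1.72, t) for t in range(1, 61))
        assert total == pytest.approx(6 * per_adm, rel=1e-12)

    def test_per_cycle_bridging(self):
        assert drug_cost_per_model_cycle(
            CAMRELIZUMAB, 1.72, bridging="per_cycle"
        ) == pytest.approx(424.35)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            drug_cost_per_model_cycle(CAMRELIZUMAB, 1.72, bridging="weekly")


class TestAECost:
    def test_published_risk_tables(self):
        costs = {"anemia": 508.2, "wbc": 466.00, "neut": 534.40}
        ctp = StrategySpec("ctp", CTP_PFS, CTP_OS,
                           ae_risks={"anemia": 0.174, "wbc": 0.242, "neut": 0.399})
        ptp = StrategySpec("ptp", CTP_PFS, CTP_OS,
                           ae_risks={"anemia": 0.135, "wbc": 0.266, "neut": 0.434})
        assert ae_cost_one_time(ctp, costs) == pytest.approx(414.4244, abs=1e-10)
        assert ae_cost_one_time(ptp, costs) == pytest.approx(424.4926, abs=1e-10)

    def test_zero_risks(self):
        spec = StrategySpec("x", CTP_PFS, CTP_OS, ae_risks={"anemia": 0.0})
        assert ae_cost_one_time(spec, {"anemia": 508.2}) == 0.0

    def test_key_mismatch_raises(self):
        spec = StrategySpec("x", CTP_PFS, CTP_OS, ae_risks={"rash": 0.1})
        with pytest.raises(KeyError):
            ae_cost_one_time(spec, {"anemia": 508.2})


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03, abs=1e-12)
        assert discount_factor(60, 0.03) == pytest.approx(1.03 ** -5, abs=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestAccrue:
    def test_all_zero_inputs_give_zero_result(self):
        spec = StrategySpec("x", CTP_PFS, CTP_OS)
        econ = zero_econ()
        _, res = run_strategy(spec, econ)
        assert res.cost_total == 0.0 and res.qaly_total == 0.0

    def test_full_pfs_year_yields_utility(self):
        """A cohort pinned in PFS for 12 undiscounted cycles accrues u_pfs QALYs."""
        occ = np.zeros((13, 3))
        occ[:, 0] = 1.0
        trace = MarkovTrace(occ, np.zeros(13), np.zeros(13))
        econ = zero_econ(u_pfs=0.68, horizon_cycles=12)
        spec = StrategySpec("x", CTP_PFS, CTP_OS)
        res = accrue(trace, spec, econ)
        assert res.qaly_pfs == pytest.approx(0.68, abs=1e-12)
        assert res.qaly_pd == 0.0

    def test_horizon_mismatch_raises(self):
        occ = np.zeros((13, 3))
        occ[:, 0] = 1.0
        trace = MarkovTrace(occ, np.zeros(13), np.zeros(13))
        with pytest.raises(ValueError):
            accrue(trace, StrategySpec("x", CTP_PFS, CTP_OS), zero_econ(horizon_cycles=60))

    def test_discounting_never_increases_totals(self, cfg):
        arm = cfg.arms[0]
        _, disc = run_strategy(arm, cfg.econ, cfg.policies)
        cfg.econ.discount_rate = 0.0
        _, undisc = run_strategy(arm, cfg.econ, cfg.policies)
        assert disc.cost_total < undisc.cost_total
        assert disc.qaly_total < undisc.qaly_total

    def test_monotone_in_utilities_and_costs(self, cfg):
        """Finite-difference monotonicity of totals in utilities and unit costs."""
        arm = cfg.arms[0]
        _, base = run_strategy(arm, cfg.econ, cfg.policies)
        cfg.econ.u_pd += 0.05
        _, bumped = run_strategy(arm, cfg.econ, cfg.policies)
        assert bumped.qaly_total > base.qaly_total
        assert bumped.cost_total == pytest.approx(base.cost_total)
        cfg.econ.unit_costs["salvage_per_cycle"] += 100.0
        _, bumped2 = run_strategy(arm, cfg.econ, cfg.policies)
        assert bumped2.cost_total > bumped.cost_total

    def test_state_components_sum_to_totals(self, cfg):
        for arm in cfg.arms:
            _, res = run_strategy(arm, cfg.econ, cfg.policies)
            assert res.cost_total == pytest.approx(res.cost_pfs + res.cost_pd, abs=1e-6)
            assert res.qaly_total == pytest.approx(res.qaly_pfs + res.qaly_pd, abs=1e-6)

    def test_membership_conventions_ordered(self, cfg):
        """cycle_start credits the most PFS time, cycle_end the least."""
        arm = cfg.arms[0]
        out = {}
        for mode in ("cycle_start", "trapezoidal", "cycle_end"):
            cfg.policies.membership = mode
            _, out[mode] = run_strategy(arm, cfg.econ, cfg.policies)
        assert out["cycle_start"].qaly_pfs > out["trapezoidal"].qaly_pfs > out["cycle_end"].qaly_pfs
        mid = 0.5 * (out["cycle_start"].qaly_pfs + out["cycle_end"].qaly_pfs)
        assert out["trapezoidal"].qaly_pfs == pytest.approx(mid, abs=1e-12)


class TestCompare:
    def test_identical_results_equivalent(self):
        r = CEAResult(10.0, 5.0, 0.5, 0.2)
        out = compare(r, r)
        assert out.status == "equivalent" and np.isnan(out.icer)

    def test_icer_uses_unrounded_deltas(self):
        # the published incremental cost over the unrounded QALY delta
        a = CEAResult(7110.56, 0.0, 0.15235, 0.0)
        b = CEAResult(0.0, 0.0, 0.0, 0.0)
        out = compare(a, b)
        assert out.icer == pytest.approx(7110.56 / 0.15235, rel=1e-12)
        assert out.icer == pytest.approx(46671.0, abs=5.0)

    def test_dominance_flags(self):
        cheap_effective = CEAResult(5.0, 0.0, 1.0, 0.0)
        dear_ineffective = CEAResult(10.0, 0.0, 0.5, 0.0)
        assert compare(cheap_effective, dear_ineffective).status == "dominant"
        assert compare(dear_ineffective, cheap_effective).status == "dominated"

    def test_zero_qaly_delta_is_undefined_not_a_crash(self):
        a = CEAResult(10.0, 0.0, 0.5, 0.0)
        b = CEAResult(5.0, 0.0, 0.5, 0.0)
        out = compare(a, b)
        assert out.status == "undefined" and np.isnan(out.icer)

    def test_identical_arms_zero_deltas(self, cfg):
        cfg.arms[1] = cfg.arms[0]
        from escc_cea.model import base_case

        cmpres = base_case(cfg).comparison
        assert cmpres.delta_cost == 0.0 and cmpres.delta_qaly == 0.0


class TestEconParamsValidation:
    def test_utility_bounds(self):
        with pytest.raises(ValueError):
            zero_econ(u_pfs=1.2)

    def test_missing_unit_cost_key(self):
        with pytest.raises(ValueError):
            EconParams(unit_costs={"followup_per_cycle": 1.0}, ae_unit_costs={})
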