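"""Cost and QALY accrual over a Markov trace, discounting, and the ICER.

Costs (2020 USD) follow the Chinese healthcare-system perspective:

* while progression-free: drug acquisition (camrelizumab and/or the
  paclitaxel-cisplatin doublet, dosed by body surface area and bridged from
  the 3-weekly schedule into the monthly cycle), routine follow-up, and
  laboratory/radiology work-up, all per cycle;
* after progression: salvage chemotherapy plus best supportive care per
  cycle;
* one-time: grade 3-4 serious-adverse-event management at model entry
  (incidence x unit management cost) and terminal care attached to incident
  deaths in the cycle they occur.

Utilities are per-year weights (PFS 0.68, PD 0.42 in the base case); a
monthly cycle contributes utility/12. Everything is discounted at
(1+r)^(-t/12) for cycle t.

State membership convention (``Policies.membership``):

``cycle_start`` (default)
    A cycle's rewards accrue on the occupancy at the cycle's start — the
    convention of cycle-tree cohort software, which credits members who
    transition during a cycle with that full cycle.
``trapezoidal``
    Classic half-cycle correction: the average of the occupancy at the
    start and end of the cycle.
``cycle_end``
    Occupancy after the cycle's transitions.

One-time costs (SAE, terminal care) are exempt from the membership
convention; they attach to the whole entering cohort or to the incident
death fraction respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .markov import (
    MarkovTrace,
    RegimenComponent,
    StrategySpec,
    monthly_background_mortality,
    run_trace,
)

__all__ = [
    "EconParams",
    "Policies",
    "CEAResult",
    "ComparisonResult",
    "DAYS_PER_MONTH",
    "chemo_dose_mg",
    "cost_per_administration",
    "drug_cost_per_model_cycle",
    "ae_cost_one_time",
    "discount_factor",
    "accrue",
    "compare",
    "run_strategy",
]

DAYS_PER_MONTH = 365.25 / 12.0

MEMBERSHIP_MODES = ("cycle_start", "trapezoidal", "cycle_end")
LABS_MODES = ("per_cycle_pfs", "one_time")
BRIDGING_MODES = ("calendar", "per_cycle")

REQUIRED_UNIT_COSTS = (
    "followup_per_cycle",
    "labs_radiology",
    "salvage_per_cycle",
    "bsc_per_cycle",
    "terminal_care",
)


@dataclass
class Policies:
    """Accrual/transition conventions the published tables leave unstated."""

    pd_death_rule: str = "os_calibrated"
    membership: str = "cycle_start"
    vial_rounding: bool = False
    labs_accrual: str = "per_cycle_pfs"
    bridging: str = "calendar"
    subtract_bg_from_progression: bool = True

    def __post_init__(self) -> None:
        if self.membership not in MEMBERSHIP_MODES:
            raise ValueError(f"unknown membership mode {self.membership!r}")
        if self.labs_accrual not in LABS_MODES:
            raise ValueError(f"unknown labs_accrual mode {self.labs_accrual!r}")
        if self.bridging not in BRIDGING_MODES:
            raise ValueError(f"unknown bridging mode {self.bridging!r}")


@dataclass
class EconParams:
    """Unit costs, utilities, and run settings shared by both arms."""

    unit_costs: dict[str, float]
    ae_unit_costs: dict[str, float]
    u_pfs: float = 0.68
    u_pd: float = 0.42
    bsa: float = 1.72
    discount_rate: float = 0.03
    wtp: float = 31498.70
    horizon_cycles: int = 60
    cycle_months: float = 1.0
    bg_annual_mortality: float = 0.00707

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_UNIT_COSTS if k not in self.unit_costs]
        if missing:
            raise ValueError(f"unit_costs missing keys: {missing}")
        if any(v < 0 for v in self.unit_costs.values()):
            raise ValueError("unit costs must be non-negative")
        if any(v < 0 for v in self.ae_unit_costs.values()):
            raise ValueError("SAE unit costs must be non-negative")
        for name, u in (("u_pfs", self.u_pfs), ("u_pd", self.u_pd)):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {name}={u} outside [0, 1]")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        if self.bsa <= 0:
            raise ValueError("body surface area must be positive")
        if not 0.0 <= self.bg_annual_mortality < 1.0:
            raise ValueError("background annual mortality must lie in [0, 1)")

    @property
    def bg_monthly(self) -> float:
        return monthly_background_mortality(self.bg_annual_mortality)


@dataclass(frozen=True)
class CEAResult:
    """Discounted cost and QALY totals, broken down by health state.

    One-time costs are bucketed with the state they belong to clinically:
    SAE management with PFS (treatment start), terminal care with PD
    (end of life).
    """

    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental cost, incremental QALYs and the ICER of arm a vs arm b.

    ``status`` is ``"icer"`` when the ratio is meaningful, ``"dominant"``
    (cheaper and more effective), ``"dominated"`` (dearer and less
    effective), ``"equivalent"`` (both deltas zero) or ``"undefined"``
    (zero QALY delta with a nonzero cost delta). ``icer`` is NaN except in
    the ``"icer"`` case.
    """

    delta_cost: float
    delta_qaly: float
    icer: float
    status: str


def chemo_dose_mg(component: RegimenComponent, bsa: float) -> float:
    """Absolute dose in mg: flat doses pass through, mg/m^2 doses scale by BSA."""
    if bsa <= 0:
        raise ValueError("body surface area must be positive")
    if component.dose_mode == "flat_mg":
        return component.dose
    return component.dose * bsa


def cost_per_administration(
    component: RegimenComponent, bsa: float, vial_rounding: bool = False
) -> float:
    """Drug cost of one administration.

    Continuous pricing charges fractional units (dose/unit_size x price);
    vial rounding charges whole vials, ceiling(dose/unit_size).
    """
    units = chemo_dose_mg(component, bsa) / component.unit_size
    if vial_rounding:
        units = math.ceil(units - 1e-9)
    return units * component.price_per_unit


def _administrations_per_cycle(component: RegimenComponent, bridging: str) -> float:
    if bridging == "per_cycle":
        return 1.0
    return DAYS_PER_MONTH / component.schedule_days


def drug_cost_per_model_cycle(
    component: RegimenComponent,
    bsa: float,
    cycle: int = 1,
    vial_rounding: bool = False,
    bridging: str = "calendar",
) -> float:
    """USD accrued by one on-treatment patient for this drug during a cycle.

    Under calendar bridging a q3w drug delivers (365.25/12)/schedule_days
    administrations per month; a finite max_administrations budget is drawn
    down on that calendar until exhausted, after which the cost is zero.
    """
    if bridging not in BRIDGING_MODES:
        raise ValueError(f"unknown bridging mode {bridging!r}")
    if cycle < 1:
        raise ValueError("cycle index must be >= 1")
    a = _administrations_per_cycle(component, bridging)
    if component.max_administrations is None:
        adm = a
    else:
        used_before = a * (cycle - 1)
        adm = min(a, max(0.0, component.max_administrations - used_before))
    return cost_per_administration(component, bsa, vial_rounding) * adm


def ae_cost_one_time(spec: StrategySpec, ae_unit_costs: dict[str, float]) -> float:
    """Expected one-time SAE management cost: sum of incidence x unit cost."""
    missing = [k for k in spec.ae_risks if k not in ae_unit_costs]
    if missing:
        raise KeyError(
            f"no unit cost for SAE(s) {missing}; available: {sorted(ae_unit_costs)}"
        )
    return sum(risk * ae_unit_costs[k] for k, risk in spec.ae_risks.items())


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor (1+r)^(-cycle/12) for a monthly cycle index."""
    if cycle < 0:
        raise ValueError("cycle index must be >= 0")
    return (1.0 + annual_rate) ** (-cycle / 12.0)


def _membership(occ: np.ndarray, t: int, mode: str) -> np.ndarray:
    if mode == "cycle_start":
        return occ[t - 1]
    if mode == "trapezoidal":
        return 0.5 * (occ[t - 1] + occ[t])
    return occ[t]


def accrue(
    trace: MarkovTrace,
    spec: StrategySpec,
    econ: EconParams,
    policies: Policies | None = None,
) -> CEAResult:
    """Accrue discounted costs and QALYs over a trace for one arm."""
    policies = policies or Policies()
    H = econ.horizon_cycles
    if trace.horizon != H:
        raise ValueError(
            f"trace horizon {trace.horizon} != econ horizon {H}"
        )
    uc = econ.unit_costs
    pd_cost_rate = uc["salvage_per_cycle"] + uc["bsc_per_cycle"]
    pfs_overhead = uc["followup_per_cycle"]
    if policies.labs_accrual == "per_cycle_pfs":
        pfs_overhead += uc["labs_radiology"]

    cost_pfs = cost_pd = qaly_pfs = qaly_pd = 0.0
    for t in range(1, H + 1):
        df = discount_factor(t, econ.discount_rate)
        m = _membership(trace.occupancy, t, policies.membership)
        drug = sum(
            drug_cost_per_model_cycle(
                comp, econ.bsa, t, policies.vial_rounding, policies.bridging
            )
            for comp in spec.regimen
        )
        cost_pfs += (drug + pfs_overhead) * m[0] * df
        cost_pd += (
            pd_cost_rate * m[1] + uc["terminal_care"] * trace.incident_deaths[t]
        ) * df
        qaly_pfs += econ.u_pfs / 12.0 * m[0] * df
        qaly_pd += econ.u_pd / 12.0 * m[1] * df

    df1 = discount_factor(1, econ.discount_rate)
    cost_pfs += ae_cost_one_time(spec, econ.ae_unit_costs) * df1
    if policies.labs_accrual == "one_time":
        cost_pfs += uc["labs_radiology"] * df1

    return CEAResult(cost_pfs, cost_pd, qaly_pfs, qaly_pd)


def compare(a: CEAResult, b: CEAResult) -> ComparisonResult:
    """Incremental comparison of arm a against reference arm b."""
    dc = a.cost_total - b.cost_total
    dq = a.qaly_total - b.qaly_total
    if dq == 0.0 and dc == 0.0:
        return ComparisonResult(dc, dq, float("nan"), "equivalent")
    if dq == 0.0:
        return ComparisonResult(dc, dq, float("nan"), "undefined")
    if dc <= 0.0 and dq > 0.0:
        return ComparisonResult(dc, dq, float("nan"), "dominant")
    if dc >= 0.0 and dq < 0.0:
        return ComparisonResult(dc, dq, float("nan"), "dominated")
    return ComparisonResult(dc, dq, dc / dq, "icer")


def run_strategy(
    spec: StrategySpec, econ: EconParams, policies: Policies | None = None
) -> tuple[MarkovTrace, CEAResult]:
    """Trace + accrual for one arm under the given economics and policies."""
    policies = policies or Policies()
    trace = run_trace(
        spec,
        horizon_cycles=econ.horizon_cycles,
        bg_monthly=econ.bg_monthly,
        pd_death_rule=policies.pd_death_rule,
        subtract_bg=policies.subtract_bg_from_progression,
    )
    return trace, accrue(trace, spec, econ, policies)
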