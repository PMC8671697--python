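"""Three-state Markov cohort engine: PFS -> PD -> Death.

The cohort starts fully progression-free. Each monthly cycle a fraction
progresses (driven by the PFS Weibull), a fraction dies, and death is
absorbing. Death is fed from two channels:

* PFS occupants die only of background (all-cause) mortality — the trial's
  progression-free curve already nets out disease deaths before progression,
  which are rare in first-line ESCC;
* PD occupants die at a rate set by the ``pd_death_rule`` policy.

``pd_death_rule`` policies
--------------------------
``os_calibrated`` (default)
    Each cycle the cohort-level death toll is pinned to the overall-survival
    Weibull: the PD death probability is solved so that total deaths equal
    alive * (1 - S_os(t)/S_os(t-1)) after background deaths in PFS are
    counted, clipped to [0, 1]. The alive fraction then tracks S_os(t)
    essentially exactly, which is what the trial's OS curve measures.
``os_hazard``
    The per-cycle OS transition probability is applied directly to PD
    occupants. Simpler, but the cohort then dies more slowly than S_os
    because the hazard never touches the PFS pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .survival import WeibullParams, cycle_transition_prob, survival_at

__all__ = [
    "RegimenComponent",
    "StrategySpec",
    "MarkovTrace",
    "monthly_background_mortality",
    "transition_row_pfs",
    "transition_row_pd",
    "run_trace",
]

PD_DEATH_RULES = ("os_calibrated", "os_hazard")


@dataclass(frozen=True)
class RegimenComponent:
    """One drug line of a treatment regimen.

    ``dose`` is mg for ``dose_mode='flat_mg'`` or mg/m^2 for ``'per_m2'``;
    ``max_administrations`` is an integer cap or None for
    treat-until-progression; ``schedule_days`` is the days between
    administrations (21 for the usual q3w oncology schedule).
    """

    drug: str
    price_per_unit: float
    unit_size: float
    dose_mode: str
    dose: float
    schedule_days: float = 21.0
    max_administrations: int | None = None

    def __post_init__(self) -> None:
        if self.dose_mode not in ("flat_mg", "per_m2"):
            raise ValueError(f"unknown dose_mode {self.dose_mode!r}")
        if self.price_per_unit < 0:
            raise ValueError("price_per_unit must be non-negative")
        if self.dose <= 0 or self.schedule_days <= 0 or self.unit_size <= 0:
            raise ValueError("dose, unit_size and schedule_days must be positive")
        if self.max_administrations is not None and self.max_administrations <= 0:
            raise ValueError("max_administrations must be positive or None")


@dataclass
class StrategySpec:
    """One treatment arm: survival parameters, SAE risk table, regimen."""

    name: str
    pfs: WeibullParams
    os: WeibullParams
    ae_risks: dict[str, float] = field(default_factory=dict)
    regimen: list[RegimenComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, v in self.ae_risks.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SAE risk {k}={v} outside [0, 1]")


@dataclass
class MarkovTrace:
    """Cohort occupancy per cycle plus incident transition fractions.

    ``occupancy`` has shape (horizon+1, 3) with columns (PFS, PD, Death);
    row 0 is the initial distribution (1, 0, 0).
    """

    occupancy: np.ndarray
    incident_deaths: np.ndarray
    incident_progressions: np.ndarray

    STATES = ("pfs", "pd", "death")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "pfs": self.occupancy[:, 0],
                "pd": self.occupancy[:, 1],
                "death": self.occupancy[:, 2],
                "incident_deaths": self.incident_deaths,
                "incident_progressions": self.incident_progressions,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def monthly_background_mortality(annual_rate: float) -> float:
    """Convert an annual all-cause death probability to a monthly one.

    Compounding, not division: 1 - (1 - annual)**(1/12), so twelve monthly
    steps recompose the annual probability exactly.
    """
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError("annual rate must lie in [0, 1)")
    return 1.0 - (1.0 - annual_rate) ** (1.0 / 12.0)


def transition_row_pfs(
    t: int, spec: StrategySpec, bg: float, subtract_bg: bool = True
) -> tuple[float, float, float]:
    """(stay, to_pd, to_death) for a PFS occupant at cycle t.

    Death from PFS is background mortality only; the PFS-curve transition
    probability is (by default) net of that background so the two channels
    are not double-counted.
    """
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    p_event = cycle_transition_prob(t, spec.pfs)
    to_death = bg
    to_pd = max(0.0, p_event - bg) if subtract_bg else min(p_event, 1.0 - bg)
    stay = 1.0 - to_pd - to_death
    return stay, to_pd, to_death


def transition_row_pd(t: int, spec: StrategySpec) -> tuple[float, float]:
    """(stay, to_death) for a PD occupant at cycle t under the os_hazard rule."""
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    to_death = cycle_transition_prob(t, spec.os)
    return 1.0 - to_death, to_death


def run_trace(
    spec: StrategySpec,
    horizon_cycles: int = 60,
    bg_monthly: float = monthly_background_mortality(0.00707),
    pd_death_rule: str = "os_calibrated",
    subtract_bg: bool = True,
) -> MarkovTrace:
    """Run the deterministic cohort trace over the horizon.

    The cohort is continuous (state fractions, no microsimulation); every
    occupancy row sums to 1 and Death is absorbing.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon must be >= 1 cycle")
    if pd_death_rule not in PD_DEATH_RULES:
        raise ValueError(f"unknown pd_death_rule {pd_death_rule!r}")

    H = horizon_cycles
    occ = np.zeros((H + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    inc_death = np.zeros(H + 1)
    inc_prog = np.zeros(H + 1)

    for t in range(1, H + 1):
        pfs, pd, dead = occ[t - 1]
        stay, to_pd, to_death = transition_row_pfs(t, spec, bg_monthly, subtract_bg)

        if pd_death_rule == "os_hazard":
            q = transition_row_pd(t, spec)[1]
        else:  # os_calibrated
            alive = pfs + pd
            h_os = cycle_transition_prob(t, spec.os)
            pd_deaths_needed = alive * h_os - pfs * to_death
            q = min(1.0, max(0.0, pd_deaths_needed / pd)) if pd > 0 else 0.0

        new_pd = pfs * to_pd
        deaths = pfs * to_death + pd * q
        occ[t] = (
            pfs * stay,
            pd * (1.0 - q) + new_pd,
            dead + deaths,
        )
        inc_death[t] = deaths
        inc_prog[t] = new_pd

    return MarkovTrace(occ, inc_death, inc_prog)
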