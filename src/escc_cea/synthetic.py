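"""Synthetic inputs: digitized-KM-like point series and random full scenarios.

The published analysis started from survival curves read off trial figures
with a graph digitizer. :func:`generate_km_points` emulates that raw
material — evenly spaced (time, survival) readings of a known Weibull
curve perturbed by Gaussian pixel-reading error, rounded, and forced
monotone — so curve fitting can be exercised end-to-end without any
external image or download. The noise model is deliberately simple:
independent error on the survival axis, no censoring structure, because
digitization reads a drawn line rather than reconstructing patient-level
data.

:func:`generate_scenario` builds a random but admissible two-arm model
configuration (plausible medians, OS dominating PFS, positive costs,
u_pfs > u_pd) for property-style testing of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DistributionSpec, ModelConfig, RunSettings, get_param
from .economics import EconParams, Policies
from .markov import RegimenComponent, StrategySpec
from .survival import SurvivalCurveData, WeibullParams, survival_at

__all__ = ["DigitizationSpec", "generate_km_points", "generate_scenario"]


@dataclass(frozen=True)
class DigitizationSpec:
    """Recipe for one synthetic digitized curve.

    ``noise_sd`` is in survival-fraction units (0.01 corresponds to reading
    a printed axis to about one percentage point); ``rounding`` the decimal
    places kept, mimicking digitizer output precision.
    """

    true_params: WeibullParams
    max_time: float = 20.0
    n_points: int = 20
    noise_sd: float = 0.01
    rounding: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


def generate_km_points(
    spec: DigitizationSpec, endpoint_label: str = "PFS", arm_label: str = "synthetic"
) -> SurvivalCurveData:
    """Emulate digitizer readings of a Weibull survival curve.

    Evenly spaced times over (0, max_time]; survival = S_true(t) plus
    Gaussian noise, clipped to [0, 1], rounded, then forced non-increasing
    by a running minimum. The exact anchor (0, 1.0) is prepended.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(spec.max_time / spec.n_points, spec.max_time, spec.n_points)
    surv = survival_at(times, spec.true_params)
    if spec.noise_sd > 0:
        surv = surv + rng.normal(0.0, spec.noise_sd, size=surv.shape)
    surv = np.clip(surv, 0.0, 1.0)
    surv = np.round(surv, spec.rounding)
    surv = np.minimum.accumulate(surv)
    points = [(0.0, 1.0)] + list(zip(times.tolist(), surv.tolist()))
    return SurvivalCurveData(points=points, endpoint_label=endpoint_label, arm_label=arm_label)


def _weibull_from_median(median: float, shape: float) -> WeibullParams:
    return WeibullParams(scale=math.log(2.0) / median**shape, shape=shape)


def generate_scenario(seed: int) -> ModelConfig:
    """Random admissible two-arm scenario in the packaged config schema.

    Weibull shapes in [0.8, 2.5]; PFS medians in [3, 24] months with the
    OS median at least as large per arm; arm A carries an extra flat-dose
    agent until progression (the intervention-cost analogue); utilities
    satisfy u_pfs > u_pd. Distributions are +/-20% triangles for costs and
    moment-matched betas for risks/utilities, so the scenario is PSA-ready.
    """
    rng = np.random.default_rng(seed)

    def arm(name: str, with_extra: bool) -> StrategySpec:
        pfs_median = rng.uniform(3.0, 24.0)
        os_median = rng.uniform(pfs_median, 24.0 * 1.5)
        pfs = _weibull_from_median(pfs_median, rng.uniform(0.8, 2.5))
        os = _weibull_from_median(os_median, rng.uniform(0.8, 2.5))
        regimen = [
            RegimenComponent(
                drug="doublet_a",
                price_per_unit=float(rng.uniform(50, 300)),
                unit_size=100.0,
                dose_mode="per_m2",
                dose=float(rng.uniform(50, 200)),
                schedule_days=21.0,
                max_administrations=int(rng.integers(4, 9)),
            ),
            RegimenComponent(
                drug="doublet_b",
                price_per_unit=float(rng.uniform(5, 50)),
                unit_size=100.0,
                dose_mode="per_m2",
                dose=float(rng.uniform(40, 100)),
                schedule_days=21.0,
                max_administrations=int(rng.integers(4, 9)),
            ),
        ]
        if with_extra:
            regimen.insert(
                0,
                RegimenComponent(
                    drug="checkpoint_x",
                    price_per_unit=float(rng.uniform(200, 800)),
                    unit_size=200.0,
                    dose_mode="flat_mg",
                    dose=200.0,
                    schedule_days=21.0,
                    max_administrations=None,
                ),
            )
        risks = {
            "anemia": float(rng.uniform(0.05, 0.5)),
            "neutropenia": float(rng.uniform(0.05, 0.5)),
        }
        return StrategySpec(name=name, pfs=pfs, os=os, ae_risks=risks, regimen=regimen)

    u_pd = float(rng.uniform(0.2, 0.6))
    u_pfs = float(rng.uniform(u_pd + 0.05, 0.95))
    econ = EconParams(
        unit_costs={
            "followup_per_cycle": float(rng.uniform(20, 150)),
            "labs_radiology": float(rng.uniform(100, 600)),
            "salvage_per_cycle": float(rng.uniform(200, 1200)),
            "bsc_per_cycle": float(rng.uniform(50, 400)),
            "terminal_care": float(rng.uniform(500, 3000)),
        },
        ae_unit_costs={
            "anemia": float(rng.uniform(200, 900)),
            "neutropenia": float(rng.uniform(200, 900)),
        },
        u_pfs=u_pfs,
        u_pd=u_pd,
        bsa=float(rng.uniform(1.4, 2.1)),
        discount_rate=0.03,
        wtp=float(rng.uniform(10000, 100000)),
        horizon_cycles=60,
        bg_annual_mortality=0.00707,
    )
    config = ModelConfig(
        name=f"synthetic-{seed}",
        arms=[arm("arm-a", True), arm("arm-b", False)],
        econ=econ,
        policies=Policies(),
        run=RunSettings(seed=seed, psa_n=200),
    )

    def tri(base: float) -> DistributionSpec:
        return DistributionSpec("triangle", base, 0.8 * base, 1.2 * base)

    def beta(base: float) -> DistributionSpec:
        return DistributionSpec("beta", base, max(0.0, 0.8 * base), min(1.0, 1.2 * base))

    dists: dict[str, DistributionSpec] = {}
    for drug in ("checkpoint_x", "doublet_a", "doublet_b"):
        dists[f"drug_price.{drug}"] = tri(get_param(config, f"drug_price.{drug}"))
    for k, v in econ.unit_costs.items():
        dists[f"cost.{k}"] = tri(v)
    for k, v in econ.ae_unit_costs.items():
        dists[f"ae_cost.{k}"] = tri(v)
    for a in config.arms:
        for k, v in a.ae_risks.items():
            dists[f"ae_risk.{a.name}.{k}"] = beta(v)
    dists["utility.pfs"] = beta(u_pfs)
    dists["utility.pd"] = beta(u_pd)
    dists["bsa"] = tri(econ.bsa)
    dists["discount_rate"] = DistributionSpec("fixed", 0.03, 0.0, 0.08)
    config.distributions = dists
    config.validate()
    return config
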