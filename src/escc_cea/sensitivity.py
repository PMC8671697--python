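"""Sensitivity analyses: tornado DSA, probabilistic analysis, CEAC, price search.

* :func:`one_way_dsa` re-runs the deterministic model with each parameter
  pushed to its lower and upper bound (Table-style printed ranges where
  available, otherwise +/-20% of base) and ranks parameters by the span of
  the resulting ICERs — the tornado diagram's data.
* :func:`run_psa` draws every distribution jointly (triangle for costs,
  moment-matched beta for probabilities and utilities, fixed parameters
  held), runs the full model per draw, and records (delta cost,
  delta QALY) pairs.
* :func:`ceac` converts those draws into a cost-effectiveness
  acceptability curve using the strict net-monetary-benefit rule
  w*dQALY - dCost > 0.
* :func:`threshold_price` bisects a drug price until the deterministic
  ICER meets a willingness-to-pay target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import (
    DistributionSpec,
    ModelConfig,
    get_param,
    param_names,
    set_param,
)
from .model import base_case

__all__ = [
    "DistributionSpec",
    "TornadoEntry",
    "PSAResults",
    "CEACPoint",
    "default_dsa_parameters",
    "one_way_dsa",
    "sample_params",
    "run_psa",
    "ceac",
    "prob_cost_effective",
    "threshold_price",
    "default_wtp_grid",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class PSAResults:
    """(delta cost, delta QALY) per probabilistic draw."""

    draws: np.ndarray  # shape (n, 2): columns (delta_cost, delta_qaly)
    seed: int
    n: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=["delta_cost", "delta_qaly"])


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_ce: float


def default_wtp_grid() -> np.ndarray:
    """$0 to $100,000 per QALY in $1,000 steps."""
    return np.arange(0.0, 100001.0, 1000.0)


def _icer_signed(config: ModelConfig) -> float:
    """ICER as a plain ratio (delta cost / delta QALY), NaN if dQALY == 0.

    For tornado/threshold work the raw ratio is what the published figures
    plot, including when a bound makes the intervention dominant.
    """
    cmp = base_case(config).comparison
    if cmp.delta_qaly == 0.0:
        return float("nan")
    return cmp.delta_cost / cmp.delta_qaly


def _bounds_for(config: ModelConfig, name: str) -> tuple[float, float]:
    if name in config.distributions:
        d = config.distributions[name]
        return d.low, d.high
    base = get_param(config, name)
    return base * 0.8, base * 1.2


def default_dsa_parameters(config: ModelConfig) -> list[str]:
    """Every distribution-listed parameter plus the PFS-duration scale."""
    names = list(config.distributions)
    if "pfs_duration" not in names:
        names.append("pfs_duration")
    return names


def one_way_dsa(
    config: ModelConfig, params_to_vary: list[str] | None = None
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis, sorted by descending span."""
    if params_to_vary is None:
        params_to_vary = default_dsa_parameters(config)
    known = set(param_names(config))
    entries = []
    for name in params_to_vary:
        if name not in known:
            raise KeyError(f"unknown parameter {name!r}")
        low, high = _bounds_for(config, name)
        icers = []
        for bound in (low, high):
            cfg = config.copy()
            set_param(cfg, name, bound)
            icers.append(_icer_signed(cfg))
        entries.append(TornadoEntry(name, low, high, icers[0], icers[1]))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def _sample_one(dist: DistributionSpec, rng: np.random.Generator) -> float:
    if dist.kind == "fixed" or dist.low == dist.high:
        return dist.base
    if dist.kind == "triangle":
        return float(rng.triangular(dist.low, dist.base, dist.high))
    # beta, moment-matched: mean = base, sd = (high-low)/(2*1.96)
    m = dist.base
    sd = (dist.high - dist.low) / (2.0 * 1.96)
    v = sd * sd
    if not 0.0 < m < 1.0 or v >= m * (1.0 - m):
        log.warning(
            "infeasible beta moments (mean=%g, sd=%g); falling back to uniform(%g, %g)",
            m, sd, dist.low, dist.high,
        )
        return float(rng.uniform(dist.low, dist.high))
    nu = m * (1.0 - m) / v - 1.0
    draw = float(rng.beta(m * nu, (1.0 - m) * nu))
    return min(1.0, max(0.0, draw))


def sample_params(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One joint probabilistic draw: a concrete config with sampled values."""
    cfg = config.copy()
    for name, dist in config.distributions.items():
        set_param(cfg, name, _sample_one(dist, rng))
    return cfg


def run_psa(config: ModelConfig, n: int = 1000, seed: int | None = None) -> PSAResults:
    """n joint draws, full deterministic model per draw; reproducible by seed."""
    if seed is None:
        seed = config.run.seed
    rng = np.random.default_rng(seed)
    draws = np.empty((n, 2))
    for i in range(n):
        cfg = sample_params(config, rng)
        cmp = base_case(cfg).comparison
        draws[i] = (cmp.delta_cost, cmp.delta_qaly)
    return PSAResults(draws=draws, seed=seed, n=n)


def ceac(psa: PSAResults, wtp_grid=None) -> list[CEACPoint]:
    """Probability of positive net monetary benefit across a WTP grid.

    Strict rule: a draw counts as cost-effective at w iff
    w * dQALY - dCost > 0; ties count as not cost-effective.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    dc = psa.draws[:, 0]
    dq = psa.draws[:, 1]
    points = []
    for w in wtp_grid:
        nmb = w * dq - dc
        points.append(CEACPoint(float(w), float(np.mean(nmb > 0.0))))
    return points


def prob_cost_effective(psa: PSAResults, wtp: float) -> float:
    """Fraction of draws with positive net monetary benefit at one WTP."""
    nmb = wtp * psa.draws[:, 1] - psa.draws[:, 0]
    return float(np.mean(nmb > 0.0))


def threshold_price(
    config: ModelConfig,
    target_wtp: float | None = None,
    param: str = "drug_price.camrelizumab",
    bracket: tuple[float, float] | None = None,
    tol: float = 1.0,
    max_iter: int = 200,
) -> float:
    """Parameter value at which the deterministic ICER equals ``target_wtp``.

    Bisection on the (monotone) ICER-vs-price curve until the re-run model
    gives an ICER within ``tol`` $/QALY of the target. Raises if the
    bracket does not straddle the target.
    """
    if target_wtp is None:
        target_wtp = config.econ.wtp
    base_value = get_param(config, param)
    if bracket is None:
        bracket = (1e-6, max(2.0 * base_value, 1.0))

    def f(value: float) -> float:
        cfg = config.copy()
        set_param(cfg, param, value)
        return _icer_signed(cfg) - target_wtp

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if not np.isfinite(flo) or not np.isfinite(fhi) or flo * fhi > 0:
        raise ValueError(
            f"ICER - target does not change sign over bracket {bracket}: "
            f"f(lo)={flo:.2f}, f(hi)={fhi:.2f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) < tol:
            return mid
        if flo * fmid <= 0:
            hi, fhi = mid, fmid
        else:
            lo, flo = mid, fmid
    raise RuntimeError("bisection failed to reach tolerance")
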