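"""Model configuration: schema, validation, YAML round-trip, parameter registry.

A :class:`ModelConfig` bundles everything one deterministic run needs —
two treatment arms (survival parameters, SAE risks, regimen), the shared
economic parameters, the accrual policy switches, and the sensitivity
distributions. The packaged default ``escort1st.yaml`` encodes the
first-line advanced-ESCC comparison of camrelizumab+chemotherapy versus
placebo+chemotherapy.

Every quantity the sensitivity analyses may vary is addressable through a
flat string registry (:func:`param_names`, :func:`get_param`,
:func:`set_param`), e.g. ``"drug_price.camrelizumab"``, ``"utility.pfs"``,
``"ae_risk.camrelizumab-chemotherapy.anemia"`` or the synthetic
``"pfs_duration"`` scale that stretches the progression-free time axis.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .economics import EconParams, Policies
from .markov import RegimenComponent, StrategySpec
from .survival import WeibullParams

__all__ = [
    "DistributionSpec",
    "RunSettings",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config",
    "config_to_dict",
    "config_from_dict",
    "param_names",
    "get_param",
    "set_param",
]

log = logging.getLogger(__name__)

DISTRIBUTION_KINDS = ("triangle", "beta", "fixed")


class ConfigError(ValueError):
    """Configuration file or schema violation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter for the probabilistic analysis.

    Triangle draws on (low, base, high); beta draws moment-matched to mean
    ``base`` and SD ``(high-low)/(2*1.96)`` for quantities on [0, 1];
    ``fixed`` never varies (the discount rate in the default scenario).
    """

    kind: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in DISTRIBUTION_KINDS:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        if not self.low <= self.base <= self.high:
            raise ConfigError(
                f"distribution bounds must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.kind == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError("beta distributions are restricted to [0, 1] quantities")


@dataclass
class RunSettings:
    seed: int = 2021
    psa_n: int = 1000

    def __post_init__(self) -> None:
        if self.psa_n < 0:
            raise ConfigError("psa_n must be >= 0")


@dataclass
class ModelConfig:
    """Full model specification: two arms, economics, policies, distributions."""

    name: str
    arms: list[StrategySpec]
    econ: EconParams
    policies: Policies = field(default_factory=Policies)
    run: RunSettings = field(default_factory=RunSettings)
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    pfs_time_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.arms) != 2:
            raise ConfigError(f"exactly two arms required, got {len(self.arms)}")
        if len({a.name for a in self.arms}) != 2:
            raise ConfigError("arm names must be distinct")
        for arm in self.arms:
            if "." in arm.name:
                raise ConfigError(f"arm name {arm.name!r} must not contain '.'")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check distribution keys resolve and bases match the deterministic values."""
        names = set(param_names(self))
        for key, dist in self.distributions.items():
            if key not in names:
                raise ConfigError(
                    f"distribution key {key!r} does not name a model parameter"
                )
            base = get_param(self, key)
            if abs(dist.base - base) > 1e-9 * max(1.0, abs(base)):
                raise ConfigError(
                    f"distribution base for {key!r} is {dist.base} but the "
                    f"deterministic value is {base}"
                )


# ---------------------------------------------------------------------------
# parameter registry


def param_names(config: ModelConfig) -> list[str]:
    """All registry-addressable parameter names for this configuration."""
    names: list[str] = []
    drugs: list[str] = []
    for arm in config.arms:
        for comp in arm.regimen:
            if comp.drug not in drugs:
                drugs.append(comp.drug)
    names += [f"drug_price.{d}" for d in drugs]
    names += [f"cost.{k}" for k in config.econ.unit_costs]
    names += [f"ae_cost.{k}" for k in config.econ.ae_unit_costs]
    for arm in config.arms:
        names += [f"ae_risk.{arm.name}.{k}" for k in arm.ae_risks]
    names += ["utility.pfs", "utility.pd", "bsa", "discount_rate", "pfs_duration"]
    return names


def get_param(config: ModelConfig, name: str) -> float:
    kind, _, rest = name.partition(".")
    if kind == "drug_price":
        for arm in config.arms:
            for comp in arm.regimen:
                if comp.drug == rest:
                    return comp.price_per_unit
        raise KeyError(f"no drug named {rest!r} in any regimen")
    if kind == "cost":
        return config.econ.unit_costs[rest]
    if kind == "ae_cost":
        return config.econ.ae_unit_costs[rest]
    if kind == "ae_risk":
        arm_name, _, sae = rest.rpartition(".")
        for arm in config.arms:
            if arm.name == arm_name:
                return arm.ae_risks[sae]
        raise KeyError(f"no arm named {arm_name!r}")
    if name == "utility.pfs":
        return config.econ.u_pfs
    if name == "utility.pd":
        return config.econ.u_pd
    if name == "bsa":
        return config.econ.bsa
    if name == "discount_rate":
        return config.econ.discount_rate
    if name == "pfs_duration":
        return config.pfs_time_scale
    raise KeyError(f"unknown parameter {name!r}")


def set_param(config: ModelConfig, name: str, value: float) -> None:
    """Set a registry parameter in place on ``config`` (use ``config.copy()`` first)."""
    kind, _, rest = name.partition(".")
    if kind == "drug_price":
        found = False
        for arm in config.arms:
            for i, comp in enumerate(arm.regimen):
                if comp.drug == rest:
                    arm.regimen[i] = replace(comp, price_per_unit=value)
                    found = True
        if not found:
            raise KeyError(f"no drug named {rest!r} in any regimen")
        return
    if kind == "cost":
        if rest not in config.econ.unit_costs:
            raise KeyError(f"unknown unit cost {rest!r}")
        config.econ.unit_costs[rest] = value
        return
    if kind == "ae_cost":
        if rest not in config.econ.ae_unit_costs:
            raise KeyError(f"unknown SAE cost {rest!r}")
        config.econ.ae_unit_costs[rest] = value
        return
    if kind == "ae_risk":
        arm_name, _, sae = rest.rpartition(".")
        for arm in config.arms:
            if arm.name == arm_name:
                if sae not in arm.ae_risks:
                    raise KeyError(f"unknown SAE {sae!r} for arm {arm_name!r}")
                arm.ae_risks[sae] = value
                return
        raise KeyError(f"no arm named {arm_name!r}")
    if name == "utility.pfs":
        config.econ.u_pfs = value
        return
    if name == "utility.pd":
        config.econ.u_pd = value
        return
    if name == "bsa":
        config.econ.bsa = value
        return
    if name == "discount_rate":
        config.econ.discount_rate = value
        return
    if name == "pfs_duration":
        # stretch the PFS time axis: median x s  <=>  scale -> scale * s**(-shape)
        factor = value / config.pfs_time_scale
        for arm in config.arms:
            arm.pfs = WeibullParams(
                scale=arm.pfs.scale * factor ** (-arm.pfs.shape),
                shape=arm.pfs.shape,
            )
        config.pfs_time_scale = value
        return
    raise KeyError(f"unknown parameter {name!r}")


# ---------------------------------------------------------------------------
# YAML serialization

_WEIBULL_KEYS = {"scale", "shape", "se_scale", "se_shape", "ci_scale", "ci_shape"}
_REGIMEN_KEYS = {
    "drug",
    "price_per_unit",
    "unit_size",
    "dose_mode",
    "dose",
    "schedule_days",
    "max_administrations",
}
_ARM_KEYS = {"name", "pfs", "os", "ae_risks", "regimen"}
_ECON_KEYS = {
    "unit_costs",
    "ae_unit_costs",
    "utilities",
    "bsa",
    "discount_rate",
    "wtp",
    "horizon_cycles",
    "cycle_months",
    "bg_annual_mortality",
}
_RUN_KEYS = {"seed", "psa_n", "policies"}
_POLICY_KEYS = {
    "pd_death_rule",
    "membership",
    "vial_rounding",
    "labs_accrual",
    "bridging",
    "subtract_bg_from_progression",
}
_TOP_KEYS = {"name", "arms", "econ", "run", "distributions"}
_DIST_KEYS = {"kind", "base", "low", "high"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _weibull_from_dict(d: dict, where: str) -> WeibullParams:
    _check_keys(d, _WEIBULL_KEYS, where)
    kw = dict(d)
    for k in ("ci_scale", "ci_shape"):
        if kw.get(k) is not None:
            kw[k] = tuple(float(x) for x in kw[k])
    try:
        return WeibullParams(**kw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


def _arm_from_dict(d: dict) -> StrategySpec:
    _check_keys(d, _ARM_KEYS, f"arm {d.get('name', '?')!r}")
    name = d["name"]
    regimen = []
    for rd in d.get("regimen", []):
        _check_keys(rd, _REGIMEN_KEYS, f"regimen of arm {name!r}")
        regimen.append(RegimenComponent(**rd))
    return StrategySpec(
        name=name,
        pfs=_weibull_from_dict(d["pfs"], f"pfs of arm {name!r}"),
        os=_weibull_from_dict(d["os"], f"os of arm {name!r}"),
        ae_risks={k: float(v) for k, v in d.get("ae_risks", {}).items()},
        regimen=regimen,
    )


def config_from_dict(d: dict) -> ModelConfig:
    _check_keys(d, _TOP_KEYS, "top level")
    for req in ("arms", "econ"):
        if req not in d:
            raise ConfigError(f"missing required section {req!r}")

    econ_d = dict(d["econ"])
    _check_keys(econ_d, _ECON_KEYS, "econ")
    utilities = econ_d.pop("utilities", {})
    extra = set(utilities) - {"pfs", "pd"}
    if extra:
        raise ConfigError(f"unknown utility key(s) {sorted(extra)}")
    try:
        econ = EconParams(
            unit_costs={k: float(v) for k, v in econ_d.pop("unit_costs").items()},
            ae_unit_costs={k: float(v) for k, v in econ_d.pop("ae_unit_costs").items()},
            u_pfs=float(utilities.get("pfs", 0.68)),
            u_pd=float(utilities.get("pd", 0.42)),
            **econ_d,
        )
    except (TypeError, ValueError, KeyError) as e:
        raise ConfigError(f"econ: {e}") from e

    run_d = dict(d.get("run", {}))
    _check_keys(run_d, _RUN_KEYS, "run")
    pol_d = run_d.pop("policies", {})
    _check_keys(pol_d, _POLICY_KEYS, "run.policies")
    try:
        policies = Policies(**pol_d)
        run = RunSettings(**run_d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"run: {e}") from e

    dists = {}
    for key, dd in (d.get("distributions") or {}).items():
        _check_keys(dd, _DIST_KEYS, f"distribution {key!r}")
        dists[key] = DistributionSpec(**{k: (dd[k] if k == "kind" else float(dd[k])) for k in dd})

    cfg = ModelConfig(
        name=d.get("name", "unnamed"),
        arms=[_arm_from_dict(a) for a in d["arms"]],
        econ=econ,
        policies=policies,
        run=run,
        distributions=dists,
    )
    cfg.validate()
    return cfg


def config_to_dict(config: ModelConfig) -> dict:
    def weibull(w: WeibullParams) -> dict:
        out = {"scale": w.scale, "shape": w.shape}
        if w.se_scale or w.se_shape:
            out.update(se_scale=w.se_scale, se_shape=w.se_shape)
        if w.ci_scale is not None:
            out["ci_scale"] = list(w.ci_scale)
        if w.ci_shape is not None:
            out["ci_shape"] = list(w.ci_shape)
        return out

    return {
        "name": config.name,
        "arms": [
            {
                "name": a.name,
                "pfs": weibull(a.pfs),
                "os": weibull(a.os),
                "ae_risks": dict(a.ae_risks),
                "regimen": [dataclasses.asdict(c) for c in a.regimen],
            }
            for a in config.arms
        ],
        "econ": {
            "unit_costs": dict(config.econ.unit_costs),
            "ae_unit_costs": dict(config.econ.ae_unit_costs),
            "utilities": {"pfs": config.econ.u_pfs, "pd": config.econ.u_pd},
            "bsa": config.econ.bsa,
            "discount_rate": config.econ.discount_rate,
            "wtp": config.econ.wtp,
            "horizon_cycles": config.econ.horizon_cycles,
            "cycle_months": config.econ.cycle_months,
            "bg_annual_mortality": config.econ.bg_annual_mortality,
        },
        "run": {
            "seed": config.run.seed,
            "psa_n": config.run.psa_n,
            "policies": dataclasses.asdict(config.policies),
        },
        "distributions": {
            k: {"kind": v.kind, "base": v.base, "low": v.low, "high": v.high}
            for k, v in config.distributions.items()
        },
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    cfg = config_from_dict(raw)
    log.info("loaded config %r from %s (%d distributions)", cfg.name, path, len(cfg.distributions))
    return cfg


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def default_config() -> ModelConfig:
    """The packaged first-line advanced-ESCC base case (escort1st.yaml)."""
    ref = resources.files("escc_cea").joinpath("data/escort1st.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)
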