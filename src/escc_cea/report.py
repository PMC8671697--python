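"""Full-pipeline runner: base case, DSA, PSA, CEAC, threshold price, serialized.

The report is deterministic given (config, seed): JSON keys are sorted,
no timestamps are embedded, and all randomness flows through one seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .config import ModelConfig, config_to_dict
from .model import BaseCaseResult, base_case
from .sensitivity import (
    ceac,
    one_way_dsa,
    prob_cost_effective,
    run_psa,
    threshold_price,
)

__all__ = ["base_case_report", "run_full_analysis"]

log = logging.getLogger(__name__)


def base_case_report(result: BaseCaseResult) -> dict:
    """Base-case totals per arm plus the incremental comparison, as plain dicts."""
    arms = {}
    for name, res in zip(result.arm_names, result.results):
        arms[name] = {
            "cost_pfs": res.cost_pfs,
            "cost_pd": res.cost_pd,
            "cost_total": res.cost_total,
            "qaly_pfs": res.qaly_pfs,
            "qaly_pd": res.qaly_pd,
            "qaly_total": res.qaly_total,
        }
    cmp = result.comparison
    return {
        "arms": arms,
        "comparison": {
            "delta_cost": cmp.delta_cost,
            "delta_qaly": cmp.delta_qaly,
            "icer": None if cmp.status != "icer" else cmp.icer,
            "status": cmp.status,
        },
    }


def run_full_analysis(
    config: ModelConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute every stage and (optionally) write report.json plus CSVs.

    Stages: deterministic base case, one-way DSA tornado, PSA draws, CEAC,
    and the threshold-price search on the first arm's flat-dose drug when
    one exists. ``run.psa_n = 0`` skips the probabilistic stages.
    """
    seed = config.run.seed if seed is None else seed
    result = base_case(config)
    report = {
        "config_name": config.name,
        "seed": seed,
        "policies": config_to_dict(config)["run"]["policies"],
        "base_case": base_case_report(result),
    }

    tornado = one_way_dsa(config)
    report["dsa"] = [
        {
            "param": e.param,
            "low": e.low,
            "high": e.high,
            "icer_at_low": e.icer_at_low,
            "icer_at_high": e.icer_at_high,
            "span": e.span,
        }
        for e in tornado
    ]

    psa = None
    if config.run.psa_n > 0:
        psa = run_psa(config, n=config.run.psa_n, seed=seed)
        curve = ceac(psa)
        report["psa"] = {
            "n": psa.n,
            "seed": psa.seed,
            "prob_ce_at_wtp": prob_cost_effective(psa, config.econ.wtp),
            "wtp": config.econ.wtp,
        }
        report["ceac"] = [{"wtp": p.wtp, "prob_ce": p.prob_ce} for p in curve]
    else:
        log.info("psa_n = 0: probabilistic stages skipped")

    price_params = [
        f"drug_price.{c.drug}"
        for c in config.arms[0].regimen
        if c.max_administrations is None
    ]
    if price_params:
        try:
            price = threshold_price(config, param=price_params[0])
            report["threshold_price"] = {"param": price_params[0], "value": price}
        except (ValueError, RuntimeError) as e:
            log.warning("threshold price search failed: %s", e)
            report["threshold_price"] = None
    else:
        report["threshold_price"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        import pandas as pd

        pd.DataFrame(report["dsa"]).to_csv(out / "tornado.csv", index=False)
        for name, trace in zip(result.arm_names, result.traces):
            trace.to_csv(out / f"trace_{name}.csv")
        if psa is not None:
            psa.to_frame().to_csv(out / "psa_draws.csv", index=False)
            pd.DataFrame(report["ceac"]).to_csv(out / "ceac.csv", index=False)
        log.info("report written to %s", out)
    return report
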