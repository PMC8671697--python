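"""Deterministic base-case evaluation of a full model configuration."""

from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig
from .economics import CEAResult, ComparisonResult, compare, run_strategy
from .markov import MarkovTrace

__all__ = ["BaseCaseResult", "base_case"]


@dataclass(frozen=True)
class BaseCaseResult:
    """Per-arm traces and discounted totals plus the incremental comparison.

    Arm 0 is the intervention, arm 1 the comparator; ``comparison`` is
    arm 0 versus arm 1.
    """

    arm_names: tuple[str, str]
    traces: tuple[MarkovTrace, MarkovTrace]
    results: tuple[CEAResult, CEAResult]
    comparison: ComparisonResult


def base_case(config: ModelConfig) -> BaseCaseResult:
    """Run both arms deterministically and compare them."""
    traces = []
    results = []
    for arm in config.arms:
        trace, res = run_strategy(arm, config.econ, config.policies)
        traces.append(trace)
        results.append(res)
    return BaseCaseResult(
        arm_names=(config.arms[0].name, config.arms[1].name),
        traces=(traces[0], traces[1]),
        results=(results[0], results[1]),
        comparison=compare(results[0], results[1]),
    )
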