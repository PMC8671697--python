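# escc-cea

A Markov cohort cost-effectiveness model of adding the PD-1 inhibitor
camrelizumab to first-line paclitaxel–cisplatin chemotherapy in advanced or
metastatic esophageal squamous cell carcinoma (ESCC), from the perspective
of the Chinese healthcare system.

The package is aimed at health-economics researchers who want a fully
scripted, testable version of this class of analysis: three health states
(progression-free survival, progressive disease, death), monthly cycles
over a 5-year horizon, Weibull-extrapolated survival, discounted cost and
QALY accrual, and the standard uncertainty toolkit (tornado one-way
analysis, probabilistic sensitivity analysis, cost-effectiveness
acceptability curve, threshold-price search).

## Model

Survival in each arm is governed by two-parameter Weibull curves fitted to
digitized trial Kaplan–Meier data,

    S(t) = exp(−λ t^γ),      P(t) = 1 − S(t)/S(t−1),

where `P(t)` is the transition probability during monthly cycle `t`.
Progression follows the PFS curve (net of background mortality, 0.707%/yr
compounded monthly); death is pinned to the OS curve each cycle. Costs
(2020 USD) cover drug acquisition (BSA-dosed chemotherapy for up to six
3-weekly administrations; camrelizumab until progression), follow-up and
laboratory/radiology work per progression-free cycle, salvage plus best
supportive care after progression, one-time grade 3–4 adverse-event
management, and terminal care at death. Utilities are 0.68 (PFS) and
0.42 (PD); costs and QALYs are discounted at 3%/yr. The decision statistic
is the incremental cost-effectiveness ratio

    ICER = ΔCost / ΔQALY,

judged against a willingness-to-pay threshold of $31,498.70/QALY
(3× Chinese per-capita GDP, 2020).

## Worked example

```python
import escc_cea as ec

cfg = ec.default_config()                 # packaged base case
result = ec.base_case(cfg)
for name, res in zip(result.arm_names, result.results):
    print(f"{name}: ${res.cost_total:,.2f}, {res.qaly_total:.3f} QALYs")
cmp = result.comparison
print(f"dCost ${cmp.delta_cost:,.2f}, dQALY {cmp.delta_qaly:.4f}, "
      f"ICER ${cmp.icer:,.2f}/QALY")
print(f"break-even camrelizumab price ${ec.threshold_price(cfg):,.2f}/200 mg")
```

prints

```
camrelizumab-chemotherapy: $19,279.78, 0.784 QALYs
placebo-chemotherapy: $12,427.14, 0.626 QALYs
dCost $6,852.64, dQALY 0.1581, ICER $43,350.72/QALY
break-even camrelizumab price $287.95/200 mg
```

Adding camrelizumab buys about 0.16 quality-adjusted life-years for about
$6,900 extra — an ICER above the national willingness-to-pay threshold, so
the combination is not cost-effective at the list price; it would become so
if the price per 200 mg dropped below roughly $290.

The same pipeline is scriptable from the shell:

```sh
escc-cea base-case
escc-cea run --out results/full --seed 1    # base case + DSA + PSA + CEAC
escc-cea threshold-price
```

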