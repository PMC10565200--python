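# graftcea

Lifetime cost-effectiveness of **decellularised** versus **fresh-frozen bone
allograft** for acetabular impaction bone grafting (IBG) during revision hip
arthroplasty (RHA), from the perspective of the UK NHS.

Decellularised allografts may incorporate better than fresh-frozen bone —
potentially fewer re-revisions — but cost far more to manufacture
(£10,040.72 vs £709.71 per femoral head; at 2.43 heads per procedure that is
an extra £22,674 per surgery). `graftcea` implements the decision model that
weighs this trade-off, for health economists and researchers evaluating bone
graft technologies.

## The model

A decision tree feeds a time-inhomogeneous three-state Markov cohort model
with yearly cycles over the patient's remaining lifetime:

* states: *post-revision* (utility 0.685, care cost £54.19/yr),
  *re-revision* (utility 0.397, full surgery cost) and *death* (absorbing);
* every patient starts with an RHA at mean age 71.7; annual transition
  probabilities p(re-revision) are derived from cumulative follow-up evidence
  under a constant hazard, T_R = −ln(1 − f)/t, T_P = 1 − e^(−T_R)
  (8%/13 yr ⇒ 0.0064/yr for the decellularised arm);
* death probabilities come from a national-style life table by attained age
  (0.0195 at 71 rising to 0.364 at 100, then certain), with a 90-day
  perioperative window replacing background mortality in revision years
  (0.047 falling to 0.306);
* costs and QALYs are discounted at 3.5%/yr and compared via the incremental
  cost-effectiveness ratio ICER = (C₁ − C₀)/(E₁ − E₀) against UK
  willingness-to-pay thresholds (£20,000–£30,000/QALY), with one-way
  scenarios, a 10,000-draw probabilistic sensitivity analysis (beta/gamma/
  normal distributions), cost-effectiveness acceptability curves, and
  break-even (threshold) searches on graft price and re-revision rate.

All inputs are generated by `graftcea.synthetic_data` — a Gompertz–Makeham
life table calibrated to the two mortality anchors and a reconstructed
base-case parameter bundle — so no external data are required.

## Worked example

```python
from graftcea import evaluate, make_base_case, make_lifetable, threshold_price

lifetable = make_lifetable()
bundle = make_base_case()
r = evaluate(bundle, lifetable).result
print(f"decellularised: £{r.cost_intervention:,.0f}, {r.effect_intervention:.2f} QALYs")
print(f"fresh-frozen:   £{r.cost_comparator:,.0f}, {r.effect_comparator:.2f} QALYs")
print(f"incremental:    £{r.incremental_cost:,.0f}, {r.incremental_effect:.3f} QALYs, "
      f"ICER £{r.icer:,.0f}/QALY")
print(f"break-even price at £30,000/QALY: £{threshold_price(bundle, lifetable, 30_000):,.0f}")
```

prints

```
decellularised: £42,272, 7.38 QALYs
fresh-frozen:   £21,302, 7.31 QALYs
incremental:    £20,970, 0.077 QALYs, ICER £272,390/QALY
break-even price at £30,000/QALY: £2,859
```

The decellularised graft costs ~£21,000 more per patient over a lifetime and
buys 0.077 QALYs (about 28 days of perfect health), an ICER of roughly
£272,000/QALY — far above the £30,000 guidance, so fresh-frozen allograft is
favoured unless the decellularised price falls to the low thousands.

The same pipeline is scriptable from the shell:

```bash
graftcea make-fixtures --out fixtures
graftcea run fixtures/config.json --lifetable fixtures/lifetable.csv --out results
graftcea sensitivity fixtures/config.json --scenarios fixtures/scenarios.json --out results
graftcea psa fixtures/config.json --specs fixtures/psa_specs.json --n 10000 --seed 1 --out results
graftcea threshold fixtures/config.json --wtp 30000 --out results
```

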