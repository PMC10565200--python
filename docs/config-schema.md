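# Configuration file format

`graftcea` reads a hierarchical JSON config with four sections. Unknown
sections or fields are rejected with an error naming the dotted path, as are
out-of-range values (probabilities and utilities outside [0, 1], negative
costs, infeasible price fractions).

```json
{
  "settings": {
    "starting_age": 71.7,
    "discount_rate": 0.035,
    "horizon_years": null,
    "cycle_length": 1.0
  },
  "strategies": {
    "decellularised": {
      "graft_price_per_head": 10040.72,
      "annual_re_revision_probability": 0.0064,
      "heads_per_surgery": 2.43,
      "surgery_base_cost": 14618.05,
      "annual_post_revision_care_cost": 54.19,
      "utility_post_revision": 0.685,
      "utility_re_revision": 0.397
    },
    "fresh_frozen": { "...": "same fields" }
  },
  "costing": {
    "tissue": 709.71,
    "reagents": 557.56,
    "labour": 12.12,
    "lab_rent": 219.75,
    "consumables_packaging": 30.48,
    "amortised_investment": 7.18,
    "indirect_overheads": 1536.80,
    "sales_distribution_fraction": 0.5,
    "operating_margin": 0.194
  },
  "evidence": {
    "decellularised": { "cumulative_revision_fraction": 0.08, "followup_years": 13 },
    "fresh_frozen":   { "cumulative_revision_fraction": 0.2238, "followup_years": 10 }
  }
}
```

Derivation rules (explicit values always win):

* a strategy missing `graft_price_per_head` takes it from `costing` — the
  selling price implied by the cost build-up for the decellularised arm, the
  tissue retrieval cost for the fresh-frozen arm;
* a strategy missing `annual_re_revision_probability` derives it from its
  `evidence` entry via the constant-hazard conversion;
* `horizon_years: null` runs the model until cohort age exceeds 100.

The life table is a separate two-column CSV with header `age,qx` (ages
contiguous single years, `qx` in [0, 1]). The cost breakdown can also be
loaded from a two-column `component,GBP` CSV via
`GraftCostBreakdown.read_csv`.

Scenario files (for `graftcea sensitivity`) are JSON lists of
`{"name", "parameter_path", "override_value"}`; PSA spec files (for
`graftcea psa`) are JSON lists of
`{"parameter_path", "family", "mean", "sd", "low", "high"}` with family one
of `beta`, `gamma`, `normal`, `fixed`. Parameter paths are dotted
(`settings.discount_rate`, `strategies.decellularised.graft_price_per_head`);
the wildcard `strategies.*.<field>` applies one value — or one shared PSA
draw — to both arms.
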