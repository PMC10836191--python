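# polypill

Cost-effectiveness modelling and pharmaceutical quality-control tooling for a
modular, variable-dose (VD) polypill compared against a fixed-dose-combination
(FDC) polypill and standard care.

The package provides:

- **`polypill.markov`** — a generic discrete-time Markov cohort engine:
  validated state spaces, constant or cycle-indexed transition matrices,
  cohort-trace propagation, and discounted accumulation of per-state and
  one-time per-transition rewards (optional half-cycle correction, optional
  separate QALY discount rate).
- **`polypill.cea`** — cost-effectiveness analytics: ICERs, strict and
  extended dominance, the efficiency frontier, willingness-to-pay decisions,
  one-way sensitivity sweeps with bisection threshold search, and tornado
  tables.
- **`polypill.model`** — the three-arm treatment model (standard care / FDC /
  VD) over the states {on treatment without side effects, on treatment after
  side effects, off treatment, post-MI, dead}, with age-indexed background
  mortality, a fatal/non-fatal MI split, competing-risk composition of annual
  probabilities, and config-level variants (split discontinuation reasons,
  MI tunnel state).
- **`polypill.titration`** — exact-rational dose titration: minimal-unit
  change-making over a catalogue of modular tablet strengths, polypill
  assembly under container capacity rules (interlocking design 1: ≤5 units in
  an AA capsule, ≤8 in a 000 capsule; rod-stacked design 2: ≤10 units), and
  taper schedules.
- **`polypill.qc`** — pharmacopeial batch calculators: content-uniformity
  acceptance value (|M − X̄| + k·s, pass < 15.0), weight variation (≤7.5 %
  for 130–324 mg tablets), friability (≤1 %, any breakage fails),
  disintegration (≤15 min), dissolution against per-drug "NLT Q% at t"
  criteria (bundled monograph table), and hardness summaries.
- **`polypill.synthetic`** — seeded generators: three-arm parameter sets with
  the structural arm orderings, tablet-batch measurement sets, and an
  individual-level Monte-Carlo oracle used to validate the cohort engine.

## CLI

One entry point, `polypill`, with subcommands:

```sh
# generate a synthetic three-arm analysis config, run it, sweep a parameter
polypill synth cea --seed 7 -o params.yaml
polypill cea run params.yaml -o results.json
polypill cea sweep params.yaml --param VD.monthly_drug_cost \
    --low 20 --high 2000 -o sweep.csv --plot sweep.png

# generic Markov model from a YAML config -> trace CSV
polypill markov trace model.yaml -o trace.csv

# dose titration against a unit catalogue (CSV: drug,strength_mg,design)
polypill titrate --design 2 --dose prednisone=17.5 --catalogue catalogue.csv

# tablet-batch QC from a directory of measurement CSVs
polypill synth batch --seed 3 -o batch_dir/
polypill qc evaluate batch_dir/ --drug rosuvastatin -o report.json
```

### Analysis config schema

`cea run`/`cea sweep` read one YAML document with a `shared` block
(`start_age`, `p_mi_fatal`, `p_death_post_mi`, `background_mortality`
(either an age→probability table or `{gompertz: {a, b}}`), `mi_event_cost`,
`post_mi_annual_cost`, `post_mi_treatment_cost`, `utilities`
(`on_treatment`/`off_treatment`/`post_mi`), `discount_rate`, `wtp`) and an
`arms` block with entries `standard-care`, `FDC`, `VD`, each holding
`p_side_effect`, `p_discontinue_given_side_effect`, `p_nonadherence`,
`p_mi_on_treatment_no_se`, `p_mi_on_treatment_after_se`,
`p_mi_off_treatment`, `monthly_drug_cost`, `side_effect_cost`,
`side_effect_disutility`. `polypill synth cea` emits a valid example. The
schema mirrors the source analysis' input tables field-for-field so a
transcription of those tables can be dropped in directly.

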