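# formuqbd

A Quality-by-Design formulation-development toolkit for gastroretentive
oral dosage forms. It covers the full workflow from powder
characterization to a simulated plasma profile:

- **`sedem`** — SeDeM powder scoring: converts 12 measured powder
  parameters into 0–10 radius scores, incidence means, summary indices
  (IP, IPP, IGC) and excipient correction percentages; exports radar
  polygon coordinates.
- **`mixture_design`** — constrained three-component mixture designs:
  extreme-vertex candidate sets, I-optimal point-exchange selection
  (Monte-Carlo average prediction variance), and Scheffé polynomial
  response models (linear / quadratic / special cubic / full cubic) in
  L-pseudo or real-proportion coding.
- **`desirability`** — Derringer–Suich desirability ramps combined by a
  weighted geometric mean, with a grid-seeded local optimizer over the
  two free simplex dimensions.
- **`dissolution`** — nonlinear least-squares fits of five release
  models (zero order, first order, Higuchi, Korsmeyer–Peppas,
  Hixson–Crowell), mechanism classification from the release exponent,
  and swelling/erosion percentages.
- **`compaction`** — Heckel analysis: relative density, the
  ln(1/(1−ρr)) transform, sliding-window linear-region detection, and
  the yield pressure Py = 1/slope.
- **`pbpk`** — a compartmental-absorption-and-transit simulator
  (stomach → 7 serial small-intestine segments → colon) driven by an
  in-vitro release function, with a gastric-retention depot for floating
  forms, two-compartment disposition, non-compartmental metrics
  (Cmax/Tmax/AUC/λz), and validation metrics (fold error, percent
  prediction error, relative bioavailability).
- **`synthetic_data`** — seeded generators for every stage (powder
  records, response surfaces, dissolution profiles, compression curves,
  plasma profiles) so the whole pipeline is testable offline.
- **`fixtures` / `pipeline` / `cli`** — packaged reference tables for
  the loxoprofen sodium minitablet case study, an end-to-end demo
  pipeline, and the umbrella CLI.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exposure
metrics, kinetic and Heckel round trips, Scheffé recovery, desirability
grid oracle, simulator properties, powder-score properties).

## CLI

```sh
formuqbd sedem score --in powders.csv --out profiles.json
formuqbd sedem correct --re 10 --rp 1.42 --target 5
formuqbd doe generate --runs 16 --replicates 5 --seed 7 --out design.csv
formuqbd doe fit --design design.csv --response lag_time_s --order linear
formuqbd doe optimize --seed 7
formuqbd dissolution fit --in profiles.csv
formuqbd compaction heckel --in press.csv --region auto
formuqbd pbpk simulate --release first_order:k=0.111 --dose 120 --hours 36
formuqbd synth dissolution --model first --k1 0.111 --seed 1 --out prof.csv
formuqbd run --seed 0 --out report.json
```

## Units

Times in hours, concentrations in µg/mL, pressures in MPa, densities in
g/mL, compositions in percent of the net formulation.
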