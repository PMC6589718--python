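# noxithresh

Simulation and analysis of adaptive two-interval forced-choice (2IFC)
threshold estimation for increases and decreases in noxious heat.

The package implements, end to end on synthetic observers:

* **Stimuli** (`noxithresh.stimuli`) — trapezoidal temperature time courses
  (hold → linear ramp → hold) with global 35–50 °C safety bounds, JSON/CSV
  export.
* **Observer** (`noxithresh.observer`) — a simulated participant with a
  power-law transducer `a·max(0, T − T0)^γ`, equal-variance Gaussian decision
  noise per interval, a lapse rate, confidence criteria, and an affine map to
  a 0–10 rating scale. Closed-form 2IFC choice probabilities are provided
  alongside trial-level simulation, so each can validate the other.
* **Staircase** (`noxithresh.staircase`) — the transformed up-down
  (3-down/1-up) adaptive rule with 0.5 °C steps, 30-trial blocks, and the
  last-20-trials threshold estimator; the analytic convergence point
  `0.5^(1/3) ≈ 79.4 %` and a bracketed psychometric-function inversion
  (`theoretical_threshold`) for parameter-recovery checks.
* **Design** (`noxithresh.design`) — presets for the three threshold
  experiments (2 °C/s vs 4 °C/s ramps, 6-s vs 10-s stimuli, matched 45 °C
  bases vs an overlapping-range 47 °C decrease base) and the 56-trial
  pain-rating task, with parity counterbalancing and post-hoc exclusion
  flagging of bound-clamped discrimination staircases.
* **Stats** (`noxithresh.stats`) — paired t with Cohen's d_z, 2×2 fully
  within-subject ANOVA with partial η², exact noncentral-t power and
  sample-size computation, and a descriptive confidence cross-tab, all from
  definitional formulas.
* **Cohort** (`noxithresh.cohort`) — seeded synthetic populations
  (heterogeneous gain/exponent/noise/lapse) plus miniature fixture datasets.
  The calibrated convex-transducer population reproduces the qualitative
  asymmetry (decreases from 45 °C are harder to detect than increases from
  45 °C, while decreases from 47 °C match increases from 45 °C); a
  linear-transducer population provides the matched null.

## CLI

```bash
# draw a 16-member synthetic cohort (convex or linear population)
noxithresh cohort --n 16 --seed 1 --out cohort.json

# run an experiment design: 1, 2, 3, or rating
noxithresh run --experiment 1 --cohort cohort.json --seed 7 --out results/exp1/

# miniature fixture bundles
noxithresh fixtures --preset exp1_small --seed 7 --out fixtures/exp1_small/
```

`run` writes `thresholds.csv` (or `ratings.csv`), per-block trial logs under
`blocks/`, and a JSON manifest (config, seed, versions). Identical seeds give
byte-identical outputs; per-participant RNG substreams mean adding a
participant never perturbs the others.

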