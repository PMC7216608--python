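# slskit

Analytics for single-leg-squat (SLS) movement screening. The package scores
frontal-plane knee trajectories with a *net trajectory angle* (the angle
between the least-squares line through the knee's path and the vertical
axis, per squat phase), runs a full test-retest reliability analysis
(medians/IQR, Wilcoxon signed-rank, Spearman, absolute-agreement ICC with
F-based confidence intervals, SEM, smallest detectable change, mean-difference
CI, Bland-Altman), and evaluates construct validity against dichotomous
visual pass/fail ratings via a 2°–20° cut-off sweep (percent agreement,
Cohen's kappa, Se/Sp/PPV/NPV with exact binomial CIs, two-segment ROC AUC
with Hanley–McNeil SE).

A synthetic-cohort generator produces 30 Hz squat trajectories with a known
between-subject / between-occasion / residual variance structure, sensor
noise, easy-mode/missing contamination, and two error-prone raters with a
consensus label — so every stage is exercisable and parameter recovery is
testable without any external data.

## Layout

| module               | purpose                                                        |
|----------------------|----------------------------------------------------------------|
| `slskit.synthetic`   | cohort/trajectory/rater simulation with known ground truth     |
| `slskit.kinematics`  | phase segmentation, net trajectory angles, exclusion bookkeeping |
| `slskit.reliability` | test-retest statistics (ICC, SEM, SDC, Wilcoxon, Bland-Altman) |
| `slskit.validity`    | cut-off sweep, 2×2 agreement and diagnostic accuracy           |
| `slskit.io` / `config` / `render` / `pipeline` / `cli` | CSV+YAML I/O, report rendering, end-to-end runs |

## CLI

```bash
# one-shot demo: simulate, score, analyse, render reports into out/
slskit run-all --seed 1 -o out/

# or stage by stage
slskit simulate -c config.yaml -o sim/
slskit score -t sim/trajectories -o scores.csv
slskit reliability -s scores.csv -o reliability.csv
slskit validity -s scores.csv -r sim/ratings.csv -o validity.csv
slskit report -s scores.csv -r sim/ratings.csv -o reports/
```

A config file is YAML/JSON with a `cohort` block (cohort size, variance
components in deg², mean angles, sensor noise, contamination rates, rater
error probability, seed) plus optional `cutoffs` and rendering options; all
randomness flows from the single seed, and identical config + seed gives
byte-identical outputs. Reports are written as full-precision CSV plus
rounded Markdown tables (significant Wilcoxon p-values and systematic mean
differences are starred), alongside Bland-Altman point sets and ROC points.

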