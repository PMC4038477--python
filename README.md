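# circakit

Tools for studying how oncogenic signalling deregulates the cellular
circadian clock: bioluminescence rhythm analysis, a reduced core-clock
ODE model with BMAL1-transactivation scaling, strong/weak-oscillator
gene-signature discovery, and interaction-network enrichment testing
against citation-matched random nulls.

## Modules

| module | what it does |
|---|---|
| `circakit.timeseries` | running-average detrending/smoothing, damped-cosine fits, oscillator classification, entrainment phase, 2^-ddCT quantification |
| `circakit.clockmodel` | 8-state Per/Cry/Rev-Erb/Bmal1 ODE model, limit-cycle features, control coefficients, antipodal Per/Cry perturbation screen, seeded calibration |
| `circakit.signature` | empirical-Bayes moderated t-test, leave-one-cell-line-out discriminative lists, Ward/Pearson clustering validation, list intersection, sample classification, exact binomial test |
| `circakit.network` | shell-structured network assembly, inter-set connection counts, citation-bin random-set null (empirical p, z, Wilcoxon signed-rank) |
| `circakit.synth` | seeded generators for luciferase traces, planted expression studies, citation-biased networks, qPCR CT tables |
| `circakit.io` / `circakit.cli` | text-format readers/writers (traces, TSV matrices, GMT, edge lists, SIF), run configuration, end-to-end pipeline |

Packaged fixtures (`circakit/data/`): the 14-gene core-clock set, the
45-gene discriminative signature, clock-related and cancer-related gene
lists, a 14+16+17-node shell network fixture, a gene-symbol alias table,
and the frozen default-calibrated clock model.

## CLI

All functionality is under a single `circakit` entry point:

```sh
circakit rhythm fit --in trace.csv --detrend 24 --smooth 4 --out fit.json
circakit rhythm entrain --in trace.csv --release 96
circakit model simulate --model default --ktt 0.4
circakit model cc --delta 0.01
circakit model screen --down 0.4 --up 1.6
circakit model calibrate --seed 7 --out model.json
circakit signature discover --expr expr.tsv --ann ann.tsv --topk 100
circakit signature binomial --correct 7 --total 8
circakit network assemble --edges edges.tsv
circakit network null --edges edges.tsv --citations cit.tsv \
    --query disc.gmt --targets core_clock,cancer_related --B 50 --seed 1
circakit simulate trace --seed 1 --mode strong --out trace.csv
circakit run --seed 1 --out results.json
```

Exit codes: 0 success, 2 validation error, 3 computation error.

## Default clock model

The shipped model (`circakit/data/default_model.json`) is the exact
output of `calibrate_default_model(seed=7)` (Latin-hypercube screen +
seeded hill-climb, then exact time-rescaling); regenerate it with
`python scripts/calibrate_default.py`. Properties: baseline period
23.0 h, Bmal1-mRNA relative amplitude ~0.61, period strictly decreasing
as the BMAL1-transactivation factor ktt moves over
{0.4, 0.7, 1.0, 1.3, 1.6} (25.4 -> 22.5 h), and a kt2 (Cry
transcription) perturbation that lengthens the period while moving Per
and Cry mRNA magnitudes in opposite directions.
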