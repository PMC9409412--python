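# agestage

Age-stage two-sex life table demography for daily-censused insect
cohorts, with bootstrap inference, an individual-based cohort simulator,
and companion assay computations (supercooling-point detection from 1-Hz
cooling curves, trehalase-difference trehalose quantification, screening
proportions with Wilson intervals, thermal-survival summaries, and
relative qPCR expression).

## What it computes

From per-individual records (stage durations, sex, fate, daily egg
counts) the life-table engine builds the age-stage survival matrix
`S_xj`, the per-female fecundity matrix `f_xj`, the age curves
`l_x = sum_j S_xj` and `m_x = sum_j S_xj f_xj / sum_j S_xj`, and the
population parameters

- net reproductive rate `R0 = sum_x l_x m_x`,
- intrinsic rate of increase `r` solving `sum_x exp(-r (x+1)) l_x m_x = 1`
  (bracketed bisection plus Newton polish, residual < 1e-10),
- finite rate `lambda = e^r` and generation time `T = ln(R0)/r`,

plus cohort trait summaries (per-stage development, preadult/adult/total
longevity, APOP, TPOP, oviposition days, fecundity). Standard errors come
from resampling individuals with replacement; two cohorts are compared
with a paired bootstrap test (resamples paired by index, two-sided
p-value from the sign distribution of the paired differences).

The simulator generates cohorts from packaged strain presets (shifted
Poisson / discretized gamma durations, per-stage survival calibrated so
the expected `R0` matches each preset's target, negative-binomial
fecundity spread over a geometric daily laying schedule) so the whole
pipeline runs without external data.

## CLI

One entry point, `agestage`, with subcommands (see `--help` on each;
file schemas are documented in `docs/formats.md`):

```sh
agestage simulate --strain WT --n0 120 --seed 1 --out wt.csv
agestage lifetable --cohort wt.csv --out-params wt_params.txt \
    --out-curves wt --plots wt.png
agestage bootstrap --cohort wt.csv --b 2000 --seed 1 --out wt_boot.csv
agestage simulate --strain MU-1 --n0 120 --seed 2 --out mu1.csv
agestage compare --cohort-a wt.csv --cohort-b mu1.csv --b 2000 --seed 3 \
    --out wt_vs_mu1.csv
agestage scp --in curves.csv --out scp_calls.csv
agestage sugars --in glucose.csv --out trehalose.csv
agestage survival --in replicates.csv --out survival_summary.csv
agestage screenstats --successes 62 --trials 100
agestage qpcr --ct-table ct.csv --reference-gene RPL32 --method ddct \
    --control-group control --out expression.csv
```

Outputs are plain CSV or flat `key=value` files; stochastic outputs embed
the seed and package version in `#` header lines, and identical seeds
give byte-identical results end to end. A YAML file passed as
`agestage --config conf.yaml <subcommand>` supplies per-subcommand
defaults that flags override.

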