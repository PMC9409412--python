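# File formats

All files are UTF-8 CSV with a header row. Lines beginning with `#` are
metadata/comments and are skipped by readers.

## Cohort file (per-individual)

See the committed example `docs/example_cohort.csv` /
`docs/example_cohort.eggs.csv` (3 individuals: one female, one male, one
preadult death).

Leading metadata lines:

```
# strain_label=<label>
# n0=<number of individuals started>
# stage_order=<comma-separated stages, the last two being the female and
#              male adult stages>
```

Columns:

| column          | meaning |
|-----------------|---------|
| `id`            | unique individual id |
| `sex`           | `female`, `male`, or `unknown` (preadult deaths only) |
| `fate`          | `died_preadult` or `died_adult` |
| `death_stage`   | stage occupied at death |
| `emergence_day` | day of adult emergence (empty for preadult deaths) |
| `death_day`     | whole days survived since oviposition (day 0) |
| `dur_<stage>`   | whole days in each *completed* preadult stage (empty if the stage was not completed) |

Conventions: age is in whole days with day 0 the day of oviposition; the
stage at age `x` is the stage at the end-of-day census, so an individual
occupies a new stage on its first day; an individual is alive at ages
`0 .. death_day - 1`; the partial time in the death stage is
`death_day - sum(dur_*)` and may be zero.

## Daily fecundity companion file

`<stem>.eggs<suffix>` next to the cohort file, long format:

```
id,age_day,eggs
```

`age_day` must satisfy `emergence_day <= age_day < death_day`. Wide
`eggs_<day>` columns in the main file are accepted on read as an
alternative.

## Cooling curves (`agestage scp`)

`t` (seconds, uniform 1-s sampling), `temp` (deg C), `pupa_id`. One curve
per `pupa_id`, at least 60 samples.

## Sugar assay (`agestage sugars`)

`sample_id`, `glucose_before`, `glucose_after` (glucose readings before
and after overnight trehalase treatment, same units).

## Thermal survival (`agestage survival`)

`strain`, `sex`, `exposure_minutes`, `n_total`, `n_alive` — one row per
replicate.

## Ct table (`agestage qpcr`)

`sample_id`, `group`, `gene`, `replicate`, `ct`. Every sample needs rows
for the designated reference gene.
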