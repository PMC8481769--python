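# primesplit

Natural-abundance δ¹³C partitioning of soil-incubation carbon pools:
litter-released C, native SOC mineralization, the priming effect, and
its chemical and microbial drivers.

## Who this is for

Soil biogeochemists running litter-addition incubations on soils with a
C3/C4 isotopic contrast — e.g. C3 tree and shrub litter added to soil
cultivated with a C4 crop such as maize. Given end-of-incubation
measurements per jar (total organic C and bulk δ¹³C) plus the litter and
soil end-member signatures, the package separates the two carbon
sources, quantifies how much extra native soil carbon the litter input
"primed" into mineralizing, and screens litter chemistry and microbial
taxa for drivers of that priming. A synthetic-experiment generator with
full ground truth makes every stage verifiable without external data.

## The model

With two isotopically distinct carbon sources, the end-of-incubation
pools satisfy

```
TOC_final              = SOC_final + C_litter
δ¹³C_final · TOC_final = δ¹³C_native · SOC_final + δ¹³C_litter · C_litter
```

so the litter-derived carbon remaining in the soil is

```
C_litter = TOC_final · (δ¹³C_native − δ¹³C_final) / (δ¹³C_native − δ¹³C_litter)
```

From there: SOC mineralization = SOC_initial − SOC_final;
litter-released C = litter C added − C_litter; the priming effect (PE)
of a treatment is its SOC mineralization minus the control mean; and
priming efficiency is PE per unit litter added. Driver models are
selected by exhaustive ordinary-least-squares search arbitrated by the
small-sample AICc. See `docs/methods.md` for assumptions, units,
flags, and the generator's design.

The packaged chemistry fixture carries the measured traits (N, C,
lignin, cellulose, soluble sugar, methanol-/water-soluble phenols,
condensed tannin, δ¹³C, each with SE) of three litters — *Artemisia
halodendron* (Ah), *Caragana microphylla* (Cm), *Populus simonii*
(Ps) — and their four equal-proportion mixtures.

## Worked example

Simulate a full experiment (7 litter treatments + control × 5 jars) and
run the pipeline on it:

```sh
primesplit simulate --seed 17 --out demo/
primesplit run --jars demo/jars.csv --chemistry demo/chemistry.csv \
               --abundance demo/abundance.csv --out demo_results/
```

`demo_results/priming_results.csv` then contains (seed 17):

```
treatment_code  priming_effect  priming_effect_se  priming_efficiency  priming_share  n
            Ah          328.23               7.23               32.82           0.50  5
            Cm          118.68               3.29               11.87           0.27  5
            Ps          533.32               4.84               53.33           0.62  5
          AhCm          160.25              10.60               16.02           0.33  5
          AhPs          446.86               9.45               44.69           0.58  5
          CmPs          341.48               7.87               34.15           0.51  5
        AhCmPs          375.79               5.71               37.58           0.54  5
```

Reading this: adding Ps litter primed an extra 533 ± 5 μg C g⁻¹ soil of
native SOC mineralization relative to the no-litter control — 62% of
that treatment's total SOC mineralization, or 53 units of priming per
gram of litter added on the reporting scale — while the
nitrogen-rich Cm litter primed least (27%). The driver stage
(`drivers.csv` / `run_report.json`) selects nitrogen and cellulose as
the chemistry drivers of priming, with the expected signs:

```
predictors: ['Ce', 'N']   coefficients: [+2.57, -10.46]   r² = 0.988   n = 35
```

i.e. priming rises with litter cellulose and falls with litter
nitrogen. `screen.csv` and `screen_taxa.csv` hold the Spearman
correlations of each response with every chemistry trait and taxon.

Library use mirrors the CLI:

```python
from primesplit import SimulationConfig, generate_experiment, partition_jars

exp = generate_experiment(SimulationConfig(seed=17))
results = partition_jars(exp.observations)
```

Other subcommands: `primesplit chemistry ratios` (printed trait
ratios), `primesplit partition`, `primesplit screen`,
`primesplit drivers`, `primesplit validate`, and `primesplit --version`
(prints the packaged chemistry fixture checksum).

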