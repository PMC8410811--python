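# amdtox

Quantitative assessment toolkit for acid-mine-drainage (AMD) studies:
heavy-metal pollution and ecological-risk indices, alpha-diversity
estimation for amplicon OTU tables, and the kinetics of urease-driven
(MICP) metal sequestration. It is written for environmental geochemists
and microbiologists who assay metal-laden effluent against a pristine
background site, profile its microbial community, and evaluate ureolytic
consortia as a bioremediation strategy.

## What it computes

**Pollution and ecological risk** (`amdtox.geochem`). For each analyte
with measured concentration C and background B:

- contamination factor CF = C/B, enrichment factor
  EF = (C/C_ref)/(B/B_ref) (falling back to CF when no conservative
  reference element is configured),
- Müller geo-accumulation index I_geo = log₂(CF/1.5),
- Hakanson risk factor Er = Tr·CF with toxic-response weight Tr, its
  EF-based variant MEr = Tr·EF, and risk quotient RQ = MEC/PNEC;

and across analytes:

- pollution load index PLI = (∏ CF_i)^(1/n),
- Nemerow pollution index PI = √((CF_max² + CF_mean²)/2) and its
  EF-based variant MPI,
- degree of contamination C_d = Σ CF_i and MC_d = C_d/n,
- risk indices RI = Σ Er_i and MRI = Σ MEr_i.

Indices are computed per replicate and reported as mean ± SEM with an
interpretation class (e.g. CF > 6 "very high", 25 ≤ EF < 50 "very high",
I_geo ≥ 5 "very severe", Er > 320 "very high", RQ > 1 "high").

**Alpha diversity** (`amdtox.diversity`). Bias-corrected Chao1 with its
log-normal 95% interval, ACE, first-order jackknife, Shannon H (nats,
bootstrap interval), the Chao–Shen coverage-adjusted Shannon
("NPShannon"), Simpson dominance λ and 1/λ, Good's coverage
(1 − F₁/N)·100, exact hypergeometric rarefaction, and Faith's PD on a
newick tree.

**Bioremediation kinetics** (`amdtox.kinetics`). Ammonium standard-curve
calibration for the phenol-hypochlorite urease assay with units defined
as 1 U = 1 µmol urea hydrolysed min⁻¹ (2 NH₃ per urea), exponential
growth rate K (h⁻¹) and doubling time Td = ln 2/K from ln(OD600) vs
time, sequestration efficiency SE = (MQM − SQ)/MQM·100, and dry
precipitate yield per culture volume.

**Synthetic data** (`amdtox.synthetic`). Seeded generators for
triplicate geochemical sampling, lognormal-abundance OTU communities at
amplicon depth, and batch ureolytic cultures with an exact internal
metal mass balance — so the whole stack runs without any downloads.

## Worked example

```python
from amdtox import geochem as gc, synthetic as syn, kinetics as kn

table, refs = syn.gen_geochem(seed=1)          # triplicate AMD sampling
report = gc.assess(table, refs)
print(report.per_metal_[["CF_mean", "CF_sem", "Igeo_mean", "CF_class"]].round(3))
```

```
                       CF_mean     CF_sem  Igeo_mean   CF_class
sample_id analyte
AMD       As         54451.422   7051.627     15.121  very high
          Cd       3126136.557  38410.170     20.991  very high
          Co        195046.233   9466.198     16.985  very high
          Cr           456.940    166.537      7.979  very high
          Fe           396.871    130.772      7.831  very high
          Ni         15981.598   3937.122     13.293  very high
          Pb        105456.157   2387.920     16.101  very high
```

Every metal is orders of magnitude above background (CF "very high");
Cd's I_geo of ≈ 21 log₂ units marks extreme accumulation. The
aggregates condense this into effluent-level grades:

```python
agg = report.aggregates_.loc["AMD"]
print(f"PLI = {agg['PLI_mean']:.4g} ± {agg['PLI_sem']:.3g} ({agg['PLI_class']})")
print(f"C_d = {agg['Cd_deg_mean']:.4g} ± {agg['Cd_deg_sem']:.3g} ({agg['Cd_deg_class']})")
```

```
PLI = 2.544e+04 ± 1.75e+03 (progressively deteriorating)
C_d = 3.498e+06 ± 4.27e+04 (severe)
```

The kinetics stage, on a simulated low-cocktail culture:

```python
run = syn.gen_bioremediation_timecourse(syn.CultureScenario(seed=1))
model = kn.ExponentialGrowthModel(window=(6, 15)).fit(
    run.timecourse["time_h"], run.timecourse["od600"])
print(f"K = {model.K_:.3f} /h, Td = {model.Td_:.2f} h")
```

```
K = 0.300 /h, Td = 2.31 h
```

with sequestration efficiencies at 24 h of 100% (Cd, Pb), 95.5% (Co),
87.4% (Ni) and 83.7% (As) from `kn.sequestration_efficiency` on the
run's sequestration records.

The same pipelines are available from the shell:

```sh
amdtox simulate geochem --seed 1 --out sim/
amdtox indices --metals sim/metals.tsv --background sim/background.tsv --out report/
amdtox diversity --otu otu_table.tsv --rarefy-depths 1000,5000 --out div/
amdtox kinetics --timecourse timecourse.tsv --window 6:18
```

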