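# defac

Quantitative pipeline for per-expression-level autophagic-flux cytometry
(DEFAC), dual-criterion drug-library screening triage, and the supporting
kinetics/genetics statistics used in drug-repurposing studies of
glycosaminoglycan (GAG) storage disease — in particular
mucopolysaccharidosis-plus syndrome (MPSPS), the recessive disorder caused by
the VPS33A p.R498W variant.

It is aimed at cell biologists and screening scientists who have
flow-cytometry event data (FCS or CSV), plate-reader screening tables,
cycloheximide-chase densitometry, litter genotype tallies or qPCR Ct tables,
and want the corresponding statistics as reproducible, tested code rather
than spreadsheet arithmetic.

## What it computes

**DEFAC** bins viable cells of a rescued knock-out line into five expression
levels by GFP intensity of the rescuing construct and quantifies autophagy in
each level as LC3 flux from a paired Bafilomycin-A1 / untreated measurement:

```
flux (%) = (LC3 MFI_BafA1 − LC3 MFI_untreated) / LC3 MFI_BafA1 × 100
```

with geometric-mean MFIs. This asks not "is autophagy active?" but "how much
of the protein is enough?" — function as a curve over expression level.

**Screening triage** runs the full funnel over a drug-library plate: vehicle
(DMSO) normalization per plate → toxicity filter (CellMask ratio < 0.5
excluded) → cell-number-adjusted GAG reporter → dual-criterion quadrant
(GAG < 0.5 and protein-stability reporter > 2.0, both strict) → category and
patient-cell exclusions, with stage-by-stage conservation accounting.

**Kinetics/genetics**: log-linear and nonlinear single-exponential chase
fits (half-life = ln 2/k), Mendelian segregation chi-square (df 2, exact
multinomial option), qPCR standard-curve relative quantification with
efficiency reporting, and the usual two-/multi-group tests (Student/Welch,
Holm, ANOVA/Tukey, Kruskal–Wallis/Mann–Whitney).

**Synthetic data** generators reproduce the statistical structure of each
input (lognormal fluorescence mixtures, mixture-distributed plate effects,
noisy exponential decay, multinomial litters), so the entire pipeline runs
and is tested without any external data.

## Worked example

```python
from defac import (DefacSimSpec, gen_defac_events, defac_analysis,
                   GenotypeCounts, mendelian_chisq,
                   gen_decay_course, fit_decay)

# per-level flux from a simulated rescue (truth: 0/40/60/60/60 %)
spec = DefacSimSpec(seed=1, n_events=20000, n_replicates=3)
pairs = gen_defac_events(spec)
table = defac_analysis([u for u, _ in pairs], [b for _, b in pairs], spec.gate)
print(table.summary[["level", "flux_mean", "flux_sd"]].round(2).to_string(index=False))
#  level  flux_mean  flux_sd
#      0       0.18     1.90
#      1      39.03     0.61
#      2      59.87     0.91
#      3      60.22     0.35
#      4      60.36     0.96

# chase half-life from a noisy synthetic course generated at t1/2 = 24 h
fit = fit_decay(gen_decay_course(24.0, cv=0.05, n_replicates=3, seed=1))
print(round(fit.half_life_h, 2))   # 23.67

# does a litter tally deviate from Mendelian 1:2:1?
res = mendelian_chisq(GenotypeCounts(n_wt=15, n_het=28, n_hom=4))
print(round(res.chi2, 3), round(res.p, 4))   # 6.872 0.0322
```

The flux table recovers the generator's truth within a fraction of a
percentage point per level; the chase fit recovers the 24 h half-life within
the noise; the genotype tally deviates significantly from 1:2:1 (p ≈ 0.032),
the signature of homozygote embryonic loss.

The same operations are available from the shell:

```
defac flux --untreated a.csv --bafa1 b.csv --gate gate.yml --out flux.tsv
defac screen --plates plates.csv --out funnel.json --hits hits.tsv
defac decay --course chase.csv
defac mendel --counts 15,28,4
defac qpcr --standards std.csv --unknowns ct.csv
defac simulate defac|screen|decay|litters --seed N --out dir/
```

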