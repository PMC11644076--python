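# rhizoscreen

Screening large genotype panels for root-system architecture that tolerates
drought and low-phosphorus stress is a core task in crop breeding: roots are
where water and phosphorus are taken up, but root traits are laborious to
measure and their response to stress is strongly genotype-dependent.
`rhizoscreen` implements the full statistical workflow used with
semi-hydroponic root-phenotyping platforms, where ~100 genotypes are grown
under a control (C), low phosphorus (LP), osmotic drought (D) and combined
(DLP) treatment in replicated blocks and harvested once for depth-resolved
root measurement. It is written for quantitative geneticists and root
biologists who have (or want to simulate) per-plant measurement tables and
need the downstream screening statistics.

## What it computes

Starting from per-plant primitives (maximum root depth MRD, root number,
per-20 cm-layer root length and mean diameter, root/shoot dry weights,
shoot height, leaf and tiller counts, P concentrations):

- **Trait derivation** — global traits (RL, RD, RA, RV, RLD, SRL, RLI, RTD,
  RGR, RSR, TDM, RP, SP, TP, ...) and depth-local traits for the 0–20 cm
  top layer (s1) versus everything below (sub), using cylinder geometry
  RA = π·d·L and RV = (π/4)·d²·L per layer.
- **Stress metrics** — relative changes Δx = (x_S − x_C)/x_C, phosphorus
  acquisition efficiency PAE = 100·P_S/P_C, and the seven dry-weight-based
  tolerance indices

  SSI = (1 − DW_S/DW_C)/(1 − D̄W_S/D̄W_C), TI = DW_C − DW_S,
  SI = DW_S/DW_C, HMI = 2·DW_C·DW_S/(DW_C + DW_S),
  MPI = (DW_C + DW_S)/2, GMPI = √(DW_C·DW_S), STI = DW_C·DW_S/D̄W_C²,

  summed into a stress tolerance score STS per stress and STS_SUM over the
  three stresses.
- **Heritability** — factorial ANOVA (genotype × phosphorus × water + block),
  Tukey HSD compact letter displays, and broad-sense heritability from
  expected mean squares: H = V_G/(V_G + V_ε/r) per treatment and
  H_com = V_G/(V_G + V_GE/e + V_ε/(r·e)) across treatments.
- **Effect sizes** — log response ratios LnR = ln(V_s/V_c) with sampling
  variance v = S_s²/(n_s·V_s²) + S_c²/(n_c·V_c²), percent transform
  100·(e^LnR − 1), 95% intervals and inverse-variance pooling (forest-plot
  tables).
- **Multivariate screening** — CV ≥ 0.3 trait selection, Pearson correlation
  matrices with significance stars, correlation-matrix PCA with
  eigenvalue > 1 retention, average-linkage Euclidean clustering of
  genotypes into k groups, and STS-based genotype grouping.

A synthetic-data generator reproduces the trial's statistical structure
(log-normal traits with genotype, genotype × treatment, block and residual
variance components; depth-consistent root layers), so the whole pipeline
is testable end-to-end without the original measurements.

## Worked example

```python
import rhizoscreen as rs

cfg = rs.wheat_screen_preset(seed=1)       # 100 genotypes x 4 treatments x 4 blocks
plants = rs.generate_dataset(cfg)
table = rs.derive_traits(plants)

summary = rs.summarize_by_treatment(table)
print(summary[summary["trait"] == "RL"][["treatment", "mean", "cv"]].round(2))

idx = rs.stress_index_table(table)
print(idx.drop_duplicates("genotype").nlargest(3, "sts_sum")[["genotype", "sts_sum"]])

vd = rs.estimate_heritability(table, "RL", treatment="C")
print(f"H(RL, control) = {vd.heritability:.2f}")

eff = rs.effect_table(table, traits=("SDW",))
row = eff[(eff.trait == "SDW") & (eff.stress == "DLP")].iloc[0]
print(f"SDW under DLP: LnR = {row.lnr:.2f} ({row.pct:.1f}%)")
```

prints

```
treatment    mean   cv
        C 1543.16 0.53
        D 2009.30 0.55
      DLP 1437.51 0.57
       LP 1475.83 0.48
 genotype  sts_sum
       11    38.19
       94    18.45
       55    18.06
H(RL, control) = 0.94
SDW under DLP: LnR = -1.54 (-78.5%)
```

Root length is highest under drought (the drought treatment alone earns
Tukey letter "a"), shoot biomass collapses by ~79% under the combined
stress, root length is highly heritable within the control, and genotype
ranking by summed stress tolerance score identifies the most tolerant
lines.

The same pipeline runs from the shell:

```sh
rhizoscreen simulate --seed 1 --out plants.csv
rhizoscreen run-all --input plants.csv --seed 1 --out results/
```

`run-all` writes every stage's CSV (trait tables, treatment summaries,
stress indices, ANOVA and heritability tables, effect sizes, correlations,
PCA, cluster assignments, STS groups) plus a `run.log`; reruns with the
same seed are byte-identical.

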