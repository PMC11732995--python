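# metpipe

Analysis pipeline for **multi-environment trials (MET)** of cultivar
panels — the trial networks plant breeders and agronomists use to separate
genotype, environment and management effects on crop traits. The package
targets winter-wheat networks of the kind run in Germany (year × location ×
management "growing conditions", hundreds of cultivars spanning five
decades of release years, two–three replicates in a row–column field
layout), but nothing is wheat-specific.

It provides, as a plain Python library:

* **QC** — recoding of physically impossible values to missing (negative
  measurements, grain yield > 3000 dt/ha, thousand-grain weight > 80 g)
  and a per-condition mean ± 4 sd outlier screen for harvest index and
  spike number; the **total fungal infection** score
  `TFI = stripe rust + Septoria + powdery mildew + leaf rust + leaf tan
  spot + Fusarium head blight`.
* **BLUEs** — per (trait, growing condition) cultivar means from the model
  `y_irc = μ + g_i + R_r + C_c`, with cultivar effects `g_i` fixed and the
  row/column effects of the field grid random (REML), absorbing soil
  gradients.
* **Trait consistency** — `R²_sma`, the coefficient of determination of a
  standardized-major-axis line through the cultivar BLUEs of two growing
  conditions, for all condition pairs, with single/double grouping by
  year, location and management, one-way ANOVA and Fisher-LSD compact
  letters.
* **Breeding progress (BP)** — the slope of BLUE on cultivar release year
  per condition, and the across-condition regression
  `BP_GY = BP_TGW + BP_HI + BP_Straw + BP_GpS + BP_SN + ε`.
* **Yield stability** — nine stability indices per cultivar
  (Finlay–Wilkinson `b_i`, Eberhart–Russell `s²_di`, Pinthus `r²_i`,
  Wricke ecovalence `W_i`, Shukla `σ²_i`, Hanson `D²_i`, Lin–Binns `P_i`,
  environmental variance `S²_xi`, Nassar–Hühn rank variance `S⁴_i`) and
  the per-index regression
  `SI_GY = SI_TGW + SI_HI + SI_Straw + SI_GpS + SI_SN + TFI + ε`.
* **LMG relative importance** — the exact averaging-over-orderings
  decomposition of regression R² among regressors (exhaustive subsets).
* **Model comparison** — trait–trait Pearson correlation tables for field
  and crop-model outputs, with the concordance gate "distance to the 1:1
  line < 0.09 and |r| > 0.5 on both axes".
* **A synthetic MET generator** with full ground truth (genotype effects,
  progress slopes, per-genotype G×E variance, field gradients, bounded
  disease scores, a shared latent factor inducing realistic trait–trait
  correlations), so every stage is testable against known answers.

## Worked example

```python
from metpipe.sim import make_demo_design, simulate
from metpipe.blues import build_blue_table
from metpipe.consistency import pairwise_consistency

records, truth = simulate(make_demo_design(n_genotypes=40, seed=7))
blues = build_blue_table(records, traits=["Seedyield"])
pairs = pairwise_consistency(blues, "Seedyield")
print(len(pairs), round(pairs["r2_sma"].mean(), 2))
```

prints `66 0.59`: with 12 growing conditions there are C(12,2) = 66
condition pairs, and on average yield in one condition explains 59 % of
the cultivar-level yield variation in another — the remaining 41 % is
genotype × environment × management interaction plus estimation noise.
The scripts in `examples/` walk through each capability the same way
(simulation + QC, BLUEs + consistency, breeding progress, stability,
model comparison) and print one-line interpretations of their numbers.

A thin CLI mirrors the stages:

```bash
metpipe simulate --design demo --seed 7 --out plots.csv
metpipe qc --input plots.csv --out clean.csv
metpipe run --out-dir out --seed 7        # full pipeline, all stages
```

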