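"""Yield stability: nine stability indices per cultivar and the regression
of yield stability on component-trait stability.

Static indices (environmental variance) penalise any variation; dynamic
indices (ecovalence, Shukla variance) penalise deviation from the average
environmental response.  The per-index regression asks which trait's
stability carries the stability of yield.
"""

from metpipe.blues import build_blue_table
from metpipe.qc import compute_tfi
from metpipe.sim import make_demo_design, simulate
from metpipe.stability import (build_trait_matrix, si_regression,
                               stability_indices, tfi_regressor)

records, truth = simulate(make_demo_design(n_genotypes=50, seed=5))
records = compute_tfi(records)
traits = ["Seedyield", "TGW", "Harvest_Index_bio", "Straw",
          "Grain_per_spike_bio", "Spike_number_bio", "Crude_protein"]
blues = build_blue_table(records, traits=traits + ["TFI"])

si_tables = {t: stability_indices(build_trait_matrix(blues, t))
             for t in traits}
gy = si_tables["Seedyield"]
print("ecovalence W_i of yield (cultivar share of the GxE interaction SS):")
print(f"  most stable  {gy['W_i'].idxmin()}: {gy['W_i'].min():8.1f}")
print(f"  least stable {gy['W_i'].idxmax()}: {gy['W_i'].max():8.1f}")
rho = gy["W_i"].corr(truth.gxe_sd["Seedyield"].loc[gy.index] ** 2,
                     method="spearman")
print(f"  rank agreement with true interaction variance: rho = {rho:.2f}")

tfi = tfi_regressor(blues, list(gy.index))
fit = si_regression(si_tables, "W_i", tfi=tfi)
print(f"regression of yield W_i on component-trait W_i + TFI: "
      f"R2 = {fit['r2_full'].iloc[0]:.2f}")
print(fit[["term", "beta", "stars"]].to_string(index=False))
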