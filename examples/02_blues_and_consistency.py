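"""Cultivar BLUEs per growing condition and yield consistency between
conditions.

The BLUE model removes row/column field gradients per condition; the
consistency statistic is the R^2 of a standardized-major-axis line fitted
to the cultivar BLUEs of every pair of conditions -- high R^2 means the
trait ranks cultivars the same way in both environments.
"""

from metpipe.blues import build_blue_table
from metpipe.consistency import (group_pairs, pairwise_consistency,
                                 summarize_groups)
from metpipe.sim import make_demo_design, simulate

records, _ = simulate(make_demo_design(n_genotypes=40, seed=7))
blues = build_blue_table(records, traits=["Seedyield"])
print(f"{len(blues)} BLUEs "
      f"({blues['fallback'].eq('none').mean():.0%} from the full model)")

pairs = pairwise_consistency(blues, "Seedyield")
print(f"{len(pairs)} condition pairs; "
      f"mean R2_sma = {pairs['r2_sma'].mean():.2f} "
      "(share of yield variation in one condition explained by another)")

grouped = group_pairs(pairs, ["management"])
print(summarize_groups(grouped).to_string(index=False))
print("levels sharing a letter do not differ at alpha = 0.05 (Fisher LSD)")
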