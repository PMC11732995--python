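"""Generate a small synthetic trial network and clean it.

Builds a 40-cultivar, 12-condition MET, applies the range recoding and the
per-condition +/-4 sd outlier screen, and derives the total fungal
infection (TFI) score per plot.
"""

from metpipe.qc import apply_range_rules, apply_sd_rule, compute_tfi
from metpipe.sim import make_demo_design, simulate

records, truth = simulate(make_demo_design(n_genotypes=40, seed=7))
print(f"simulated {len(records)} plot-trait records, "
      f"{records['genotype'].nunique()} cultivars, "
      f"{records.groupby(['year', 'location', 'management']).ngroups} conditions")

records, n_recoded = apply_range_rules(records)
records, n_excluded = apply_sd_rule(records)
records = compute_tfi(records)
tfi = records[records["trait"] == "TFI"]["value"]

print(f"range rules recoded {n_recoded} values to missing; "
      f"sd screen excluded {n_excluded} observations")
print(f"TFI per plot: mean {tfi.mean():.1f}, max {tfi.max():.1f} "
      "(summed % infected area over six diseases)")
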