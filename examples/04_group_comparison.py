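"""Full cohort group comparison across the sparsity ladder.

Simulates the default cohort (within-module correlation raised by 0.15 in
the poor group's orthographic session only), runs connectivity ->
thresholding -> clustering, and prints which (session, sparsity) cells
show Bonferroni-significant Cp group differences.  The expected pattern:
hits in the orthographic session, none in the phonological one.
"""

from readnet import SyntheticCohortSpec, compare_global_metrics, simulate_cohort
from readnet.pipeline import cohort_connectivity, cohort_metric_table
from readnet.connectivity import default_sparsities

spec = SyntheticCohortSpec(seed=1)
ts_sets, _ = simulate_cohort(spec)
zmats = cohort_connectivity(ts_sets)
table = cohort_metric_table(zmats, default_sparsities(), metrics_wanted=("Cp",))
cmp_table = compare_global_metrics(table, metrics=("Cp",))

print("Cp group comparison (t = good - poor; family = 10 sparsities):")
for session in ("phonological", "orthographic"):
    rows = cmp_table[cmp_table.session == session]
    sig = rows[rows.significant_bonferroni]
    print(f"\n  {session}: {len(sig)}/{len(rows)} Bonferroni-significant")
    for _, row in sig.iterrows():
        print(f"    s={row['sparsity']:.2f}: Cp {row['mean_a']:.3f}+/-{row['sd_a']:.3f} "
              f"vs {row['mean_b']:.3f}+/-{row['sd_b']:.3f}, "
              f"t(30) = {row['t']:.2f}, p = {row['p']:.2g}")
# Negative t: the poor group's orthographic networks are MORE clustered,
# as the injected within-module correlation increase dictates.
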