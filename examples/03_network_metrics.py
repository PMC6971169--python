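"""From one subject's time series to small-world metrics.

Computes the Fisher-z correlation matrix, thresholds it across the
5%-50% sparsity ladder, and prints Cp, Lp, efficiency and the normalized
small-world indices (20 degree-preserving rewired nulls each).
"""

from readnet import (
    SyntheticCohortSpec,
    compute_global_metrics,
    make_block_design,
    roi_correlation_matrix,
    simulate_subject_timeseries,
    sparsity_ladder,
)
from readnet.synthetic import subject_seed

spec = SyntheticCohortSpec(seed=1)
schedule = make_block_design()
ts = simulate_subject_timeseries(
    spec, schedule, "poor", "orthographic",
    subject_seed(1, "poor", "orthographic", 0),
)
zc = roi_correlation_matrix(ts)
print(f"z-matrix: {zc.n_nodes} x {zc.n_nodes}, "
      f"max off-diagonal z = {zc.z.max():.2f}")

print(f"\n{'s':>5} {'Cp':>6} {'Lp':>6} {'E_glob':>7} {'E_loc':>6} "
      f"{'gamma':>6} {'lambda':>7} {'sigma':>6}")
for net in sparsity_ladder(zc):
    m = compute_global_metrics(net, n_null=20, seed=7)
    print(f"{net.sparsity:5.2f} {m['Cp']:6.3f} {m['Lp']:6.3f} "
          f"{m['E_glob']:7.3f} {m['E_loc']:6.3f} {m['gamma']:6.3f} "
          f"{m['lambda']:7.3f} {m['sigma']:6.3f}")
# sigma > 1 across the ladder indicates small-world organization: the
# module-structured generator yields far more clustering than degree-
# matched random graphs (gamma) at only slightly longer paths (lambda).
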