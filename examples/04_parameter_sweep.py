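"""A parameter-grid sweep with reuse of compatible intermediate results.

Plans a 2x2x2 grid (8 assemblies), shows that only sort=1, split=1,
pairwise=2 and assembly=8 step nodes are needed, runs it cold and then
warm, and prints the resource report.  The warm run executes zero nodes —
every intermediate is recognized as compatible and reused.
"""

import tempfile
from pathlib import Path

from omsweep import (
    ErrorProfile, plan_sweep, random_reference, resource_report, run_sweep,
    simulate_molecules,
)

ref = random_reference(500_000, 10.5, seed=5)
ms, _ = simulate_molecules(ref, err=ErrorProfile(seed=6), n_molecules=80)

grid = {
    "pvalue_threshold": [1.11e-4, 1.11e-6],
    "fp_per_100kbp": [0.5, 1.5],
    "fn_rate": [0.15],
    "min_length_kbp": [100.0, 150.0],
    "min_labels": [6],
}
plan = plan_sweep(grid)
print(f"grid: {len(plan.parameter_sets)} parameter combinations")
print(f"planned step nodes: {plan.counts}")

with tempfile.TemporaryDirectory() as cache:
    cold = run_sweep(ms, plan, Path(cache), n_null=100)
    print(f"\ncold run executed {len(cold.executed)} nodes")
    warm = run_sweep(ms, plan, Path(cache), n_null=100)
    print(f"warm run executed {len(warm.executed)} nodes (cache hit on all)")
    print("\nresource report (cold):")
    print(resource_report(plan, cold.executed).to_string(index=False))

best = max(cold.results.items(), key=lambda kv: kv[1].report.n50_bp)
print(f"\nbest N50 {best[1].report.n50_bp/1e3:.0f} kbp at "
      f"threshold={best[0].pvalue_threshold:g}, fp={best[0].fp_per_100kbp}, "
      f"min_length={best[0].min_length_kbp:g} kbp")
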