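"""Primer utilization and priming frequency: table arithmetic + emergent run.

First the arithmetic on published replicate counts (G+U in elongated /
unelongated primers, leading-strand dC), then the same pipeline fed by
simulated forks, where the counts are tallied directly from the primers and
fragments of each run.
"""

from okacycle import SimConfig, make_minicircle, table1_report
from okacycle.experiments import ExperimentSpec, run_table1_pipeline

print("--- arithmetic on published replicate counts (100 uM dGTP) ---")
rep = table1_report(
    [(650, 380, 54_000), (630, 290, 53_000), (810, 380, 82_000)],
    frac_dC=0.45, filled_length=1500,
)
print(rep.rows.to_string(index=False))
print(f"average utilization : {rep.avg_utilization_pct}%  "
      f"(sd {rep.sd_utilization_pct:.0f})")
print(f"average ratio       : {rep.avg_priming_ratio}  "
      f"(sd {rep.sd_priming_ratio:.4f})")
print(f"G+U per fragment    : {rep.gu_per_fragment}")

print("\n--- emergent counts from simulated forks ---")
tpl = make_minicircle(seed=1)
spec = ExperimentSpec(
    name="table1",
    base=SimConfig(template=tpl, duration=120.0, seed=1),
    replicates=20,
)
sim_rep = run_table1_pipeline(spec)
print(f"replicate forks      : {len(sim_rep.rows)}")
print(f"average utilization  : {sim_rep.avg_utilization_pct}%")
print(f"average ratio        : {sim_rep.avg_priming_ratio}")
print(f"gap-filled length    : {sim_rep.filled_length:.0f} nt")
print(f"G+U per fragment     : {sim_rep.gu_per_fragment}")
print(
    "\nWith 12-mer primers on the 48.9%-C template, ~8 of the 12 primer "
    "residues are G or U, and the emergent G+U per fragment lands at 8 - "
    "the same number the count arithmetic yields.  (Simulated utilization "
    "is ~100% because the default model cycles with zero latency; raise "
    "reinit_latency to strand unused primers as in the experiments.)"
)
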