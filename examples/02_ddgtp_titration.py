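"""Chain-terminator titration: fragments shorten, synthesis stays linear.

ddGTP competes with dGTP at every template C and freezes the 3' end when
incorporated.  Under signaling cycling the polymerase abandons the
terminated fragment as soon as the next primer appears, so overall
lagging-strand synthesis continues linearly; under collision cycling the
polymerase is stuck for minutes and synthesis arrests.
"""

from okacycle import SimConfig, make_minicircle
from okacycle.experiments import ExperimentSpec, run_ddgtp_titration

tpl = make_minicircle(seed=1)
base = SimConfig(template=tpl, duration=60.0, seed=1)

for model in ("signaling", "collision"):
    spec = ExperimentSpec(
        name=model,
        base=SimConfig(template=tpl, model=model, duration=60.0, seed=1),
        sweep_param="ddGTP",
        sweep_values=(0.0, 1.0, 2.0, 4.0),
        replicates=10,
    )
    df = run_ddgtp_titration(spec)
    print(f"\n=== {model} model ===")
    print(df.round(3).to_string(index=False))

print(
    "\nSignaling: mean fragment length falls with ddGTP while the linearity "
    "R^2 of cumulative synthesis stays near 1 (cycling continues).\n"
    "Collision: ~1 fragment per fork and a low R^2 (synthesis arrests after "
    "the first terminated fragment)."
)
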