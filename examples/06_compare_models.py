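"""Head-to-head discrimination of the cycling models.

Two statistics separate collision from signaling cycling:
(1) with a chain terminator, signaling keeps cumulative synthesis linear
    while collision arrests;
(2) with the lagging polymerase slowed below the fork rate, collision
    fragments grow geometrically (each fragment must span everything the
    fork exposed while the previous one finished), while signaling
    fragments stay constant-length with gaps.
"""

import json
import warnings

from okacycle import SimConfig, make_minicircle
from okacycle.experiments import ExperimentSpec, compare_models

tpl = make_minicircle(seed=1)
spec = ExperimentSpec(
    name="cmp",
    base=SimConfig(template=tpl, duration=60.0, seed=1),
    replicates=10,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = compare_models(spec)
print(json.dumps(report, indent=2))
print(
    "\nCollision shows a low terminator R^2 and an enormous positive "
    "fragment-length trend; signaling (and the hybrid, whose slow intrinsic "
    "release never beats the primer signal) shows linear synthesis and flat "
    "lengths - the signature observed experimentally."
)
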