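"""From fragments to a densitometry lane to the molar mean length.

Longer fragments carry more label, so raw lane intensity over-weights long
products; the molar mean L = sum(density)/sum(density/length) removes that
bias.  A high-molecular-weight leading-strand smear is added to show why
the statistic is computed below an 8-kb cutoff.
"""

import numpy as np

from okacycle import (
    SimConfig,
    add_leading_smear,
    make_minicircle,
    molar_mean_direct,
    molar_mean_length,
    render_lane,
    simulate,
    write_lane,
)

tpl = make_minicircle(seed=1)
r = simulate(SimConfig(template=tpl, duration=120.0, seed=3))
print(f"fragments simulated   : {len(r.fragments)}")
print(f"direct molar mean     : {molar_mean_direct(r.fragments):.0f} nt")

lane = render_lane(r.fragments, label="dGTP", noise_frac=0.01, seed=3)
print(f"lane molar mean (<8kb): {molar_mean_length(lane):.0f} nt")

smeared = add_leading_smear(lane, leading_extent=r.leading_extent)
print(f"with leading smear    : {molar_mean_length(smeared):.0f} nt  (8-kb cutoff)")
print(f"without cutoff        : {molar_mean_length(smeared, cutoff=np.inf):.0f} nt")

write_lane(smeared, "lane.tsv")
print(
    "\nThe cutoff statistic is untouched by the leading-strand smear, while "
    "the uncut mean is dragged upward by it - the reason only density below "
    "8 kb enters the fragment-length quantification.  Lane written to lane.tsv."
)
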