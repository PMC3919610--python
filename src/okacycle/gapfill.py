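"""In-silico gap-fill assay.

After deproteinization, a non-strand-displacing thermophilic polymerase
extends every fragment's 3' end up to the 5' end of the next downstream
primer.  If fragments were released prematurely (signaling model under slowed
lagging-strand synthesis), the filled lengths reveal the true inter-primer
spacing and the fill increments reveal the gaps.  Pure interval arithmetic:
only the endpoints matter, no polymerase kinetics.

ddGMP-terminated 3' ends cannot be extended (no polymerase removes the
terminator without strand displacement), so runs containing ddGTP are
refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .simulator import OkazakiFragment, SimResult

__all__ = ["FilledFragment", "gap_fill", "gap_stats", "write_gapfill_tsv"]


class GapFillError(ValueError):
    """Gap fill refused or input invalid."""


class EmptyInputError(ValueError):
    """Operation requires at least one fragment."""


@dataclass(frozen=True)
class FilledFragment:
    """An Okazaki fragment after 3'-extension to the next primer."""

    original: OkazakiFragment
    filled_end: int

    @property
    def start(self) -> int:
        return self.original.start

    @property
    def filled_length(self) -> int:
        return self.filled_end - self.original.start

    @property
    def gap_filled(self) -> int:
        return self.filled_end - self.original.end


def gap_fill(
    source: Union[SimResult, Sequence[FilledFragment]],
    leading_extent: int | None = None,
) -> list:
    """Extend each fragment to the next downstream fragment's primer 5' end.

    The most distal fragment is extended to ``leading_extent``.  Idempotent:
    re-filling filled fragments (or a gapless result) changes nothing.
    Refuses results produced in the presence of ddGTP, whose terminated 3'
    ends are not extendable.
    """
    if isinstance(source, SimResult):
        if source.config.pool("ddGTP") > 0:
            raise GapFillError(
                "cannot gap-fill products synthesized with ddGTP: "
                "ddGMP-terminated 3' ends are not extendable"
            )
        frags = list(source.fragments)
        bound = source.leading_extent
        intervals = [(f.start, f.end, f) for f in frags]
    else:
        filled = list(source)
        if leading_extent is None and filled:
            leading_extent = max(f.filled_end for f in filled)
        bound = leading_extent
        intervals = [(f.start, f.filled_end, f.original) for f in filled]

    if not intervals:
        raise EmptyInputError("gap_fill requires at least one fragment")

    intervals.sort(key=lambda iv: iv[0])
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if e0 > s1:
            raise GapFillError(f"overlapping fragments at [{s0},{e0}) and start {s1}")

    out = []
    for i, (start, end, orig) in enumerate(intervals):
        target = intervals[i + 1][0] if i + 1 < len(intervals) else bound
        out.append(FilledFragment(original=orig, filled_end=max(end, target)))
    return out


def gap_stats(filled: Sequence[FilledFragment]) -> dict:
    """Arithmetic summaries of a filled fragment set.

    ``mean_filled_length`` equals the mean inter-primer spacing of used
    primers; ``gap_fraction`` is mean_gap / mean_filled_length.
    """
    filled = list(filled)
    if not filled:
        raise EmptyInputError("gap_stats requires a non-empty list")
    mean_gap = sum(f.gap_filled for f in filled) / len(filled)
    mean_filled = sum(f.filled_length for f in filled) / len(filled)
    return {
        "mean_gap": mean_gap,
        "mean_filled_length": mean_filled,
        "gap_fraction": mean_gap / mean_filled if mean_filled else 0.0,
    }


def write_gapfill_tsv(filled: Sequence[FilledFragment], path, summary_path=None) -> None:
    """Per-fragment TSV (original length, filled length, gap) and optional
    JSON summary."""
    df = pd.DataFrame(
        {
            "start": [f.start for f in filled],
            "original_length": [f.original.length for f in filled],
            "filled_length": [f.filled_length for f in filled],
            "gap_filled": [f.gap_filled for f in filled],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(gap_stats(filled), fh, indent=2)
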