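"""Quantification statistics for lagging-strand products.

Two families of statistics:

* **Molar mean fragment length** from a densitometry lane.  Band intensity is
  proportional to (molar amount) x (length) because longer fragments carry
  more label, so the number-weighted mean length is
  ``L = sum(density_i) / sum(density_i / L_i)``, restricted to bins below a
  cutoff (default 8 kb) that excludes leading-strand products.
  ``molar_mean_direct`` computes the same number-weighted mean straight from
  a fragment multiset and serves as the oracle for the lane-based route.

* **Primer utilization and priming frequency** from incorporation counts:
  utilization = (G+U in elongated primers) / (G+U in all primers);
  priming ratio = (G+U in elongated primers) per leading-strand dNMP, where
  total leading dNMPs are inferred from the leading dC count and the leading
  strand's dC fraction (0.45 by convention); G+U per fragment = priming
  ratio x gap-filled fragment length.

Averaging conventions are reverse-engineered from the published table:
utilization percentages are averaged *after* integer rounding, priming
ratios are averaged *before* rounding.  Both are explicit options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gapfill import FilledFragment
from .gel import LaneProfile
from .simulator import OkazakiFragment

__all__ = [
    "QuantReport",
    "Table1Report",
    "molar_mean_length",
    "molar_mean_direct",
    "utilization_efficiency",
    "priming_ratio",
    "gu_per_fragment",
    "table1_report",
]


class EmptySignalError(ValueError):
    """No usable density below the cutoff / empty fragment set."""


class UndefinedInputError(ValueError):
    """Denominator counts are all zero."""


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class QuantReport:
    """Bundle of the quantification statistics for one condition."""

    molar_mean_length: float | None
    cutoff_used: float
    utilization_pct: int
    priming_ratio: float
    gu_per_fragment: int
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.utilization_pct <= 100:
            raise ValueError("utilization percentage outside [0, 100]")


def molar_mean_length(profile: LaneProfile, cutoff: float = 8000.0) -> float:
    """Molar (number-weighted) mean fragment length from a lane profile.

    ``L = sum(density_i) / sum(density_i / L_i)`` over bins with
    ``L_i < cutoff``; scale-invariant in the densities.  The default 8-kb
    cutoff excludes leading-strand products (a 20-kb cutoff is used for some
    figures; pass it explicitly).
    """
    mask = profile.bin_lengths < cutoff
    dens = profile.density[mask]
    lens = profile.bin_lengths[mask]
    total = dens.sum()
    if total <= 0:
        raise EmptySignalError(f"no density below cutoff {cutoff} nt")
    return float(total / (dens / lens).sum())


def molar_mean_direct(fragments) -> float:
    """Number-weighted mean length of a fragment multiset (the oracle for
    :func:`molar_mean_length`)."""
    lens = []
    for f in fragments:
        if isinstance(f, OkazakiFragment):
            lens.append(f.length)
        elif isinstance(f, FilledFragment):
            lens.append(f.filled_length)
        else:
            lens.append(float(f))
    if not lens:
        raise EmptySignalError("molar_mean_direct requires >= 1 fragment")
    return float(np.mean(lens))


def utilization_efficiency(eGU: float, uGU: float) -> int:
    """Primer utilization as integer percent: 100 * eGU / (eGU + uGU).

    ``eGU``/``uGU`` are G+U counts in elongated / unelongated primers.
    """
    if eGU < 0 or uGU < 0:
        raise UndefinedInputError("G+U counts must be non-negative")
    if eGU + uGU == 0:
        raise UndefinedInputError("both primer G+U counts are zero")
    return int(_round_half_up(100.0 * eGU / (eGU + uGU)))


def priming_ratio(eGU: float, dC_lead: float, frac_dC: float = 0.45) -> float:
    """G+U in elongated primers per leading-strand dNMP, rounded to 4 dp.

    Total leading dNMPs are estimated as dC_lead / frac_dC.
    """
    if dC_lead <= 0:
        raise UndefinedInputError("leading-strand dC count must be > 0")
    if not 0 < frac_dC <= 1:
        raise UndefinedInputError(f"frac_dC={frac_dC} outside (0, 1]")
    return _round_half_up(eGU / (dC_lead / frac_dC), 4)


def gu_per_fragment(ratio: float, filled_length: float) -> int:
    """G+U residues per Okazaki fragment: round(ratio x gap-filled length)."""
    if ratio < 0 or filled_length < 0:
        raise UndefinedInputError("ratio and filled length must be >= 0")
    return int(_round_half_up(ratio * filled_length))


@dataclass(frozen=True)
class Table1Report:
    """Per-row and averaged primer-utilization / priming-frequency columns."""

    rows: pd.DataFrame
    avg_utilization_pct: int
    sd_utilization_pct: float
    avg_priming_ratio: float
    sd_priming_ratio: float
    gu_per_fragment: int
    filled_length: float
    frac_dC: float


def table1_report(
    rows: Sequence[tuple],
    frac_dC: float = 0.45,
    filled_length: float = 1500.0,
    round_eff_before_avg: bool = True,
    round_ratio_before_avg: bool = False,
) -> Table1Report:
    """Full primer-utilization / priming-frequency table for one condition.

    ``rows`` are (eGU, uGU, dC_lead) triples for replicate determinations.
    Per-row utilization is integer percent and per-row ratio is 4 dp;
    default averaging (utilization after rounding, ratio before) reproduces
    the published convention.  G+U per fragment comes from the averaged
    (4 dp) ratio and the gap-filled fragment length.  Standard deviations
    are sample SDs of the per-row values.
    """
    if len(rows) == 0:
        raise UndefinedInputError("table1_report requires >= 1 row")
    recs = []
    for i, (eGU, uGU, dC_lead) in enumerate(rows):
        try:
            eff = utilization_efficiency(eGU, uGU)
            ratio_exact = eGU / (dC_lead / frac_dC)
            ratio = priming_ratio(eGU, dC_lead, frac_dC)
        except UndefinedInputError as exc:
            raise UndefinedInputError(f"row {i}: {exc}") from exc
        recs.append(
            {
                "eGU": eGU, "uGU": uGU, "dC_lead": dC_lead,
                "utilization_pct": eff,
                "priming_ratio": ratio,
                "_ratio_exact": ratio_exact,
                "_eff_exact": 100.0 * eGU / (eGU + uGU),
            }
        )
    df = pd.DataFrame(recs)

    eff_vals = df["utilization_pct"] if round_eff_before_avg else df["_eff_exact"]
    avg_eff = int(_round_half_up(float(eff_vals.mean())))
    ratio_vals = df["priming_ratio"] if round_ratio_before_avg else df["_ratio_exact"]
    avg_ratio = _round_half_up(float(ratio_vals.mean()), 4)

    return Table1Report(
        rows=df.drop(columns=["_ratio_exact", "_eff_exact"]),
        avg_utilization_pct=avg_eff,
        sd_utilization_pct=float(eff_vals.std(ddof=1)) if len(df) > 1 else 0.0,
        avg_priming_ratio=avg_ratio,
        sd_priming_ratio=float(ratio_vals.std(ddof=1)) if len(df) > 1 else 0.0,
        gu_per_fragment=gu_per_fragment(avg_ratio, filled_length),
        filled_length=filled_length,
        frac_dC=frac_dC,
    )
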