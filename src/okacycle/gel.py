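"""Synthetic alkaline-agarose densitometry lanes.

Real fragment populations are observed through a denaturing gel: each
radiolabeled product contributes signal proportional to the number of labeled
nucleotides it carries (longer fragments carry more label — the bias the
molar-mean statistic later removes), spread into a band.  This module renders
a fragment population into a binned lane profile (signal vs length) with a
log-normal band shape and additive truncated-Gaussian noise, so the
quantification statistics can be exercised end to end without gel images.

Mobility physics is abstracted to log-length binning; bins are taken as
already length-calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gapfill import FilledFragment
from .simulator import OkazakiFragment

__all__ = [
    "LaneProfile",
    "render_lane",
    "add_leading_smear",
    "write_lane",
    "read_lane",
    "write_lane_bundle",
]


class LaneFormatError(ValueError):
    """Malformed lane TSV."""


@dataclass(frozen=True)
class LaneProfile:
    """Binned densitometry signal vs fragment length.

    ``bin_lengths`` (nt) are strictly increasing bin centers on a log grid;
    ``density`` is the non-negative signal per bin.
    """

    bin_lengths: np.ndarray
    density: np.ndarray
    label: str = "dGTP"
    meta: str = ""

    def __post_init__(self) -> None:
        bl = np.asarray(self.bin_lengths, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if bl.shape != d.shape:
            raise LaneFormatError("bin_lengths and density must have equal length")
        if np.any(np.diff(bl) <= 0):
            raise LaneFormatError("bin_lengths must be strictly increasing")
        if np.any(d < 0):
            raise LaneFormatError("densities must be non-negative")
        object.__setattr__(self, "bin_lengths", bl)
        object.__setattr__(self, "density", d)


def _length_and_weight(frag, label: str) -> tuple[float, float]:
    if isinstance(frag, OkazakiFragment):
        w = frag.dGMP_count if label == "dGTP" else frag.length
        return float(frag.length), float(w)
    if isinstance(frag, FilledFragment):
        # fill assay labels uniformly (alpha-32P dATP): weight ~ length
        return float(frag.filled_length), float(frag.filled_length)
    return float(frag), float(frag)       # bare length: internal labeling


def render_lane(
    fragments,
    label: str = "dGTP",
    n_bins: int = 200,
    length_range: tuple = (50.0, 50000.0),
    band_sigma_log10: float = 0.02,
    noise_frac: float = 0.01,
    seed: int = 0,
    meta: str = "",
) -> LaneProfile:
    """Render a fragment population into a lane profile.

    Each fragment contributes mass equal to its labeled-nucleotide count
    (dGTP label: its dGMP count; bare lengths and filled fragments: the
    length itself), spread as a Gaussian in log10(length) with width
    ``band_sigma_log10`` and discretized exactly onto the log bin grid (mass
    is conserved up to truncation at the range edges).  Additive Gaussian
    noise with sigma = ``noise_frac`` x max signal, truncated at zero.
    Deterministic per seed.
    """
    lo, hi = length_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid length range {length_range}")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    log_edges = np.log10(edges)

    pairs = [_length_and_weight(f, label) for f in fragments]
    rng = np.random.default_rng(seed)

    if not pairs:
        warnings.warn("rendering an empty fragment list: noise-only lane")
        density = np.clip(rng.normal(0.0, noise_frac, n_bins), 0.0, None)
        return LaneProfile(centers, density, label=label, meta=meta)

    lengths = np.array([p[0] for p in pairs])
    qlo, qhi = np.percentile(lengths, [0.5, 99.5])
    if qlo < lo or qhi > hi:
        warnings.warn(
            f"lane range {length_range} does not cover the fragment length "
            f"percentiles ({qlo:.0f}, {qhi:.0f}); edge bands are truncated"
        )

    density = np.zeros(n_bins)
    for length, w in pairs:
        if length <= 0:
            raise ValueError(f"fragment length must be positive, got {length}")
        if w <= 0:
            continue
        mu = np.log10(length)
        if band_sigma_log10 <= 0:
            j = np.clip(np.searchsorted(edges, length) - 1, 0, n_bins - 1)
            density[j] += w
        else:
            cdf = norm.cdf(log_edges, loc=mu, scale=band_sigma_log10)
            density += w * np.diff(cdf)

    if noise_frac > 0:
        sigma = noise_frac * density.max()
        if sigma > 0:
            density = np.clip(density + rng.normal(0.0, sigma, n_bins), 0.0, None)
    return LaneProfile(centers, density, label=label, meta=meta)


def add_leading_smear(
    profile: LaneProfile, leading_extent: float, label: str = "dCTP",
    weight: float | None = None,
) -> LaneProfile:
    """Add a high-molecular-weight leading-strand band above 8 kb.

    The band is placed at the leading extent, clamped into the lane's range,
    so that the 8-kb analysis cutoff can be exercised.  Zero extent returns
    the profile unchanged.
    """
    if leading_extent == 0:
        return profile
    if leading_extent <= 8000:
        raise ValueError("leading extent must exceed the 8 kb cutoff")
    edges_hi = profile.bin_lengths[-1]
    pos = min(float(leading_extent), 0.9 * edges_hi)
    w = float(weight) if weight is not None else float(leading_extent)
    log_c = np.log10(profile.bin_lengths)
    kernel = np.exp(-0.5 * ((log_c - np.log10(pos)) / 0.02) ** 2)
    kernel /= kernel.sum()
    return replace(profile, density=profile.density + w * kernel)


def write_lane(profile: LaneProfile, path) -> None:
    """Two-column TSV: length_nt, density."""
    pd.DataFrame(
        {"length_nt": profile.bin_lengths, "density": profile.density}
    ).to_csv(path, sep="\t", index=False)


def read_lane(path, label: str = "dGTP", meta: str = "") -> LaneProfile:
    """Read a lane TSV written by :func:`write_lane`."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise LaneFormatError(f"{path}: empty lane file") from exc
    if df.empty:
        raise LaneFormatError(f"{path}: empty lane file")
    if not {"length_nt", "density"} <= set(df.columns):
        raise LaneFormatError(f"{path}: expected columns length_nt, density")
    return LaneProfile(
        df["length_nt"].to_numpy(float), df["density"].to_numpy(float),
        label=label, meta=meta,
    )


def write_lane_bundle(profiles: dict, path) -> None:
    """Multi-lane wide TSV: one density column per condition name."""
    items = list(profiles.items())
    if not items:
        raise ValueError("no lanes to write")
    base = items[0][1].bin_lengths
    data = {"length_nt": base}
    for name, prof in items:
        if not np.array_equal(prof.bin_lengths, base):
            raise LaneFormatError("all lanes in a bundle must share one bin grid")
        data[name] = prof.density
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
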