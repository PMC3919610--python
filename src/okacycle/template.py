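"""Minicircle templates for rolling-circle replication.

A rolling-circle fork copies a small circular duplex over and over, so the
lagging-strand polymerase sees an effectively infinite concatemer of one
circular sequence.  The templates built here have a deliberately asymmetric
base composition between the two strands: the strand copied by the
lagging-strand polymerase carries far more C than G (50:1 by default), so
dGTP analogs (chain terminators, slow analogs) perturb lagging-strand
synthesis almost exclusively.

Coordinates are 0-based, half-open, on the infinite concatemer; the circular
position of a linear coordinate is ``pos % length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularTemplate",
    "make_minicircle",
    "concatemer_position",
    "write_fasta",
    "read_fasta",
]

_BASES = frozenset("ACGT")


class CompositionError(ValueError):
    """Requested base composition does not fit the template length."""


class CoordinateError(ValueError):
    """Invalid concatemer coordinate."""


class FastaFormatError(ValueError):
    """Malformed template FASTA."""


@dataclass(frozen=True)
class CircularTemplate:
    """A minicircle, represented by its lagging-strand template sequence.

    ``lagging_template_seq`` is the strand copied by the lagging-strand
    polymerase, i.e. the leading-strand product read as template.
    ``unique_site`` is the circular position recognised by the exogenous
    15-mer primer in primase-free reactions.
    """

    lagging_template_seq: str
    unique_site: int = 0
    # Derived prefix sums, filled in __post_init__ (kept out of equality).
    _c_prefix: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _ca_prefix: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        seq = self.lagging_template_seq
        if not seq:
            raise CompositionError("template sequence must be non-empty")
        bad = set(seq) - _BASES
        if bad:
            raise FastaFormatError(f"non-ACGT characters in template: {sorted(bad)}")
        if not 0 <= self.unique_site < len(seq):
            raise CoordinateError(
                f"unique_site {self.unique_site} outside [0, {len(seq)})"
            )
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = arr == ord("C")
        is_ca = is_c | (arr == ord("A"))
        object.__setattr__(self, "_c_prefix", np.concatenate([[0], np.cumsum(is_c)]))
        object.__setattr__(self, "_ca_prefix", np.concatenate([[0], np.cumsum(is_ca)]))

    @property
    def length(self) -> int:
        return len(self.lagging_template_seq)

    @property
    def n_C(self) -> int:
        return int(self._c_prefix[-1])

    @property
    def n_G(self) -> int:
        return self.lagging_template_seq.count("G")

    @property
    def n_A(self) -> int:
        return self.lagging_template_seq.count("A")

    @property
    def n_T(self) -> int:
        return self.lagging_template_seq.count("T")

    def base_at(self, linear_pos: int) -> str:
        """Template base at a linear concatemer position (circular lookup)."""
        return concatemer_position(self, linear_pos)

    def count_c(self, start: int, end: int) -> int:
        """Number of template C in concatemer interval ``[start, end)``."""
        return self._count(self._c_prefix, start, end)

    def count_ca(self, start: int, end: int) -> int:
        """Number of template C or A (primer G or U positions) in [start, end)."""
        return self._count(self._ca_prefix, start, end)

    def _count(self, prefix: np.ndarray, start: int, end: int) -> int:
        if start < 0 or end < start:
            raise CoordinateError(f"bad interval [{start}, {end})")
        L = self.length
        per_circle = int(prefix[-1])

        def upto(p: int) -> int:
            return (p // L) * per_circle + int(prefix[p % L])

        return upto(end) - upto(start)


def make_minicircle(
    length: int = 409,
    n_C: int = 200,
    n_G: int = 4,
    seed: int = 0,
    unique_site: int = 0,
) -> CircularTemplate:
    """Generate a minicircle with the requested C and G counts.

    Remaining positions are filled with A and T split as evenly as possible
    (A gets the extra base on odd remainders); base order is a seeded random
    shuffle, so the call is deterministic for fixed arguments.  The default
    composition (200 C : 4 G on 409 nt) gives the 50:1 C:G asymmetry used to
    perturb lagging-strand synthesis specifically.
    """
    if length < 1:
        raise CompositionError("length must be >= 1")
    if n_C < 0 or n_G < 0 or n_C + n_G > length:
        raise CompositionError(
            f"composition n_C={n_C}, n_G={n_G} exceeds length {length}"
        )
    n_rest = length - n_C - n_G
    n_A = (n_rest + 1) // 2
    n_T = n_rest // 2
    bases = np.array(list("C" * n_C + "G" * n_G + "A" * n_A + "T" * n_T))
    rng = np.random.default_rng(seed)
    rng.shuffle(bases)
    return CircularTemplate("".join(bases), unique_site=unique_site)


def concatemer_position(template: CircularTemplate, linear_pos: int) -> str:
    """Base at a linear position on the rolling-circle concatemer."""
    if linear_pos < 0:
        raise CoordinateError(f"negative concatemer position {linear_pos}")
    return template.lagging_template_seq[linear_pos % template.length]


def write_fasta(template: CircularTemplate, path) -> None:
    """Write the template as a single-record FASTA (70-column, uppercase)."""
    rec = SeqRecord(
        Seq(template.lagging_template_seq),
        id=f"minicircle|len={template.length}|site={template.unique_site}",
        description="",
    )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_fasta(path) -> CircularTemplate:
    """Read a single-record template FASTA written by :func:`write_fasta`.

    Lowercase bases are normalised to uppercase; the unique priming site is
    recovered from the ``site=`` header field (0 if absent).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FastaFormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise FastaFormatError(f"{path}: expected 1 record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    site = 0
    for part in rec.id.split("|"):
        if part.startswith("site="):
            site = int(part[5:])
    return CircularTemplate(seq, unique_site=site)
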