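"""Discrete-event simulation of one coupled rolling-circle replication fork.

The model fork carries one leading-strand polymerase that advances
continuously at ``v_lead``, exposing lagging-strand template, and exactly one
lagging-strand polymerase (dimeric replisome).  Primers appear either as a
Poisson process at the fork (DnaG mode) or, in primase-free reactions, by
Bernoulli annealing of a synthetic 15-mer each time the fork passes the
template's unique site (exogenous mode).

The lagging polymerase elongates base by base with deterministic dwell times
(1/rate per nucleotide; the per-C rate comes from the nucleotide pools, all
other positions run at the saturated rate).  At each template C it may
incorporate the chain terminator ddGMP and stall.  What makes it let go of an
unfinished or finished fragment is the *cycling model*:

* ``signaling``  -- deposition of a new primer at the fork triggers release,
  even mid-fragment; a polymerase that finishes (nick) or stalls first waits
  idle for the next primer.
* ``collision``  -- release only through the slow intrinsic pathways:
  exponential release from a nick after fragment completion, or from a
  ddGMP-terminated chain sitting in a gap.
* ``hybrid``     -- both triggers armed, first one wins.

Internally time is tracked against the fork (template coordinates in order of
exposure); results are exported with positions measured along the
lagging-strand product, so a fragment's interval ``[start, end)`` begins at
its primer's 5' end and gap-filling extends ``end`` toward the next
downstream fragment.  Lengths, gaps and spacings are identical in the two
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    KineticParams,
    ddgmp_termination_prob,
    insertion_rate_opposite_C,
    sample_release_time,
)
from .template import CircularTemplate

__all__ = [
    "SimConfig",
    "Primer",
    "OkazakiFragment",
    "SimResult",
    "simulate",
    "incorporation_totals",
    "cumulative_lagging_curve",
    "export_bed",
    "export_events",
]

MODELS = ("collision", "signaling", "hybrid")
PRIMING_MODES = ("dnag", "exogenous")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one fork simulation.

    ``pools`` are concentrations in uM for ``dGTP``, ``ddGTP`` and
    ``dGDPNP`` (missing keys default to 0).  ``target_spacing`` sets the DnaG
    priming rate as ``v_lead / target_spacing`` unless ``primase_rate`` is
    given explicitly; the 1500-nt default corresponds to the physiological
    1-2 kb Okazaki fragment range.
    """

    template: CircularTemplate
    model: str = "signaling"
    priming_mode: str = "dnag"
    primase_rate: Optional[float] = None   # events/s at the fork (dnag mode)
    target_spacing: float = 1500.0
    p_anneal: float = 0.23
    primer_len_dnag: int = 12
    primer_len_exo: int = 15
    pools: dict = field(default_factory=lambda: {"dGTP": 100.0})
    duration: float = 60.0
    seed: int = 0
    params: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.priming_mode not in PRIMING_MODES:
            raise ConfigError(
                f"priming_mode must be one of {PRIMING_MODES}, got {self.priming_mode!r}"
            )
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not 0.0 <= self.p_anneal <= 1.0:
            raise ConfigError("p_anneal must be in [0, 1]")
        unknown = set(self.pools) - {"dGTP", "ddGTP", "dGDPNP"}
        if unknown:
            raise ConfigError(f"unknown pool species {sorted(unknown)}")
        if any(v < 0 for v in self.pools.values()):
            raise ConfigError("pool concentrations must be >= 0")
        if self.pool("dGTP") <= 0 and self.pool("dGDPNP") <= 0:
            raise ConfigError("pools must include dGTP > 0 or dGDPNP > 0")
        if self.priming_mode == "dnag" and self.dnag_rate() <= 0:
            raise ConfigError("primase rate must be > 0 in dnag mode")

    def pool(self, species: str) -> float:
        return float(self.pools.get(species, 0.0))

    def dnag_rate(self) -> float:
        if self.primase_rate is not None:
            return self.primase_rate
        return self.params.v_lead / self.target_spacing

    @property
    def primer_len(self) -> int:
        return self.primer_len_dnag if self.priming_mode == "dnag" else self.primer_len_exo


@dataclass
class Primer:
    """A primer deposited at the fork.

    ``start`` is the concatemer position of the 5' end (product coordinates
    in a finished :class:`SimResult`).  ``gu_count`` is the number of G + U
    residues in a DnaG RNA primer (complement of template C/A); exogenous
    DNA primers carry none.
    """

    start: int
    length: int
    deposited_at: float
    gu_count: int
    used: bool = False


@dataclass
class OkazakiFragment:
    """One lagging-strand product, interval ``[start, end)`` including its primer."""

    primer: Primer
    start: int
    end: int
    terminated_by: str            # nick | ddGMP | signal | timeout
    completed_at: float
    dGMP_count: int
    init_time: float = 0.0        # polymerase bound the primer
    elong_end: float = 0.0        # active synthesis stopped

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def synthesized(self) -> int:
        """Nucleotides polymerised by Pol III (fragment minus primer)."""
        return self.length - self.primer.length


@dataclass
class SimResult:
    """Everything one simulated fork produced."""

    config: SimConfig
    fragments: list
    primers: list
    leading_extent: int
    leading_dCMP_count: int
    gaps: list                    # (start, end) uncovered between fragments
    slack: int                    # censored/unreplicated span (active primer site, trailing)
    event_log: list = field(default_factory=list)

    def total_gap_length(self) -> int:
        return sum(e - s for s, e in self.gaps)

    def check_conservation(self) -> None:
        """Exact bookkeeping identity: fragments + gaps + slack tile the
        leading-strand extent."""
        covered = sum(f.length for f in self.fragments)
        total = covered + self.total_gap_length() + self.slack
        if total != self.leading_extent:
            raise AssertionError(
                f"coverage identity violated: {covered} + gaps "
                f"{self.total_gap_length()} + slack {self.slack} != {self.leading_extent}"
            )


# ---------------------------------------------------------------------------
# internal engine (fork coordinates: position = template exposed before it)
# ---------------------------------------------------------------------------


class _Engine:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.tpl = config.template
        self.params = config.params
        self.rng = np.random.default_rng(config.seed)

        p = self.params
        self.v_oth = p.v_sat * p.alpha_lag
        r_c = 0.0
        if config.pool("dGTP") > 0:
            r_c += insertion_rate_opposite_C("dGTP", config.pool("dGTP"), p)
        if config.pool("dGDPNP") > 0:
            r_c += insertion_rate_opposite_C("dGDPNP", config.pool("dGDPNP"), p)
        self.r_c = r_c * p.alpha_lag
        self.p_term = ddgmp_termination_prob(
            config.pool("ddGTP"), config.pool("dGTP"), p
        )

        seq = np.frombuffer(self.tpl.lagging_template_seq.encode(), dtype=np.uint8)
        self.circle_c_pos = np.flatnonzero(seq == ord("C"))
        self.L = self.tpl.length
        self.Lp = config.primer_len

        self.events: list = []
        self.primers: list = []          # internal records, fork coordinates
        self.unused: list = []           # stack of indices into self.primers
        self.fragments: list = []        # internal fragment dicts
        self._exo_k = -1                 # last circle passage index considered

    # -- template arithmetic ------------------------------------------------

    def _elong_time(self, low: int, high: int) -> float:
        """Seconds to synthesize template interval [low, high)."""
        n = high - low
        if n <= 0:
            return 0.0
        n_c = self.tpl.count_c(low, high)
        if n_c > 0 and self.r_c <= 0:
            return math.inf
        t = (n - n_c) / self.v_oth
        if n_c > 0:
            t += n_c / self.r_c
        return t

    def _advance(self, top_synth: int, floor_pos: int, elapsed: float) -> int:
        """Lowest covered position after ``elapsed`` s of synthesis downward
        from ``top_synth`` (never below ``floor_pos``)."""
        lo, hi = 0, top_synth - floor_pos     # nt synthesized
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self._elong_time(top_synth - mid, top_synth) <= elapsed:
                lo = mid
            else:
                hi = mid - 1
        return top_synth - lo

    def _kth_c_below(self, top: int, k: int) -> Optional[int]:
        """Position of the k-th template C strictly below ``top`` (downward
        scan), or None if fewer than k exist above position 0."""
        total = self.tpl.count_c(0, top)
        j = total - k          # 0-based index of that C from the origin
        if j < 0:
            return None
        n_circle = len(self.circle_c_pos)
        return (j // n_circle) * self.L + int(self.circle_c_pos[j % n_circle])

    # -- primer streams ------------------------------------------------------

    def _next_primer(self, t_after: float):
        """(time, fork position) of the next primer deposition after t_after."""
        cfg = self.cfg
        v = self.params.v_lead
        if cfg.priming_mode == "dnag":
            t = t_after + self.rng.exponential(1.0 / cfg.dnag_rate())
            return (t, int(v * t)) if t < cfg.duration else None
        # exogenous: Bernoulli(p_anneal) at each passage of the unique site
        if cfg.p_anneal == 0.0:
            return None
        site = self.tpl.unique_site
        k = self._exo_k
        while True:
            k += 1
            pos = site + k * self.L
            t = pos / v
            if t <= t_after:
                continue
            if t >= cfg.duration:
                self._exo_k = k
                return None
            self._exo_k = k
            if self.rng.random() < cfg.p_anneal:
                return (t, pos)

    def _deposit(self, t: float, pos: int) -> None:
        if self.cfg.priming_mode == "dnag":
            gu = self.tpl.count_ca(max(0, pos - self.Lp), pos)
        else:
            gu = 0
        self.primers.append(
            {"pos": pos, "t": t, "gu": gu, "used": False, "len": self.Lp}
        )
        self.unused.append(len(self.primers) - 1)
        self.events.append((t, "primer", f"pos={pos}"))

    # -- main loop -----------------------------------------------------------

    def run(self) -> SimResult:
        cfg = self.cfg
        dur = cfg.duration
        signalling = cfg.model in ("signaling", "hybrid")
        collision = cfg.model in ("collision", "hybrid")

        t = 0.0
        state = "unbound"
        pol_ready = 0.0              # earliest time an unbound pol may bind
        boundary = 0                 # coverage top of the previous fragment
        cur = None                   # active fragment (dict) while bound
        t_nick = math.inf
        t_stall = math.inf
        stall_pos = None
        t_release = math.inf         # collision-pathway release completes
        t_signal = math.inf          # pending signaling trigger fires
        t_stalled_at = math.inf      # when active synthesis hit a ddGMP
        next_primer = self._next_primer(0.0)

        def close_fragment(low: int, terminated_by: str, completed_at: float,
                           elong_end: float) -> None:
            nonlocal boundary, cur
            cur["low"] = low
            cur["terminated_by"] = terminated_by
            cur["completed_at"] = completed_at
            cur["elong_end"] = elong_end
            self.fragments.append(cur)
            boundary = cur["top"]
            self.events.append(
                (completed_at, "fragment", f"[{low},{cur['top']}) {terminated_by}")
            )
            cur = None

        def position_now(at: float) -> int:
            start_pos = cur["top"] - self.Lp
            floor_pos = stall_pos if stall_pos is not None else cur["target"]
            return self._advance(start_pos, floor_pos, at - cur["t_init"])

        while True:
            # candidate events, ties broken by listed priority
            cands = []
            if state == "elongating":
                cands.append((t_nick, 0, "nick"))
                cands.append((t_stall, 0, "stall"))
            if collision and state == "releasing":
                cands.append((t_release, 1, "release"))
            if t_signal < math.inf:
                cands.append((t_signal, 2, "signal"))
            if next_primer is not None:
                cands.append((next_primer[0], 3, "primer"))
            if state == "unbound" and self.unused:
                cands.append((max(t, pol_ready), 4, "bind"))

            cands = [c for c in cands if c[0] < dur and c[0] < math.inf]
            if not cands:
                break
            t, _, kind = min(cands)

            if kind == "primer":
                tp, pos = next_primer
                self._deposit(tp, pos)
                next_primer = self._next_primer(tp)
                if signalling and state != "unbound":
                    t_signal = min(t_signal, tp + self.params.signaling_latency)

            elif kind == "nick":
                if cfg.model == "signaling":
                    state = "complete"   # waits idle for the next primer
                    self.events.append((t, "nick", f"pos={cur['target']}"))
                else:
                    close_fragment(cur["target"], "nick", t, t)
                    t_release = t + sample_release_time("nick", self.params, self.rng)
                    state = "releasing"
                t_nick = t_stall = math.inf

            elif kind == "stall":
                self.events.append((t, "stall", f"pos={stall_pos}"))
                if cfg.model == "signaling":
                    state = "stalled"
                    t_stalled_at = t
                else:
                    close_fragment(stall_pos, "ddGMP", t, t)
                    t_release = t + sample_release_time("stall", self.params, self.rng)
                    state = "releasing"
                    stall_pos = None
                t_nick = t_stall = math.inf

            elif kind == "release":
                state = "unbound"
                pol_ready = t + self.params.reinit_latency
                t_release = math.inf
                t_signal = math.inf
                stall_pos = None

            elif kind == "signal":
                if state == "elongating":
                    close_fragment(position_now(t), "signal", t, t)
                elif state == "stalled":
                    close_fragment(stall_pos, "ddGMP", t, t_stalled_at)
                elif state == "complete":
                    close_fragment(cur["target"], "nick", cur["t_nick"], cur["t_nick"])
                state = "unbound"
                pol_ready = t + self.params.reinit_latency
                t_signal = math.inf
                t_release = math.inf
                t_nick = t_stall = math.inf
                stall_pos = None
                t_stalled_at = math.inf

            elif kind == "bind":
                idx = self.unused.pop()
                prm = self.primers[idx]
                if prm["pos"] - self.Lp < boundary:
                    continue  # primer annealed over covered DNA; skip it
                prm["used"] = True
                cur = {
                    "primer_idx": idx,
                    "top": prm["pos"],
                    "target": boundary,
                    "t_init": t,
                    "t_nick": math.inf,
                }
                start_pos = cur["top"] - self.Lp
                dist = start_pos - cur["target"]
                self.events.append((t, "init", f"primer@{prm['pos']}"))
                # schedule nick / stall
                t_nick = t + self._elong_time(cur["target"], start_pos)
                cur["t_nick"] = t_nick
                t_stall = math.inf
                stall_pos = None
                if self.p_term > 0.0 and dist > 0:
                    k = int(self.rng.geometric(self.p_term))
                    m = self.tpl.count_c(cur["target"], start_pos)
                    if k <= m:
                        z = self._kth_c_below(start_pos, k)
                        n_nt = start_pos - z
                        t_stall = t + k / self.r_c + (n_nt - k) / self.v_oth
                        stall_pos = z
                        t_nick = math.inf
                state = "elongating"
                if dist <= 0:            # nothing to synthesize: instant nick
                    t_nick = t
                    t_stall = math.inf
                    stall_pos = None

        # --- end of run: close out censored state --------------------------
        if cur is not None:
            if state == "elongating":
                close_fragment(position_now(dur), "timeout", dur, dur)
            elif state == "stalled":
                close_fragment(stall_pos, "ddGMP", dur, t_stalled_at)
            elif state == "complete":
                close_fragment(cur["target"], "nick", cur["t_nick"], cur["t_nick"])

        return self._build_result()

    # -- result assembly (flip to product coordinates) ----------------------

    def _build_result(self) -> SimResult:
        cfg = self.cfg
        L_tot = int(self.params.v_lead * cfg.duration)
        lead_c = self.tpl.count_c(0, L_tot)

        primer_objs = []
        for p in self.primers:
            primer_objs.append(
                Primer(
                    start=L_tot - p["pos"],
                    length=p["len"],
                    deposited_at=p["t"],
                    gu_count=p["gu"],
                    used=p["used"],
                )
            )

        frags = []
        gaps = []
        slack = L_tot
        prev_top = 0
        for f in sorted(self.fragments, key=lambda d: d["top"]):
            prm = primer_objs[f["primer_idx"]]
            low, top = f["low"], f["top"]
            synth_top = top - prm.length
            dgmp = self.tpl.count_c(low, max(low, synth_top))
            frags.append(
                OkazakiFragment(
                    primer=prm,
                    start=L_tot - top,
                    end=L_tot - low,
                    terminated_by=f["terminated_by"],
                    completed_at=f["completed_at"],
                    dGMP_count=dgmp,
                    init_time=f["t_init"],
                    elong_end=f["elong_end"],
                )
            )
            if low > prev_top:
                if f["terminated_by"] == "timeout":
                    pass                      # censored span stays slack
                else:
                    gaps.append((L_tot - low, L_tot - prev_top))
                    slack -= low - prev_top
            slack -= top - low
            prev_top = top

        frags.sort(key=lambda fr: fr.start)
        gaps.sort()
        result = SimResult(
            config=cfg,
            fragments=frags,
            primers=primer_objs,
            leading_extent=L_tot,
            leading_dCMP_count=lead_c,
            gaps=gaps,
            slack=slack,
            event_log=sorted(self.events),
        )
        result.check_conservation()
        return result


def simulate(config: SimConfig) -> SimResult:
    """Run one fork to ``config.duration`` seconds.

    Deterministic for a fixed ``(config, seed)``.  A lagging polymerase with
    zero elongation rate never raises; the open fragment is closed with the
    ``timeout`` flag at the end of the run.
    """
    return _Engine(config).run()


def incorporation_totals(result: SimResult, strand: str) -> int:
    """Labeled-nucleotide tally: dCMP on the leading strand, dGMP summed over
    Okazaki fragments on the lagging strand (the two radiolabels of the
    rolling-circle assay)."""
    if strand == "leading":
        return result.leading_dCMP_count
    if strand == "lagging":
        return sum(f.dGMP_count for f in result.fragments)
    raise ValueError(f"strand must be 'leading' or 'lagging', got {strand!r}")


def cumulative_lagging_curve(result: SimResult, times: np.ndarray) -> np.ndarray:
    """Cumulative lagging-strand nucleotides synthesized at each time point.

    Within a fragment, synthesis is interpolated linearly between the
    polymerase binding its primer and the end of active elongation; this is
    exact for a composition-homogeneous template and a very close
    approximation otherwise.
    """
    times = np.asarray(times, dtype=float)
    total = np.zeros_like(times)
    for f in result.fragments:
        n = f.synthesized
        if n <= 0:
            continue
        t0, t1 = f.init_time, f.elong_end
        if t1 <= t0:
            total += np.where(times >= t1, n, 0.0)
        else:
            frac = np.clip((times - t0) / (t1 - t0), 0.0, 1.0)
            total += n * frac
    return total


def export_bed(result: SimResult, path) -> None:
    """Write fragments, primers and gaps as a BED-like TSV (0-based,
    half-open, positions along the lagging-strand product)."""
    rows = []
    for i, f in enumerate(result.fragments):
        rows.append(("concatemer", f.start, f.end, f"fragment_{i}",
                     f"fragment:{f.terminated_by}"))
    for i, p in enumerate(result.primers):
        rows.append(("concatemer", p.start, p.start + p.length, f"primer_{i}",
                     f"primer:{'used' if p.used else 'unused'}"))
    for i, (s, e) in enumerate(result.gaps):
        rows.append(("concatemer", s, e, f"gap_{i}", "gap"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "kind"])
    df.to_csv(path, sep="\t", index=False)


def export_events(result: SimResult, path) -> None:
    """Write the time-stamped event log as TSV."""
    df = pd.DataFrame(result.event_log, columns=["time", "kind", "detail"])
    df.to_csv(path, sep="\t", index=False)
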