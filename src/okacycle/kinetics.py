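"""Rate laws for the replication-fork simulator.

Three kinetic ingredients drive the model:

* Michaelis-Menten insertion opposite template C.  dGTP is fast and tight
  (K_m ~ 2 uM); the non-hydrolysable analog dGDPNP binds weakly (K_m ~ 40 uM)
  and is chemistry-limited, so lowering its concentration dials down the
  lagging-strand elongation rate without starving the other dNTPs.
* Chain termination by ddGTP.  Each template C is a competition between dGTP
  and ddGTP; incorporation of ddGMP freezes the 3' end.
* Polymerase release.  Release of the replicase from a nick (completed
  fragment) or from a ddNMP-terminated chain in a gap is slow (half-lives of
  minutes, exponential); release on a signaling trigger is effectively
  instantaneous.

``v_chem_dGDPNP`` and ``f_sel`` are calibrated, not measured: the former so
that a template with 25% C (the M13 surrogate) elongates at 23 nt/s with
30 uM dGDPNP, the latter so that 4 uM ddGTP against 100 uM dGTP halves a
1500-nt fragment.  Both calibrations are closed-form / root-found here and
shipped as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "insertion_rate_opposite_C",
    "composite_velocity",
    "calibrate_dgdpnp",
    "ddgmp_termination_prob",
    "sample_release_time",
    "V_CHEM_DGDPNP_DEFAULT",
    "F_SEL_DEFAULT",
]

LN2 = math.log(2.0)


class ParameterError(ValueError):
    """Unknown species or invalid kinetic parameter."""


class CalibrationError(ValueError):
    """Requested calibration target is infeasible."""


def _solve_v_chem(
    v_sat: float, km: float, target_rate: float, f_c: float, conc: float
) -> float:
    # Invert the harmonic composite velocity for the per-C rate, then the
    # MM form for the chemistry-limited maximum.
    inv_rest = (1.0 - f_c) / v_sat
    if target_rate >= v_sat or 1.0 / target_rate <= inv_rest:
        raise CalibrationError(
            f"target rate {target_rate} nt/s infeasible with v_sat={v_sat}"
        )
    r_c = f_c / (1.0 / target_rate - inv_rest)
    return r_c * (km + conc) / conc


def _solve_f_sel(
    *,
    spacing: float = 1500.0,
    target_len: float = 750.0,
    f_c: float = 200.0 / 409.0,
    ddgtp: float = 4.0,
    dgtp: float = 100.0,
) -> float:
    """Selection factor such that ddGTP at ``ddgtp`` uM halves a fragment.

    Run length to the terminating nucleotide is geometric with per-nt hazard
    q = f_C * p; E[min(run, spacing)] = (1-(1-q)^spacing)/q is set equal to
    ``target_len`` and solved for q, then p, then f_sel.
    """

    def expected(q: float) -> float:
        return (1.0 - (1.0 - q) ** spacing) / q

    q = brentq(lambda q: expected(q) - target_len, 1e-8, 0.5, xtol=1e-14)
    p = q / f_c
    odds = p / (1.0 - p)
    return odds * dgtp / ddgtp


#: Chemistry-limited maximal insertion rate opposite C with dGDPNP (nt/s),
#: calibrated to the 23 nt/s composite velocity on a 25%-C template at 30 uM.
V_CHEM_DGDPNP_DEFAULT: float = _solve_v_chem(570.0, 40.0, 23.0, 0.25, 30.0)

#: ddGTP-vs-dGTP selection factor, calibrated to ~2-fold fragment shortening
#: at 4 uM ddGTP / 100 uM dGTP on the default (48.9% C) template.
F_SEL_DEFAULT: float = _solve_f_sel()


@dataclass(frozen=True)
class KineticParams:
    """All rate constants used by the fork simulator.

    Rates in nt/s, concentrations in uM, times in s.  ``alpha_lag`` is the
    empirical fork-coupled acceleration of the lagging-strand polymerase; it
    is a free parameter (default 1, no acceleration) because the coupled-fork
    rate has not been measured directly.
    """

    v_sat: float = 570.0            # elongation at saturating dNTPs
    v_lead: float = 420.0           # leading strand on the minicircle
    Km_dGTP: float = 2.0
    Km_dGDPNP: float = 40.0
    v_chem_dGDPNP: float = V_CHEM_DGDPNP_DEFAULT
    f_sel: float = F_SEL_DEFAULT
    t_half_nick: float = 120.0      # release after gap -> nick conversion
    t_half_stall: float = 480.0     # release of ddNMP-terminated chain (6-11 min range)
    alpha_lag: float = 1.0
    signaling_latency: float = 0.0
    reinit_latency: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "v_sat", "v_lead", "Km_dGTP", "Km_dGDPNP", "v_chem_dGDPNP",
            "t_half_nick", "t_half_stall",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.f_sel < 0:
            raise ParameterError("f_sel must be >= 0")
        if self.signaling_latency < 0 or self.reinit_latency < 0:
            raise ParameterError("latencies must be >= 0")
        if self.alpha_lag < 1.0:
            import warnings

            warnings.warn(
                f"alpha_lag={self.alpha_lag} < 1: lagging polymerase slower "
                "than its uncoupled rate", stacklevel=2,
            )


def insertion_rate_opposite_C(
    species: str,
    conc: float,
    params: KineticParams,
    fork_coupled: bool = False,
) -> float:
    """Michaelis-Menten insertion rate opposite template C (nt/s).

    ``fork_coupled=True`` applies the ``alpha_lag`` multiplier used for the
    lagging-strand polymerase inside a coupled fork.
    """
    if conc < 0:
        raise ParameterError(f"negative concentration {conc}")
    if species == "dGTP":
        vmax, km = params.v_sat, params.Km_dGTP
    elif species == "dGDPNP":
        vmax, km = params.v_chem_dGDPNP, params.Km_dGDPNP
    else:
        raise ParameterError(f"unknown nucleotide species {species!r}")
    rate = vmax * conc / (km + conc)
    if fork_coupled:
        rate *= params.alpha_lag
    return rate


def composite_velocity(f_C: float, r_C: float, params: KineticParams) -> float:
    """Mean elongation velocity on a template with C fraction ``f_C``.

    Harmonic mixture of the per-C rate ``r_C`` and the saturated rate at all
    other positions: 1 / (f_C/r_C + (1-f_C)/v_sat).  A stalled per-C rate
    (r_C = 0 with f_C > 0) gives velocity 0, not an error.
    """
    if not 0.0 <= f_C <= 1.0:
        raise ParameterError(f"f_C={f_C} outside [0, 1]")
    if f_C == 0.0:
        return params.v_sat
    if r_C <= 0.0:
        return 0.0
    return 1.0 / (f_C / r_C + (1.0 - f_C) / params.v_sat)


def calibrate_dgdpnp(
    params: KineticParams,
    target_rate: float = 23.0,
    f_C: float = 0.25,
    conc: float = 30.0,
) -> KineticParams:
    """Return params with ``v_chem_dGDPNP`` set so the composite velocity on a
    ``f_C``-C template at ``conc`` uM dGDPNP equals ``target_rate``."""
    v_chem = _solve_v_chem(params.v_sat, params.Km_dGDPNP, target_rate, f_C, conc)
    return replace(params, v_chem_dGDPNP=v_chem)


def ddgmp_termination_prob(
    ddGTP_conc: float, dGTP_conc: float, params: KineticParams
) -> float:
    """Probability that a given template C receives ddGMP (chain terminator).

    Simple competitive incorporation: p = s/(1+s) with the selection-weighted
    concentration ratio s = f_sel * [ddGTP]/[dGTP].  Zero dGTP with any ddGTP
    present forces termination (p = 1).
    """
    if ddGTP_conc < 0:
        raise ParameterError("ddGTP concentration must be >= 0")
    if ddGTP_conc == 0.0:
        return 0.0
    if dGTP_conc <= 0.0:
        return 1.0
    s = params.f_sel * ddGTP_conc / dGTP_conc
    return s / (1.0 + s)


def sample_release_time(
    context: str, params: KineticParams, rng: np.random.Generator
) -> float:
    """Draw a polymerase release time (s) for the given context.

    ``nick`` and ``stall`` are exponential with the corresponding half-life
    (scale = t_half / ln 2); ``signal`` is the constant signaling latency.
    """
    if context == "nick":
        return float(rng.exponential(params.t_half_nick / LN2))
    if context == "stall":
        return float(rng.exponential(params.t_half_stall / LN2))
    if context == "signal":
        return params.signaling_latency
    raise ParameterError(f"unknown release context {context!r}")
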