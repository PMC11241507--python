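"""Non-compartmental analysis of single- and multiple-dose concentration profiles.

All areas use the strictly linear trapezoidal rule (AUC on C, AUMC on t*C).
The terminal elimination rate constant ke is the negative slope of ln(C)
versus t over a terminal window; by default the window is chosen by an
exhaustive search over all contiguous windows of at least ``min_points``
positive concentrations strictly after Tmax, maximizing the adjusted r².
Extrapolations to infinity follow the standard identities

    AUC_inf  = AUC_t  + C_last / ke
    AUMC_inf = AUMC_t + C_last * t_last / ke + C_last / ke**2

with CL/F = dose / AUC_inf (single dose) or dose / AUC_tau (multiple dose),
MRT = AUMC_inf / AUC_inf, and Vss/F = CL/F * MRT.  The accumulation index for
a three-day once-daily regimen is AUC_tau(day 3) / AUC_tau(day 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .pk_models import ConcentrationProfile

__all__ = [
    "NCAError",
    "TerminalPhase",
    "NCAResult",
    "terminal_phase",
    "auc_aumc",
    "nca_single_dose",
    "nca_multiple_dose",
]


class NCAError(ValueError):
    """Profile unsuitable for the requested NCA computation."""


#: Above this many candidate terminal points the window search anchors at the
#: last measurable point instead of trying every start/end pair.
_FULL_SEARCH_LIMIT = 50


@dataclass(frozen=True)
class TerminalPhase:
    """Terminal log-linear regression result."""

    ke: float
    t_half: float
    n_points: int
    r2: float
    adjusted_r2: float
    t_start: float
    t_end: float


@dataclass
class NCAResult:
    """The full non-compartmental parameter set for one profile.

    Multiple-dose-only entries (``AUC_tau``, ``Cavg``, ``accumulation_index``)
    are ``None`` for single-dose profiles.
    """

    analyte: str | None
    subject_id: str | None
    ke: float
    t_half: float
    Tmax: float
    Cmax: float
    AUC_t: float
    AUC_inf: float
    AUMC_t: float
    AUMC_inf: float
    CL_over_F: float
    MRT: float
    Vss_over_F: float
    n_terminal_points: int
    terminal_r2: float
    AUC_tau: float | None = None
    Cavg: float | None = None
    accumulation_index: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# terminal phase
# ---------------------------------------------------------------------------


def _fit_window(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """(slope, r2) of the log-linear regression over one candidate window."""
    res = stats.linregress(t, logc)
    return res.slope, res.rvalue**2


def terminal_phase(
    profile: ConcentrationProfile,
    *,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> TerminalPhase:
    """Estimate ke and t_half by log-linear regression of the terminal phase.

    With ``window=None`` contiguous windows of >= ``min_points`` positive
    concentrations strictly after Tmax are scored and the best adjusted-r²
    window (ties to the longer window) wins.  Sparse profiles (up to
    ``_FULL_SEARCH_LIMIT`` candidate points) are searched exhaustively over
    every start/end pair; denser profiles search the windows anchored at the
    last measurable point, the usual best-fit convention, which keeps the
    search linear in profile length.  An explicit ``(t_start, t_end)`` window
    overrides the search.  Raises :class:`NCAError` when fewer than
    ``min_points`` usable points exist or no window has a negative slope.
    """
    t = profile.times
    c = profile.concentrations
    imax = int(np.argmax(c))  # earliest maximum
    usable = [i for i in range(imax + 1, len(t)) if c[i] > 0]
    if window is not None:
        lo, hi = window
        usable = [i for i in usable if lo <= t[i] <= hi]
        if len(usable) < min_points:
            raise NCAError(
                f"terminal window [{lo}, {hi}] holds {len(usable)} positive points after Tmax; "
                f"need >= {min_points}"
            )
        candidates = [usable]
    else:
        if len(usable) < min_points:
            raise NCAError(
                f"{len(usable)} positive concentrations after Tmax; need >= {min_points} "
                "for terminal regression"
            )
        if len(usable) <= _FULL_SEARCH_LIMIT:
            candidates = [
                usable[i : j + 1]
                for i in range(len(usable))
                for j in range(i + min_points - 1, len(usable))
            ]
        else:
            candidates = [usable[i:] for i in range(len(usable) - min_points + 1)]

    best: tuple[float, int, list[int], float, float] | None = None
    for idx in candidates:
        ts, logc = t[idx], np.log(c[idx])
        if np.ptp(ts) == 0:
            continue
        slope, r2 = _fit_window(ts, logc)
        if slope >= 0:
            continue
        n = len(idx)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        key = (adj, n)
        if best is None or key > (best[0], best[1]):
            best = (adj, n, idx, slope, r2)
    if best is None:
        raise NCAError("no terminal window with a negative slope (no measurable elimination)")
    adj, n, idx, slope, r2 = best
    ke = -slope
    return TerminalPhase(
        ke=ke,
        t_half=math.log(2) / ke,
        n_points=n,
        r2=r2,
        adjusted_r2=adj,
        t_start=float(t[idx[0]]),
        t_end=float(t[idx[-1]]),
    )


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------


def _interval_grid(
    t: np.ndarray, c: np.ndarray, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    if t_end <= t_start:
        raise NCAError(f"empty integration interval [{t_start}, {t_end}]")
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise NCAError(
            f"interval [{t_start}, {t_end}] extends beyond observations [{t[0]}, {t[-1]}]"
        )
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inner], [t_end]])
    cc = np.concatenate([[np.interp(t_start, t, c)], c[inner], [np.interp(t_end, t, c)]])
    return tt, cc


def auc_aumc(
    profile: ConcentrationProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> tuple[float, float]:
    """Linear-trapezoid AUC and AUMC over ``[t_start, t_end]`` (default: full profile).

    Endpoints that are not observation times are linearly interpolated.
    """
    t, c = profile.times, profile.concentrations
    tt, cc = _interval_grid(t, c, t[0] if t_start is None else t_start, t[-1] if t_end is None else t_end)
    return float(np.trapezoid(cc, tt)), float(np.trapezoid(tt * cc, tt))


# ---------------------------------------------------------------------------
# single- and multiple-dose NCA
# ---------------------------------------------------------------------------


def _extrapolate(
    auc_t: float, aumc_t: float, c_last: float, t_last: float, ke: float
) -> tuple[float, float]:
    if c_last <= 0:
        return auc_t, aumc_t
    return (
        auc_t + c_last / ke,
        aumc_t + c_last * t_last / ke + c_last / ke**2,
    )


def nca_single_dose(
    profile: ConcentrationProfile,
    dose: float,
    *,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> NCAResult:
    """Full single-dose NCA; ``dose`` must share the profile's unit system."""
    term = terminal_phase(profile, min_points=min_points, window=window)
    t, c = profile.times, profile.concentrations
    auc_t, aumc_t = auc_aumc(profile)
    auc_inf, aumc_inf = _extrapolate(auc_t, aumc_t, float(c[-1]), float(t[-1]), term.ke)
    imax = int(np.argmax(c))  # ties broken by earliest time
    cl = dose / auc_inf
    mrt = aumc_inf / auc_inf
    return NCAResult(
        analyte=profile.analyte,
        subject_id=profile.subject_id,
        ke=term.ke,
        t_half=term.t_half,
        Tmax=float(t[imax]),
        Cmax=float(c[imax]),
        AUC_t=auc_t,
        AUC_inf=auc_inf,
        AUMC_t=aumc_t,
        AUMC_inf=aumc_inf,
        CL_over_F=cl,
        MRT=mrt,
        Vss_over_F=cl * mrt,
        n_terminal_points=term.n_points,
        terminal_r2=term.r2,
    )


def _shifted(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Profile re-expressed as time after its first observation (dose time)."""
    return ConcentrationProfile(
        analyte=profile.analyte,
        times=profile.times - profile.times[0],
        concentrations=profile.concentrations.copy(),
        subject_id=profile.subject_id,
        species=profile.species,
        body_weight_kg=profile.body_weight_kg,
        meta=dict(profile.meta),
    )


def nca_multiple_dose(
    day1_profile: ConcentrationProfile,
    dayN_profile: ConcentrationProfile,
    dose: float,
    tau: float,
    *,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> NCAResult:
    """Multiple-dose NCA from the first and last dosing-interval profiles.

    Each profile must start at its dose time and span at least one full
    interval ``tau``.  CL/F uses dose / AUC_tau of the final interval, the
    accumulation index is AUC_tau(day N) / AUC_tau(day 1), and terminal-phase
    and moment quantities come from the final-interval profile (expressed as
    time after dose).
    """
    for name, prof in (("day 1", day1_profile), ("day N", dayN_profile)):
        span = prof.times[-1] - prof.times[0]
        if span < tau - 1e-9:
            raise NCAError(f"{name} profile spans {span} h, shorter than tau = {tau} h")
    d1 = _shifted(day1_profile)
    dn = _shifted(dayN_profile)
    auc_tau_1, _ = auc_aumc(d1, 0.0, tau)
    auc_tau_n, _ = auc_aumc(dn, 0.0, tau)
    if auc_tau_1 <= 0:
        raise NCAError("day 1 AUC_tau is zero; accumulation index undefined")
    term = terminal_phase(dn, min_points=min_points, window=window)
    t, c = dn.times, dn.concentrations
    auc_t, aumc_t = auc_aumc(dn)
    auc_inf, aumc_inf = _extrapolate(auc_t, aumc_t, float(c[-1]), float(t[-1]), term.ke)
    imax = int(np.argmax(c))
    cl = dose / auc_tau_n
    mrt = aumc_inf / auc_inf
    return NCAResult(
        analyte=dayN_profile.analyte,
        subject_id=dayN_profile.subject_id,
        ke=term.ke,
        t_half=term.t_half,
        Tmax=float(t[imax]),
        Cmax=float(c[imax]),
        AUC_t=auc_t,
        AUC_inf=auc_inf,
        AUMC_t=aumc_t,
        AUMC_inf=aumc_inf,
        CL_over_F=cl,
        MRT=mrt,
        Vss_over_F=cl * mrt,
        n_terminal_points=term.n_points,
        terminal_r2=term.r2,
        AUC_tau=auc_tau_n,
        Cavg=auc_tau_n / tau,
        accumulation_index=auc_tau_n / auc_tau_1,
    )
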