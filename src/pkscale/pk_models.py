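"""Compartmental models for oral pyronaridine, artesunate, and dihydroartemisinin.

Four structures are supported, all with first-order absorption from a depot
compartment and first-order (apparent, bioavailability-uncorrected) disposition:

* one-compartment parent model (pyronaridine in hamsters and rats),
* two-compartment parent model (pyronaridine in dogs),
* parent-metabolite model with enzyme-turnover auto-induction and a
  one-compartment parent (artesunate/dihydroartemisinin in hamsters),
* the same with a two-compartment parent (artesunate/dihydroartemisinin in rats).

In the auto-induction variants a relative enzyme amount ``AENZ`` (baseline 1)
multiplies the parent elimination clearance.  Enzyme production is stimulated by
the parent concentration through an Emax relationship,

    dAENZ/dt = k_enz * (1 + Emax * C / (EC50 + C)) - k_enz * AENZ,

so repeated dosing transiently raises the parent's apparent clearance and the
day-3 exposure falls below day-1 (accumulation index < 1).  The eliminated
parent mass feeds the metabolite compartment, whose apparent volume and
clearance are scaled by the (unidentifiable) product F*Fm.

The engine is unit-agnostic: doses, volumes, and clearances must share one
consistent unit system per dataset (per-kg dosing pairs with per-kg volumes and
clearances).  Molar or salt-form conversions are the caller's responsibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ModelError",
    "DoseEvent",
    "Regimen",
    "OneCptOralParams",
    "TwoCptOralParams",
    "ParentMetaboliteAutoInductionParams",
    "ConcentrationProfile",
    "PARENT",
    "METABOLITE",
    "state_names",
    "initial_state",
    "evaluate_rhs",
    "simulate",
    "closed_form_one_cpt_oral",
    "apply_blood_plasma_ratio",
]

# Solver defaults: stiff-capable integrator (LSODA via scipy.integrate.odeint),
# restarted at every dose event so the depot discontinuities are exact.
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
_MAX_STEPS = 10**6
# Negative concentrations from solver wobble are clamped to zero on output; a
# warning is raised only when the excursion exceeds this multiple of atol.
NEG_CLAMP_WARN_FACTOR = 100.0

PARENT = "parent"
METABOLITE = "metabolite"


class ModelError(ValueError):
    """Invalid model parameters, state, dosing input, or solver failure."""


def _check_positive(obj, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if value is None or not math.isfinite(value) or value <= 0:
            raise ModelError(f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}")


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEvent:
    """An instantaneous oral bolus into the absorption compartment."""

    time: float
    amount: float
    analyte: str = PARENT

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ModelError(f"dose time must be >= 0, got {self.time!r}")
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ModelError(f"dose amount must be >= 0, got {self.amount!r}")


@dataclass(frozen=True)
class Regimen:
    """A sequence of dose events plus the nominal dosing interval.

    ``tau`` (hours) is required whenever more than one dose is given; it is the
    interval used for AUC_tau / C_avg computations downstream.
    """

    doses: tuple[DoseEvent, ...]
    tau: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        if not self.doses:
            raise ModelError("a regimen needs at least one dose event")
        times = [d.time for d in self.doses]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ModelError("dose times must be strictly increasing")
        if self.n_doses > 1 and (self.tau is None or self.tau <= 0):
            raise ModelError("tau > 0 is required for multiple dosing")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "Regimen":
        return cls((DoseEvent(time, amount),))

    @classmethod
    def daily(cls, amount: float, n_doses: int, tau: float = 24.0) -> "Regimen":
        doses = tuple(DoseEvent(i * tau, amount) for i in range(n_doses))
        return cls(doses, tau=tau if n_doses > 1 else None)


# ---------------------------------------------------------------------------
# parameter vectors (the model structure is implied by the parameter type)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OneCptOralParams:
    """One-compartment oral model: depot -> central -> out."""

    ka: float
    V_over_F: float
    CL_over_F: float

    def __post_init__(self) -> None:
        _check_positive(self, ("ka", "V_over_F", "CL_over_F"))

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("ka", "V_over_F", "CL_over_F")

    @property
    def ke(self) -> float:
        return self.CL_over_F / self.V_over_F


@dataclass(frozen=True)
class TwoCptOralParams:
    """Two-compartment oral model with intercompartmental clearance CL2."""

    ka: float
    V_over_F: float
    V2_over_F: float
    CL_over_F: float
    CL2_over_F: float

    def __post_init__(self) -> None:
        _check_positive(self, ("ka", "V_over_F", "V2_over_F", "CL_over_F", "CL2_over_F"))

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("ka", "V_over_F", "V2_over_F", "CL_over_F", "CL2_over_F")

    @property
    def Vss_over_F(self) -> float:
        """Steady-state volume: central plus peripheral."""
        return self.V_over_F + self.V2_over_F


@dataclass(frozen=True)
class ParentMetaboliteAutoInductionParams:
    """Parent-metabolite model with enzyme-turnover auto-induction.

    The peripheral parent compartment (``V2_over_F``/``CL2_over_F``) is
    optional: supply both for the two-compartment-parent variant, neither for
    the one-compartment-parent variant.  ``Emax = 0`` reduces the system to a
    plain parent-metabolite model (AENZ stays at its baseline of 1).
    """

    ka: float
    V_over_F: float
    CL_over_F: float
    Vm_over_FFm: float
    CLm_over_FFm: float
    k_enz: float
    Emax: float
    EC50: float
    V2_over_F: float | None = None
    CL2_over_F: float | None = None

    def __post_init__(self) -> None:
        _check_positive(
            self, ("ka", "V_over_F", "CL_over_F", "Vm_over_FFm", "CLm_over_FFm", "k_enz", "EC50")
        )
        if not math.isfinite(self.Emax) or self.Emax < 0:
            raise ModelError(f"Emax must be >= 0, got {self.Emax!r}")
        if (self.V2_over_F is None) != (self.CL2_over_F is None):
            raise ModelError("V2_over_F and CL2_over_F must be supplied together")
        if self.has_peripheral:
            _check_positive(self, ("V2_over_F", "CL2_over_F"))

    @property
    def has_peripheral(self) -> bool:
        return self.V2_over_F is not None

    @property
    def param_names(self) -> tuple[str, ...]:
        base = ["ka", "V_over_F", "CL_over_F"]
        if self.has_peripheral:
            base += ["V2_over_F", "CL2_over_F"]
        base += ["Vm_over_FFm", "CLm_over_FFm", "k_enz", "Emax", "EC50"]
        return tuple(base)

    @property
    def Vss_over_F(self) -> float:
        return self.V_over_F + (self.V2_over_F or 0.0)


ModelParams = OneCptOralParams | TwoCptOralParams | ParentMetaboliteAutoInductionParams


def params_to_dict(params: ModelParams) -> dict[str, float]:
    return {name: getattr(params, name) for name in params.param_names}


def params_with_values(params: ModelParams, values: Mapping[str, float]) -> ModelParams:
    """A copy of ``params`` with the named entries replaced."""
    unknown = set(values) - set(params.param_names)
    if unknown:
        raise ModelError(f"unknown parameter names: {sorted(unknown)}")
    return replace(params, **dict(values))


# ---------------------------------------------------------------------------
# state and right-hand side
# ---------------------------------------------------------------------------


def state_names(params: ModelParams) -> tuple[str, ...]:
    if isinstance(params, OneCptOralParams):
        return ("Aa", "A1")
    if isinstance(params, TwoCptOralParams):
        return ("Aa", "A1", "A2")
    if isinstance(params, ParentMetaboliteAutoInductionParams):
        if params.has_peripheral:
            return ("Aa", "A1", "A2", "Am", "AENZ")
        return ("Aa", "A1", "Am", "AENZ")
    raise ModelError(f"unsupported parameter type {type(params).__name__}")


def initial_state(params: ModelParams) -> np.ndarray:
    """All amounts zero; the relative enzyme amount starts at its baseline 1."""
    names = state_names(params)
    y0 = np.zeros(len(names))
    if "AENZ" in names:
        y0[names.index("AENZ")] = 1.0
    return y0


def evaluate_rhs(params: ModelParams, state: Sequence[float], t: float = 0.0) -> np.ndarray:
    """Time derivative of the amounts for the structure implied by ``params``.

    ``state`` is ordered as :func:`state_names` reports: depot, central,
    (peripheral), (metabolite), (enzyme).
    """
    names = state_names(params)
    y = np.asarray(state, dtype=float)
    if y.shape != (len(names),):
        raise ModelError(
            f"state has shape {y.shape}, expected ({len(names)},) for {type(params).__name__}"
        )

    if isinstance(params, OneCptOralParams):
        Aa, A1 = y
        C = A1 / params.V_over_F
        return np.array([-params.ka * Aa, params.ka * Aa - C * params.CL_over_F])

    if isinstance(params, TwoCptOralParams):
        Aa, A1, A2 = y
        C = A1 / params.V_over_F
        C2 = A2 / params.V2_over_F
        dA1 = params.ka * Aa + C2 * params.CL2_over_F - C * params.CL2_over_F - C * params.CL_over_F
        dA2 = C * params.CL2_over_F - C2 * params.CL2_over_F
        return np.array([-params.ka * Aa, dA1, dA2])

    # parent-metabolite with auto-induction
    if params.has_peripheral:
        Aa, A1, A2, Am, AENZ = y
    else:
        Aa, A1, Am, AENZ = y
    C = A1 / params.V_over_F
    Cm = Am / params.Vm_over_FFm
    elim = C * params.CL_over_F * AENZ  # induction acts on parent elimination only
    dAa = -params.ka * Aa
    dA1 = params.ka * Aa - elim
    if params.has_peripheral:
        C2 = A2 / params.V2_over_F
        dA1 += C2 * params.CL2_over_F - C * params.CL2_over_F
        dA2 = C * params.CL2_over_F - C2 * params.CL2_over_F
    dAm = elim - Cm * params.CLm_over_FFm
    dAENZ = params.k_enz * (1.0 + params.Emax * C / (params.EC50 + C)) - params.k_enz * AENZ
    if params.has_peripheral:
        return np.array([dAa, dA1, dA2, dAm, dAENZ])
    return np.array([dAa, dA1, dAm, dAENZ])


def _compiled_rhs(params: ModelParams):
    """A specialized right-hand-side closure for the integrator.

    Semantically identical to :func:`evaluate_rhs` but with the structure
    dispatch and validation hoisted out of the per-step call.
    """
    if isinstance(params, OneCptOralParams):
        ka, V, CL = params.ka, params.V_over_F, params.CL_over_F

        def rhs(t, y):
            Aa, A1 = y
            absorbed = ka * Aa
            return (-absorbed, absorbed - A1 / V * CL)

        return rhs

    if isinstance(params, TwoCptOralParams):
        ka, V, V2, CL, CL2 = (
            params.ka,
            params.V_over_F,
            params.V2_over_F,
            params.CL_over_F,
            params.CL2_over_F,
        )

        def rhs(t, y):
            Aa, A1, A2 = y
            C = A1 / V
            C2 = A2 / V2
            exchange = C * CL2 - C2 * CL2
            return (-ka * Aa, ka * Aa - exchange - C * CL, exchange)

        return rhs

    ka, V, CL = params.ka, params.V_over_F, params.CL_over_F
    Vm, CLm = params.Vm_over_FFm, params.CLm_over_FFm
    kenz, Emax, EC50 = params.k_enz, params.Emax, params.EC50
    if params.has_peripheral:
        V2, CL2 = params.V2_over_F, params.CL2_over_F

        def rhs(t, y):
            Aa, A1, A2, Am, AENZ = y
            C = A1 / V
            C2 = A2 / V2
            elim = C * CL * AENZ
            exchange = C * CL2 - C2 * CL2
            return (
                -ka * Aa,
                ka * Aa - exchange - elim,
                exchange,
                elim - Am / Vm * CLm,
                kenz * (1.0 + Emax * C / (EC50 + C)) - kenz * AENZ,
            )

        return rhs

    def rhs(t, y):
        Aa, A1, Am, AENZ = y
        C = A1 / V
        elim = C * CL * AENZ
        return (
            -ka * Aa,
            ka * Aa - elim,
            elim - Am / Vm * CLm,
            kenz * (1.0 + Emax * C / (EC50 + C)) - kenz * AENZ,
        )

    return rhs


# ---------------------------------------------------------------------------
# concentration profiles
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationProfile:
    """Analyte concentration versus time for one subject (or pooled pseudo-subject)."""

    analyte: str
    times: np.ndarray
    concentrations: np.ndarray
    subject_id: str | None = None
    species: str | None = None
    body_weight_kg: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ModelError("times and concentrations must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise ModelError("profile times must be nondecreasing")
        if not np.all(np.isfinite(self.concentrations)) or np.any(self.concentrations < 0):
            raise ModelError("concentrations must be finite and >= 0")


def apply_blood_plasma_ratio(profile: ConcentrationProfile, ratio: float) -> ConcentrationProfile:
    """Convert a plasma profile to whole blood by a constant blood:plasma ratio.

    Artesunate and dihydroartemisinin use a ratio of 0.75.
    """
    if not math.isfinite(ratio) or ratio <= 0:
        raise ModelError(f"blood:plasma ratio must be > 0, got {ratio!r}")
    meta = dict(profile.meta)
    meta["blood_plasma_ratio"] = meta.get("blood_plasma_ratio", 1.0) * ratio
    return ConcentrationProfile(
        analyte=profile.analyte,
        times=profile.times.copy(),
        concentrations=profile.concentrations * ratio,
        subject_id=profile.subject_id,
        species=profile.species,
        body_weight_kg=profile.body_weight_kg,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _clamp_negatives(values: np.ndarray, atol: float) -> np.ndarray:
    worst = values.min(initial=0.0)
    if worst < -NEG_CLAMP_WARN_FACTOR * atol:
        warnings.warn(
            f"clamping negative concentration {worst:.3e} (beyond {NEG_CLAMP_WARN_FACTOR} * atol) to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.where(values < 0, 0.0, values)


def simulate(
    params: ModelParams,
    regimen: Regimen,
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    subject_id: str | None = None,
    species: str | None = None,
    body_weight_kg: float | None = None,
    analyte_names: Mapping[str, str] | None = None,
) -> dict[str, ConcentrationProfile]:
    """Integrate the model over a dosing regimen and sample concentrations.

    Doses are instantaneous additions to the depot compartment; the integrator
    is restarted at each dose event.  A sample that falls exactly on a dose
    time is the pre-dose (trough) value, so ``t = 0`` reads 0.

    Returns a dict keyed by analyte role (``"parent"``, and ``"metabolite"``
    for parent-metabolite structures), optionally renamed via
    ``analyte_names``.
    """
    t_obs = np.asarray(times, dtype=float)
    if t_obs.ndim != 1 or t_obs.size == 0:
        raise ModelError("times must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(t_obs)) or np.any(t_obs < 0):
        raise ModelError("sample times must be finite and >= 0")
    if np.any(np.diff(t_obs) < 0):
        raise ModelError("sample times must be nondecreasing")

    names = state_names(params)
    state = initial_state(params)
    y_out = np.tile(state, (t_obs.size, 1))

    rhs = _compiled_rhs(params)

    # Segment boundaries: dose times plus the final sample time.  Samples in
    # (a, b] belong to the segment starting at a (pre-dose convention at b).
    dose_times = [d.time for d in regimen.doses]
    t_end = max(t_obs[-1], dose_times[-1])
    boundaries = [b for b in sorted({t for t in dose_times if t > 0} | {t_end}) if b > 0]
    dose_at = {d.time: d.amount for d in regimen.doses}

    t_prev = 0.0
    state[0] += dose_at.get(0.0, 0.0)  # a dose at t=0 applies after the t=0 sample
    for t_next in boundaries:
        seg_mask = (t_obs > t_prev) & (t_obs <= t_next)
        t_eval = np.unique(np.concatenate([[t_prev], t_obs[seg_mask], [t_next]]))
        if t_next > t_prev:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=Warning)
                try:
                    sol, info = odeint(
                        rhs,
                        state,
                        t_eval,
                        rtol=rtol,
                        atol=atol,
                        tfirst=True,
                        mxstep=_MAX_STEPS,
                        full_output=True,
                    )
                except Warning as exc:  # odeint reports trouble via warnings
                    raise ModelError(
                        f"ODE solver failed on [{t_prev}, {t_next}] for {type(params).__name__}: {exc}"
                    ) from None
            if info["message"] != "Integration successful.":
                raise ModelError(
                    f"ODE solver failed on [{t_prev}, {t_next}] for {type(params).__name__}: "
                    f"{info['message']}"
                )
            for k, tk in enumerate(t_eval):
                y_out[seg_mask & (t_obs == tk)] = sol[k]
            state = sol[-1].copy()
        state[0] += dose_at.get(t_next, 0.0)
        t_prev = t_next

    name_map = {PARENT: PARENT, METABOLITE: METABOLITE}
    if analyte_names:
        name_map.update(analyte_names)
    common = dict(
        subject_id=subject_id,
        species=species,
        body_weight_kg=body_weight_kg,
        meta={"structure": type(params).__name__, "rtol": rtol, "atol": atol},
    )

    out: dict[str, ConcentrationProfile] = {}
    c_parent = _clamp_negatives(y_out[:, names.index("A1")] / params.V_over_F, atol)
    out[PARENT] = ConcentrationProfile(name_map[PARENT], t_obs.copy(), c_parent, **common)
    if "Am" in names:
        cm = _clamp_negatives(y_out[:, names.index("Am")] / params.Vm_over_FFm, atol)
        out[METABOLITE] = ConcentrationProfile(name_map[METABOLITE], t_obs.copy(), cm, **common)
    return out


def closed_form_one_cpt_oral(
    params: OneCptOralParams, dose: float, times: Sequence[float]
) -> np.ndarray:
    """Analytic single-dose solution of the one-compartment oral model.

    C(t) = dose * ka / (V * (ka - ke)) * (exp(-ke t) - exp(-ka t)), used as an
    independent oracle for the ODE path.  The flip-flop degenerate case
    ka == ke is rejected; perturb one rate by ~1e-9 relative to take the limit.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ModelError("times must be >= 0")
    ke = params.ke
    ka = params.ka
    if abs(ka - ke) <= 1e-12 * max(ka, ke):
        raise ModelError("ka == ke (flip-flop degenerate); perturb one rate to take the limit")
    c = dose * ka / (params.V_over_F * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return np.where(c < 0, 0.0, c)
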