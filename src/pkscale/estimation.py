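"""Maximum-likelihood fitting of the compartmental structures.

Two estimation schemes are provided, matching how sparse (naive-pooled) and
dense (per-animal) designs are analyzed:

* :func:`fit_pooled` — naive-pooled Gaussian maximum likelihood: one parameter
  vector explains every observation in the dataset (typically a pooled
  pseudo-subject of per-time mean concentrations).
* :func:`fit_individuals_two_stage` — stage 1 fits each subject separately;
  stage 2 summarizes the population as the geometric mean of the subject
  estimates (typical values) and the variance of their logs (the lognormal
  inter-individual variance omega², matching theta_i = theta_TV * exp(eta_i)).

Residual error is additive (C_obs = C_pred + eps) or proportional
(C_obs = C_pred * (1 + eps)) with eps ~ N(0, sigma²); sigma is profiled out of
the likelihood per analyte unless fixed.  Structural parameters are optimized
on the log scale (enforcing positivity): a gradient-based trust-region least
squares on the (error-model-weighted) residual vector, followed by a
derivative-free simplex polish of the exact concentrated -2 log-likelihood
(which carries the extra Jacobian term of the proportional model).  Parameter
uncertainty (CV%) comes from the inverse observed information at the optimum,
delta-method on the log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .pk_models import (
    METABOLITE,
    PARENT,
    ConcentrationProfile,
    ModelError,
    ModelParams,
    ParentMetaboliteAutoInductionParams,
    Regimen,
    params_to_dict,
    params_with_values,
    simulate,
)

__all__ = [
    "FitError",
    "Subject",
    "ErrorModel",
    "PopulationModel",
    "FitResult",
    "fit_pooled",
    "fit_individuals_two_stage",
    "information_criteria",
    "gof_diagnostics",
]

logger = logging.getLogger(__name__)

# Solver tolerances used inside objective evaluations.  Looser than the
# reporting defaults but orders of magnitude below the estimation precision
# being assessed.
FIT_RTOL = 1e-8
FIT_ATOL = 1e-10
_PENALTY = 1e12
_LOG_FLOOR = 1e-290  # keeps log(sigma_hat^2) finite on noise-free data


class FitError(RuntimeError):
    """Estimation could not be carried out (bad input or failed optimization)."""


@dataclass
class Subject:
    """One subject's dosing history and observed profiles.

    ``observations`` is keyed by model role (``"parent"``/``"metabolite"``);
    dataset analyte names are mapped to roles by the I/O layer.
    """

    subject_id: str
    regimen: Regimen
    observations: dict[str, ConcentrationProfile]
    species: str | None = None
    body_weight_kg: float | None = None


@dataclass(frozen=True)
class ErrorModel:
    """Residual error model: ``kind`` is 'additive' or 'proportional'.

    ``sigma`` fixes the residual scale; ``None`` profiles it by ML (one sigma
    per analyte role).  Reported sigmas only have meaning together with the
    model kind: additive sigma is in concentration units, proportional sigma
    is dimensionless.
    """

    kind: str
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional"):
            raise ValueError(f"error model kind must be 'additive' or 'proportional', got {self.kind!r}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError(f"sigma must be > 0 when fixed, got {self.sigma!r}")


@dataclass
class PopulationModel:
    """Two-stage population summary: typical values and log-scale variances."""

    theta_TV: dict[str, float]
    omega2: dict[str, float]
    n_subjects: int


@dataclass
class FitResult:
    estimates: dict[str, float]
    cv_percent: dict[str, float]
    sigma: dict[str, float]
    error_model: ErrorModel
    minus2LL: float
    AIC: float
    BIC: float
    n_obs: int
    n_params: int
    fitted_params: ModelParams
    convergence: dict = field(default_factory=dict)
    residuals: pd.DataFrame | None = None

    @property
    def cv_available(self) -> bool:
        return all(math.isfinite(v) for v in self.cv_percent.values())


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _predict_subject(
    params: ModelParams, subject: Subject, rtol: float, atol: float
) -> dict[str, np.ndarray]:
    """Model predictions at each observed time, per analyte role."""
    roles = list(subject.observations)
    bad = [r for r in roles if r not in (PARENT, METABOLITE)]
    if bad:
        raise FitError(f"unknown analyte roles {bad}; map dataset analytes to parent/metabolite")
    if METABOLITE in roles and not isinstance(params, ParentMetaboliteAutoInductionParams):
        raise FitError("metabolite observations require a parent-metabolite model structure")
    all_times = np.unique(np.concatenate([subject.observations[r].times for r in roles]))
    sims = simulate(params, subject.regimen, all_times, rtol=rtol, atol=atol)
    out = {}
    for role in roles:
        idx = np.searchsorted(all_times, subject.observations[role].times)
        out[role] = sims[role].concentrations[idx]
    return out


def _collect(subjects: list[Subject], params: ModelParams, rtol: float, atol: float):
    """(obs, pred) arrays per role, concatenated over subjects.

    Subjects sharing a regimen and sampling schedule (replicate animals in one
    dose group) share one model solution, so their predictions are simulated
    once and reused.
    """
    obs: dict[str, list[np.ndarray]] = {}
    pred: dict[str, list[np.ndarray]] = {}
    cache: dict = {}
    for subject in subjects:
        key = (
            subject.regimen,
            tuple(
                (role, subject.observations[role].times.tobytes())
                for role in sorted(subject.observations)
            ),
        )
        if key not in cache:
            cache[key] = _predict_subject(params, subject, rtol, atol)
        p = cache[key]
        for role, prof in subject.observations.items():
            obs.setdefault(role, []).append(prof.concentrations)
            pred.setdefault(role, []).append(p[role])
    return (
        {r: np.concatenate(v) for r, v in obs.items()},
        {r: np.concatenate(v) for r, v in pred.items()},
    )


def _role_m2ll(obs: np.ndarray, pred: np.ndarray, error_model: ErrorModel) -> tuple[float, float]:
    """(-2 log L, sigma_hat) for one analyte role.

    Proportional error cannot weight a zero observation (pre-dose and
    below-quantification zeros), so only positive observations enter that
    likelihood; the prediction in the denominator is floored at a tiny
    positive value so that deep-tail solver underflow cannot destabilize it.
    """
    if error_model.kind == "additive":
        r = obs - pred
        n = r.size
        if error_model.sigma is not None:
            s2 = error_model.sigma**2
            return n * math.log(2 * math.pi * s2) + float(r @ r) / s2, error_model.sigma
        s2 = max(float(r @ r) / n, _LOG_FLOOR)
        return n * (math.log(2 * math.pi * s2) + 1.0), math.sqrt(s2)

    positive = obs > 0
    o = obs[positive]
    n = o.size
    if n == 0:
        raise FitError("no positive observations for the proportional error model")
    p = np.maximum(pred[positive], 1e-12 * float(o.max()))
    u = (o - p) / p
    log_pred2 = float(np.sum(np.log(p**2)))
    if error_model.sigma is not None:
        s2 = error_model.sigma**2
        return n * math.log(2 * math.pi * s2) + log_pred2 + float(u @ u) / s2, error_model.sigma
    s2 = max(float(u @ u) / n, _LOG_FLOOR)
    return n * (math.log(2 * math.pi * s2) + 1.0) + log_pred2, math.sqrt(s2)


def _minus2ll(
    params: ModelParams, subjects: list[Subject], error_model: ErrorModel, rtol: float, atol: float
) -> tuple[float, dict[str, float]]:
    obs, pred = _collect(subjects, params, rtol, atol)
    total = 0.0
    sigmas = {}
    for role in sorted(obs):
        value, sigma = _role_m2ll(obs[role], pred[role], error_model)
        total += value
        sigmas[role] = sigma
    return total, sigmas


def information_criteria(minus2LL: float, p: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2LL + 2p and BIC = -2LL + p ln(n_obs)."""
    if p < 1:
        raise ValueError(f"number of parameters must be >= 1, got {p}")
    if n_obs < 1:
        raise ValueError(f"number of observations must be >= 1, got {n_obs}")
    return minus2LL + 2 * p, minus2LL + p * math.log(n_obs)


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return H


def _cv_percent(obj, x_opt: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Asymptotic CV% per parameter from the observed information on the log scale."""
    try:
        info = 0.5 * _numerical_hessian(obj, x_opt)
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        cv = 100.0 * np.sqrt(np.expm1(var))
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; CV%% unavailable")
        return {name: math.nan for name in names}
    return dict(zip(names, cv))


# ---------------------------------------------------------------------------
# pooled fit
# ---------------------------------------------------------------------------


def fit_pooled(
    subjects: list[Subject] | Subject,
    init: ModelParams,
    error_model: ErrorModel = ErrorModel("additive"),
    *,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
    maxiter: int | None = None,
    compute_cv: bool = True,
    compute_residuals: bool = True,
) -> FitResult:
    """Naive-pooled maximum-likelihood fit of one parameter vector to all data.

    ``init`` both carries the starting values and selects the model structure.
    The non-compartmental estimates of V, CL, and ke are good starting points.
    """
    if isinstance(subjects, Subject):
        subjects = [subjects]
    names = init.param_names
    n_obs = sum(p.times.size for s in subjects for p in s.observations.values())
    if n_obs == 0:
        raise FitError("dataset has no observation records (dose-only data cannot be fitted)")
    if n_obs < len(names) + 2:
        raise FitError(f"{n_obs} observations for {len(names)} parameters; need >= p + 2")

    x0 = np.log([getattr(init, k) for k in names])

    def _params_at(x: np.ndarray) -> ModelParams:
        return params_with_values(init, dict(zip(names, np.exp(x))))

    def obj(x: np.ndarray) -> float:
        if np.any(~np.isfinite(x)) or np.any(np.abs(x) > 50):
            return _PENALTY
        try:
            value, _ = _minus2ll(_params_at(x), subjects, error_model, rtol, atol)
        except (ModelError, FitError):
            return _PENALTY
        return value if math.isfinite(value) else _PENALTY

    def residual_vector(x: np.ndarray) -> np.ndarray:
        try:
            obs, pred = _collect(subjects, _params_at(x), rtol, atol)
        except (ModelError, FitError):
            return np.full(n_obs, 1e6)
        chunks = []
        for role in sorted(obs):
            o, p = obs[role], pred[role]
            if error_model.kind == "additive":
                chunks.append(o - p)
            else:
                keep = o > 0  # static mask: proportional error on positive obs only
                o, p = o[keep], np.maximum(p[keep], 1e-12 * float(o[keep].max()))
                chunks.append((o - p) / p)
        r = np.concatenate(chunks)
        return np.where(np.isfinite(r), r, 1e6)

    # Stage 1: gradient-based least squares on the residual vector (exact ML
    # for additive error; the proportional-error weighting is refined next).
    # diff_step must stay well above the ODE solver noise floor or the
    # finite-difference Jacobian degenerates.
    ls = least_squares(
        residual_vector,
        x0,
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        diff_step=1e-4,
        max_nfev=200 * len(names),
    )
    # Stage 2 (proportional error only): derivative-free simplex polish of the
    # exact concentrated -2LL, which carries the extra sum-of-log-prediction
    # term absent from the residual sum of squares.  For additive error the
    # least-squares optimum already is the exact ML optimum.
    best_x = ls.x
    nm = None
    if error_model.kind == "proportional":
        nm = minimize(
            obj,
            ls.x,
            method="Nelder-Mead",
            options={
                "xatol": 1e-9,
                "fatol": 1e-9,
                "maxiter": maxiter or max(200, 40 * len(names)),
                "adaptive": len(names) > 5,
            },
        )
        if nm.fun <= obj(ls.x):
            best_x = nm.x
    best_fun = obj(best_x)
    if not math.isfinite(best_fun) or best_fun >= _PENALTY:
        raise FitError("optimization failed: objective did not reach a finite value")

    estimates = dict(zip(names, np.exp(best_x)))
    fitted = params_with_values(init, estimates)
    m2ll, sigmas = _minus2ll(fitted, subjects, error_model, rtol, atol)
    n_sigma = 0 if error_model.sigma is not None else len(sigmas)
    p_total = len(names) + n_sigma
    aic, bic = information_criteria(m2ll, p_total, n_obs)
    cv = _cv_percent(obj, best_x, names) if compute_cv else {k: math.nan for k in names}
    grad_norm = float(np.linalg.norm(ls.grad))
    result = FitResult(
        estimates=estimates,
        cv_percent=cv,
        sigma=sigmas,
        error_model=error_model,
        minus2LL=m2ll,
        AIC=aic,
        BIC=bic,
        n_obs=n_obs,
        n_params=p_total,
        fitted_params=fitted,
        convergence={
            "success": bool(ls.success or (nm is not None and nm.success)),
            "nfev": int(ls.nfev * (len(names) + 1) + (nm.nfev if nm is not None else 0)),
            "objective": float(best_fun),
            "grad_norm": grad_norm,
            "message": str(ls.message),
        },
    )
    if not result.convergence["success"]:
        logger.warning(
            "fit did not formally converge (|grad| = %.3g): %s",
            grad_norm,
            result.convergence["message"],
        )
    if compute_residuals:
        result.residuals = gof_diagnostics(result, subjects)
    return result


# ---------------------------------------------------------------------------
# two-stage population analysis
# ---------------------------------------------------------------------------


def fit_individuals_two_stage(
    subjects: list[Subject],
    init: ModelParams,
    error_model: ErrorModel = ErrorModel("additive"),
    **fit_kwargs,
) -> tuple[dict[str, FitResult], PopulationModel]:
    """Per-subject fits plus a two-stage population summary.

    Stage 2 sets theta_TV to the geometric mean of the per-subject estimates
    and omega² to the (ddof = 1) variance of their logs.  Subjects whose
    individual fit fails are excluded with a warning; fewer than two successes
    aborts stage 2.
    """
    if len(subjects) < 2:
        raise FitError("two-stage analysis requires at least two subjects")
    results: dict[str, FitResult] = {}
    for subject in subjects:
        try:
            results[subject.subject_id] = fit_pooled([subject], init, error_model, **fit_kwargs)
        except (FitError, ModelError) as exc:
            logger.warning("excluding subject %s from stage 2: %s", subject.subject_id, exc)
    if len(results) < 2:
        raise FitError(f"only {len(results)} subjects fitted successfully; need >= 2 for stage 2")
    names = init.param_names
    logs = np.array([[math.log(r.estimates[k]) for k in names] for r in results.values()])
    theta = dict(zip(names, np.exp(logs.mean(axis=0))))
    omega2 = dict(zip(names, logs.var(axis=0, ddof=1)))
    return results, PopulationModel(theta_TV=theta, omega2=omega2, n_subjects=len(results))


# ---------------------------------------------------------------------------
# goodness-of-fit diagnostics
# ---------------------------------------------------------------------------


def _time_after_dose(times: np.ndarray, regimen: Regimen) -> np.ndarray:
    dose_times = np.array([d.time for d in regimen.doses])
    idx = np.searchsorted(dose_times, times, side="right") - 1
    tad = times - dose_times[np.clip(idx, 0, None)]
    tad[idx < 0] = times[idx < 0]  # samples before the first dose
    return tad


def gof_diagnostics(fit: FitResult, subjects: list[Subject] | Subject) -> pd.DataFrame:
    """Residual table: DV, PRED, raw and standardized residuals, vs time after dose.

    Standardization follows the error model: (DV - PRED) / sigma for additive,
    (DV - PRED) / (sigma * PRED) for proportional (undefined at PRED = 0).
    For per-subject (two-stage) fits PRED is the individual prediction.
    """
    if isinstance(subjects, Subject):
        subjects = [subjects]
    rows = []
    for subject in subjects:
        preds = _predict_subject(fit.fitted_params, subject, FIT_RTOL, FIT_ATOL)
        for role, prof in subject.observations.items():
            sigma = fit.sigma.get(role, math.nan)
            tad = _time_after_dose(prof.times, subject.regimen)
            for t, td, dv, pr in zip(prof.times, tad, prof.concentrations, preds[role]):
                res = dv - pr
                if fit.error_model.kind == "additive":
                    wres = res / sigma if sigma > 0 else math.nan
                else:
                    wres = res / (sigma * pr) if sigma > 0 and pr > 0 else math.nan
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "analyte": role,
                        "time_h": t,
                        "tad_h": td,
                        "DV": dv,
                        "PRED": pr,
                        "RES": res,
                        "WRES": wres,
                    }
                )
    return pd.DataFrame(rows)
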