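"""Simple allometric scaling of PK parameters across species.

The allometric power law Y = a * W**b relates a PK parameter Y (in absolute
units: L, L/h, or 1/h) to body weight W (kg).  On base-10 logarithms it is a
straight line, log10 Y = log10 a + b * log10 W, fitted by ordinary least
squares across species; evaluating the line at a 70 kg body weight yields the
predicted human parameter.  First-order rate constants (ka) scale poorly with
weight, so when too few species are available their exponent is fixed at the
conventional -0.25 and only the intercept is estimated.

Per-kg parameters (L/kg, L/h/kg) must first be converted to absolute values
with the actual mean body weight of each species (:func:`to_absolute`); mixing
per-kg and absolute points in one regression is refused by construction.

The module also ships the reference species table for pyronaridine,
artesunate, and dihydroartemisinin (model-based per-kg estimates plus mean
body weights) that the scaling analysis of this package reproduces, and the
published log-log coefficients for the artesunate/dihydroartemisinin fits
whose underlying dog points cannot be re-derived (the literature dog values
arrive partly per-kg with an unstated conversion weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometryError",
    "SpeciesPoint",
    "AllometricFit",
    "to_absolute",
    "fit_power_law",
    "fit_fixed_exponent",
    "predict_at_weight",
    "REFERENCE_BODY_WEIGHTS_KG",
    "PYRONARIDINE_PER_KG",
    "ARTESUNATE_KA_PER_H",
    "LITERATURE_LOGLOG_FITS",
    "pyronaridine_species_points",
    "species_reference_table",
    "pyronaridine_human_predictions",
    "artesunate_dha_human_predictions",
]

DEFAULT_HUMAN_WEIGHT_KG = 70.0
KA_FIXED_EXPONENT = -0.25


class AllometryError(ValueError):
    """Invalid scaling input (nonpositive values, too few species, ...)."""


@dataclass(frozen=True)
class SpeciesPoint:
    """One species' (body weight, absolute parameter value) pair."""

    species: str
    body_weight_kg: float
    value: float
    parameter: str = ""

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise AllometryError(f"body weight must be > 0, got {self.body_weight_kg!r}")
        if not self.value > 0:
            raise AllometryError(f"parameter value must be > 0 (log-transformable), got {self.value!r}")


@dataclass(frozen=True)
class AllometricFit:
    """A fitted (or fixed-exponent) base-10 log-log power law."""

    b: float
    log10_a: float
    r2: float  # nan for fixed-exponent fits
    points: tuple[SpeciesPoint, ...] = ()
    fixed_exponent: bool = False
    parameter: str = ""

    @property
    def a(self) -> float:
        return 10.0**self.log10_a

    def predict(self, body_weight_kg: float) -> float:
        return predict_at_weight(self, body_weight_kg)


def to_absolute(value_per_kg: float, body_weight_kg: float) -> float:
    """Convert a per-kg parameter (L/kg, L/h/kg) to absolute units (L, L/h)."""
    if not value_per_kg > 0 or not body_weight_kg > 0:
        raise AllometryError(
            f"per-kg value and body weight must be > 0, got {value_per_kg!r}, {body_weight_kg!r}"
        )
    return value_per_kg * body_weight_kg


def fit_power_law(points: list[SpeciesPoint] | tuple[SpeciesPoint, ...]) -> AllometricFit:
    """OLS fit of log10 Y on log10 W; r² is the squared Pearson correlation."""
    points = tuple(points)
    if len(points) < 2:
        raise AllometryError(f"power-law fit needs >= 2 species points, got {len(points)}")
    logw = np.log10([p.body_weight_kg for p in points])
    logy = np.log10([p.value for p in points])
    if np.ptp(logw) == 0:
        raise AllometryError("zero variance in body weight; slope is unidentifiable")
    res = stats.linregress(logw, logy)
    labels = {p.parameter for p in points if p.parameter}
    return AllometricFit(
        b=float(res.slope),
        log10_a=float(res.intercept),
        r2=float(res.rvalue**2),
        points=points,
        parameter=labels.pop() if len(labels) == 1 else "",
    )


def fit_fixed_exponent(
    points: list[SpeciesPoint] | tuple[SpeciesPoint, ...], b_fixed: float
) -> AllometricFit:
    """Least-squares intercept with the exponent held at ``b_fixed``.

    The log10 intercept is the mean over points of log10 Y - b_fixed * log10 W;
    r² is not defined for a one-parameter fit and is reported as NaN.
    """
    points = tuple(points)
    if not points:
        raise AllometryError("fixed-exponent fit needs at least one species point")
    logw = np.log10([p.body_weight_kg for p in points])
    logy = np.log10([p.value for p in points])
    labels = {p.parameter for p in points if p.parameter}
    return AllometricFit(
        b=float(b_fixed),
        log10_a=float(np.mean(logy - b_fixed * logw)),
        r2=math.nan,
        points=points,
        fixed_exponent=True,
        parameter=labels.pop() if len(labels) == 1 else "",
    )


def predict_at_weight(fit: AllometricFit, body_weight_kg: float) -> float:
    """Evaluate Y = a * W**b at the target body weight (e.g., 70 kg human)."""
    if not body_weight_kg > 0:
        raise AllometryError(f"target body weight must be > 0, got {body_weight_kg!r}")
    return float(10.0 ** (fit.log10_a + fit.b * math.log10(body_weight_kg)))


# ---------------------------------------------------------------------------
# reference species data (model-based estimates behind the scaling analysis)
# ---------------------------------------------------------------------------

#: Measured mean body weights used for unit conversion and regression.
REFERENCE_BODY_WEIGHTS_KG: dict[str, float] = {"hamster": 0.10201, "rat": 0.2052, "dog": 9.52}

#: Pyronaridine per-kg parameter estimates per species.  The dog Vss/F is the
#: sum of central and peripheral volumes (18.98 + 13.70 L/kg) from the
#: two-compartment model.
PYRONARIDINE_PER_KG: dict[str, dict[str, float]] = {
    "Vss_over_F": {"hamster": 53.32, "rat": 110.00, "dog": 32.68},  # L/kg
    "CL_over_F": {"hamster": 2.15, "rat": 2.18, "dog": 0.68},  # L/h/kg
}

#: Pyronaridine absorption rate constants (already absolute units, 1/h).
PYRONARIDINE_KA_PER_H: dict[str, float] = {"hamster": 11.62, "rat": 1.67, "dog": 2.46}

#: Artesunate absorption rate constants (1/h); no dog value exists (the only
#: dog study is intravenous), hence the fixed -0.25 exponent for ka.
ARTESUNATE_KA_PER_H: dict[str, float] = {"hamster": 2.08, "rat": 1.54}

#: Published log10 power-law coefficients (b, log10_a) for the artesunate /
#: dihydroartemisinin regressions that include literature dog values whose
#: per-kg-to-absolute conversion weight is unpublished; these fits are
#: evaluated, not re-derived.
LITERATURE_LOGLOG_FITS: dict[str, tuple[float, float]] = {
    "artesunate_Vss_over_F": (-1.4725, 0.8671),
    "artesunate_CL_over_F": (-0.1547, 1.4524),
    "dha_Vm_over_FFm": (1.2933, -0.9876),
    "dha_CLm_over_FFm": (0.2509, 1.5725),
}


def pyronaridine_species_points(parameter: str) -> list[SpeciesPoint]:
    """Absolute-unit species points for a pyronaridine parameter.

    ``parameter`` is ``"Vss_over_F"``, ``"CL_over_F"``, or ``"ka"``; per-kg
    values are converted with the reference mean body weights.
    """
    if parameter == "ka":
        return [
            SpeciesPoint(sp, REFERENCE_BODY_WEIGHTS_KG[sp], ka, "ka")
            for sp, ka in PYRONARIDINE_KA_PER_H.items()
        ]
    try:
        per_kg = PYRONARIDINE_PER_KG[parameter]
    except KeyError:
        raise AllometryError(f"unknown pyronaridine parameter {parameter!r}") from None
    return [
        SpeciesPoint(sp, REFERENCE_BODY_WEIGHTS_KG[sp], to_absolute(v, REFERENCE_BODY_WEIGHTS_KG[sp]), parameter)
        for sp, v in per_kg.items()
    ]


def species_reference_table() -> pd.DataFrame:
    """The packaged species parameter table (long format, absolute units)."""
    rows = []
    for parameter in ("Vss_over_F", "CL_over_F", "ka"):
        unit = {"Vss_over_F": "L", "CL_over_F": "L/h", "ka": "1/h"}[parameter]
        for point in pyronaridine_species_points(parameter):
            rows.append(
                {
                    "drug": "pyronaridine",
                    "parameter": parameter,
                    "species": point.species,
                    "body_weight_kg": point.body_weight_kg,
                    "value": point.value,
                    "unit": unit,
                }
            )
    for sp, ka in ARTESUNATE_KA_PER_H.items():
        rows.append(
            {
                "drug": "artesunate",
                "parameter": "ka",
                "species": sp,
                "body_weight_kg": REFERENCE_BODY_WEIGHTS_KG[sp],
                "value": ka,
                "unit": "1/h",
            }
        )
    return pd.DataFrame(rows)


def pyronaridine_human_predictions(
    target_weight_kg: float = DEFAULT_HUMAN_WEIGHT_KG,
) -> dict[str, dict]:
    """Full pyronaridine scaling chain: per-kg estimates -> fits -> human values."""
    out = {}
    for parameter in ("Vss_over_F", "CL_over_F", "ka"):
        fit = fit_power_law(pyronaridine_species_points(parameter))
        out[parameter] = {"fit": fit, "human": predict_at_weight(fit, target_weight_kg)}
    return out


def artesunate_dha_human_predictions(
    target_weight_kg: float = DEFAULT_HUMAN_WEIGHT_KG,
) -> dict[str, dict]:
    """Artesunate/dihydroartemisinin human predictions at the target weight.

    The ka fit is recomputed from the hamster and rat points with the exponent
    fixed at -0.25; the remaining fits evaluate the published coefficients.
    """
    ka_points = [
        SpeciesPoint(sp, REFERENCE_BODY_WEIGHTS_KG[sp], ka, "ka")
        for sp, ka in ARTESUNATE_KA_PER_H.items()
    ]
    ka_fit = fit_fixed_exponent(ka_points, KA_FIXED_EXPONENT)
    out = {"artesunate_ka": {"fit": ka_fit, "human": predict_at_weight(ka_fit, target_weight_kg)}}
    for label, (b, log10_a) in LITERATURE_LOGLOG_FITS.items():
        fit = AllometricFit(b=b, log10_a=log10_a, r2=math.nan, parameter=label)
        out[label] = {"fit": fit, "human": predict_at_weight(fit, target_weight_kg)}
    return out
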