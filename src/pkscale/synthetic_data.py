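"""Synthetic concentration-time datasets emulating the animal study designs.

No raw animal profiles are deposited with the source study, so every pipeline
stage is exercised on simulated data carrying the same statistical structure
the analysis assumes: the five study designs (hamster H1/H2 destructive
multiple-dose, rat R1 single-dose and R2 multiple-dose dense sampling, dog D1
single-dose), lognormal inter-individual variability theta_i = theta_TV *
exp(eta_i), additive or proportional residual error, body-weight variability,
and the 0.75 blood:plasma conversion for artesunate/dihydroartemisinin.

Typical parameter values default to the model-based estimates of the source
study (overridable); residual sigmas and hamster per-timepoint sample sizes
are generator parameters.  All randomness flows from the single seed of the
:class:`GeneratorConfig`; identical seeds give byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import cli_io
from .pk_models import (
    METABOLITE,
    PARENT,
    ModelParams,
    OneCptOralParams,
    ParentMetaboliteAutoInductionParams,
    Regimen,
    TwoCptOralParams,
    params_with_values,
    simulate,
)

__all__ = [
    "StudyDesign",
    "GeneratorConfig",
    "design_from_key",
    "default_config",
    "generate_dataset",
    "pool_destructive",
    "PYRONARIDINE_TYPICAL",
    "ARTESUNATE_TYPICAL",
    "DEFAULT_OMEGA",
    "MOLAR_MASS_G_PER_MOL",
    "PYRONARIDINE_TETRAPHOSPHATE_BASE_FRACTION",
    "BLOOD_PLASMA_RATIO_ARTESUNATE",
]

# ---------------------------------------------------------------------------
# reference values (typical parameters and constants)
# ---------------------------------------------------------------------------

#: Model-based typical parameter values per species (per-kg volume/clearance
#: units; EC50 in nmol/L for the artesunate models).
PYRONARIDINE_TYPICAL: dict[str, ModelParams] = {
    "hamster": OneCptOralParams(ka=11.62, V_over_F=53.32, CL_over_F=2.15),
    "rat": OneCptOralParams(ka=1.67, V_over_F=110.00, CL_over_F=2.18),
    "dog": TwoCptOralParams(ka=2.46, V_over_F=18.98, V2_over_F=13.70, CL_over_F=0.68, CL2_over_F=1.30),
}

ARTESUNATE_TYPICAL: dict[str, ParentMetaboliteAutoInductionParams] = {
    "hamster": ParentMetaboliteAutoInductionParams(
        ka=2.08,
        V_over_F=1571.71,
        CL_over_F=3555.94,
        Vm_over_FFm=0.02,
        CLm_over_FFm=117.68,
        k_enz=47.40,
        Emax=7.06,
        EC50=0.42,
    ),
    "rat": ParentMetaboliteAutoInductionParams(
        ka=1.54,
        V_over_F=33.03,
        CL_over_F=13.33,
        Vm_over_FFm=0.16,
        CLm_over_FFm=237.25,
        k_enz=1.04,
        Emax=76.89,
        EC50=0.49,
        V2_over_F=481.05,
        CL2_over_F=82.69,
    ),
}

#: Reported lognormal IIV standard deviations (sqrt of the omega² estimates)
#: where the study estimated them; empty for naive-pooled hamster data.
DEFAULT_OMEGA: dict[tuple[str, str], dict[str, float]] = {
    ("pyronaridine", "hamster"): {},
    ("pyronaridine", "rat"): {"ka": math.sqrt(0.02), "V_over_F": math.sqrt(1.69), "CL_over_F": math.sqrt(0.04)},
    ("pyronaridine", "dog"): {"ka": math.sqrt(0.46), "V_over_F": math.sqrt(0.03), "CL_over_F": math.sqrt(0.05)},
    ("artesunate", "hamster"): {},
    ("artesunate", "rat"): {
        "CL2_over_F": math.sqrt(0.18),
        "CLm_over_FFm": math.sqrt(1.13),
        "k_enz": math.sqrt(1.32),
    },
}

#: Reported residual-error scales; the additive pyronaridine sigmas are in the
#: concentration unit of the source assay.  Artesunate/dihydroartemisinin used
#: a proportional model whose reported scale is ambiguous, so a realistic 20%
#: proportional residual is the generator default.
DEFAULT_SIGMA: dict[tuple[str, str], tuple[str, float]] = {
    ("pyronaridine", "hamster"): ("additive", 0.36),
    ("pyronaridine", "rat"): ("additive", 0.34),
    ("pyronaridine", "dog"): ("additive", 0.20),
    ("artesunate", "hamster"): ("proportional", 0.20),
    ("artesunate", "rat"): ("proportional", 0.20),
}

MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "pyronaridine": 518.05,
    "artesunate": 384.42,
    "dihydroartemisinin": 284.35,
}
#: Mass fraction of pyronaridine base in the tetraphosphate salt (51.2 mg of
#: base in a 90 mg salt dose).
PYRONARIDINE_TETRAPHOSPHATE_BASE_FRACTION = 51.2 / 90.0
BLOOD_PLASMA_RATIO_ARTESUNATE = 0.75

_ANALYTE_NAMES = {
    "pyronaridine": {PARENT: "pyronaridine"},
    "artesunate": {PARENT: "artesunate", METABOLITE: "dihydroartemisinin"},
}


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """One arm of the animal study: subjects, dosing, and sampling schedule.

    ``optional_times_h`` are early times sampled in only part of the animals
    (assigned round-robin); ``extension_times_h`` extend the horizon for every
    second subject (the rat single-dose arm followed half its animals longer).
    Destructive-sparse sampling means each animal contributes a single
    terminal sample and profiles are pooled by nominal time.
    """

    key: str
    species: str
    n_subjects: int
    body_weight_mean_kg: float
    body_weight_sd_kg: float
    dose_mg_per_kg: Mapping[str, float]  # per drug; dog uses absolute mg
    dose_is_per_kg: bool
    n_doses: int
    tau_h: float
    sampling_times_h: tuple[float, ...]
    optional_times_h: tuple[float, ...] = ()
    extension_times_h: tuple[float, ...] = ()
    sampling_mode: str = "dense"  # "dense" | "destructive"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_mode not in ("dense", "destructive"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")
        horizon = (self.n_doses - 1) * self.tau_h + max(
            self.sampling_times_h + self.optional_times_h + self.extension_times_h or (0.0,)
        )
        for t in self.sampling_times_h + self.optional_times_h:
            if t < 0 or t > horizon:
                raise ValueError(f"sampling time {t} outside study horizon [0, {horizon}]")


_HAMSTER_TIMES = (
    0, 0.08, 0.25, 0.5, 0.75, 1, 2, 4, 8, 12, 24,
    47, 48.08, 48.25, 48.5, 48.75, 49, 50, 52, 56, 60, 72,
)
_RAT_OPTIONAL_EARLY = (0.05, 0.08, 0.16, 0.33, 0.5, 0.75)

_DESIGNS: dict[str, StudyDesign] = {
    "H1": StudyDesign(
        key="H1",
        species="hamster",
        n_subjects=60,
        body_weight_mean_kg=0.10201,
        body_weight_sd_kg=0.00572,
        dose_mg_per_kg={"pyronaridine": 180.0, "artesunate": 60.0},
        dose_is_per_kg=True,
        n_doses=3,
        tau_h=24.0,
        sampling_times_h=_HAMSTER_TIMES,
        sampling_mode="destructive",
    ),
    "H2": StudyDesign(
        key="H2",
        species="hamster",
        n_subjects=48,
        body_weight_mean_kg=0.10201,
        body_weight_sd_kg=0.00572,
        dose_mg_per_kg={"pyronaridine": 360.0, "artesunate": 120.0},
        dose_is_per_kg=True,
        n_doses=3,
        tau_h=24.0,
        sampling_times_h=_HAMSTER_TIMES,
        sampling_mode="destructive",
    ),
    "R1": StudyDesign(
        key="R1",
        species="rat",
        n_subjects=6,
        body_weight_mean_kg=0.2052,
        body_weight_sd_kg=0.0073,
        dose_mg_per_kg={"pyronaridine": 60.0, "artesunate": 20.0},
        dose_is_per_kg=True,
        n_doses=1,
        tau_h=24.0,
        sampling_times_h=(0, 1, 2, 4, 8, 12, 24, 48, 96, 144),
        optional_times_h=_RAT_OPTIONAL_EARLY,
        extension_times_h=(216,),
    ),
    "R2": StudyDesign(
        key="R2",
        species="rat",
        n_subjects=5,
        body_weight_mean_kg=0.2052,
        body_weight_sd_kg=0.0073,
        dose_mg_per_kg={"pyronaridine": 60.0, "artesunate": 20.0},
        dose_is_per_kg=True,
        n_doses=3,
        tau_h=24.0,
        sampling_times_h=(0, 1, 2, 4, 8, 12, 24, 48, 49, 50, 52, 56, 60, 72, 96, 144, 192, 264),
        optional_times_h=_RAT_OPTIONAL_EARLY + (48.05, 48.17, 48.33, 48.5, 48.75),
    ),
    "D1": StudyDesign(
        key="D1",
        species="dog",
        n_subjects=9,
        body_weight_mean_kg=9.5,
        body_weight_sd_kg=0.3,
        dose_mg_per_kg={"pyronaridine": 90.0},  # mg per head (absolute)
        dose_is_per_kg=False,
        n_doses=1,
        tau_h=24.0,
        sampling_times_h=(0, 0.5, 1, 2, 4, 6, 24, 72, 120),
    ),
}


def design_from_key(species_key: str) -> StudyDesign:
    """The study design for key H1, H2, R1, R2, or D1."""
    try:
        return _DESIGNS[species_key]
    except KeyError:
        raise ValueError(
            f"unknown design key {species_key!r}; expected one of {sorted(_DESIGNS)}"
        ) from None


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Everything stochastic about one simulated dataset.

    ``omega`` holds lognormal IIV standard deviations per parameter name;
    ``sigma`` is the residual scale for ``error_kind`` ('additive' in
    concentration units, 'proportional' dimensionless).  ``dose_conversion``
    rescales the nominal dose into the concentration unit system (e.g., mg to
    nmol via the molar mass, or salt to base); ``n_per_timepoint`` overrides
    the subject count of destructive designs (subjects = n * timepoints).
    """

    drug: str
    params: ModelParams
    omega: dict[str, float] = field(default_factory=dict)
    error_kind: str = "additive"
    sigma: float = 0.0
    blood_plasma_ratio: float = 1.0
    dose_conversion: float = 1.0
    conc_unit: str = "mg/L"
    dose_unit: str = "mg/kg"
    seed: int = 0
    n_per_timepoint: int | None = None

    def __post_init__(self) -> None:
        if self.error_kind not in ("additive", "proportional"):
            raise ValueError(f"unknown error kind {self.error_kind!r}")
        if self.sigma < 0 or any(w < 0 for w in self.omega.values()):
            raise ValueError("sigma and omega entries must be >= 0")
        unknown = set(self.omega) - set(self.params.param_names)
        if unknown:
            raise ValueError(f"omega names not in the model: {sorted(unknown)}")


def default_config(drug: str, species: str, seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults for one drug/species combination."""
    if drug == "pyronaridine":
        params = PYRONARIDINE_TYPICAL[species]
        bpr, conversion, conc_unit = 1.0, 1.0, "mg/L"
        dose_unit = "mg/kg" if species != "dog" else "mg"
    elif drug == "artesunate":
        params = ARTESUNATE_TYPICAL[species]
        bpr = BLOOD_PLASMA_RATIO_ARTESUNATE
        conversion = 1e6 / MOLAR_MASS_G_PER_MOL["artesunate"]  # mg -> nmol
        conc_unit, dose_unit = "nmol/L", "nmol/kg"
    else:
        raise ValueError(f"unknown drug {drug!r}")
    kind, sigma = DEFAULT_SIGMA[(drug, species)]
    return GeneratorConfig(
        drug=drug,
        params=params,
        omega=dict(DEFAULT_OMEGA[(drug, species)]),
        error_kind=kind,
        sigma=sigma,
        blood_plasma_ratio=bpr,
        dose_conversion=conversion,
        conc_unit=conc_unit,
        dose_unit=dose_unit,
        seed=seed,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at +/- 3 SD (body weights stay positive and sane)."""
    if sd == 0:
        return mean
    while True:
        z = rng.standard_normal()
        if abs(z) <= 3.0:
            return mean + sd * z


def _subject_times(design: StudyDesign, i: int) -> np.ndarray:
    times = set(design.sampling_times_h)
    if design.optional_times_h and i % 2 == 0:
        times |= set(design.optional_times_h)
    if design.extension_times_h and i % 2 == 1:
        times |= set(design.extension_times_h)
    return np.array(sorted(times))


def generate_dataset(design: StudyDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Simulate one dataset in the long tabular record format.

    Per subject: draw a body weight, draw eta ~ N(0, omega²) per parameter,
    simulate the individual model over the regimen, convert plasma to blood,
    add residual error, clamp negatives to zero (below-quantification mimic),
    and emit dose and observation records.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    analyte_names = _ANALYTE_NAMES[config.drug]
    dose_nominal = design.dose_mg_per_kg[config.drug]

    if design.sampling_mode == "destructive":
        all_times = sorted(design.sampling_times_h)
        n_subjects = (
            config.n_per_timepoint * len(all_times)
            if config.n_per_timepoint
            else design.n_subjects
        )
    else:
        n_subjects = design.n_subjects

    rows: list[dict] = []
    omega_names = sorted(config.omega)
    for i in range(n_subjects):
        subject_id = f"{design.key}-{i + 1:03d}"
        bw = _truncated_normal(rng, design.body_weight_mean_kg, design.body_weight_sd_kg)
        etas = {name: rng.normal(0.0, config.omega[name]) for name in omega_names}
        params_i = params_with_values(
            config.params,
            {k: getattr(config.params, k) * math.exp(e) for k, e in etas.items()},
        )
        amount = dose_nominal if design.dose_is_per_kg else dose_nominal / bw
        amount *= config.dose_conversion
        regimen = Regimen.daily(amount, design.n_doses, design.tau_h)

        if design.sampling_mode == "destructive":
            times = np.array([all_times[i % len(all_times)]], dtype=float)
        else:
            times = _subject_times(design, i)

        try:
            sims = simulate(
                params_i,
                regimen,
                times,
                subject_id=subject_id,
                species=design.species,
                body_weight_kg=bw,
                analyte_names=analyte_names,
            )
        except Exception as exc:  # noqa: BLE001 - reattach subject context
            raise RuntimeError(f"simulation failed for subject {subject_id}: {exc}") from exc

        for dose in regimen.doses:
            rows.append(
                {
                    "subject_id": subject_id,
                    "species": design.species,
                    "body_weight_kg": bw,
                    "analyte": analyte_names[PARENT],
                    "time_h": dose.time,
                    "conc": np.nan,
                    "conc_unit": config.conc_unit,
                    "dose_amount": amount,
                    "dose_unit": config.dose_unit,
                    "dose_time_h": dose.time,
                    "evid": 1,
                }
            )
        for role in sorted(sims):
            conc = sims[role].concentrations * config.blood_plasma_ratio
            if config.sigma > 0:
                if config.error_kind == "additive":
                    conc = conc + rng.normal(0.0, config.sigma, size=conc.size)
                else:
                    conc = conc * (1.0 + rng.normal(0.0, config.sigma, size=conc.size))
                conc = np.where(conc < 0, 0.0, conc)  # clamp; mimics below-LLOQ zeros
            for t, c in zip(times, conc):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "species": design.species,
                        "body_weight_kg": bw,
                        "analyte": sims[role].analyte,
                        "time_h": float(t),
                        "conc": float(c),
                        "conc_unit": config.conc_unit,
                        "dose_amount": np.nan,
                        "dose_unit": np.nan,
                        "dose_time_h": np.nan,
                        "evid": 0,
                    }
                )
    df = pd.DataFrame(rows, columns=list(cli_io.REQUIRED_COLUMNS))
    return cli_io.sort_dataset(df)


def pool_destructive(dataset: pd.DataFrame) -> pd.DataFrame:
    """Naive pooling of a destructive-sparse dataset.

    The mean concentration at each nominal time becomes one pooled
    pseudo-subject per analyte (no SDs: each time may hold few animals).  Dose
    records are taken from the first subject; per-kg dosing makes them shared.
    """
    obs = dataset[dataset["evid"] == 0]
    if obs.empty:
        raise ValueError("dataset has no observation records to pool")
    if obs["conc"].isna().any():
        raise ValueError("observation records with missing concentrations cannot be pooled")
    pooled = (
        obs.groupby(["analyte", "time_h"], as_index=False)
        .agg(
            conc=("conc", "mean"),
            species=("species", "first"),
            conc_unit=("conc_unit", "first"),
        )
        .assign(
            subject_id="pooled",
            body_weight_kg=obs["body_weight_kg"].mean(),
            dose_amount=np.nan,
            dose_unit=np.nan,
            dose_time_h=np.nan,
            evid=0,
        )
    )
    first_subject = dataset["subject_id"].iloc[0]
    doses = dataset[(dataset["subject_id"] == first_subject) & (dataset["evid"] == 1)].copy()
    doses["subject_id"] = "pooled"
    doses["body_weight_kg"] = obs["body_weight_kg"].mean()
    out = pd.concat([doses, pooled], ignore_index=True)[list(cli_io.REQUIRED_COLUMNS)]
    return cli_io.sort_dataset(out)
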