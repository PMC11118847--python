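"""Synthetic paired-measurement cohorts for pipeline testing and calibration.

The generator emulates the statistical structure of a repeated-measures
saliva/plasma biomarker study: n subjects, each measured in two
menstrual-cycle phases (follicular F, luteal L) and at two timepoints
(pre/post high-intensity exercise), for three lipid-peroxidation analytes
(DC, TC, SB).  Per subject x stratum x analyte:

* the plasma value is Gaussian around the stratum mean, with an additive
  subject random intercept (ICC configurable, default 0.5) shared across
  strata so that pre/post pairs are correlated within subject;
* the saliva value is the conditional mean given plasma at correlation rho
  plus independent Gaussian noise, optionally distorted by an injected
  differential (additive) and proportional (multiplicative) bias;
* stratum means shift by exercise_effect_d and phase_effect_d standard
  deviations (both expressed as Cohen's d on the plasma scale);
* draws producing non-positive concentrations are redrawn (truncation by
  redraw preserves the distributional shape; redraws are logged).

Defaults are calibrated so the no-bias cohort reproduces the regime the
analysis suite is built for: saliva-plasma correlations in the high 0.7s
to 0.9s, slopes near 1, intercepts near 0, strongly significant post-
exercise increases, and a luteal > follicular phase shift that is largest
for SB.  DC/TC live on a ~0.3-0.7 relative-unit scale and SB on a
~150-350 relative-unit scale.  These are plausibility anchors for the
assay's output ranges, not published study means.

All randomness flows from the seed in the config; identical configs give
bit-identical cohorts on a given platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleODError
from .quantify import (DC_COEFFICIENT, OD_INPUT_COLUMNS, SB_COEFFICIENT,
                       TC_COEFFICIENT)

logger = logging.getLogger(__name__)

ANALYTES = ("DC", "TC", "SB")
PHASES = ("F", "L")
TIMEPOINTS = ("pre", "post")

_COEF = {"DC": DC_COEFFICIENT, "TC": TC_COEFFICIENT, "SB": SB_COEFFICIENT}

_MAX_REDRAW_ROUNDS = 1000


@dataclass(frozen=True)
class AnalyteParams:
    """Generating parameters for one analyte.

    mu_plasma_pre_F is the plasma mean in the follicular pre-exercise
    stratum; the other strata shift it by the effect sizes.  noise_sd
    defaults to sd_plasma * sqrt(1 - rho^2), which makes the marginal
    saliva-plasma correlation equal rho when no bias is injected.
    """

    mu_plasma_pre_F: float
    sd_plasma: float
    rho: float
    exercise_effect_d: float = 0.0
    phase_effect_d: float = 0.0
    differential_bias: float = 0.0
    proportional_bias: float = 1.0
    noise_sd: Optional[float] = None

    def validate(self, name: str) -> list:
        bad = []
        if self.sd_plasma <= 0:
            bad.append(f"{name}.sd_plasma must be > 0")
        if not abs(self.rho) < 1:
            bad.append(f"{name}.rho must satisfy |rho| < 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            bad.append(f"{name}.noise_sd must be >= 0")
        return bad

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.sd_plasma * float(np.sqrt(1.0 - self.rho**2))


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int
    seed: int
    analytes: Dict[str, AnalyteParams] = field(default_factory=dict)
    subject_icc: float = 0.5
    lognormal: bool = False

    def validate(self) -> None:
        bad = []
        if self.n_subjects < 3:
            bad.append("n_subjects must be >= 3")
        if not isinstance(self.seed, (int, np.integer)):
            bad.append("seed must be an integer (no silent clock seeding)")
        if not 0 <= self.subject_icc < 1:
            bad.append("subject_icc must be in [0, 1)")
        if not self.analytes:
            bad.append("at least one analyte block required")
        for name, params in self.analytes.items():
            bad.extend(params.validate(name))
        if bad:
            raise ConfigError("invalid SimulationConfig: " + "; ".join(bad))


def default_config(seed: int, n_subjects: int = 12) -> SimulationConfig:
    """The calibrated default cohort (see module docstring for rationale)."""
    return SimulationConfig(
        n_subjects=n_subjects,
        seed=seed,
        analytes={
            "DC": AnalyteParams(mu_plasma_pre_F=0.50, sd_plasma=0.12, rho=0.82,
                                exercise_effect_d=1.5, phase_effect_d=0.6),
            "TC": AnalyteParams(mu_plasma_pre_F=0.40, sd_plasma=0.10, rho=0.85,
                                exercise_effect_d=1.5, phase_effect_d=0.6),
            "SB": AnalyteParams(mu_plasma_pre_F=220.0, sd_plasma=55.0, rho=0.90,
                                exercise_effect_d=1.5, phase_effect_d=1.0),
        },
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated paired values in long layout.

    ``rows`` columns: subject_id, cycle_phase, timepoint, analyte, plasma,
    saliva — one row per subject x stratum x analyte.
    """

    config: SimulationConfig
    rows: pd.DataFrame

    def paired_datasets(self) -> list:
        from .agreement import paired_datasets_from_long
        return paired_datasets_from_long(self.rows)


def sample_correlated_pairs(
    n: int,
    rho: float,
    rng: np.random.Generator,
    mu: float = 0.0,
    sd: float = 1.0,
) -> tuple:
    """Draw n bivariate-normal pairs with equal marginals and correlation rho.

    Returns (x, y).  This is the generator's core kernel, exposed for tests
    and simulation studies that need plain paired draws without the
    subject-effect and truncation machinery.
    """
    x = rng.normal(mu, sd, size=n)
    y = mu + rho * (x - mu) + sd * np.sqrt(1 - rho**2) * rng.normal(size=n)
    return x, y


def _draw_stratum(
    params: AnalyteParams,
    mu: float,
    subject_effects: np.ndarray,
    residual_sd: float,
    rng: np.random.Generator,
    truncate: bool,
) -> tuple:
    """One stratum's (plasma, saliva) vectors, truncated at 0 by redraw.

    plasma = mu + subject_effect + residual; its marginal sd is sd_plasma
    because subject_effects carry icc*sd^2 and residual_sd^2 = (1-icc)*sd^2.
    saliva = bias + slope * E[saliva | plasma] + noise.
    """
    n = subject_effects.size
    plasma = np.empty(n)
    saliva = np.empty(n)
    mask = np.ones(n, dtype=bool)
    redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        k = int(mask.sum())
        p = mu + subject_effects[mask] + residual_sd * rng.normal(size=k)
        cond_mean = mu + params.rho * (p - mu)
        s = (params.differential_bias
             + params.proportional_bias * cond_mean
             + params.effective_noise_sd * rng.normal(size=k))
        plasma[mask] = p
        saliva[mask] = s
        if not truncate:
            break
        mask = (plasma <= 0) | (saliva <= 0)
        if not mask.any():
            break
        redraws += int(mask.sum())
    else:
        raise ConfigError(
            "could not draw positive concentrations; stratum mean too close "
            "to 0 relative to sd"
        )
    if redraws:
        logger.info("redrew %d non-positive draw(s)", redraws)
    return plasma, saliva


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full 2-phase x 2-timepoint x 3-analyte cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]

    records = []
    for analyte, params in config.analytes.items():
        sd = params.sd_plasma
        # subject random intercept, shared across all four strata
        subject_effects = rng.normal(
            0.0, sd * np.sqrt(config.subject_icc), size=config.n_subjects
        )
        residual_sd = sd * float(np.sqrt(1.0 - config.subject_icc))
        for phase in PHASES:
            for tp in TIMEPOINTS:
                mu = params.mu_plasma_pre_F
                if phase == "L":
                    mu += params.phase_effect_d * sd
                if tp == "post":
                    mu += params.exercise_effect_d * sd
                plasma, saliva = _draw_stratum(
                    params, mu, subject_effects, residual_sd, rng,
                    truncate=not config.lognormal,
                )
                if config.lognormal:
                    # reinterpret the Gaussian draws as log-scale deviations:
                    # positive by construction, median preserved
                    scale = max(abs(mu), sd)
                    plasma = mu * np.exp((plasma - mu) / scale)
                    saliva = mu * np.exp((saliva - mu) / scale)
                for j, sid in enumerate(subjects):
                    records.append((sid, phase, tp, analyte,
                                    float(plasma[j]), float(saliva[j])))
    rows = pd.DataFrame.from_records(
        records,
        columns=["subject_id", "cycle_phase", "timepoint", "analyte",
                 "plasma", "saliva"],
    )
    return SyntheticCohort(config=config, rows=rows)


def inject_bias(
    cohort: SyntheticCohort,
    differential: float = 0.0,
    proportional: float = 1.0,
    analytes: Optional[tuple] = None,
) -> SyntheticCohort:
    """Post-hoc bias injection: saliva' = differential + proportional * saliva.

    Plasma is untouched.  Produces positive controls for the bias-detection
    rules.  ``analytes`` restricts the injection; default all.
    """
    rows = cohort.rows.copy()
    sel = rows["analyte"].isin(analytes) if analytes is not None \
        else pd.Series(True, index=rows.index)
    rows.loc[sel, "saliva"] = differential + proportional * rows.loc[sel, "saliva"]
    return SyntheticCohort(config=cohort.config, rows=rows)


def cohort_to_od(
    cohort: SyntheticCohort,
    od220_up: float = 1.0,
    od220_lp: float = 1.0,
    split: float = 0.5,
    max_od: float = 3.0,
) -> pd.DataFrame:
    """Back-generate an optical-density table that quantifies to the cohort.

    Right-inverse of the quantification equations: for each analyte with
    correction coefficient k and target concentration c, the total ratio
    sum is S = c / k; a fraction ``split`` of S goes to the upper phase and
    the rest to the lower phase, and the analyte's absorbance in each phase
    is the ratio times that phase's fixed 220 nm absorbance.  Quantifying
    the result recovers the input to floating precision.
    """
    if not 0 < split < 1:
        raise ConfigError(f"split must be in (0, 1), got {split}")
    if od220_up <= 0 or od220_lp <= 0:
        raise ConfigError("od220 values must be > 0")

    wavelength_col = {"DC": "od232", "TC": "od278", "SB": "od400"}
    records: dict = {}
    for row in cohort.rows.itertuples(index=False):
        for fluid in ("plasma", "saliva"):
            key = (row.subject_id, fluid, row.cycle_phase, row.timepoint)
            if key not in records:
                records[key] = {
                    "specimen_id": f"{row.subject_id}-{fluid}-{row.cycle_phase}-{row.timepoint}",
                    "subject_id": row.subject_id,
                    "fluid": fluid,
                    "cycle_phase": row.cycle_phase,
                    "timepoint": row.timepoint,
                    "od220_up": od220_up,
                    "od220_lp": od220_lp,
                }
            conc = getattr(row, fluid)
            if conc < 0:
                raise InfeasibleODError(f"negative concentration {conc} for {key}")
            total_ratio = conc / _COEF[row.analyte]
            up = split * total_ratio * od220_up
            lp = (1.0 - split) * total_ratio * od220_lp
            if up > max_od or lp > max_od:
                raise InfeasibleODError(
                    f"{row.analyte} concentration {conc} implies absorbance "
                    f"{max(up, lp):.3g} > cap {max_od} for specimen {key}"
                )
            col = wavelength_col[row.analyte]
            records[key][f"{col}_up"] = up
            records[key][f"{col}_lp"] = lp
    od = pd.DataFrame.from_records(list(records.values()))
    for col in OD_INPUT_COLUMNS:
        if col not in od.columns:  # analytes absent from the cohort read as 0
            od[col] = 0.0
    return od[OD_INPUT_COLUMNS]


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    if "seed" not in payload:
        raise ConfigError("seed is mandatory in simulation configs")
    analytes = {
        name: AnalyteParams(**block)
        for name, block in payload.get("analytes", {}).items()
    }
    cfg = SimulationConfig(
        n_subjects=int(payload.get("n_subjects", 12)),
        seed=int(payload["seed"]),
        analytes=analytes,
        subject_icc=float(payload.get("subject_icc", 0.5)),
        lognormal=bool(payload.get("lognormal", False)),
    )
    cfg.validate()
    return cfg


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different seed."""
    return replace(config, seed=seed)
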