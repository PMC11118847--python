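"""Spectrophotometric quantification of lipid-peroxidation (LPO) products.

Lipids are extracted from saliva or blood plasma into a two-phase system:
heptane (upper phase, mostly neutral lipids) and isopropanol (lower phase,
mostly phospholipids).  Each phase is read at four wavelengths: 220 nm
(isolated double bonds, the normalising channel), 232 nm (diene conjugates,
DC), 278 nm (triene conjugates, TC) and 400 nm (Schiff bases, SB).  The
concentration of each product, in relative units, is a correction
coefficient times the sum of the per-phase absorbance ratios:

    DC = (OD232_up/OD220_up + OD232_lp/OD220_lp) * 0.14
    TC = (OD278_up/OD220_up + OD278_lp/OD220_lp) * 0.16
    SB = (OD400_up/OD220_up + OD400_lp/OD220_lp) * 52

Blank (reagent-control) subtraction is assumed already applied upstream;
this module consumes net absorbances.  Negative absorbances are rejected by
default (they usually mean an instrument or blanking problem) but can be
clamped to zero on request.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import InvalidDenominatorError, SchemaError

logger = logging.getLogger(__name__)

#: Correction coefficients applied to the summed phase ratios.
DC_COEFFICIENT = 0.14
TC_COEFFICIENT = 0.16
SB_COEFFICIENT = 52.0

FLUIDS = ("saliva", "plasma")

#: Input CSV schema: one row per specimen, absorbances of both phases.
OD_INPUT_COLUMNS = [
    "specimen_id", "subject_id", "fluid", "cycle_phase", "timepoint",
    "od220_up", "od232_up", "od278_up", "od400_up",
    "od220_lp", "od232_lp", "od278_lp", "od400_lp",
]

#: Output CSV schema of :func:`quantify_table`.
CONC_OUTPUT_COLUMNS = [
    "specimen_id", "subject_id", "fluid", "cycle_phase", "timepoint",
    "dc", "tc", "sb",
]


@dataclass(frozen=True)
class PhaseODReadings:
    """Absorbances of one extract phase at the four assay wavelengths."""

    od220: float
    od232: float
    od278: float
    od400: float

    def __post_init__(self) -> None:
        for name in ("od220", "od232", "od278", "od400"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(
                    f"{name} must be non-negative, got {value!r} "
                    "(negative net absorbance suggests a blanking problem; "
                    "use clamp_negative_od upstream to force to 0)"
                )


@dataclass(frozen=True)
class SpecimenOD:
    """Both phases of one specimen's lipid extract, with identity metadata."""

    specimen_id: str
    fluid: str
    upper: PhaseODReadings
    lower: PhaseODReadings

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"fluid must be one of {FLUIDS}, got {self.fluid!r}")


@dataclass(frozen=True)
class LPOConcentrations:
    """DC, TC and SB concentrations of one specimen, in relative units."""

    dc: float
    tc: float
    sb: float


def _check_denominators(upper: PhaseODReadings, lower: PhaseODReadings) -> None:
    if upper.od220 <= 0:
        raise InvalidDenominatorError(
            f"upper (heptane) phase od220 must be > 0, got {upper.od220!r}"
        )
    if lower.od220 <= 0:
        raise InvalidDenominatorError(
            f"lower (isopropanol) phase od220 must be > 0, got {lower.od220!r}"
        )


def compute_dc(upper: PhaseODReadings, lower: PhaseODReadings) -> float:
    """Diene-conjugate concentration in relative units."""
    _check_denominators(upper, lower)
    return (upper.od232 / upper.od220 + lower.od232 / lower.od220) * DC_COEFFICIENT


def compute_tc(upper: PhaseODReadings, lower: PhaseODReadings) -> float:
    """Triene-conjugate concentration in relative units."""
    _check_denominators(upper, lower)
    return (upper.od278 / upper.od220 + lower.od278 / lower.od220) * TC_COEFFICIENT


def compute_sb(upper: PhaseODReadings, lower: PhaseODReadings) -> float:
    """Schiff-base concentration in relative units."""
    _check_denominators(upper, lower)
    return (upper.od400 / upper.od220 + lower.od400 / lower.od220) * SB_COEFFICIENT


def quantify_specimen(specimen: SpecimenOD) -> LPOConcentrations:
    """Compute all three LPO product concentrations for one specimen."""
    try:
        return LPOConcentrations(
            dc=compute_dc(specimen.upper, specimen.lower),
            tc=compute_tc(specimen.upper, specimen.lower),
            sb=compute_sb(specimen.upper, specimen.lower),
        )
    except InvalidDenominatorError as exc:
        raise InvalidDenominatorError(
            f"specimen {specimen.specimen_id!r}: {exc}"
        ) from exc


def read_od_csv(path: Union[str, Path], clamp_negative_od: bool = False) -> pd.DataFrame:
    """Read an optical-density table, validating the schema.

    With ``clamp_negative_od`` negative absorbances (possible after blank
    subtraction) are set to 0 with a logged warning instead of raising later.
    """
    df = pd.read_csv(path)
    missing = [c for c in OD_INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"OD table {path} missing columns: {missing}")
    od_cols = [c for c in OD_INPUT_COLUMNS if c.startswith("od")]
    if clamp_negative_od:
        n_neg = int((df[od_cols] < 0).to_numpy().sum())
        if n_neg:
            logger.warning("clamping %d negative absorbance(s) to 0", n_neg)
            df[od_cols] = df[od_cols].clip(lower=0)
    return df


def quantify_table(od: pd.DataFrame) -> pd.DataFrame:
    """Quantify every specimen row of an OD table.

    Returns a concentrations table with columns ``CONC_OUTPUT_COLUMNS``.
    Row errors are raised with the offending specimen_id and line number.
    """
    missing = [c for c in OD_INPUT_COLUMNS if c not in od.columns]
    if missing:
        raise SchemaError(f"OD table missing columns: {missing}")
    records = []
    for i, row in enumerate(od.itertuples(index=False)):
        try:
            specimen = SpecimenOD(
                specimen_id=str(row.specimen_id),
                fluid=str(row.fluid),
                upper=PhaseODReadings(row.od220_up, row.od232_up,
                                      row.od278_up, row.od400_up),
                lower=PhaseODReadings(row.od220_lp, row.od232_lp,
                                      row.od278_lp, row.od400_lp),
            )
            conc = quantify_specimen(specimen)
        except (ValueError, InvalidDenominatorError) as exc:
            raise type(exc)(f"row {i + 1} (specimen {row.specimen_id!r}): {exc}") from exc
        records.append({
            "specimen_id": row.specimen_id,
            "subject_id": row.subject_id,
            "fluid": row.fluid,
            "cycle_phase": row.cycle_phase,
            "timepoint": row.timepoint,
            "dc": conc.dc,
            "tc": conc.tc,
            "sb": conc.sb,
        })
    return pd.DataFrame.from_records(records, columns=CONC_OUTPUT_COLUMNS)


def format_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding for reports: 2 decimals for DC/TC, 1 for SB.

    Computation never rounds; this is applied only when writing reports.
    """
    out = conc.copy()
    out["dc"] = out["dc"].round(2)
    out["tc"] = out["tc"].round(2)
    out["sb"] = out["sb"].round(1)
    return out
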