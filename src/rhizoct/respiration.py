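"""MicroResp: indicator-plate absorbance to soil respiration rate.

The MicroResp assay reads a CO₂-sensitive indicator gel at 570 nm before
and after a (default 6 h, 25 °C) incubation over soil in a 96 deep-well
plate. The chain implemented here:

1. per-well time-zero normalisation of the final absorbance,
2. a rational calibration curve from normalised absorbance to headspace
   %CO₂:  %CO₂ = A + B / (1 + D·Ai),
3. ideal-gas conversion of the headspace CO₂ increment over ambient to
   µg CO₂-C per g dry soil per day.

The calibration constants are assay-specific and must come from a gel
calibration; the defaults below are standard published values for the
cresol-red gel and are deliberately exposed as configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class RespirationError(ValueError):
    pass


@dataclass
class Calibration:
    """Parameters of %CO₂ = A + B / (1 + D·Ai)."""

    A: float = -0.2265
    B: float = -1.606
    D: float = -6.771


@dataclass
class RespirationAssay:
    """Physical constants of one MicroResp incubation."""

    soil_mass_g: float = 0.5
    headspace_ul: float = 900.0  # 1200 µl well minus soil volume
    incubation_h: float = 6.0
    temperature_c: float = 25.0
    calibration: Calibration = None

    def __post_init__(self) -> None:
        if self.calibration is None:
            self.calibration = Calibration()
        if not self.soil_mass_g > 0:
            raise RespirationError("soil mass must be > 0 g")
        if not self.headspace_ul > 0:
            raise RespirationError("headspace volume must be > 0 µl")
        if not self.incubation_h > 0:
            raise RespirationError("incubation time must be > 0 h")


def normalize_absorbance(a570_t6: float, a570_t0: float, plate_mean_t0: float) -> float:
    """Per-well time-zero correction: Ai = A_t6 × (plate mean t0 / A_t0)."""
    for name, v in (("a570_t6", a570_t6), ("a570_t0", a570_t0), ("plate_mean_t0", plate_mean_t0)):
        if not v > 0:
            raise RespirationError(f"{name} must be > 0, got {v}")
    return a570_t6 * (plate_mean_t0 / a570_t0)


def absorbance_to_co2(ai: float, calibration: Calibration) -> float:
    """Headspace %CO₂ from normalised absorbance via the calibration curve."""
    denom = 1.0 + calibration.D * ai
    if denom <= 0:
        raise RespirationError(
            f"calibration denominator 1 + D*Ai = {denom:.4g} <= 0 at Ai={ai}: absorbance outside the curve's domain"
        )
    return max(calibration.A + calibration.B / denom, 0.0)


# CO₂ molar volume at STP (ml/mmol) and molar masses (g/mol)
MOLAR_VOLUME_STP = 22.414
M_CO2 = 44.0
M_C = 12.0


def co2_to_rate(pct_co2: float, pct_co2_ambient: float, assay: RespirationAssay) -> float:
    """Respiration rate in µg CO₂-C g⁻¹ dry soil d⁻¹.

    Ideal-gas conversion of the headspace CO₂ increment: volume %CO₂ →
    µl CO₂ → µg CO₂ at the incubation temperature → µg C, normalised per
    g soil and per day. A negative increment (evaporative or colour drift)
    is clipped to 0 with a warning.
    """
    delta = pct_co2 - pct_co2_ambient
    if delta < 0:
        warnings.warn(
            f"negative CO2 increment ({delta:.4g} %): clipped to 0 (colour/evaporative drift)", stacklevel=2
        )
        delta = 0.0
    co2_ul = delta / 100.0 * assay.headspace_ul
    # g/L == µg/µl; density of CO₂ at T via molar volume scaled from 273 K
    co2_ug = co2_ul * (M_CO2 / MOLAR_VOLUME_STP) * (273.0 / (273.0 + assay.temperature_c))
    c_ug = co2_ug * (M_C / M_CO2)
    return c_ug / assay.soil_mass_g * (24.0 / assay.incubation_h)


def process_plate(readings: pd.DataFrame, assay: RespirationAssay) -> pd.DataFrame:
    """Convert a long-format plate readout into per-well respiration rates.

    ``readings`` needs columns ``well, role, timepoint, a570`` with
    timepoints ``t0``/``t6`` and roles ``sample``/``ambient`` (ambient wells
    give the reference headspace %CO₂; with none, ambient defaults to
    0.04 %). Extra columns (e.g. ``sample_id``) are carried through.
    """
    required = {"well", "role", "timepoint", "a570"}
    missing = required - set(readings.columns)
    if missing:
        raise RespirationError(f"plate readings lack columns {sorted(missing)}")
    wide = readings.pivot_table(index="well", columns="timepoint", values="a570", aggfunc="first")
    for tp in ("t0", "t6"):
        if tp not in wide.columns:
            raise RespirationError(f"plate readings lack timepoint {tp!r}")
    roles = readings.drop_duplicates("well").set_index("well")["role"]
    plate_mean_t0 = float(wide["t0"].mean())

    pct = {}
    for well, row in wide.iterrows():
        ai = normalize_absorbance(row["t6"], row["t0"], plate_mean_t0)
        pct[well] = absorbance_to_co2(ai, assay.calibration)
    ambient_wells = [w for w in pct if roles.get(w) == "ambient"]
    ambient = float(np.mean([pct[w] for w in ambient_wells])) if ambient_wells else 0.04

    rows = []
    carry = readings.drop_duplicates("well").set_index("well")
    for well, p in pct.items():
        if roles.get(well) != "sample":
            continue
        rate = co2_to_rate(p, ambient, assay)
        rec = {"well": well, "pct_co2": p, "rate_ug_c_per_g_per_day": rate}
        for col in carry.columns:
            if col not in ("role", "timepoint", "a570"):
                rec[col] = carry.loc[well, col]
        rows.append(rec)
    return pd.DataFrame(rows)
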