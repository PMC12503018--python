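"""Wet-lab arithmetic for the colorimetric peroxidase assays.

Converts a reaction condition into a pipetting recipe (stock dilution
volumes plus the phosphate–citrate buffer split), and raw plate-reader
absorbances into specific enzymatic activities.

Unit conventions: volumes in µL, concentrations in mM (salt, cosubstrate) or
%(v/v) (solvent), activities in U mg^-1.  One unit (U) is the turnover of
1 µmol substrate per minute; for the pyrogallol assay the historical rule
"1 U oxidizes 1 mg pyrogallol in 20 s" applies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "AssaySpec",
    "VolumeSet",
    "AbsorbanceReading",
    "ASSAY_PRESETS",
    "PYROGALLOL_MOLAR_MASS",
    "buffer_volumes",
    "mcilvaine_split",
    "concentration_from_absorbance",
    "specific_activity",
    "replicate_cv",
]

PYROGALLOL_MOLAR_MASS = 126.11  # g mol^-1

UnitRule = Literal["umol_per_min", "pyrogallol_mg_per_20s"]


@dataclass(frozen=True)
class AssaySpec:
    """Per-assay constants.

    ``epsilon`` (mM^-1 cm^-1) is instrument/substrate specific and must be
    supplied by the user; there is no meaningful default.
    """

    v_total: float = 200.0  # µL
    v_substrate: float = 20.0  # µL
    c_substrate: float = 0.3  # mM
    c_salt_stock: float = 2000.0  # mM
    c_cosubstrate_stock: float = 100.0  # mM
    c_solvent_stock: float = 100.0  # % (v/v)
    c_enzyme: float = 5e-4  # mg mL^-1
    reaction_time: float = 60.0  # s
    stop_reagent: str = "sodium azide (1%)"
    stop_volume: float = 20.0  # µL
    wavelength: float = 420.0  # nm
    epsilon: Optional[float] = None  # mM^-1 cm^-1 at `wavelength`
    path_length: float = 1.0  # cm
    unit_rule: UnitRule = "umol_per_min"
    subtract_enzyme_volume: bool = False
    v_enzyme: float = 20.0  # µL, only used if subtract_enzyme_volume

    def __post_init__(self) -> None:
        for name in (
            "v_total",
            "v_substrate",
            "c_substrate",
            "c_salt_stock",
            "c_cosubstrate_stock",
            "c_solvent_stock",
            "c_enzyme",
            "reaction_time",
            "path_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# The four enzyme–substrate pairings screened on the platform.
ASSAY_PRESETS: dict[str, AssaySpec] = {
    "upo-abts": AssaySpec(),
    "hrp-abts": AssaySpec(),
    "hrp-pyrogallol": AssaySpec(
        c_substrate=40.0,
        c_enzyme=2.5e-3,
        reaction_time=60.0,
        stop_reagent="sodium azide (1%) + 1 M NaSO3",
        stop_volume=20.0,
        wavelength=420.0,
        unit_rule="pyrogallol_mg_per_20s",
    ),
    "hrp-tmb": AssaySpec(
        c_substrate=1.0,
        c_enzyme=1e-4,
        reaction_time=30.0,
        stop_reagent="H2SO4 (2 M)",
        stop_volume=50.0,
        wavelength=450.0,
    ),
}


@dataclass(frozen=True)
class VolumeSet:
    """Pipetting volumes for one well; sums with the substrate volume to the
    total assay volume exactly."""

    v_buffer_high_salt: float
    v_cosubstrate: float
    v_solvent: float
    v_buffer_low_salt: float

    def total_with_substrate(self, spec: AssaySpec) -> float:
        return (
            self.v_buffer_high_salt
            + self.v_cosubstrate
            + self.v_solvent
            + self.v_buffer_low_salt
            + spec.v_substrate
        )


@dataclass(frozen=True)
class AbsorbanceReading:
    a_sample: float
    a_blank: float
    wavelength: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_sample) and np.isfinite(self.a_blank)):
            raise ValueError("absorbances must be finite")


def buffer_volumes(point: np.ndarray, spec: AssaySpec) -> VolumeSet:
    """Stock-dilution volumes for a reaction condition.

    ``point`` is (pH, temperature, salt mM, solvent %(v/v), cosubstrate mM);
    only the three concentration coordinates enter.  Each additive volume is
    (target / stock) × V_total and the low-salt buffer takes up the rest,
    after the fixed substrate aliquot.  With ``subtract_enzyme_volume`` the
    enzyme aliquot is also subtracted from the buffer make-up volume.
    """
    _, _, c_salt, c_solv, c_cosub = (float(v) for v in point)
    if c_salt > spec.c_salt_stock or c_cosub > spec.c_cosubstrate_stock or (
        c_solv > spec.c_solvent_stock
    ):
        raise ValueError("target concentration exceeds stock concentration")
    v_high = (c_salt / spec.c_salt_stock) * spec.v_total
    v_cosub = (c_cosub / spec.c_cosubstrate_stock) * spec.v_total
    v_solv = (c_solv / spec.c_solvent_stock) * spec.v_total
    v_low = spec.v_total - v_high - v_cosub - v_solv - spec.v_substrate
    if spec.subtract_enzyme_volume:
        v_low -= spec.v_enzyme
    if v_low < -1e-9:
        raise ValueError(
            f"infeasible recipe at point {np.asarray(point)}: "
            f"buffer make-up volume {v_low:.3f} µL < 0"
        )
    return VolumeSet(v_high, v_cosub, v_solv, max(v_low, 0.0))


# McIlvaine phosphate–citrate reference table: pH -> mL of 0.2 M Na2HPO4 per
# 20 mL total (the remainder is 0.1 M citric acid).  0.2-pH steps, 2.2–8.0.
_MCILVAINE_PHOSPHATE_ML = {
    2.2: 0.40, 2.4: 1.24, 2.6: 2.18, 2.8: 3.17, 3.0: 4.11,
    3.2: 4.94, 3.4: 5.70, 3.6: 6.44, 3.8: 7.10, 4.0: 7.71,
    4.2: 8.28, 4.4: 8.82, 4.6: 9.35, 4.8: 9.86, 5.0: 10.30,
    5.2: 10.72, 5.4: 11.15, 5.6: 11.60, 5.8: 12.09, 6.0: 12.63,
    6.2: 13.22, 6.4: 13.85, 6.6: 14.55, 6.8: 15.45, 7.0: 16.47,
    7.2: 17.39, 7.4: 18.17, 7.6: 18.73, 7.8: 19.15, 8.0: 19.45,
}
_MCILVAINE_PH = np.array(sorted(_MCILVAINE_PHOSPHATE_ML))
_MCILVAINE_CA_FRACTION = np.array(
    [(20.0 - _MCILVAINE_PHOSPHATE_ML[ph]) / 20.0 for ph in _MCILVAINE_PH]
)


def mcilvaine_split(volume: float, ph: float) -> tuple[float, float]:
    """Split a buffer volume into 0.1 M citric acid and 0.2 M Na2HPO4 parts.

    Fractions come from the McIlvaine mixing table, linearly interpolated
    between the tabulated 0.2-pH entries; the two parts sum to ``volume``
    exactly.
    """
    if volume < 0:
        raise ValueError("volume must be nonnegative")
    if not (_MCILVAINE_PH[0] - 1e-9 <= ph <= _MCILVAINE_PH[-1] + 1e-9):
        raise ValueError(
            f"pH {ph} outside the McIlvaine table range "
            f"[{_MCILVAINE_PH[0]}, {_MCILVAINE_PH[-1]}]"
        )
    ca_frac = float(np.interp(ph, _MCILVAINE_PH, _MCILVAINE_CA_FRACTION))
    v_ca = ca_frac * volume
    return v_ca, volume - v_ca


def concentration_from_absorbance(
    reading: AbsorbanceReading, spec: AssaySpec
) -> float:
    """Beer–Lambert: c = (A_sample − A_blank) / (ε · d), in mM.

    Negative values are possible with noisy blanks and are returned as-is.
    """
    if spec.epsilon is None:
        raise ValueError("AssaySpec.epsilon must be set for this assay")
    if spec.epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if abs(reading.wavelength - spec.wavelength) > 1e-9:
        raise ValueError(
            f"reading at {reading.wavelength} nm does not match the assay "
            f"wavelength {spec.wavelength} nm"
        )
    return (reading.a_sample - reading.a_blank) / (spec.epsilon * spec.path_length)


def specific_activity(c: float, spec: AssaySpec) -> float:
    """Specific reaction rate v = c / (t · c_enzyme), in U mg^-1.

    For µmol-based units, c in mM equals µmol mL^-1 and t is taken in
    minutes.  For the pyrogallol rule, c is first converted to mg mL^-1 via
    the molar mass and t is taken in 20-s blocks.
    """
    if spec.c_enzyme <= 0:
        raise ValueError("enzyme concentration must be positive")
    if spec.reaction_time <= 0:
        raise ValueError("reaction time must be positive")
    if spec.unit_rule == "umol_per_min":
        t = spec.reaction_time / 60.0  # minutes
        return c / (t * spec.c_enzyme)
    elif spec.unit_rule == "pyrogallol_mg_per_20s":
        c_mg_per_ml = c * PYROGALLOL_MOLAR_MASS / 1000.0
        t = spec.reaction_time / 20.0  # 20-s blocks
        return c_mg_per_ml / (t * spec.c_enzyme)
    raise ValueError(f"unknown unit rule {spec.unit_rule!r}")


def replicate_cv(values) -> float:
    """Sample coefficient of variation: SD (n−1 denominator) over mean."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two replicates")
    m = vals.mean()
    if m == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return float(vals.std(ddof=1) / m)
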