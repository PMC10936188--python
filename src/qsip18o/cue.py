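"""Community-level carbon use efficiency (CUE) from the 18O-water method.

New DNA synthesized during the incubation draws its oxygen from soil water,
so the 18O atom fraction of extracted DNA is a two-pool mixture of old DNA
(at natural abundance) and new DNA (at the soil-water atom fraction).  The
fraction of new DNA converts — through the measured DNA pool and a
sample-specific DNA→microbial-biomass-carbon factor — into a biomass
production rate C_growth, and

    CUE = C_growth / (C_growth + C_respiration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import NAT_ABUND_18O

__all__ = [
    "CueSample",
    "water_atom_fraction",
    "fraction_new_dna",
    "c_growth",
    "cue_ratio",
    "cue_from_sample",
]


@dataclass
class CueSample:
    """One microcosm's respiration and DNA-isotope measurements.

    Units: ``c_respiration`` in ng C/g soil/h (24-h CO2 accumulation divided
    by 24); ``dna_total`` in ng DNA/g soil; atom fractions dimensionless in
    [0, 1]; ``conv_factor`` in ng MBC per ng DNA; ``t`` in hours.
    """

    sample_id: str
    treatment: str
    c_respiration: float
    dna_total: float
    a_dna_labeled: float
    a_dna_natural: float
    a_water: float
    conv_factor: float
    t: float = 24.0
    cue: float = field(default=float("nan"))

    def __post_init__(self):
        for name in ("a_dna_labeled", "a_dna_natural", "a_water"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name}={a} outside [0, 1]")
        if self.c_respiration < 0:
            raise ValueError("respiration must be non-negative")


def water_atom_fraction(
    vol_added_ul: float = 400.0,
    added_atom_fraction: float = 0.98,
    dry_soil_g: float = 2.0,
    moisture_g_per_g: float = 0.20,
    natural: float = NAT_ABUND_18O,
) -> float:
    """Atom fraction 18O of soil water after adding labeled water.

    Mixes the added heavy water (volume in µL, density ~1 g/mL) with the
    water already held by the soil (dry mass × gravimetric moisture) at
    natural abundance.
    """
    added_g = vol_added_ul / 1000.0
    existing_g = dry_soil_g * moisture_g_per_g
    total = added_g + existing_g
    if total <= 0:
        raise ValueError("no water in the system")
    return (added_g * added_atom_fraction + existing_g * natural) / total


def fraction_new_dna(
    a_dna_labeled: float,
    a_dna_natural: float,
    a_water: float,
    tol: float = 1e-9,
) -> float:
    """Fraction of the DNA pool synthesized during incubation (two-pool
    linear isotope mixing); clipped to [0, 1] with a warning when outside by
    more than ``tol``."""
    if a_water <= a_dna_natural:
        raise ValueError("soil-water atom fraction must exceed natural abundance")
    f_new = (a_dna_labeled - a_dna_natural) / (a_water - a_dna_natural)
    if f_new < -tol or f_new > 1 + tol:
        warnings.warn(
            f"fraction of new DNA {f_new:.4f} outside [0, 1]; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.clip(f_new, 0.0, 1.0))


def c_growth(
    f_new: float,
    dna_total: float,
    conv_factor: float,
    t: float,
    water_o_fraction: float = 1.0,
) -> float:
    """Biomass-C production rate (ng C/g soil/h) from the new-DNA fraction.

    ``water_o_fraction`` is the proportion of oxygen in new DNA that is
    derived from water; 1.0 assumes all of it is (configurable because
    published variants of the method differ on this correction).
    """
    if conv_factor <= 0:
        raise ValueError("conversion factor must be positive")
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if not 0 < water_o_fraction <= 1:
        raise ValueError("water_o_fraction must be in (0, 1]")
    dna_produced = (f_new / water_o_fraction) * dna_total
    return conv_factor * dna_produced / t


def cue_ratio(cg: float, cr: float) -> float:
    """CUE = C_growth / (C_growth + C_respiration), in [0, 1)."""
    if cg < 0 or cr < 0:
        raise ValueError("carbon fluxes must be non-negative")
    if cg == 0 and cr == 0:
        raise ValueError("CUE undefined when growth and respiration are both zero")
    return cg / (cg + cr)


def cue_from_sample(sample: CueSample, water_o_fraction: float = 1.0) -> CueSample:
    """Fill in the derived CUE of one microcosm and return it."""
    f_new = fraction_new_dna(sample.a_dna_labeled, sample.a_dna_natural, sample.a_water)
    cg = c_growth(
        f_new, sample.dna_total, sample.conv_factor, sample.t, water_o_fraction
    )
    sample.cue = cue_ratio(cg, sample.c_respiration)
    return sample
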