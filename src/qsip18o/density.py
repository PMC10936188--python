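"""Per-taxon weighted buoyant density, molecular weight, and excess atom
fraction (EAF) of 18O.

The chain follows the standard qSIP calculation: the abundance-weighted mean
buoyant density of a taxon in the unlabeled (16O) gradient fixes its GC
content and hence the molecular weight of its unlabeled DNA; the density
shift observed in the labeled (18O) gradient is converted to a mass shift,
and the mass shift to an excess atom fraction relative to the maximum
possible 18O incorporation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import (
    DENSITY_GC0,
    DENSITY_PER_GC,
    MAX_MASS_GAIN_18O,
    MW_GC0,
    MW_PER_GC,
    NAT_ABUND_18O,
)

__all__ = [
    "weighted_density",
    "gc_from_density",
    "density_from_gc",
    "mw_from_gc",
    "gc_and_mw_from_light",
    "eaf_18O",
]


def gc_from_density(w_light):
    """GC content from unlabeled buoyant density (inverse of the linear map)."""
    return (np.asarray(w_light, dtype=float) - DENSITY_GC0) / DENSITY_PER_GC


def density_from_gc(gc):
    """Unlabeled buoyant density (g/mL) of DNA with the given GC content."""
    return DENSITY_GC0 + DENSITY_PER_GC * np.asarray(gc, dtype=float)


def mw_from_gc(gc):
    """Mean nucleotide molecular weight (g/mol) of unlabeled DNA."""
    return MW_GC0 + MW_PER_GC * np.asarray(gc, dtype=float)


def weighted_density(rel_abundance, adjusted_copies, densities):
    """Abundance-weighted mean buoyant density of one taxon in one gradient.

    Parameters
    ----------
    rel_abundance
        The taxon's relative abundance in each retained fraction.
    adjusted_copies
        Recovery-adjusted absolute 16S copies of each fraction; set to ones
        to weight by relative abundance alone.
    densities
        Buoyant density (g/mL) of each fraction.

    Returns
    -------
    float
        ``W = sum(density * y) / sum(y)`` with ``y = rel_abundance *
        adjusted_copies``; NaN when the taxon is absent from every fraction.
    """
    y = np.asarray(rel_abundance, dtype=float) * np.asarray(adjusted_copies, dtype=float)
    total = y.sum()
    if not total > 0:
        return float("nan")
    return float(np.dot(np.asarray(densities, dtype=float), y) / total)


def gc_and_mw_from_light(w_light, clamp: bool = True):
    """GC content and unlabeled molecular weight from the light-gradient density.

    GC values falling outside [0, 1] (possible under measurement noise) are
    clamped with a warning when ``clamp`` is true.
    """
    gc = gc_from_density(w_light)
    if clamp:
        out_of_range = (gc < 0) | (gc > 1)
        if np.any(out_of_range & np.isfinite(gc)):
            warnings.warn(
                "GC content outside [0, 1] inferred from buoyant density; clamping",
                RuntimeWarning,
                stacklevel=2,
            )
            gc = np.clip(gc, 0.0, 1.0)
    m_light = mw_from_gc(gc)
    if np.ndim(w_light) == 0:
        return float(gc), float(m_light)
    return gc, m_light


def eaf_18O(w_lab, w_light, clamp_gc: bool = True):
    """Excess atom fraction 18O from labeled and unlabeled weighted densities.

    Returns ``(m_lab, m_heavy_max, eaf)`` where ``m_lab`` is the molecular
    weight of the taxon's DNA in the labeled gradient, ``m_heavy_max`` the
    weight at maximal 18O substitution, and ``eaf`` the excess atom fraction
    (negative values are reported as-is; activity is decided by the CI rule,
    not by the point estimate).
    """
    w_lab = np.asarray(w_lab, dtype=float)
    w_light_arr = np.asarray(w_light, dtype=float)
    gc, m_light = gc_and_mw_from_light(w_light_arr, clamp=clamp_gc)
    m_lab = (w_lab / w_light_arr) * m_light
    m_heavy_max = m_light + MAX_MASS_GAIN_18O
    eaf = ((m_lab - m_light) / (m_heavy_max - m_light)) * (1.0 - NAT_ABUND_18O)
    if np.ndim(w_lab) == 0 and np.ndim(w_light) == 0:
        return float(m_lab), float(m_heavy_max), float(eaf)
    return m_lab, m_heavy_max, eaf
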