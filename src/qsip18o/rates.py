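"""Per-capita reproduction, mortality and net growth under the exponential
birth-death model, plus community-weighted aggregates.

The model assumes that during the incubation every newly synthesized 16S
rRNA gene copy is 18O-labeled and that labeled and unlabeled copies are lost
at the same per-capita rate.  Reproduction is then read off the emergence of
labeled copies, mortality off the loss of unlabeled copies:

    b = (1/t) ln(N_t / N_light_t)      (reproduction, day^-1, >= 0)
    d = (1/t) ln(N_light_t / N_0)      (mortality, day^-1, <= 0)
    r = b + d = (1/t) ln(N_t / N_0)    (net growth, day^-1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "unlabeled_copies",
    "per_capita_rates",
    "absolute_taxon_abundance",
    "community_rates",
    "mean_lifespan",
    "CommunityRates",
]


def unlabeled_copies(n_t, m_lab, m_light, m_heavy_max):
    """Unlabeled 16S copies remaining at the end of the incubation.

    Under full labeling of new copies, the share of unlabeled (old) copies
    in the taxon's DNA pool is the lever-rule complement of the mass shift:
    ``n_light_t = n_t * (m_heavy_max - m_lab) / (m_heavy_max - m_light)``.
    """
    m_light = np.asarray(m_light, dtype=float)
    m_heavy_max = np.asarray(m_heavy_max, dtype=float)
    span = m_heavy_max - m_light
    if np.any(span <= 0):
        raise ValueError("degenerate molecular-weight span: m_heavy_max must exceed m_light")
    return np.asarray(n_t, dtype=float) * (m_heavy_max - np.asarray(m_lab, dtype=float)) / span


def per_capita_rates(n0, n_t, n_light_t, t):
    """Per-capita (b, d, r) in day^-1 from copy numbers and incubation time.

    Raises on non-positive ``n0``/``n_t``/``t``; ``n_light_t = 0`` leaves the
    reproduction rate undefined (returned as NaN) because all copies were
    replaced within the incubation.
    """
    n0 = float(n0)
    n_t = float(n_t)
    n_light_t = float(n_light_t)
    t = float(t)
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if n0 <= 0 or n_t <= 0:
        raise ValueError("copy numbers must be positive")
    if n_light_t < 0 or n_light_t > n_t:
        raise ValueError("unlabeled copies must lie in [0, n_t]")
    if n_light_t == 0:
        return float("nan"), float("nan"), np.log(n_t / n0) / t
    b = np.log(n_t / n_light_t) / t
    d = np.log(n_light_t / n0) / t
    return b, d, b + d


def absolute_taxon_abundance(rel_abund, total_copies):
    """Absolute copy number of a taxon from its share of a measured total."""
    total = np.asarray(total_copies, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total copies must be positive")
    return np.asarray(rel_abund, dtype=float) * total


def mean_lifespan(d_comm: float) -> float:
    """Mean microbial life span (days) as the inverse of the mortality rate."""
    d_comm = float(d_comm)
    if d_comm == 0:
        return float("inf")
    return 1.0 / abs(d_comm)


@dataclass(frozen=True)
class CommunityRates:
    """Abundance-weighted community rates (day^-1) and derived life span."""

    treatment: str
    b_comm: float
    d_comm: float
    r_comm: float
    mean_lifespan: float
    n_taxa: int


def community_rates(
    taxon_rates: pd.DataFrame,
    weights,
    treatment: str = "",
) -> CommunityRates:
    """Abundance-weighted community reproduction, mortality and net growth.

    Each rate is averaged independently over taxa where it is defined,
    weighted by the supplied abundances (typically absolute abundance at the
    end of incubation).  Mortality is kept signed; presentation layers may
    take absolute values.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(taxon_rates):
        raise ValueError("weights must align with taxon_rates rows")

    b = taxon_rates["b"].to_numpy(dtype=float)
    d = taxon_rates["d"].to_numpy(dtype=float)
    # One joint mask so the identity r_comm = b_comm + d_comm holds exactly.
    ok = np.isfinite(b) & np.isfinite(d) & np.isfinite(w) & (w >= 0)
    if not ok.any() or w[ok].sum() <= 0:
        raise ValueError("no taxon with defined rates")
    wn = w[ok] / w[ok].sum()
    b_comm = float(np.dot(wn, b[ok]))
    d_comm = float(np.dot(wn, d[ok]))
    r_comm = b_comm + d_comm
    return CommunityRates(
        treatment=treatment,
        b_comm=b_comm,
        d_comm=d_comm,
        r_comm=r_comm,
        mean_lifespan=mean_lifespan(d_comm) if np.isfinite(d_comm) else float("nan"),
        n_taxa=int(ok.sum()),
    )
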