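"""OTU-table filters, density-window selection, and the qPCR
recovery-efficiency adjustment.

Tables follow two conventions throughout the package:

* **counts** — a :class:`pandas.DataFrame` of non-negative counts with taxon
  ids on the index and a two-level column MultiIndex ``(sample_id,
  fraction)``; unfractionated samples use fraction ``0``.
* **fractions** — a flat :class:`pandas.DataFrame` with one row per gradient
  fraction and columns ``sample_id, replicate, treatment, label, fraction,
  density_g_ml, volume_ul, qpcr_copies_per_ul`` (and ``adjusted_copies``
  once the recovery adjustment has run; this column holds *absolute* copies
  per fraction, not copies/µL).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_rare_otus",
    "filter_prevalence",
    "prevalence_mask",
    "select_density_window",
    "qpcr_recovery",
]


def filter_rare_otus(counts: pd.DataFrame, min_frac: float = 5e-5) -> pd.DataFrame:
    """Drop OTUs whose share of all sequences falls below ``min_frac``.

    The grand total is computed *before* any removal, and the comparison is
    ``>=`` (an OTU sitting exactly at the threshold is kept).
    """
    if counts.size == 0:
        raise ValueError("empty OTU table")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative counts in OTU table")
    grand_total = values.sum()
    if grand_total <= 0:
        raise ValueError("OTU table contains no sequences")
    keep = values.sum(axis=1) / grand_total >= min_frac
    return counts.loc[keep]


def filter_prevalence(
    counts: pd.DataFrame,
    sample_replicates: pd.Series | dict,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Keep OTUs present (total count > 0) in at least ``min_reps`` distinct
    replicates.

    ``sample_replicates`` maps each sample_id appearing in the table's
    columns to its replicate label.  The caller is responsible for passing
    the columns of one treatment × isotope-label group (replicates are the
    resampling unit, so presence is judged within such a group); apply the
    filter per group and intersect when an analysis needs several groups.
    """
    if isinstance(sample_replicates, dict):
        sample_replicates = pd.Series(sample_replicates)
    samples = counts.columns.get_level_values(0)
    missing = set(samples) - set(sample_replicates.index)
    if missing:
        raise ValueError(f"missing replicate metadata for samples: {sorted(missing)}")
    per_sample = counts.T.groupby(level=0).sum().T  # taxa x sample totals
    reps = sample_replicates.loc[per_sample.columns]
    present_reps = (per_sample > 0).T.groupby(reps.values).any().T.sum(axis=1)
    return counts.loc[present_reps >= min_reps]


def prevalence_mask(
    counts: pd.DataFrame,
    sample_replicates: pd.Series | dict,
    min_reps: int = 2,
) -> pd.Series:
    """Boolean per-taxon pass/fail of the prevalence rule (helper for
    intersecting several treatment × label groups)."""
    kept = filter_prevalence(counts, sample_replicates, min_reps=min_reps).index
    return pd.Series(counts.index.isin(kept), index=counts.index)


def select_density_window(
    fractions: pd.DataFrame, lo: float = 1.69, hi: float = 1.74
) -> pd.DataFrame:
    """Keep gradient fractions with buoyant density in the closed interval
    [lo, hi]; raises if any sample loses all of its fractions."""
    dens = fractions["density_g_ml"].to_numpy(dtype=float)
    if not np.isfinite(dens).all():
        raise ValueError("non-finite fraction densities")
    kept = fractions.loc[(dens >= lo) & (dens <= hi)]
    lost = set(fractions["sample_id"]) - set(kept["sample_id"])
    if lost:
        raise ValueError(
            f"density window [{lo}, {hi}] empty for sample(s): {sorted(lost)}"
        )
    return kept


def qpcr_recovery(
    sample_fractions: pd.DataFrame, unfractionated_total: float
) -> pd.DataFrame:
    """Rescale one sample's per-fraction qPCR copies by its recovery
    efficiency.

    ``recovery = sum(copies_per_uL * volume_uL) / unfractionated_total``;
    each fraction's absolute copies are divided by this single per-sample
    ratio, so the adjusted copies sum to the unfractionated total exactly.
    Returns a copy of the input with an ``adjusted_copies`` column (absolute
    copies per fraction).
    """
    if unfractionated_total <= 0:
        raise ValueError("unfractionated total must be positive")
    if sample_fractions["sample_id"].nunique() > 1:
        raise ValueError("qpcr_recovery expects the fractions of a single sample")
    absolute = (
        sample_fractions["qpcr_copies_per_ul"].to_numpy(dtype=float)
        * sample_fractions["volume_ul"].to_numpy(dtype=float)
    )
    recovery = absolute.sum() / unfractionated_total
    if recovery <= 0:
        raise ValueError("recovery efficiency is non-positive")
    if recovery > 1:
        warnings.warn(
            f"recovery efficiency {recovery:.3f} exceeds 1 for sample "
            f"{sample_fractions['sample_id'].iloc[0]}",
            RuntimeWarning,
            stacklevel=2,
        )
    out = sample_fractions.copy()
    out["adjusted_copies"] = absolute / recovery
    return out
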