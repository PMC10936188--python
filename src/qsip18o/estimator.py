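"""Per-replicate estimation chain: filtered tables -> weighted densities,
absolute abundances, EAF and per-capita rates.

This module holds the deterministic estimation core shared by the point
estimates and by the replicate bootstrap: everything is expressed as
functions of per-replicate weighted densities and abundances, so a bootstrap
resample only has to average different replicate subsets and push them
through :func:`estimates_from_means`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MAX_MASS_GAIN_18O, NAT_ABUND_18O
from . import filtering
from .density import gc_and_mw_from_light

__all__ = [
    "EstimatorConfig",
    "ReplicateEstimates",
    "build_replicate_estimates",
    "estimates_from_means",
    "point_estimates",
]


@dataclass
class EstimatorConfig:
    """Thresholds and switches of the estimation chain.

    ``density_lo``/``density_hi`` bound the retained gradient fractions in
    g/mL; ``t_days`` is the incubation length; ``n0_floor`` replaces a zero
    time-zero abundance (taxon undetected at t0 but present at t_end) so
    rates stay finite; ``weight_by_copies`` weights the per-fraction
    relative abundances by recovery-adjusted absolute copies when computing
    weighted densities (switch off to weight by relative abundance alone).
    """

    min_frac: float = 5e-5
    min_reps: int = 2
    density_lo: float = 1.69
    density_hi: float = 1.74
    t_days: float = 1.0
    n0_floor: float = 1.0
    weight_by_copies: bool = True


@dataclass
class ReplicateEstimates:
    """Per-replicate summaries of one treatment, aligned on a common taxon
    index: weighted densities in the light and labeled gradients, absolute
    abundance at t_end (labeled arm), and absolute abundance at t0."""

    taxa: pd.Index
    w_light: np.ndarray  # (n_taxa, n_light_reps)
    w_lab: np.ndarray  # (n_taxa, n_lab_reps)
    n_t: np.ndarray  # (n_taxa, n_lab_reps)
    n0: np.ndarray  # (n_taxa, n_t0_reps)
    t_days: float
    treatment: str = ""
    n0_floored: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


def _sample_profiles(counts: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Taxon x fraction relative abundances for one sample, computed over
    *all* sequenced taxa of each fraction library."""
    sub = counts.xs(sample_id, level=0, axis=1).astype(float)
    colsums = sub.sum(axis=0)
    rel = sub.div(colsums.where(colsums > 0, np.nan), axis=1).fillna(0.0)
    return rel


def build_replicate_estimates(
    fractions: pd.DataFrame,
    counts: pd.DataFrame,
    totals: pd.DataFrame,
    t0_counts: pd.DataFrame,
    cfg: EstimatorConfig | None = None,
    treatment: str | None = None,
    log: list | None = None,
) -> ReplicateEstimates:
    """Run the filtering chain and reduce one treatment to per-replicate
    quantities.

    Filtering order is fixed: rare-OTU filter on the pooled sequence total
    (gradient plus t0 libraries), then the prevalence rule within each
    treatment x isotope-label group (an OTU must pass in both the 16O and
    the 18O group), then recovery adjustment over all fractions of each
    sample, then the density-window selection.
    """
    cfg = cfg or EstimatorConfig()
    if treatment is None:
        treatment = str(fractions["treatment"].iloc[0])
    fr = fractions[fractions["treatment"] == treatment]
    if fr.empty:
        raise ValueError(f"no fractions for treatment {treatment!r}")

    # --- rare-OTU filter on the pooled table -----------------------------
    t0_cols = pd.DataFrame(
        t0_counts.to_numpy(dtype=float),
        index=t0_counts.index,
        columns=pd.MultiIndex.from_product([t0_counts.columns, [0]]),
    )
    combined = pd.concat([counts, t0_cols], axis=1).fillna(0.0)
    n_before = len(combined)
    combined = filtering.filter_rare_otus(combined, min_frac=cfg.min_frac)
    if log is not None:
        log.append(
            f"rare-OTU filter (min_frac={cfg.min_frac}): {n_before} -> {len(combined)} taxa"
        )

    # --- prevalence within each treatment x label group ------------------
    rep_map = fr.drop_duplicates("sample_id").set_index("sample_id")["replicate"]
    masks = []
    for label in ("16O", "18O"):
        group_samples = fr.loc[fr["label"] == label, "sample_id"].unique()
        if len(group_samples) == 0:
            raise ValueError(f"missing {label} samples for treatment {treatment!r}")
        group_counts = counts.loc[
            combined.index, counts.columns.get_level_values(0).isin(group_samples)
        ]
        masks.append(
            filtering.prevalence_mask(group_counts, rep_map, min_reps=cfg.min_reps)
        )
    keep = masks[0] & masks[1]
    taxa = combined.index[keep.to_numpy()]
    if log is not None:
        log.append(
            f"prevalence filter (min_reps={cfg.min_reps}): {len(combined)} -> {len(taxa)} taxa"
        )
    if len(taxa) == 0:
        raise ValueError("no taxa survive filtering")

    # --- recovery adjustment (all fractions), then density window --------
    tend = totals[totals["timepoint"] == "tend"].set_index("sample_id")["total_copies"]
    adjusted = []
    for sample_id, sample_fr in fr.groupby("sample_id", sort=False):
        if sample_id not in tend.index:
            raise ValueError(f"missing unfractionated t_end total for {sample_id}")
        adjusted.append(filtering.qpcr_recovery(sample_fr, float(tend[sample_id])))
    fr_adj = pd.concat(adjusted, ignore_index=True)
    n_frac_before = len(fr_adj)
    fr_win = filtering.select_density_window(fr_adj, cfg.density_lo, cfg.density_hi)
    if log is not None:
        log.append(
            f"density window [{cfg.density_lo}, {cfg.density_hi}] g/mL: "
            f"{n_frac_before} -> {len(fr_win)} fractions"
        )

    # --- per-replicate weighted densities and abundances -----------------
    def _per_sample(sample_id: str):
        rows = fr_win[fr_win["sample_id"] == sample_id]
        rel = _sample_profiles(counts, sample_id)
        rel = rel.reindex(index=taxa, columns=rows["fraction"].to_numpy()).fillna(0.0)
        weights = (
            rows["adjusted_copies"].to_numpy(dtype=float)
            if cfg.weight_by_copies
            else np.ones(len(rows))
        )
        y = rel.to_numpy() * weights[None, :]
        tot = y.sum(axis=1)
        dens = rows["density_g_ml"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(tot > 0, y @ dens / np.where(tot > 0, tot, 1.0), np.nan)
        abund = (rel.to_numpy() * rows["adjusted_copies"].to_numpy(dtype=float)[None, :]).sum(
            axis=1
        )
        return w, abund

    meta = fr.drop_duplicates("sample_id")[["sample_id", "label", "replicate"]]
    light_samples = meta.loc[meta["label"] == "16O"].sort_values("replicate")["sample_id"]
    lab_samples = meta.loc[meta["label"] == "18O"].sort_values("replicate")["sample_id"]

    w_light = np.column_stack([_per_sample(s)[0] for s in light_samples])
    lab = [_per_sample(s) for s in lab_samples]
    w_lab = np.column_stack([w for w, _ in lab])
    n_t = np.column_stack([a for _, a in lab])

    # --- t0 absolute abundances ------------------------------------------
    t0_tot = totals[totals["timepoint"] == "t0"].set_index("sample_id")["total_copies"]
    t0 = t0_counts.astype(float)
    shares = t0.div(t0.sum(axis=0).where(t0.sum(axis=0) > 0, np.nan), axis=1)
    shares = shares.reindex(index=taxa).fillna(0.0)
    n0_cols = []
    for s in t0.columns:
        if s not in t0_tot.index:
            raise ValueError(f"missing unfractionated t0 total for {s}")
        n0_cols.append(shares[s].to_numpy() * float(t0_tot[s]))
    n0 = np.column_stack(n0_cols)
    floored = n0 <= 0
    n0 = np.where(floored, cfg.n0_floor, n0)

    return ReplicateEstimates(
        taxa=pd.Index(taxa, name="taxon_id"),
        w_light=w_light,
        w_lab=w_lab,
        n_t=n_t,
        n0=n0,
        t_days=cfg.t_days,
        treatment=treatment,
        n0_floored=floored.any(axis=1),
    )


def estimates_from_means(w_light, w_lab, n0, n_t, t_days: float) -> dict:
    """EAF and (b, d, r) from replicate-averaged inputs.

    Vectorized over taxa (and over bootstrap resamples when the inputs carry
    an extra axis).  The estimator-level unlabeled pool is clipped into
    ``(0, min(n_t, n0)]`` before taking logarithms so that b >= 0 and d <= 0
    under measurement noise; the clip leaves r = b + d = ln(n_t/n0)/t exact
    because the unlabeled pool cancels in the sum.  A non-positive unlabeled
    pool (apparent complete turnover) leaves b and d undefined (NaN).
    """
    w_light = np.asarray(w_light, dtype=float)
    w_lab = np.asarray(w_lab, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    n_t = np.asarray(n_t, dtype=float)

    gc, m_light = gc_and_mw_from_light(w_light, clamp=True)
    m_lab = np.where(w_light > 0, w_lab / w_light, np.nan) * m_light
    m_heavy = m_light + MAX_MASS_GAIN_18O
    eaf = ((m_lab - m_light) / MAX_MASS_GAIN_18O) * (1.0 - NAT_ABUND_18O)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_light = n_t * (m_heavy - m_lab) / MAX_MASS_GAIN_18O
        defined = np.isfinite(n_light) & (n_light > 0) & (n_t > 0) & (n0 > 0)
        n_light_used = np.clip(n_light, None, np.minimum(n_t, n0))
        b = np.where(defined, np.log(n_t / n_light_used) / t_days, np.nan)
        d = np.where(defined, np.log(n_light_used / n0) / t_days, np.nan)
        r = np.where(
            (n_t > 0) & (n0 > 0), np.log(np.where(n0 > 0, n_t / n0, np.nan)) / t_days, np.nan
        )
        # keep the identity exact where b and d are defined
        r = np.where(defined, b + d, r)
    return {
        "gc": gc,
        "m_light": m_light,
        "m_lab": m_lab,
        "m_heavy_max": m_heavy,
        "eaf": eaf,
        "n_light_t": n_light,
        "b": b,
        "d": d,
        "r": r,
    }


def point_estimates(est: ReplicateEstimates) -> pd.DataFrame:
    """Per-taxon point estimates from replicate means (W_light averaged over
    the 16O replicates in which the taxon passes filters)."""
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        wl = np.nanmean(est.w_light, axis=1)
        wh = np.nanmean(est.w_lab, axis=1)
    n0 = est.n0.mean(axis=1)
    nt = est.n_t.mean(axis=1)
    vals = estimates_from_means(wl, wh, n0, nt, est.t_days)
    df = pd.DataFrame(
        {
            "w_light": wl,
            "w_lab": wh,
            "n0": n0,
            "n_t": nt,
            **{k: vals[k] for k in ("gc", "m_light", "m_lab", "m_heavy_max", "eaf", "n_light_t", "b", "d", "r")},
        },
        index=est.taxa,
    )
    df["n0_floored"] = est.n0_floored
    df["treatment"] = est.treatment
    return df
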