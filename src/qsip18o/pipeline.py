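"""End-to-end orchestration: tables in, EAF/rate/activity/CUE tables out,
with a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .bootstrap import BootstrapConfig, bootstrap_qsip, call_active, summarize_activity
from .cue import CueSample, cue_from_sample
from .estimator import EstimatorConfig, build_replicate_estimates
from .rates import community_rates

__all__ = ["PipelineConfig", "run_pipeline", "analyze_treatment"]


@dataclass
class PipelineConfig:
    """Paths and settings of a full run.

    ``counts``/``fractions``/``totals``/``t0_counts`` are TSV paths (see
    :mod:`qsip18o.io` for the column contracts); ``cue_samples`` is optional.
    """

    counts: str = ""
    fractions: str = ""
    totals: str = ""
    t0_counts: str = ""
    cue_samples: str = ""
    out_dir: str = "qsip_out"
    seed: int = 0
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    weight_timepoint: str = "tend"  # abundance weights for community rates
    active_only_community: bool = False
    water_o_fraction: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def analyze_treatment(
    fractions: pd.DataFrame,
    counts: pd.DataFrame,
    totals: pd.DataFrame,
    t0_counts: pd.DataFrame,
    treatment: str,
    est_cfg: EstimatorConfig,
    boot_cfg: BootstrapConfig,
    weight_timepoint: str = "tend",
    active_only_community: bool = False,
    log: list | None = None,
) -> dict:
    """Full inference for one treatment: filtering, per-taxon EAF and rates
    with bootstrap CIs, activity calls, and community-weighted rates."""
    est = build_replicate_estimates(
        fractions, counts, totals, t0_counts, est_cfg, treatment, log=log
    )
    taxon_table = bootstrap_qsip(est, boot_cfg)
    taxon_table["active"] = call_active(taxon_table)
    n_total, n_active, pct = summarize_activity(taxon_table["active"])

    weights = taxon_table["n_t" if weight_timepoint == "tend" else "n0"]
    table_for_comm = taxon_table[taxon_table["active"]] if active_only_community else taxon_table
    w_for_comm = weights.loc[table_for_comm.index]
    comm = community_rates(table_for_comm, w_for_comm, treatment=treatment)
    return {
        "treatment": treatment,
        "taxon_table": taxon_table,
        "community": comm,
        "activity": {"n_total": n_total, "n_active": n_active, "pct_active": pct},
    }


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every treatment found in the fraction metadata and write outputs.

    Writes per-taxon EAF/rate tables, a community summary, an activity
    summary, an optional CUE table, and ``manifest.json`` recording the
    package version, configuration hash and seeds.  Deterministic given the
    configuration and seed.
    """
    fractions = io.read_fractions(cfg.fractions)
    counts = io.read_counts(cfg.counts)
    totals = io.read_totals(cfg.totals)
    t0_counts = io.read_t0_counts(cfg.t0_counts)

    out = io.ensure_dir(cfg.out_dir)
    log: list[str] = []
    results = {}
    comm_rows = []
    act_rows = []
    for i, treatment in enumerate(pd.unique(fractions["treatment"])):
        boot = BootstrapConfig(
            n_boot=cfg.bootstrap.n_boot,
            alpha=cfg.bootstrap.alpha,
            seed=cfg.seed + i,
            scheme=cfg.bootstrap.scheme,
        )
        log.append(f"treatment {treatment}: start")
        res = analyze_treatment(
            fractions,
            counts,
            totals,
            t0_counts,
            treatment,
            cfg.estimator,
            boot,
            weight_timepoint=cfg.weight_timepoint,
            active_only_community=cfg.active_only_community,
            log=log,
        )
        results[treatment] = res
        io.write_table(res["taxon_table"], out / f"taxa_{treatment}.tsv")
        comm = res["community"]
        comm_rows.append(
            {
                "treatment": treatment,
                "b_comm": comm.b_comm,
                "d_comm": comm.d_comm,
                "r_comm": comm.r_comm,
                "mean_lifespan_days": comm.mean_lifespan,
                "n_taxa": comm.n_taxa,
            }
        )
        act_rows.append({"treatment": treatment, **res["activity"]})

    community_df = pd.DataFrame(comm_rows)
    activity_df = pd.DataFrame(act_rows)
    io.write_table(community_df, out / "community_rates.tsv", index=False)
    io.write_table(activity_df, out / "activity_summary.tsv", index=False)

    cue_df = None
    if cfg.cue_samples:
        raw = io.read_cue_samples(cfg.cue_samples)
        rows = []
        for _, row in raw.iterrows():
            sample = CueSample(
                sample_id=str(row["sample_id"]),
                treatment=str(row["treatment"]),
                c_respiration=float(row["c_respiration"]),
                dna_total=float(row["dna_total"]),
                a_dna_labeled=float(row["a_dna_labeled"]),
                a_dna_natural=float(row["a_dna_natural"]),
                a_water=float(row["a_water"]),
                conv_factor=float(row["conv_factor"]),
                t=float(row.get("t", 24.0)),
            )
            cue_from_sample(sample, water_o_fraction=cfg.water_o_fraction)
            rows.append({**row.to_dict(), "cue": sample.cue})
        cue_df = pd.DataFrame(rows)
        io.write_table(cue_df, out / "cue.tsv", index=False)

    manifest = {
        "package": "qsip18o",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "log": log,
    }
    (Path(out) / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "treatments": results,
        "community": community_df,
        "activity": activity_df,
        "cue": cue_df,
        "manifest": manifest,
    }
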