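"""TSV readers/writers with schema validation.

All tables are UTF-8 TSV with '.' decimal separators.  Count-table columns
use ``sample:fraction`` headers (fraction 0 for unfractionated samples).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FRACTION_COLUMNS = [
    "sample_id",
    "replicate",
    "treatment",
    "label",
    "fraction",
    "density_g_ml",
    "volume_ul",
    "qpcr_copies_per_ul",
]

TOTAL_COLUMNS = ["sample_id", "replicate", "treatment", "label", "timepoint", "total_copies"]

VALID_LABELS = {"16O", "18O", "t0"}


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{s}:{f}" for s, f in out.columns]
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated taxon ids: {dupes}")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative counts in count table")
    cols = []
    for c in df.columns:
        sample, _, frac = c.rpartition(":")
        if not sample:
            raise ValueError(f"count column {c!r} is not in 'sample:fraction' form")
        cols.append((sample, int(frac)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["sample_id", "fraction"])
    df.index.name = "taxon_id"
    return df


def write_t0_counts(t0_counts: pd.DataFrame, path) -> None:
    out = t0_counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_t0_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicated taxon ids in t0 count table")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative counts in t0 count table")
    df.index.name = "taxon_id"
    return df


def write_fractions(fractions: pd.DataFrame, path) -> None:
    fractions.to_csv(path, sep="\t", index=False)


def read_fractions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FRACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - VALID_LABELS
    if bad:
        raise ValueError(f"unknown isotope labels: {sorted(bad)}")
    if (df["qpcr_copies_per_ul"].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative qPCR readings")
    return df


def write_totals(totals: pd.DataFrame, path) -> None:
    totals.to_csv(path, sep="\t", index=False)


def read_totals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TOTAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"totals table missing columns: {sorted(missing)}")
    if (df["total_copies"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("non-positive unfractionated totals")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_cue_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {
        "sample_id",
        "treatment",
        "c_respiration",
        "dna_total",
        "a_dna_labeled",
        "a_dna_natural",
        "a_water",
        "conv_factor",
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"CUE table missing columns: {sorted(missing)}")
    for col in ("a_dna_labeled", "a_dna_natural", "a_water"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
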