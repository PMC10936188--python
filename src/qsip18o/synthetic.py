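"""Synthetic gradient-fractionation experiments and CUE microcosms with
known ground truth.

The generator emulates the measurement chain of an 18O-water qSIP study:
a community of taxa with lognormal absolute abundances and GC-dependent
unlabeled buoyant densities grows and dies exponentially over a 24-h
incubation; at the end, each taxon's 16S copies split into an unlabeled pool
(old copies, banding at the GC-determined density) and a labeled pool (new
copies, banding at the density implied by full 18O substitution).  Both
pools spread over a CsCl density grid with Gaussian kernels, are partially
lost during fractionation (a per-sample recovery factor), and are observed
through multinomial amplicon sequencing of each fraction library and
lognormally noisy qPCR.

The forward density↔molecular-weight mapping is the same published qSIP
mapping the estimator inverts, so the full chain is exact in the noise-free
limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MAX_MASS_GAIN_18O, NAT_ABUND_18O
from .cue import CueSample, water_atom_fraction
from .density import density_from_gc, mw_from_gc

__all__ = [
    "TrueTaxonParams",
    "GradientDesign",
    "ExperimentTables",
    "simulate_community",
    "simulate_gradient",
    "simulate_experiment",
    "simulate_cue_microcosm",
    "implied_eaf",
]


@dataclass(frozen=True)
class TrueTaxonParams:
    """Ground truth for one simulated taxon.

    ``true_eaf`` is the taxon-level excess atom fraction the estimator
    should recover; for a community generated by :func:`simulate_community`
    it is tied to the reproduction rate by the full-labeling identity
    ``true_eaf = (1 - exp(-b_true * t)) * (1 - NAT_ABUND_18O)``.
    """

    taxon_id: str
    gc: float
    n0: float
    true_eaf: float
    b_true: float
    d_true: float

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if not 0.0 <= self.true_eaf <= 1.0:
            raise ValueError("true_eaf must be in [0, 1]")
        if self.b_true < 0:
            raise ValueError("reproduction rate must be non-negative")
        if self.d_true > 0:
            raise ValueError("mortality rate must be non-positive (signed convention)")

    @property
    def r_true(self) -> float:
        return self.b_true + self.d_true


def implied_eaf(b: float, t: float) -> float:
    """Taxon-level EAF implied by reproduction rate b over incubation t
    when every new copy is fully labeled."""
    return (1.0 - np.exp(-b * t)) * (1.0 - NAT_ABUND_18O)


@dataclass
class GradientDesign:
    """Design of one simulated gradient-fractionation experiment.

    ``seq_depth`` is the number of reads per sequencing library (each
    gradient fraction and each unfractionated time-zero sample is its own
    library).  ``qpcr_cv`` is the coefficient of variation of per-fraction
    qPCR noise; unfractionated totals are simulated as the mean of
    ``qpcr_tech_reps`` technical replicates at the same CV.  ``exact=True``
    switches off all measurement noise (expected read counts, noise-free
    qPCR) for oracle round-trip checks; the recovery loss remains and is
    inverted exactly by the estimator.
    """

    n_fractions: int = 20
    density_grid: np.ndarray | None = None
    band_sd: float = 0.006
    seq_depth: int = 50_000
    qpcr_cv: float = 0.1
    initial_density: float = 1.718
    n_replicates: int = 3
    t_incubation: float = 1.0
    volume_ul: float = 250.0
    recovery_range: tuple[float, float] = (0.6, 0.95)
    qpcr_tech_reps: int = 3
    exact: bool = False

    def __post_init__(self):
        if self.density_grid is None:
            self.density_grid = np.linspace(1.640, 1.800, self.n_fractions)
        self.density_grid = np.asarray(self.density_grid, dtype=float)
        if self.density_grid.ndim != 1 or len(self.density_grid) != self.n_fractions:
            raise ValueError("density_grid must have n_fractions entries")
        if not np.all(np.diff(self.density_grid) > 0):
            raise ValueError("density_grid must be strictly increasing")
        if self.band_sd <= 0:
            raise ValueError("band_sd must be positive")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be positive")


@dataclass
class ExperimentTables:
    """All tables of one simulated treatment: paired 16O/18O gradients plus
    unfractionated time-zero sequencing and qPCR."""

    fractions: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.DataFrame
    t0_counts: pd.DataFrame
    truth: pd.DataFrame
    treatment: str


_LAW_DEFAULT = {"name": "lognormal", "mu": 10.0, "sigma": 1.0}


def simulate_community(
    n_taxa: int,
    seed: int,
    abundance_law: dict | None = None,
    inactive_fraction: float = 0.0,
    t_incubation: float = 1.0,
    gc_range: tuple[float, float] = (0.3, 0.7),
    b_range: tuple[float, float] = (0.05, 0.6),
    d_range: tuple[float, float] = (-0.6, -0.1),
) -> list[TrueTaxonParams]:
    """Draw a community with lognormal absolute abundances and plausible
    per-capita rates.

    ``inactive_fraction`` of the taxa get b_true = 0 (and hence
    true_eaf = 0) to provide ground-truth-negative taxa for calibration
    checks.  Deterministic given ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    law = dict(_LAW_DEFAULT if abundance_law is None else abundance_law)
    name = law.pop("name", None)
    if name != "lognormal":
        raise ValueError(f"unknown abundance law: {name!r}")
    mu = float(law.pop("mu", _LAW_DEFAULT["mu"]))
    sigma = float(law.pop("sigma", _LAW_DEFAULT["sigma"]))
    if law:
        raise ValueError(f"unknown abundance-law parameters: {sorted(law)}")

    rng = np.random.default_rng(seed)
    gc = rng.uniform(*gc_range, size=n_taxa)
    n0 = np.exp(rng.normal(mu, sigma, size=n_taxa))
    b = rng.uniform(*b_range, size=n_taxa)
    inactive = rng.random(n_taxa) < inactive_fraction
    b[inactive] = 0.0
    d = rng.uniform(d_range[0], d_range[1], size=n_taxa)
    eaf = implied_eaf(b, t_incubation)
    return [
        TrueTaxonParams(
            taxon_id=f"otu{i + 1:04d}",
            gc=float(gc[i]),
            n0=float(n0[i]),
            true_eaf=float(eaf[i]),
            b_true=float(b[i]),
            d_true=float(d[i]),
        )
        for i in range(n_taxa)
    ]


def _band_weights(grid: np.ndarray, centers: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian band profile of each taxon over the density grid, normalized
    to unit mass per taxon (mass outside the grid is truncated onto it)."""
    lo, hi = grid[0], grid[-1]
    outside = (centers < lo) | (centers > hi)
    if np.any(outside):
        warnings.warn(
            "band center outside density grid; mass truncated at grid ends",
            RuntimeWarning,
            stacklevel=3,
        )
    k = stats.norm.pdf(grid[None, :], loc=centers[:, None], scale=sd)
    totals = k.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return k / totals


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def simulate_gradient(
    community: list[TrueTaxonParams],
    design: GradientDesign,
    label: str,
    seed: int,
    treatment: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one isotope arm (all replicates) of a treatment.

    Returns ``(fractions, counts, totals)``: per-fraction metadata with
    qPCR readings, the taxon × (sample, fraction) read-count table, and the
    unfractionated qPCR totals at t0 and t_end per replicate.  For
    ``label="16O"`` every effective EAF is forced to zero.
    """
    if not community:
        raise ValueError("empty community")
    if label not in ("16O", "18O"):
        raise ValueError("label must be '16O' or '18O'")
    rng = np.random.default_rng(seed)
    grid = design.density_grid
    t = design.t_incubation

    gc = np.array([tx.gc for tx in community])
    n0 = np.array([tx.n0 for tx in community])
    b = np.array([tx.b_true for tx in community])
    d = np.array([tx.d_true for tx in community])
    eaf = np.array([tx.true_eaf for tx in community])
    if label == "16O":
        eaf = np.zeros_like(eaf)

    n_t = n0 * np.exp((b + d) * t)
    # Labeled-pool share; clipping at 1 raises the pool mass instead so the
    # mixture centroid always sits at the density implied by true_eaf.
    s = np.clip(eaf / (1.0 - NAT_ABUND_18O), 0.0, 1.0)
    labeled_mass = s * n_t
    unlabeled_mass = n_t - labeled_mass

    w_light = density_from_gc(gc)
    m_light = mw_from_gc(gc)
    m_pool = np.where(
        s > 0,
        m_light + (eaf / np.where(s > 0, s, 1.0)) / (1.0 - NAT_ABUND_18O) * MAX_MASS_GAIN_18O,
        m_light,
    )
    w_pool = (m_pool / m_light) * w_light

    k_light = _band_weights(grid, w_light, design.band_sd)
    k_pool = _band_weights(grid, w_pool, design.band_sd)

    frac_rows = []
    count_cols = {}
    total_rows = []
    taxa = [tx.taxon_id for tx in community]

    for rep in range(1, design.n_replicates + 1):
        sample_id = f"{treatment}_{label}_r{rep}"
        # expected taxon x fraction copy numbers at t_end (before loss)
        expected = unlabeled_mass[:, None] * k_light + labeled_mass[:, None] * k_pool
        frac_totals = expected.sum(axis=0)
        recovery = rng.uniform(*design.recovery_range)

        qpcr_noise = (
            np.ones(design.n_fractions)
            if design.exact
            else _mean_one_lognormal(rng, design.qpcr_cv, (design.n_fractions,))
        )
        conc = frac_totals * recovery / design.volume_ul * qpcr_noise

        if design.exact:
            counts = expected.copy()
        else:
            counts = np.zeros_like(expected)
            for f in range(design.n_fractions):
                tot = frac_totals[f]
                if tot > 0:
                    counts[:, f] = rng.multinomial(design.seq_depth, expected[:, f] / tot)

        for f in range(design.n_fractions):
            frac_rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "treatment": treatment,
                    "label": label,
                    "fraction": f + 1,
                    "density_g_ml": grid[f],
                    "volume_ul": design.volume_ul,
                    "qpcr_copies_per_ul": conc[f],
                }
            )
            count_cols[(sample_id, f + 1)] = counts[:, f]

        tend_noise = (
            1.0
            if design.exact
            else float(
                _mean_one_lognormal(
                    rng, design.qpcr_cv, (design.qpcr_tech_reps,)
                ).mean()
            )
        )
        t0_noise = (
            1.0
            if design.exact
            else float(
                _mean_one_lognormal(
                    rng, design.qpcr_cv, (design.qpcr_tech_reps,)
                ).mean()
            )
        )
        total_rows.append(
            {
                "sample_id": sample_id,
                "replicate": rep,
                "treatment": treatment,
                "label": label,
                "timepoint": "tend",
                "total_copies": n_t.sum() * tend_noise,
            }
        )
        total_rows.append(
            {
                "sample_id": f"{treatment}_t0_r{rep}",
                "replicate": rep,
                "treatment": treatment,
                "label": "t0",
                "timepoint": "t0",
                "total_copies": n0.sum() * t0_noise,
            }
        )

    fractions = pd.DataFrame(frac_rows)
    counts_df = pd.DataFrame(count_cols, index=pd.Index(taxa, name="taxon_id"))
    counts_df.columns = pd.MultiIndex.from_tuples(
        counts_df.columns, names=["sample_id", "fraction"]
    )
    totals = pd.DataFrame(total_rows)
    return fractions, counts_df, totals


def _simulate_t0(
    community: list[TrueTaxonParams],
    design: GradientDesign,
    rng: np.random.Generator,
    treatment: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unfractionated time-zero sequencing and qPCR, one library per
    replicate."""
    n0 = np.array([tx.n0 for tx in community])
    taxa = [tx.taxon_id for tx in community]
    shares = n0 / n0.sum()
    cols = {}
    total_rows = []
    for rep in range(1, design.n_replicates + 1):
        sample_id = f"{treatment}_t0_r{rep}"
        if design.exact:
            cols[sample_id] = shares * design.seq_depth
            noise = 1.0
        else:
            cols[sample_id] = rng.multinomial(design.seq_depth, shares).astype(float)
            noise = float(
                _mean_one_lognormal(rng, design.qpcr_cv, (design.qpcr_tech_reps,)).mean()
            )
        total_rows.append(
            {
                "sample_id": sample_id,
                "replicate": rep,
                "treatment": treatment,
                "label": "t0",
                "timepoint": "t0",
                "total_copies": n0.sum() * noise,
            }
        )
    t0_counts = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon_id"))
    return t0_counts, pd.DataFrame(total_rows)


def simulate_experiment(
    community: list[TrueTaxonParams],
    design: GradientDesign,
    seed: int,
    treatment: str = "control",
) -> ExperimentTables:
    """Simulate the paired 16O/18O arms of one treatment plus shared
    time-zero measurements (the t0 sample belongs to the field replicate and
    is measured once)."""
    rng = np.random.default_rng(seed)
    child = rng.spawn(3)
    t0_counts, t0_totals = _simulate_t0(community, design, child[0], treatment)
    frac_l, counts_l, totals_l = simulate_gradient(
        community, design, "16O", _child_seed(child[1]), treatment
    )
    frac_h, counts_h, totals_h = simulate_gradient(
        community, design, "18O", _child_seed(child[2]), treatment
    )
    fractions = pd.concat([frac_l, frac_h], ignore_index=True)
    counts = pd.concat([counts_l, counts_h], axis=1)
    tend_totals = pd.concat(
        [
            totals_l[totals_l["timepoint"] == "tend"],
            totals_h[totals_h["timepoint"] == "tend"],
        ],
        ignore_index=True,
    )
    totals = pd.concat([t0_totals, tend_totals], ignore_index=True)
    truth = pd.DataFrame(
        {
            "taxon_id": [tx.taxon_id for tx in community],
            "gc": [tx.gc for tx in community],
            "n0": [tx.n0 for tx in community],
            "true_eaf": [tx.true_eaf for tx in community],
            "b_true": [tx.b_true for tx in community],
            "d_true": [tx.d_true for tx in community],
            "r_true": [tx.r_true for tx in community],
        }
    ).set_index("taxon_id")
    return ExperimentTables(
        fractions=fractions,
        counts=counts,
        totals=totals,
        t0_counts=t0_counts,
        truth=truth,
        treatment=treatment,
    )


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_cue_microcosm(
    true_cue: float,
    c_respiration: float,
    water_atom_pct: float = 100 * water_atom_fraction(),
    seed: int = 0,
    noise_cv: float = 0.0,
    dna_total: float = 10_000.0,
    conv_factor: float = 40.0,
    t: float = 24.0,
    sample_id: str = "sim",
    treatment: str = "control",
) -> CueSample:
    """Back-compute a CUE microcosm consistent with a known true CUE.

    ``C_growth = C_respiration * cue / (1 - cue)``; the labeled-DNA atom
    fraction is then set by inverting the two-pool mixing model, with
    optional multiplicative measurement noise (CV ``noise_cv``) on the
    respiration rate and the isotope excess.
    """
    if not 0.0 <= true_cue < 1.0:
        raise ValueError("true_cue must be in [0, 1)")
    if c_respiration <= 0:
        raise ValueError("respiration must be positive")
    rng = np.random.default_rng(seed)
    a_water = water_atom_pct / 100.0
    a_nat = NAT_ABUND_18O

    cg = c_respiration * true_cue / (1.0 - true_cue)
    dna_produced = cg * t / conv_factor
    f_new = dna_produced / dna_total
    if f_new > 1:
        raise ValueError(
            "implied new-DNA fraction exceeds 1; increase dna_total or lower true_cue"
        )
    excess = f_new * (a_water - a_nat)
    cr_obs = c_respiration
    if noise_cv > 0:
        excess *= float(_mean_one_lognormal(rng, noise_cv, ()))
        cr_obs *= float(_mean_one_lognormal(rng, noise_cv, ()))
    return CueSample(
        sample_id=sample_id,
        treatment=treatment,
        c_respiration=cr_obs,
        dna_total=dna_total,
        a_dna_labeled=a_nat + excess,
        a_dna_natural=a_nat,
        a_water=a_water,
        conv_factor=conv_factor,
        t=t,
    )
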