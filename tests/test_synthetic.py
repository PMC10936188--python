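"""The gradient-experiment generator: determinism, degenerate kernels,
label symmetry, closed-form band centroids, and CUE microcosms."""

import numpy as np
import pytest

from qsip18o.constants import MAX_MASS_GAIN_18O, NAT_ABUND_18O
from qsip18o.cue import cue_from_sample
from qsip18o.density import density_from_gc, mw_from_gc
from qsip18o.filtering import qpcr_recovery
from qsip18o.synthetic import (
    GradientDesign,
    TrueTaxonParams,
    implied_eaf,
    simulate_community,
    simulate_cue_microcosm,
    simulate_experiment,
    simulate_gradient,
)


class TestCommunity:
    def test_single_taxon_smoke(self):
        (taxon,) = simulate_community(1, seed=1)
        for value in (taxon.gc, taxon.n0, taxon.true_eaf, taxon.b_true, taxon.d_true):
            assert np.isfinite(value)
        assert taxon.n0 > 0

    def test_same_seed_identical(self):
        assert simulate_community(25, seed=42) == simulate_community(25, seed=42)

    def test_lognormal_abundance_law(self):
        community = simulate_community(
            500, seed=2, abundance_law={"name": "lognormal", "mu": 10.0, "sigma": 2.0}
        )
        logs = np.log([t.n0 for t in community])
        se = 2.0 / np.sqrt(500)
        assert abs(logs.mean() - 10.0) < 3 * se

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError):
            simulate_community(5, seed=1, abundance_law={"name": "pareto"})

    def test_eaf_tied_to_reproduction_rate(self):
        for taxon in simulate_community(20, seed=3):
            assert taxon.true_eaf == pytest.approx(implied_eaf(taxon.b_true, 1.0))


class TestGradient:
    def test_degenerate_kernel_concentrates_mass(self):
        taxon = TrueTaxonParams("t1", gc=0.5, n0=1e6, true_eaf=0.0, b_true=0.0, d_true=-0.1)
        design = GradientDesign(band_sd=1e-3, exact=True)
        fr, counts, _ = simulate_gradient([taxon], design, "16O", seed=4)
        col_totals = counts.sum(axis=0)
        nearest = int(np.argmin(np.abs(design.density_grid - density_from_gc(0.5)))) + 1
        one_sample = col_totals.loc["control_16O_r1"]
        assert one_sample[nearest] / one_sample.sum() > 0.999

    def test_no_label_symmetry_when_eaf_zero(self):
        taxa = [
            TrueTaxonParams(f"t{i}", gc=g, n0=1e6, true_eaf=0.0, b_true=0.0, d_true=-0.2)
            for i, g in enumerate([0.4, 0.6])
        ]
        design = GradientDesign(exact=True)
        _, c16, _ = simulate_gradient(taxa, design, "16O", seed=5)
        _, c18, _ = simulate_gradient(taxa, design, "18O", seed=5)
        assert np.allclose(c16.to_numpy(), c18.to_numpy())

    def test_full_labeling_centroid_matches_closed_form(self):
        # Hand oracle: at eaf=1 the band centroid sits at the density implied
        # by the maximum-labeling molecular weight scaled by 1/(1 - natural
        # abundance).
        gc = 0.5
        taxon = TrueTaxonParams("t1", gc=gc, n0=1e6, true_eaf=1.0, b_true=1.0, d_true=-0.1)
        design = GradientDesign(
            n_fractions=80, density_grid=np.linspace(1.62, 1.84, 80), exact=True
        )
        _, counts, _ = simulate_gradient([taxon], design, "18O", seed=6)
        profile = counts.sum(axis=0).loc["control_18O_r1"].to_numpy()
        centroid = float(np.dot(design.density_grid, profile) / profile.sum())
        m_light = mw_from_gc(gc)
        w_light = density_from_gc(gc)
        m_max = m_light + MAX_MASS_GAIN_18O / (1.0 - NAT_ABUND_18O)
        expected = m_max / m_light * w_light
        assert centroid == pytest.approx(expected, abs=1e-3)

    def test_adjusted_copies_conserve_unfractionated_total(self):
        community = simulate_community(10, seed=7)
        design = GradientDesign(seq_depth=10_000, qpcr_cv=0.05)
        fr, _, totals = simulate_gradient(community, design, "18O", seed=8)
        tend = totals[totals["timepoint"] == "tend"].set_index("sample_id")["total_copies"]
        for sample_id, sub in fr.groupby("sample_id"):
            adj = qpcr_recovery(sub, float(tend[sample_id]))
            assert adj["adjusted_copies"].sum() == pytest.approx(float(tend[sample_id]))

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            simulate_gradient([], GradientDesign(), "16O", seed=1)

    def test_band_outside_grid_warns(self):
        taxon = TrueTaxonParams("t1", gc=0.99, n0=1e6, true_eaf=0.0, b_true=0.0, d_true=-0.1)
        design = GradientDesign(density_grid=np.linspace(1.64, 1.70, 20), exact=True)
        with pytest.warns(RuntimeWarning):
            simulate_gradient([taxon], design, "16O", seed=1)

    def test_experiment_deterministic_given_seed(self):
        community = simulate_community(8, seed=9)
        design = GradientDesign(seq_depth=5_000, qpcr_cv=0.1)
        a = simulate_experiment(community, design, seed=10)
        b = simulate_experiment(community, design, seed=10)
        assert a.counts.equals(b.counts)
        assert a.fractions.equals(b.fractions)
        assert a.totals.equals(b.totals)


class TestCueMicrocosm:
    def test_no_growth_means_natural_abundance(self):
        sample = simulate_cue_microcosm(0.0, c_respiration=500.0, seed=1)
        assert sample.a_dna_labeled == pytest.approx(sample.a_dna_natural)

    def test_cue_half_means_growth_equals_respiration(self):
        sample = simulate_cue_microcosm(0.5, c_respiration=400.0, seed=1)
        # invert the mixing model by hand
        f_new = (sample.a_dna_labeled - sample.a_dna_natural) / (
            sample.a_water - sample.a_dna_natural
        )
        cg = f_new * sample.dna_total * sample.conv_factor / sample.t
        assert cg == pytest.approx(400.0, rel=1e-9)

    @pytest.mark.parametrize("true_cue", [0.1, 0.35, 0.6, 0.9])
    def test_roundtrip_recovers_cue(self, true_cue):
        sample = simulate_cue_microcosm(true_cue, c_respiration=650.0, seed=2)
        assert cue_from_sample(sample).cue == pytest.approx(true_cue, abs=1e-9)

    def test_cue_of_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_cue_microcosm(1.0, c_respiration=100.0, seed=1)
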