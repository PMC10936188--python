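"""OTU filters, density window, and qPCR recovery adjustment, each checked
against small brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsip18o.filtering import (
    filter_prevalence,
    filter_rare_otus,
    qpcr_recovery,
    select_density_window,
)


def _counts(data, samples=None):
    """Build a counts table with (sample, fraction) columns from a dict of
    taxon -> list of counts."""
    df = pd.DataFrame(data).T
    n = df.shape[1]
    samples = samples or [("s1", f + 1) for f in range(n)]
    df.columns = pd.MultiIndex.from_tuples(samples, names=["sample_id", "fraction"])
    df.index.name = "taxon_id"
    return df


class TestRareFilter:
    def test_threshold_arithmetic(self):
        table = _counts({"a": [4], "b": [99996]})
        kept = filter_rare_otus(table, min_frac=5e-5)
        assert list(kept.index) == ["b"]  # 4/100000 < 5e-5

    def test_boundary_kept_at_exact_threshold(self):
        table = _counts({"a": [5], "b": [99995]})
        kept = filter_rare_otus(table, min_frac=5e-5)
        assert set(kept.index) == {"a", "b"}  # 5/100000 == 5e-5, >= keeps

    @pytest.mark.parametrize("min_frac", [5e-5, 1e-3, 5e-3, 0.05])
    def test_printed_toy_table_matches_bruteforce(self, min_frac):
        counts = {"a": 5000, "b": 300, "c": 10, "d": 5, "e": 4, "f": 1}
        table = _counts({k: [v] for k, v in counts.items()})
        total = sum(counts.values())
        expected = {k for k, v in counts.items() if v / total >= min_frac}
        kept = filter_rare_otus(table, min_frac=min_frac)
        assert set(kept.index) == expected

    def test_idempotent(self):
        table = _counts({"a": [5000], "b": [3], "c": [40000]})
        once = filter_rare_otus(table, min_frac=1e-4)
        twice = filter_rare_otus(once, min_frac=1e-4)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_rare_otus(pd.DataFrame())


class TestPrevalence:
    reps = {"s1": 1, "s2": 2, "s3": 3}

    def _table(self, rows):
        return _counts(rows, samples=[("s1", 1), ("s2", 1), ("s3", 1)])

    def test_present_in_two_replicates_kept(self):
        table = self._table({"a": [3, 1, 0]})
        assert "a" in filter_prevalence(table, self.reps).index

    def test_present_in_one_replicate_removed(self):
        table = self._table({"a": [0, 0, 9]})
        assert "a" not in filter_prevalence(table, self.reps).index

    def test_random_table_matches_bruteforce_tally(self):
        rng = np.random.default_rng(5)
        data = {f"t{i}": rng.integers(0, 3, size=3).tolist() for i in range(20)}
        table = self._table(data)
        kept = filter_prevalence(table, self.reps, min_reps=2)
        expected = {k for k, v in data.items() if sum(x > 0 for x in v) >= 2}
        assert set(kept.index) == expected

    def test_missing_replicate_metadata_rejected(self):
        table = self._table({"a": [1, 1, 1]})
        with pytest.raises(ValueError):
            filter_prevalence(table, {"s1": 1})


class TestDensityWindow:
    def _fractions(self, densities):
        return pd.DataFrame(
            {
                "sample_id": "s1",
                "replicate": 1,
                "treatment": "control",
                "label": "18O",
                "fraction": np.arange(1, len(densities) + 1),
                "density_g_ml": densities,
                "volume_ul": 250.0,
                "qpcr_copies_per_ul": 10.0,
            }
        )

    def test_boundary_cases(self):
        fr = self._fractions([1.689, 1.70, 1.69, 1.74])
        kept = select_density_window(fr)
        assert set(kept["density_g_ml"]) == {1.70, 1.69, 1.74}

    def test_even_grid_matches_interval_oracle(self):
        grid = np.linspace(1.65, 1.78, 20)
        kept = select_density_window(self._fractions(grid), 1.69, 1.74)
        expected = [d for d in grid if 1.69 <= d <= 1.74]
        assert np.allclose(sorted(kept["density_g_ml"]), expected)

    def test_window_emptying_a_sample_is_an_error(self):
        fr = self._fractions([1.60, 1.62])
        with pytest.raises(ValueError, match="s1"):
            select_density_window(fr)


class TestRecovery:
    def test_hand_arithmetic(self, toy_fractions):
        # (100 + 300) copies/µL x 250 µL = 100000; /200000 -> recovery 0.5
        adj = qpcr_recovery(toy_fractions, unfractionated_total=200_000.0)
        assert np.allclose(adj["adjusted_copies"], [50_000.0, 150_000.0])
        assert adj["adjusted_copies"].sum() == pytest.approx(200_000.0)

    def test_identity_when_sums_already_match(self, toy_fractions):
        adj = qpcr_recovery(toy_fractions, unfractionated_total=100_000.0)
        raw = toy_fractions["qpcr_copies_per_ul"] * toy_fractions["volume_ul"]
        assert np.allclose(adj["adjusted_copies"], raw)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        base = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "volume_ul": [250.0] * 3,
                "qpcr_copies_per_ul": [10.0, 70.0, 20.0],
            }
        )
        scaled = base.assign(qpcr_copies_per_ul=base["qpcr_copies_per_ul"] * scale)
        a = qpcr_recovery(base, 60_000.0)["adjusted_copies"]
        b = qpcr_recovery(scaled, 60_000.0)["adjusted_copies"]
        assert np.allclose(a, b)

    def test_total_conserved_on_random_inputs(self):
        rng = np.random.default_rng(11)
        fr = pd.DataFrame(
            {
                "sample_id": ["s1"] * 8,
                "volume_ul": rng.uniform(200, 300, 8),
                "qpcr_copies_per_ul": rng.uniform(1, 500, 8),
            }
        )
        total = 1.7e6
        adj = qpcr_recovery(fr, total)
        assert adj["adjusted_copies"].sum() == pytest.approx(total, rel=1e-12)

    def test_recovery_above_one_warns(self, toy_fractions):
        with pytest.warns(RuntimeWarning):
            qpcr_recovery(toy_fractions, unfractionated_total=50_000.0)

    def test_nonpositive_total_rejected(self, toy_fractions):
        with pytest.raises(ValueError):
            qpcr_recovery(toy_fractions, unfractionated_total=0.0)
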