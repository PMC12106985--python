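"""EFI, cluster aggregates and weighted descriptive tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgmspatial.community import (
    age_at_cutting_distribution,
    community_aggregates,
    efi,
    weighted_prevalence,
)


def women_frame(**overrides):
    base = {
        "cluster_id": ["c1"] * 4,
        "state_id": "s0",
        "zone": "north_west",
        "residence": "rural",
        "mother_education": ["none", "secondary", "higher", "none"],
        "mother_support": ["yes", "no", "no", "no"],
        "mother_fgm": ["cut", "cut", "uncut", "uncut"],
        "ethnicity": ["hausa", "hausa", "fulani", "hausa"],
        "religion": ["islam", "islam", "christian", "islam"],
        "wealth": ["poorest", "poorer", "poorer", "middle"],
        "weight": [1.0] * 4,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestEfi:
    @pytest.mark.parametrize(
        "shares,expected",
        [([0.5, 0.5], 0.5), ([1.0], 0.0), ([0.6, 0.3, 0.1], 0.54)],
    )
    def test_known_values(self, shares, expected):
        assert efi(np.array(shares)) == pytest.approx(expected)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_equal_groups_attain_maximum(self, n):
        assert efi(np.full(n, 1.0 / n)) == pytest.approx(1 - 1 / n)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8))
    def test_matches_direct_summation(self, raw):
        s = np.array(raw) / np.sum(raw)
        assert efi(s) == pytest.approx(1.0 - sum(x * x for x in s), abs=1e-12)

    def test_not_summing_to_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            efi(np.array([0.5, 0.4]))


class TestCommunityAggregates:
    def test_equal_weight_percentages(self):
        prof = community_aggregates(women_frame()).iloc[0]
        assert prof["pct_cut"] == pytest.approx(50.0)
        assert prof["pct_support"] == pytest.approx(25.0)
        assert prof["pct_secondary_plus"] == pytest.approx(50.0)

    def test_weighted_pct_cut(self):
        df = women_frame(
            weight=[3.0, 1.0, 1.0, 1.0], mother_fgm=["cut", "uncut", "uncut", "uncut"]
        )
        assert community_aggregates(df).iloc[0]["pct_cut"] == pytest.approx(50.0)

    def test_single_ethnicity_cluster_has_zero_efi(self):
        df = women_frame(ethnicity=["igbo"] * 4)
        assert community_aggregates(df).iloc[0]["efi"] == pytest.approx(0.0)

    def test_modal_tie_broken_by_declared_order(self):
        df = women_frame(religion=["islam", "islam", "christian", "christian"])
        # christian precedes islam in the declared order
        assert community_aggregates(df).iloc[0]["main_religion"] == "christian"

    def test_permutation_invariance(self, rng):
        df = women_frame(weight=[2.0, 1.0, 0.5, 3.0])
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = community_aggregates(df).iloc[0]
        b = community_aggregates(shuffled).iloc[0]
        for col in ("pct_cut", "pct_support", "efi", "main_religion", "main_wealth"):
            assert a[col] == b[col]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            community_aggregates(women_frame().iloc[0:0])


class TestWeightedPrevalence:
    def girls(self, statuses, weights, **extra):
        df = pd.DataFrame(
            {"fgm_status": statuses, "weight": weights, "state_id": "s0", "zone": "z"}
        )
        for k, v in extra.items():
            df[k] = v
        return df

    def test_unweighted_half(self):
        t = weighted_prevalence(self.girls([1, 1, 0, 0], [1, 1, 1, 1]))
        assert t["prevalence_pct"].iloc[0] == pytest.approx(50.0)
        assert t["n_unweighted"].iloc[0] == 4

    def test_weighted_ratio(self):
        t = weighted_prevalence(self.girls([1, 0, 0], [2, 1, 1]))
        assert t["prevalence_pct"].iloc[0] == pytest.approx(50.0)

    def test_weight_rescaling_invariance(self):
        df = self.girls([1, 0, 1, 0, 0], [0.5, 1.5, 2.0, 0.7, 1.1], zone=list("aabbb"))
        a = weighted_prevalence(df, by=["zone"])
        df2 = df.assign(weight=df["weight"] * 2)
        b = weighted_prevalence(df2, by=["zone"])
        assert np.allclose(a["prevalence_pct"], b["prevalence_pct"])

    def test_national_equals_zone_aggregation(self, lattice):
        from fgmspatial.scenarios import recovery_dataset

        records, *_ = recovery_dataset(seed=23, n_clusters_per_state=2, n_girls_per_cluster=20)
        national = weighted_prevalence(records)["prevalence_pct"].iloc[0]
        by_zone = weighted_prevalence(records, by=["zone"])
        combined = (
            by_zone["prevalence_pct"] * by_zone["n_weighted"]
        ).sum() / by_zone["n_weighted"].sum()
        assert national == pytest.approx(combined, abs=1e-9)


class TestAgeAtCutting:
    def girls(self, ages_at_cutting, girl_ages=None, weights=None):
        n = len(ages_at_cutting)
        return pd.DataFrame(
            {
                "fgm_status": 1,
                "age_at_cutting": ages_at_cutting,
                "girl_age": girl_ages or [14] * n,
                "weight": weights or [1.0] * n,
            }
        )

    def test_all_cut_at_zero(self):
        t = age_at_cutting_distribution(self.girls([0, 0, 0]))
        assert t.set_index("band").loc["<=1", "pct"] == pytest.approx(100.0)

    def test_two_girls_split_between_extreme_bands(self):
        t = age_at_cutting_distribution(self.girls([1, 12])).set_index("band")
        assert list(t["pct"]) == pytest.approx([50.0, 0.0, 0.0, 50.0])

    def test_bands_sum_to_hundred(self, rng):
        ages = rng.integers(0, 15, size=40).astype(float)
        w = rng.uniform(0.2, 3.0, size=40)
        t = age_at_cutting_distribution(self.girls(list(ages), weights=list(w)))
        assert t["pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_no_cut_girls_rejected(self):
        df = self.girls([0]).assign(fgm_status=0)
        with pytest.raises(ValueError, match="no cut girls"):
            age_at_cutting_distribution(df)
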