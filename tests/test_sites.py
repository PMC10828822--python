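import numpy as np
import pytest

from tmtd.layout import two_proteome_layout
from tmtd.simulate import simulate_site_protein_pairs
from tmtd.sites import (
    AggregatedFeature,
    aggregate,
    balance_and_ratio,
    pick_protein_group,
)


class TestAggregate:
    def test_intensity_weighted_eil(self):
        feats = aggregate(
            psm_intensities=[{"A": 100.0}, {"A": 300.0}],
            psm_eils=[0.1, 0.3],
            grouping=["p1", "p1"],
            level="protein",
        )
        assert feats[0].eil == pytest.approx(0.25)
        assert feats[0].intensities["A"] == pytest.approx(400.0)
        assert feats[0].n_psms == 2

    def test_single_psm_keeps_its_eil(self):
        (feat,) = aggregate([{"A": 42.0}], [0.37], ["p"], "site")
        assert feat.eil == 0.37

    def test_ms3_quantified_feature_gets_zero_eil(self):
        (feat,) = aggregate([{"A": 10.0}], [0.5], ["p"], "protein", ms3_flags=[True])
        assert feat.eil == 0.0

    def test_zero_intensity_feature_has_missing_eil(self):
        with pytest.warns(UserWarning, match="zero total intensity"):
            (feat,) = aggregate([{}], [0.5], ["p"], "protein")
        assert feat.eil is None


@pytest.fixture(scope="module")
def layout():
    return two_proteome_layout()


def feature(layout, level, value, eil, feature_id="f"):
    return AggregatedFeature(
        feature_id=feature_id,
        level=level,
        intensities={c: value for c in layout.peptide_channels},
        eil=eil,
        n_psms=1,
    )


class TestBalance:
    def test_delta_interference_by_hand(self, layout):
        # protein mean 100, EIL 0.2 vs site EIL 0.5 -> +60 on every channel
        site = feature(layout, "site", 50.0, 0.5)
        protein = feature(layout, "protein", 100.0, 0.2)
        out = balance_and_ratio(site, protein, layout)
        assert out.adjusted == "protein"
        assert out.delta_interference == pytest.approx(60.0)
        assert out.delta_eil == pytest.approx(0.3)

    def test_equal_eils_mean_plain_division(self, layout):
        site = feature(layout, "site", 30.0, 0.4)
        protein = feature(layout, "protein", 60.0, 0.4)
        out = balance_and_ratio(site, protein, layout)
        assert out.adjusted == "none"
        assert out.delta_interference == 0.0
        for v in out.ratios.values():
            assert v == pytest.approx(0.5)

    def test_site_adjusted_when_less_interfered(self, layout):
        site = feature(layout, "site", 50.0, 0.1)
        protein = feature(layout, "protein", 100.0, 0.3)
        out = balance_and_ratio(site, protein, layout)
        assert out.adjusted == "site"
        # site mean 50: 50 * 0.9/0.7 - 50
        assert out.delta_interference == pytest.approx(50.0 * 0.9 / 0.7 - 50.0)

    def test_normalized_ratio_median_is_one(self, layout, rng=np.random.default_rng(0)):
        site = AggregatedFeature(
            "s", "site",
            {c: float(rng.lognormal(3, 0.5)) for c in layout.peptide_channels}, 0.5, 1,
        )
        protein = AggregatedFeature(
            "p", "protein",
            {c: float(rng.lognormal(5, 0.5)) for c in layout.peptide_channels}, 0.2, 1,
        )
        out = balance_and_ratio(site, protein, layout)
        assert np.median(list(out.normalized_ratios.values())) == pytest.approx(1.0)

    def test_adjustment_equalizes_implied_interference(self, layout):
        # after adding delta, mean * (1 - EIL_s) equals original mean * (1 - EIL_p)
        protein = feature(layout, "protein", 100.0, 0.2)
        site = feature(layout, "site", 50.0, 0.5)
        out = balance_and_ratio(site, protein, layout)
        adjusted_mean = 100.0 + out.delta_interference
        assert adjusted_mean * (1 - 0.5) == pytest.approx(100.0 * (1 - 0.2), abs=1e-9)

    def test_saturated_eil_pair_skipped(self, layout):
        site = feature(layout, "site", 50.0, 1.0)
        protein = feature(layout, "protein", 100.0, 0.2)
        with pytest.warns(UserWarning, match="skipped"):
            assert balance_and_ratio(site, protein, layout) is None

    def test_multi_group_sites_pick_largest_group(self, layout):
        a = feature(layout, "protein", 10.0, 0.1, "B_protein")
        a.n_psms = 5
        b = feature(layout, "protein", 10.0, 0.1, "A_protein")
        b.n_psms = 5
        c = feature(layout, "protein", 10.0, 0.1, "C_protein")
        c.n_psms = 9
        with pytest.warns(UserWarning, match="3 protein groups"):
            assert pick_protein_group("s1", [a, b, c]).feature_id == "C_protein"
        with pytest.warns(UserWarning, match="2 protein groups"):
            assert pick_protein_group("s1", [a, b]).feature_id == "A_protein"


class TestBiasRemoval:
    def test_balancing_removes_group_trend_without_inflating_variance(self, layout):
        pattern = {}
        for g in layout.groups.values():
            for c in g.channels:
                pattern[c] = 1.0 + g.spike_amount / 18.0
        pairs = simulate_site_protein_pairs(
            200, layout, pattern, site_interference=0.4, protein_interference=0.1,
            noise_sd=0.1, seed=3,
        )
        def group_means(ratios):
            return [
                np.log2(np.mean([ratios[c] for c in g.channels if c in ratios]))
                for g in layout.groups.values()
            ]

        naive_means, balanced_means = [], []
        naive_var, balanced_var = [], []
        for p in pairs:
            site = AggregatedFeature("s", "site", p["site_intensities"], p["site_eil"], 1)
            prot = AggregatedFeature("p", "protein", p["protein_intensities"], p["protein_eil"], 1)
            balanced = balance_and_ratio(site, prot, layout)
            site0 = AggregatedFeature("s", "site", p["site_intensities"], 0.0, 1)
            prot0 = AggregatedFeature("p", "protein", p["protein_intensities"], 0.0, 1)
            naive = balance_and_ratio(site0, prot0, layout)
            naive_means.append(group_means(naive.normalized_ratios))
            balanced_means.append(group_means(balanced.normalized_ratios))
            naive_var.append(np.var(np.log2(list(naive.normalized_ratios.values()))))
            balanced_var.append(np.var(np.log2(list(balanced.normalized_ratios.values()))))
        naive_trend = np.ptp(np.mean(naive_means, axis=0))
        balanced_trend = np.ptp(np.mean(balanced_means, axis=0))
        assert naive_trend > 0.08  # systematic interference-driven trend
        assert balanced_trend < 0.02
        assert np.mean(balanced_var) <= np.mean(naive_var) + 1e-9
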