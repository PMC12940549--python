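"""Quantile classes, class-level correlation, and HDP/HSIP selection."""

import math

import numpy as np
import pytest

from keynet.datatypes import WeightedNetwork
from keynet.fixtures import load_published_key_proteins
from keynet.selection import (
    assemble_key_proteins,
    class_level_correlation,
    cs_percentile_threshold,
    degree_class_score_points,
    key_proteins,
    quantile_class_table,
    select_hdps,
    select_hsips,
)

from conftest import random_network


class TestQuantileClassTable:
    def test_top_class_holds_values_above_80th_percentile(self):
        table = quantile_class_table(range(1, 11))
        top = table.class_summary(0.2)
        assert top.member_count == 2
        assert top.mean_value == pytest.approx(9.5)  # members {9, 10}
        assert table.cut_points[3] == pytest.approx(8.2)

    def test_counts_partition_all_values(self):
        vals = np.random.default_rng(0).normal(size=137)
        table = quantile_class_table(vals)
        assert sum(c.member_count for c in table.classes) == 137

    def test_all_identical_one_occupied_class(self):
        table = quantile_class_table([7.0] * 12)
        occupied = [c for c in table.classes if c.member_count]
        assert len(occupied) == 1
        assert occupied[0].member_count == 12

    def test_boundary_values_fall_to_lower_class(self):
        # 20th/40th/... percentiles of 1..5 are exactly the values themselves
        table = quantile_class_table([1, 2, 3, 4, 5])
        assert [c.member_count for c in table.classes] == [1, 1, 1, 1, 1]
        assert table.class_summary(1.0).mean_value == pytest.approx(1.0)

    def test_matches_sort_based_partition_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 70, size=60).astype(float)
        table = quantile_class_table(vals)
        cuts = np.percentile(vals, [20, 40, 60, 80])
        # oracle: count values strictly above the 80th-percentile cut
        assert table.class_summary(0.2).member_count == int((vals > cuts[3]).sum())
        assert table.class_summary(1.0).member_count == int((vals <= cuts[0]).sum())

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_class_table([1, 2, 3])


class TestClassLevelCorrelation:
    def test_perfectly_linear_points(self):
        pts = [[(1.0, 100.0), (2.0, 200.0), (3.0, 300.0)]]
        r, p = class_level_correlation(pts)
        assert r == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        pts = [[(0.0, 0.0), (1.0, 1.0), (2.0, 4.0)]]
        r, _ = class_level_correlation(pts)
        x, y = np.array([0, 1, 2.0]), np.array([0, 1, 4.0])
        dx, dy = x - x.mean(), y - y.mean()
        expected = (dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum())
        assert r == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        pts = [[(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)]]
        r, p = class_level_correlation(pts)
        assert math.isnan(r) and math.isnan(p)

    def test_degree_class_points_shape(self, random_net):
        pts = degree_class_score_points(random_net)
        assert 1 <= len(pts) <= 5
        for deg, score in pts:
            assert deg >= 1
            assert 0 <= score <= 1000


class TestSelectHdps:
    def test_star_center_first(self, star5):
        assert select_hdps(star5, 1)[0].symbol == "HUB"

    def test_k_exceeding_nodes_rejected(self, triangle):
        with pytest.raises(ValueError):
            select_hdps(triangle, 4)

    def test_tie_broken_by_incident_score_then_symbol(self):
        # all nodes have degree 2; incident sums C=1000, A=D=600, B=200;
        # the A/D tie falls back to lexicographic order
        net = WeightedNetwork.from_edges(
            [("A", "B", 100), ("B", "D", 100), ("A", "C", 500), ("C", "D", 500)]
        )
        records = select_hdps(net, 3)
        assert [r.symbol for r in records] == ["C", "A", "D"]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_full_sort_oracle(self, seed):
        net = random_network(18, 0.3, seed=seed)
        got = [r.symbol for r in select_hdps(net, 3)]
        scores = {
            n: sum(net.score(n, nb) for nb in net.neighbors(n)) for n in net.nodes()
        }
        oracle = sorted(
            net.nodes(), key=lambda n: (-net.degree(n), -scores[n], n)
        )[:3]
        assert got == oracle


class TestCsPercentileThreshold:
    def test_constant_scores(self):
        net = WeightedNetwork.from_edges(
            [("A", "B", 500), ("B", "C", 500), ("C", "D", 500)]
        )
        assert cs_percentile_threshold(net, 90) == 500

    def test_linear_interpolation_oracle(self):
        net = WeightedNetwork.from_edges(
            (f"A{i}", f"B{i}", i) for i in range(1, 101)
        )
        # sorted scores 1..100: 90th percentile = 1 + 0.9*99 = 90.1 -> 90
        assert cs_percentile_threshold(net, 90) == 90
        # 50th percentile = 50.5, rounds half-to-even to 50
        assert cs_percentile_threshold(net, 50) == 50

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            cs_percentile_threshold(WeightedNetwork.from_edges([], nodes=["A"]))


class TestSelectHsips:
    def test_strict_inequality_excludes_boundary(self):
        net = WeightedNetwork.from_edges(
            [("H", "A", 700), ("H", "B", 700), ("H", "C", 700)]
        )
        hdps = select_hdps(net, 1)
        assert select_hsips(net, hdps, 700) == ()

    def test_partners_above_threshold(self, star5):
        hdps = select_hdps(star5, 1)
        records = select_hsips(star5, hdps, 350)
        assert {r.partner for r in records} == {"L3", "L4", "L5"}
        assert all(r.hub == "HUB" for r in records)


@pytest.fixture(scope="module")
def keysets():
    return load_published_key_proteins()


class TestKeyProteinFixture:
    """The published key-protein table loaded from the packaged TSV."""

    def test_nh_hub_partners(self, keysets):
        nh = keysets["NH"]
        bdnf = [(r.partner, r.combined_score) for r in nh.hsips if r.hub == "BDNF"]
        assert bdnf == [("NTRK2", 999), ("NTF3", 991), ("GDNF", 963)]
        assert all(s > nh.cs_threshold for _, s in bdnf)

    def test_nh_pvalb_has_no_partners(self, keysets):
        assert not [r for r in keysets["NH"].hsips if r.hub == "PVALB"]

    def test_unique_member_counts(self, keysets):
        assert len(keysets["NH"].unique_members) == 7
        assert len(keysets["AS"].unique_members) == 16
        assert len(keysets["Tin"].unique_members) == 21

    def test_tin_cross_hub_duplicates_counted_once(self, keysets):
        tin = keysets["Tin"]
        partners = [r.partner for r in tin.hsips]
        assert partners.count("NGFR") == 2
        assert partners.count("CASP3") == 2
        assert len(tin.unique_members) == 3 + len(tin.hsips) - 2

    def test_symbol_normalization_applied(self, keysets):
        assert "APOE" in keysets["Tin"].unique_members
        assert "ApoE" not in keysets["Tin"].unique_members

    def test_thresholds(self, keysets):
        assert {c: k.cs_threshold for c, k in keysets.items()} == {
            "NH": 930, "AS": 896, "Tin": 908
        }


class TestAssembleKeyProteins:
    def test_empty_hsips_members_are_hubs(self, triangle):
        hdps = select_hdps(triangle, 2)
        ks = assemble_key_proteins("x", hdps, (), cs_threshold=999)
        assert ks.unique_members == {h.symbol for h in hdps}

    def test_member_count_bound(self):
        for seed in range(5):
            net = random_network(20, 0.35, seed=seed)
            ks = key_proteins(net, "x", k=3, hsip_percentile=80)
            assert len(ks.unique_members) <= 3 + len(ks.hsips)

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_percentile_shrinks_membership(self, seed):
        net = random_network(25, 0.3, seed=seed)
        low = key_proteins(net, "x", hsip_percentile=50).unique_members
        high = key_proteins(net, "x", hsip_percentile=90).unique_members
        assert high <= low

    def test_unknown_hub_rejected(self, triangle):
        from keynet.selection import HSIPRecord
        hdps = select_hdps(triangle, 1)
        bad = (HSIPRecord(hub="NOPE", partner="A", combined_score=900),)
        with pytest.raises(ValueError):
            assemble_key_proteins("x", hdps, bad, 500)
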