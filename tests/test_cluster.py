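from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmsflow import cluster as clu
from apmsflow.cluster import Profile

from _oracles import naive_average_linkage, pearson_r


def enrich_frame(rows):
    """rows: (accession, cell_line, bait, control, ratio)"""
    return pd.DataFrame(
        [
            {
                "accession": a,
                "gene_symbol": a,
                "cell_line": cl,
                "bait_mean": b,
                "control_mean": c,
                "ratio": r,
                "specific": pd.NA,
            }
            for a, cl, b, c, r in rows
        ]
    )


class TestPearsonDistance:
    def test_identical_vectors(self):
        assert clu.pearson_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_anticorrelated(self):
        a = [1.0, 2.0, 3.0]
        b = [-x + 10 for x in a]
        assert clu.pearson_distance(a, b) == pytest.approx(2.0)

    def test_matches_covariance_oracle(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        assert clu.pearson_distance(a, b) == pytest.approx(
            1.0 - pearson_r(a, b), abs=1e-12
        )

    def test_constant_vector_distance_one(self):
        assert clu.pearson_distance([5, 5, 5], [1, 2, 3]) == 1.0
        assert clu.pearson_distance([1, 2, 3], [0, 0, 0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            clu.pearson_distance([1, 2], [1, 2, 3])

    @given(
        vec=st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        other=st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        alpha=st.floats(0.01, 50),
        beta=st.floats(-50, 50),
    )
    @settings(max_examples=60)
    def test_symmetry_and_affine_invariance(self, vec, other, alpha, beta):
        n = min(len(vec), len(other))
        a, b = vec[:n], other[:n]
        d_ab = clu.pearson_distance(a, b)
        assert clu.pearson_distance(b, a) == pytest.approx(d_ab, abs=1e-9)
        scaled = [alpha * x + beta for x in b]
        if len(set(b)) > 1 and len(set(scaled)) > 1:
            assert clu.pearson_distance(a, scaled) == pytest.approx(
                d_ab, abs=1e-6
            )


def random_profiles(rng, n_leaves, n_cols=6):
    return [
        Profile(f"P{i}", tuple(rng.normal(0, 1, n_cols)))
        for i in range(n_leaves)
    ]


class TestHclust:
    def test_identical_pair_merges_first_at_zero(self):
        profiles = [
            Profile("A", (1.0, 2.0, 3.0, 4.0)),
            Profile("B", (1.0, 2.0, 3.0, 4.0)),
            Profile("C", (4.0, 1.0, 0.0, 5.0)),
        ]
        dend = clu.hclust(profiles)
        first = dend.nodes[0]
        assert dend.member_proteins(first.node_id) == ["A", "B"]
        assert first.height == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_profiles(self):
        with pytest.raises(ValueError, match="at least 2"):
            clu.hclust([Profile("A", (1.0, 2.0))])

    def test_matches_bruteforce_oracle_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            profiles = random_profiles(rng, n)
            self.assert_matches_oracle(profiles)

    @staticmethod
    def assert_matches_oracle(profiles):
        dend = clu.hclust(profiles)
        names = sorted(p.protein for p in profiles)
        by_name = {p.protein: p.values for p in profiles}
        dist = {
            (a, b): clu.pearson_distance(by_name[a], by_name[b])
            for a, b in itertools.combinations(names, 2)
        }
        expected = naive_average_linkage(names, dist)
        got = [
            (frozenset(dend.member_proteins(nd.node_id)), nd.height)
            for nd in dend.nodes
        ]
        assert len(got) == len(expected)
        for (g_set, g_h), (e_set, e_h) in zip(got, expected):
            assert g_set == e_set
            assert g_h == pytest.approx(e_h, abs=1e-9)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        profiles = random_profiles(rng, 6)
        d1 = clu.hclust(profiles)
        d2 = clu.hclust(list(reversed(profiles)))
        assert d1.leaves == d2.leaves
        for a, b in zip(d1.nodes, d2.nodes):
            assert a.members == b.members
            assert a.height == pytest.approx(b.height, abs=1e-12)

    def test_heights_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        dend = clu.hclust(random_profiles(rng, 20))
        heights = [nd.height for nd in dend.nodes]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        assert all(0.0 <= h <= 2.0 + 1e-12 for h in heights)

    def test_newick_parses(self):
        rng = np.random.default_rng(5)
        dend = clu.hclust(random_profiles(rng, 8))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        assert all(leaf in nwk for leaf in dend.leaves)


class TestSelectClusters:
    @staticmethod
    def two_group_setup(control_high=()):
        """Two tight profile groups; optionally raise control for some."""
        rows = []
        patterns = {
            "A": (100.0, 1.0, 1.0),
            "B": (1.0, 100.0, 1.0),
        }
        lines = ["A4", "X4C0", "A4P_A5L"]
        for grp, patt in patterns.items():
            for i in range(3):
                acc = f"{grp}{i}"
                ctrl = 5.0 if acc in control_high else 0.2
                for cl, bait in zip(lines, patt):
                    rows.append(
                        (acc, cl, bait + i * 2.0, ctrl, (bait + 1) / (ctrl + 1))
                    )
        return enrich_frame(rows)

    def test_groups_recovered(self):
        enrich = self.two_group_setup()
        dend = clu.hclust(clu.build_profiles(enrich))
        sel = clu.select_clusters(dend, enrich, min_corr=0.6, control_cap=1.0)
        groups = {frozenset(c.members) for c in sel.clusters}
        assert frozenset({"A0", "A1", "A2"}) in groups
        assert frozenset({"B0", "B1", "B2"}) in groups

    def test_control_cap_excludes_members(self):
        enrich = self.two_group_setup(control_high={"A1"})
        dend = clu.hclust(clu.build_profiles(enrich))
        sel = clu.select_clusters(dend, enrich, min_corr=0.6, control_cap=1.0)
        for c in sel.clusters:
            assert "A1" not in c.members
            assert c.max_control_mean <= 1.0

    def test_threshold_inclusive(self):
        enrich = self.two_group_setup()
        dend = clu.hclust(clu.build_profiles(enrich))
        # pick an actual merge correlation and use it as min_corr: the
        # node must still be eligible at exactly its own correlation
        sel_all = clu.select_clusters(dend, enrich, min_corr=-1.0, control_cap=1e9)
        root_corr = dend.node(dend.root_id).node_correlation
        sel = clu.select_clusters(
            dend, enrich, min_corr=root_corr, control_cap=1e9
        )
        assert sel.clusters[0].node_id == dend.root_id

    def test_root_qualifies_gives_single_cluster(self):
        enrich = self.two_group_setup()
        dend = clu.hclust(clu.build_profiles(enrich))
        sel = clu.select_clusters(dend, enrich, min_corr=-1.0, control_cap=1e9)
        assert len(sel.clusters) == 1
        assert set(sel.clusters[0].members) == set(dend.leaves)

    def test_no_selected_node_is_ancestor_of_another(self):
        enrich = self.two_group_setup()
        dend = clu.hclust(clu.build_profiles(enrich))
        sel = clu.select_clusters(dend, enrich, min_corr=0.2, control_cap=1e9)
        for a, b in itertools.combinations(sel.clusters, 2):
            assert not (set(a.members) <= set(b.members))
            assert not (set(b.members) <= set(a.members))

    def test_unknown_leaf_errors(self):
        enrich = self.two_group_setup()
        dend = clu.hclust(clu.build_profiles(enrich))
        with pytest.raises(ValueError, match="absent"):
            clu.select_clusters(dend, enrich[enrich["accession"] != "A0"])


class TestFlagBackground:
    def test_control_dominated_cluster_flagged(self):
        rows = []
        lines = ["A4", "X4C0", "A4P_A5L"]
        for i in range(4):  # background: strong control, ratio < 1
            for cl in lines:
                rows.append((f"BG{i}", cl, 2.0 + i, 30.0 + i, 0.1))
        for i in range(4):  # specific: enriched, low control
            for cl in lines:
                rows.append((f"SP{i}", cl, 60.0 + i, 0.2, 50.0))
        enrich = enrich_frame(rows)
        dend = clu.hclust(clu.build_profiles(enrich))
        flagged = clu.flag_background_clusters(
            dend, enrich, ratio_threshold=1.82, control_cap=1.0
        )
        flagged_members = {
            m for node in flagged for m in dend.member_proteins(node)
        }
        assert flagged_members == {f"BG{i}" for i in range(4)}

    def test_all_specific_data_unflagged(self):
        rows = []
        for i in range(5):
            for cl in ["A4", "X4C0", "A4P_A5L"]:
                rows.append((f"SP{i}", cl, 50.0 + i, 0.1, 46.0))
        enrich = enrich_frame(rows)
        dend = clu.hclust(clu.build_profiles(enrich))
        assert clu.flag_background_clusters(
            dend, enrich, ratio_threshold=1.82, control_cap=1.0
        ) == set()
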