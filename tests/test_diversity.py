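import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ripdiv import (
    CommunityMatrix, Phylogeny, TraitTable, TraitSpace, build_trait_space,
    faith_pd, functional_richness, gower_dissimilarity, shannon_index,
    simulate_tree, species_richness,
)

from conftest import random_community


def brute_force_pd(phy: Phylogeny, species: set[str]) -> float:
    """Independent PD oracle: union of root-to-tip edge sets."""
    edges = {}
    for leaf in phy.tree.leaf_node_iter():
        if leaf.taxon.label in species:
            node = leaf
            while node.parent_node is not None:
                if node.edge.length is not None:
                    edges[id(node)] = node.edge.length
                node = node.parent_node
    return sum(edges.values())


def community_of(species_sets, all_species) -> CommunityMatrix:
    ab = pd.DataFrame(0, index=[f"s{i}" for i in range(len(species_sets))],
                      columns=list(all_species))
    for i, s in enumerate(species_sets):
        for sp in s:
            ab.iloc[i, ab.columns.get_loc(sp)] = 1
    return CommunityMatrix(ab)


class TestRichnessAndShannon:
    def test_richness_counts_positive_entries(self):
        ab = pd.DataFrame([[0, 0, 0], [2, 1, 0]], index=["s1", "s2"],
                          columns=list("abc"))
        assert species_richness(CommunityMatrix(ab)).tolist() == [0, 2]

    def test_richness_equals_brute_force_row_scan(self):
        cm = random_community(np.random.default_rng(0))
        expected = [(row > 0).sum() for _, row in cm.abundance.iterrows()]
        assert species_richness(cm).tolist() == expected

    @pytest.mark.parametrize("row,expected", [
        ([5, 0, 0], 0.0),          # single species
        ([3, 3, 0], 1.0),          # perfectly even pair: one bit
        ([2, 1, 1], 1.5),          # 0.5*1 + 2*(0.25*2)
    ])
    def test_known_shannon_values_base2(self, row, expected):
        cm = CommunityMatrix(pd.DataFrame([row], index=["s"], columns=list("abc")))
        assert shannon_index(cm).iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_shannon_bounded_by_log_richness(self):
        cm = random_community(np.random.default_rng(3))
        h = shannon_index(cm)
        s = species_richness(cm)
        assert (h <= np.log2(np.maximum(s, 1)) + 1e-9).all()

    def test_empty_site_warns_and_returns_zero(self, caplog):
        cm = CommunityMatrix(pd.DataFrame([[0, 0], [1, 2]], index=["s1", "s2"],
                                          columns=list("ab")))
        with caplog.at_level("WARNING", logger="ripdiv"):
            h = shannon_index(cm)
        assert h.iloc[0] == 0.0
        assert any("empty" in m for m in caplog.messages)


class TestGower:
    def test_identical_rows_have_zero_dissimilarity(self):
        tt = TraitTable(pd.DataFrame({"x": [1.0, 1.0], "c": ["a", "a"]},
                                     index=["A", "B"]),
                        {"x": "continuous", "c": "categorical"})
        assert gower_dissimilarity(tt).loc["A", "B"] == 0.0

    def test_range_extremes_give_one(self):
        tt = TraitTable(pd.DataFrame({"x": [0.0, 10.0]}, index=["A", "B"]),
                        {"x": "continuous"})
        assert gower_dissimilarity(tt).loc["A", "B"] == 1.0

    def test_hand_computed_mixed_matrix(self):
        # continuous 0,1,2 (range 2) and categories x,x,y; averages by hand
        tt = TraitTable(pd.DataFrame({"v": [0.0, 1.0, 2.0],
                                      "c": ["x", "x", "y"]},
                                     index=["A", "B", "C"]),
                        {"v": "continuous", "c": "categorical"})
        D = gower_dissimilarity(tt)
        assert D.loc["A", "B"] == pytest.approx(0.25)
        assert D.loc["A", "C"] == pytest.approx(1.0)
        assert D.loc["B", "C"] == pytest.approx(0.75)

    def test_zero_range_trait_contributes_zero_with_warning(self, caplog):
        tt = TraitTable(pd.DataFrame({"flat": [1.0, 1.0], "x": [0.0, 2.0]},
                                     index=["A", "B"]),
                        {"flat": "continuous", "x": "continuous"})
        with caplog.at_level("WARNING", logger="ripdiv"):
            D = gower_dissimilarity(tt)
        assert D.loc["A", "B"] == pytest.approx(0.5)
        assert any("zero range" in m for m in caplog.messages)

    def test_values_in_unit_interval_and_symmetric(self, synth_dataset):
        D = gower_dissimilarity(synth_dataset.traits).to_numpy()
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestTraitSpace:
    def test_three_equidistant_points_embed_as_equilateral(self):
        D = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("ABC"),
                         columns=list("ABC"))
        space = build_trait_space(D)
        d = pdist(space.coordinates.to_numpy()[:, :2])
        assert np.allclose(d, d[0], atol=1e-9)

    def test_euclidean_input_round_trips(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        D = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(8)])
        space = build_trait_space(D)
        assert space.correction == "none"
        emb = pdist(space.coordinates.to_numpy())
        assert np.allclose(emb, pdist(pts), atol=1e-8)

    def test_agrees_with_skbio_pcoa_on_euclidean_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        names = [f"s{i}" for i in range(10)]
        D = pd.DataFrame(squareform(pdist(pts)), index=names, columns=names)
        ours = build_trait_space(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.to_numpy(), ids=names))
        assert np.allclose(ours.eigenvalues[:3],
                           theirs.eigvals.to_numpy()[:3], atol=1e-8)

    def test_m_max_truncates_axes(self):
        D = pd.DataFrame(0.5 * (1 - np.eye(4)), index=list("ABCD"),
                         columns=list("ABCD"))
        space = build_trait_space(D, m_max=1)
        assert space.m == 1
        assert space.coordinates.shape == (4, 1)

    def test_gower_matrix_gets_corrected_when_needed(self, synth_dataset):
        D = gower_dissimilarity(synth_dataset.traits)
        space = build_trait_space(D)
        assert space.correction in ("none", "lingoes")
        assert np.isfinite(space.coordinates.to_numpy()).all()


class TestFunctionalRichness:
    def make_space(self, coords, names):
        df = pd.DataFrame(coords, index=names,
                          columns=[f"PCo{i+1}" for i in range(coords.shape[1])])
        return TraitSpace(df, np.ones(coords.shape[1]), "none", coords.shape[1])

    def test_whole_pool_has_unit_fraction(self):
        space = self.make_space(np.array([[0., 0.], [1., 0.], [0., 1.]]),
                                list("ABC"))
        cm = community_of([{"A", "B", "C"}], list("ABC"))
        out = functional_richness(cm, space, m=2)
        assert out["FRic"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert out["FRic_raw"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_three_square_corners_cover_half(self):
        space = self.make_space(np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]]),
                                list("ABCD"))
        cm = community_of([{"A", "B", "C"}], list("ABCD"))
        out = functional_richness(cm, space, m=2)
        assert out["FRic"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_two_species_cannot_form_a_2d_hull(self):
        space = self.make_space(np.array([[0., 0.], [1., 0.], [0., 1.]]),
                                list("ABC"))
        cm = community_of([{"A", "B"}], list("ABC"))
        out = functional_richness(cm, space, m=2)
        assert np.isnan(out["FRic"].iloc[0])

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(4)
        names = [f"sp{i}" for i in range(10)]
        space = self.make_space(rng.normal(size=(10, 2)), names)
        for _ in range(25):
            small = set(rng.choice(names, size=4, replace=False))
            big = small | set(rng.choice(names, size=3, replace=False))
            cm = community_of([small, big], names)
            out = functional_richness(cm, space, m=2)["FRic"]
            if np.isfinite(out.iloc[0]) and np.isfinite(out.iloc[1]):
                assert out.iloc[1] >= out.iloc[0] - 1e-12


class TestFaithPD:
    def test_cherry_plus_outgroup_values(self, toy_tree):
        cm = community_of([{"A", "B"}, {"A", "B", "C"}, {"C"}], list("ABC"))
        pd_vals = faith_pd(cm, toy_tree)
        assert pd_vals.tolist() == pytest.approx([3.0, 5.0, 2.0])

    def test_root_exclusion_drops_the_stem(self, toy_tree):
        cm = community_of([{"A", "B"}], list("ABC"))
        assert faith_pd(cm, toy_tree, include_root=False).iloc[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_edge_union(self, seed):
        rng = np.random.default_rng(seed)
        phy = simulate_tree(8, seed=seed)
        tips = phy.tip_labels
        sets = [set(rng.choice(tips, size=rng.integers(1, 9), replace=False))
                for _ in range(6)]
        cm = community_of(sets, tips)
        got = faith_pd(cm, phy)
        for i, s in enumerate(sets):
            assert got.iloc[i] == pytest.approx(brute_force_pd(phy, s), abs=1e-12)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(9)
        phy = simulate_tree(12, seed=9)
        tips = phy.tip_labels
        small = set(rng.choice(tips, 4, replace=False))
        big = small | set(rng.choice(tips, 4, replace=False))
        cm = community_of([small, big], tips)
        vals = faith_pd(cm, phy)
        assert vals.iloc[1] >= vals.iloc[0] - 1e-12

    def test_species_not_on_tree_rejected(self, toy_tree):
        cm = community_of([{"A", "Z"}], ["A", "Z"])
        with pytest.raises(ValueError, match="not on the tree"):
            faith_pd(cm, toy_tree)


def test_raw_fd_and_pd_track_richness(synth_dataset):
    """Raw FRic and PD correlate positively with S on synthetic data."""
    from scipy.stats import pearsonr
    from ripdiv import diversity_profile
    prof = diversity_profile(synth_dataset.community, synth_dataset.traits,
                             synth_dataset.phylogeny)
    s = prof["S"]
    for col in ("FRic", "PD"):
        ok = prof[col].notna()
        r, p = pearsonr(s[ok], prof.loc[ok, col])
        assert r > 0.3 and p < 0.01
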