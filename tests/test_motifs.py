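"""Motif comparison, BBH merging, known-motif annotation, profile clustering."""

import numpy as np
import pandas as pd
import pytest

from epimotif.motifs import (bbh_graph, compare_motifs, connected_components,
                             match_known, merge_cluster_pwm, merge_motifs,
                             model_profile_clustering, sharing_summary)
from epimotif.pwm import PwmMotif

from conftest import sharp_pwm


def random_pwm(rng, width, name):
    return PwmMotif(rng.dirichlet(np.ones(4) * 0.5, size=width), name=name,
                    n_sites=30)


class TestCompareMotifs:
    def test_self_match_is_perfect(self):
        m = sharp_pwm("ACGTTGCAGT", name="m")
        match = compare_motifs(m, m, n_permutations=500)
        assert match.score == pytest.approx(1.0)
        assert match.offset == 0 and match.orientation == "+"
        assert match.p_value <= 2 / 501

    def test_reverse_complement_same_score_opposite_orientation(self):
        m = sharp_pwm("ACGTTGCAGT", name="m")
        rc = m.reverse_complement()
        fwd = compare_motifs(m, m, n_permutations=100)
        rev = compare_motifs(m, rc, n_permutations=100)
        assert rev.score == pytest.approx(fwd.score)
        assert rev.orientation == "-"

    def test_width_below_min_overlap_rejected(self):
        small = sharp_pwm("ACGTT")
        with pytest.raises(ValueError):
            compare_motifs(small, sharp_pwm("ACGTACGT"))

    def test_best_offset_matches_exhaustive_enumeration(self, rng):
        """Brute-force every offset/orientation with plain-python Pearson."""
        for _ in range(20):
            q = random_pwm(rng, 8, "q")
            t = random_pwm(rng, 9, "t")
            got = compare_motifs(q, t, min_overlap=7, n_permutations=0)

            def col_corr(a, b):
                a = a - a.mean(); b = b - b.mean()
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                return 0.0 if na < 1e-12 or nb < 1e-12 else float(a @ b / (na * nb))

            best = (-np.inf, None, None)
            for orient, tm in [("+", t.freq_matrix),
                               ("-", t.reverse_complement().freq_matrix)]:
                for off in range(-(9 - 7), 8 - 7 + 1):
                    cols = [(i, i - off) for i in range(8) if 0 <= i - off < 9]
                    if len(cols) < 7:
                        continue
                    score = np.mean([col_corr(q.freq_matrix[i], tm[j])
                                     for i, j in cols])
                    if score > best[0]:
                        best = (score, off, orient)
            assert got.score == pytest.approx(best[0], abs=1e-12)
            assert (got.offset, got.orientation) == (best[1], best[2])

    def test_symmetric_best_score(self, rng):
        a, b = random_pwm(rng, 10, "a"), random_pwm(rng, 10, "b")
        ab = compare_motifs(a, b, n_permutations=0)
        ba = compare_motifs(b, a, n_permutations=0)
        assert ab.score == pytest.approx(ba.score, abs=1e-12)

    def test_permutation_p_deterministic_under_seed(self, rng):
        a, b = random_pwm(rng, 9, "a"), random_pwm(rng, 9, "b")
        p1 = compare_motifs(a, b, n_permutations=300, seed=5).p_value
        p2 = compare_motifs(a, b, n_permutations=300, seed=5).p_value
        assert p1 == p2


class TestBBHGraph:
    def test_duplicated_pair_one_edge(self, rng):
        dup = sharp_pwm("ACGTTGCAGTAC", name="dup1")
        dup2 = PwmMotif(dup.freq_matrix.copy(), name="dup2", n_sites=30)
        others = [random_pwm(rng, 10, f"r{i}") for i in range(3)]
        edges = bbh_graph([dup, dup2] + others, n_permutations=300)
        assert ("dup1", "dup2") in edges

    def test_dissimilar_random_motifs_no_edges(self, rng):
        motifs = [random_pwm(rng, 12, f"r{i}") for i in range(5)]
        edges = bbh_graph(motifs, n_permutations=300)
        assert edges == []

    def test_best_hit_asymmetry_blocks_edge(self):
        """a's best hit is b, but b's best hit is its duplicate c: no a-b edge."""
        b = sharp_pwm("ACGTTGCAGTCC", name="b")
        c = PwmMotif(b.freq_matrix.copy(), name="c", n_sites=30)
        # a shares a weak half-site with b only
        a = sharp_pwm("ACGTTGAAAAAA", name="a")
        edges = bbh_graph([a, b, c], n_permutations=300)
        assert ("b", "c") in edges
        assert not any("a" in e for e in edges)

    def test_fewer_than_two_motifs_error(self):
        with pytest.raises(ValueError):
            bbh_graph([sharp_pwm("ACGTACGTAA")])


class TestConnectedComponents:
    def _motifs(self, rng, n):
        return [random_pwm(rng, 8, f"m{i}") for i in range(n)]

    def test_no_edges_all_singletons(self, rng):
        motifs = self._motifs(rng, 4)
        clusters = connected_components([], motifs)
        assert all(c.is_singleton for c in clusters)
        assert sorted(m for c in clusters for m in c.members) == \
               [m.name for m in motifs]

    def test_triangle_single_cluster(self, rng):
        motifs = self._motifs(rng, 3)
        edges = [("m0", "m1"), ("m1", "m2"), ("m0", "m2")]
        clusters = connected_components(edges, motifs)
        assert len(clusters) == 1 and not clusters[0].is_singleton

    def test_random_graphs_match_dfs_oracle(self, rng):
        """Partition equals a hand-rolled depth-first-search on 100 graphs."""
        for _ in range(100):
            n = int(rng.integers(2, 10))
            motifs = self._motifs(rng, n)
            names = [m.name for m in motifs]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        edges.append((names[i], names[j]))
            clusters = connected_components(edges, motifs)
            # DFS oracle
            adj = {name: set() for name in names}
            for a, b in edges:
                adj[a].add(b); adj[b].add(a)
            seen, comps = set(), []
            for name in names:
                if name in seen:
                    continue
                stack, comp = [name], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(adj[u] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            assert {frozenset(c.members) for c in clusters} == set(comps)

    def test_partition_property(self, rng):
        motifs = self._motifs(rng, 6)
        clusters = connected_components([("m0", "m1")], motifs)
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(m.name for m in motifs)


class TestMergeClusterPwm:
    def test_singleton_unchanged(self):
        m = sharp_pwm("ACGTACGTAA", name="solo")
        merged = merge_cluster_pwm([m])
        assert np.allclose(merged.freq_matrix, m.freq_matrix)

    def test_identical_members_same_pwm(self):
        m1 = sharp_pwm("ACGTTGCAGT", name="a")
        m2 = PwmMotif(m1.freq_matrix.copy(), name="b", n_sites=50)
        merged = merge_cluster_pwm([m1, m2])
        assert merged.width == m1.width
        assert np.allclose(merged.freq_matrix, m1.freq_matrix, atol=0.02)

    def test_shifted_copies_cover_union(self):
        """A 2-column shift of the same motif widens the merged PWM by 2."""
        base = sharp_pwm("ACGTTGCAGT", name="base", p=0.97)
        shifted = PwmMotif(np.vstack([base.freq_matrix[2:],
                                      [[0.97, 0.01, 0.01, 0.01]] * 2]),
                           name="shift", n_sites=50)
        merged = merge_cluster_pwm([base, shifted])
        assert merged.width == base.width + 2

    def test_empty_cluster_error(self):
        with pytest.raises(ValueError):
            merge_cluster_pwm([])


class TestMatchKnown:
    def test_db_containing_motif_matched(self, rng):
        m = sharp_pwm("ACGTTGCAGTCA", name="query")
        db = [PwmMotif(m.freq_matrix.copy(), name="known", n_sites=10)] + \
             [random_pwm(rng, 10, f"k{i}") for i in range(3)]
        tab = match_known([m], db, n_permutations=300)
        assert not tab["novel"].iloc[0]
        assert tab["match"].iloc[0] == "known"

    def test_empty_db_all_novel(self):
        tab = match_known([sharp_pwm("ACGTACGTAA", name="q")], [])
        assert tab["novel"].all()

    def test_dissimilar_db_novel(self, rng):
        q = sharp_pwm("ACGTTGCAGTCA", name="q")
        db = [random_pwm(rng, 10, f"k{i}") for i in range(4)]
        tab = match_known([q], db, e_threshold=0.05, n_permutations=300)
        assert tab["novel"].iloc[0]


class TestProfileClustering:
    def test_identical_profiles_distance_zero_merge_first(self):
        presence = pd.DataFrame(
            [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 1, 1]],
            index=["A", "B", "C", "D"])
        linkage, newick = model_profile_clustering(presence)
        assert linkage[0, 2] == 0.0          # A and B merge at height 0
        assert set(map(int, linkage[0, :2])) == {0, 1}
        assert newick.endswith(";") and "A" in newick and "D" in newick

    def test_complementary_profiles_maximal_distance(self):
        presence = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"])
        linkage, _ = model_profile_clustering(presence)
        assert linkage[0, 2] == pytest.approx(1.0)

    def test_four_leaf_tree_matches_hand_computed_upgma(self):
        """Hamming distances chosen so UPGMA heights are hand-checkable."""
        presence = pd.DataFrame(
            [[1, 1, 1, 1, 0, 0, 0, 0],
             [1, 1, 1, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 1, 1, 1, 1],
             [0, 0, 0, 1, 1, 1, 1, 0]],
            index=["w", "x", "y", "z"])
        # d(w,x)=1/8, d(y,z)=2/8, d(w,y)=8/8, d(w,z)=6/8, d(x,y)=7/8, d(x,z)=7/8
        linkage, _ = model_profile_clustering(presence)
        assert linkage[0, 2] == pytest.approx(1 / 8)    # w-x first
        assert linkage[1, 2] == pytest.approx(2 / 8)    # then y-z
        # final merge at mean of the four cross distances
        assert linkage[2, 2] == pytest.approx((8 + 6 + 7 + 7) / 4 / 8)

    def test_heights_nondecreasing(self, rng):
        presence = pd.DataFrame((rng.random((6, 20)) < 0.5).astype(int))
        linkage, _ = model_profile_clustering(presence)
        assert np.all(np.diff(linkage[:, 2]) >= -1e-12)

    def test_single_model_error(self):
        with pytest.raises(ValueError):
            model_profile_clustering(pd.DataFrame([[1, 0]], index=["A"]))


class TestSharingSummary:
    def _clusters(self, groups):
        from epimotif.motifs import MotifCluster
        return [MotifCluster(list(g), sharp_pwm("ACGTACGTAA"), len(g) == 1)
                for g in groups]

    def test_disjoint_models_all_shared_by_one(self):
        clusters = self._clusters([["a1"], ["a2"], ["b1"]])
        owner = {"a1": "A", "a2": "A", "b1": "B"}
        tab = sharing_summary(clusters, owner)
        assert tab.set_index("n_models").loc[1, "n_motifs"] == 3

    def test_motif_in_all_models(self):
        clusters = self._clusters([["a1", "b1", "c1"]])
        owner = {"a1": "A", "b1": "B", "c1": "C"}
        tab = sharing_summary(clusters, owner)
        assert tab.set_index("n_models").loc[3, "n_motifs"] == 1

    def test_fuzz_against_set_algebra(self, rng):
        for _ in range(50):
            models = ["A", "B", "C"]
            owner, groups, idx = {}, [], 0
            for _ in range(int(rng.integers(1, 6))):
                size = int(rng.integers(1, 4))
                group = []
                for _ in range(size):
                    name = f"m{idx}"; idx += 1
                    owner[name] = models[int(rng.integers(0, 3))]
                    group.append(name)
                groups.append(group)
            tab = sharing_summary(self._clusters(groups), owner).set_index("n_models")
            for k in range(1, 4):
                expect = sum(1 for g in groups
                             if len({owner[m] for m in g}) == k)
                got = tab["n_motifs"].get(k, 0)
                assert got == expect
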