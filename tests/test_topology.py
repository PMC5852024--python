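"""Connectivity, TOM, module detection, eigen-diseases and hubs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import comorbnet as cn
from comorbnet.network import AdjacencyMatrix, build_adjacency, similarity_matrix
from comorbnet.records import DiagnosisRecord, build_yearly_occurrence
from comorbnet.topology import (
    GREY,
    ModulePartition,
    cluster_eigen_diseases,
    compute_eigen_diseases,
    connectivity,
    connectivity_table,
    detect_modules,
    eigen_disease,
    identify_hubs,
    intramodular_connectivity,
    tom,
    tom_connectivity,
)


def adjacency_from(A, tau=0.01):
    A = np.asarray(A, dtype=float)
    return AdjacencyMatrix([f"d{i}" for i in range(len(A))], A, tau, 2000)


def tom_brute_force(A):
    """Triple-loop oracle for the topological overlap matrix."""
    n = len(A)
    K = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(K[i], K[j]) + 1 - A[i, j])
    return T


class TestConnectivity:
    def test_zero_matrix(self):
        K = connectivity(adjacency_from(np.zeros((4, 4))))
        assert (K == 0).all()

    def test_three_node_path(self):
        A = np.array([[0, 0.2, 0], [0.2, 0, 0.5], [0, 0.5, 0]])
        K = connectivity(adjacency_from(A))
        assert list(K) == pytest.approx([0.2, 0.7, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        A = rng.uniform(0, 1, (n, n))
        A = np.triu(A, 1) + np.triu(A, 1).T
        K = connectivity(adjacency_from(A))
        brute = [sum(A[i, j] for j in range(n) if j != i) for i in range(n)]
        assert np.allclose(K, brute, atol=1e-12)


class TestTOM:
    def test_no_edge_no_shared_neighbours(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.5
        T = tom(adjacency_from(A))
        assert T.TOM[0, 2] == 0.0

    def test_two_node_closed_form(self):
        # two nodes joined only to each other: TOM = w / (w + 1 - w) = w
        for w in (0.1, 0.5, 0.9):
            A = np.array([[0, w], [w, 0]])
            T = tom(adjacency_from(A))
            assert T.TOM[0, 1] == pytest.approx(w)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_and_bounded(self, seed):
        """Vectorised TOM equals the triple loop; entries stay in [0, 1]."""
        rng = np.random.default_rng(seed)
        n = 10
        A = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.5)
        A = np.triu(A, 1) + np.triu(A, 1).T
        T = tom(adjacency_from(A)).TOM
        assert np.allclose(T, tom_brute_force(A), atol=1e-12)
        assert (T >= -1e-12).all() and (T <= 1 + 1e-12).all()
        assert np.allclose(T, T.T)

    def test_diss_tom_diagonal_zero(self, planted_occurrence):
        adj = build_adjacency(similarity_matrix(planted_occurrence), 0.03)
        T = tom(adj)
        assert np.allclose(np.diag(T.dissTOM), 0)

    def test_single_edge_tom_connectivity(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.4
        T = tom(adjacency_from(A))
        k = tom_connectivity(T)
        assert k["d0"] == pytest.approx(T.TOM[0, 1])
        assert k["d1"] == pytest.approx(T.TOM[0, 1])

    def test_k_and_big_k_highly_rank_correlated(self, planted_occurrence):
        """Weighted (TOM) and unweighted connectivity rank diseases alike."""
        from scipy.stats import spearmanr

        adj = build_adjacency(similarity_matrix(planted_occurrence), 0.03)
        K = connectivity(adj)
        k = tom_connectivity(tom(adj))
        rho = spearmanr(K, k).statistic
        assert rho > 0.8


class TestDetectModules:
    def test_two_separated_cliques(self):
        n = 24
        A = np.zeros((n, n))
        A[:12, :12] = 0.6
        A[12:, 12:] = 0.6
        np.fill_diagonal(A, 0)
        part = detect_modules(tom(adjacency_from(A)), min_module_size=10)
        assert part.n_modules() == 2
        assert (part.labels != GREY).all()
        # each clique is one module
        assert len(set(part.labels.iloc[:12])) == 1
        assert len(set(part.labels.iloc[12:])) == 1

    def test_colour_names_follow_size_order(self, planted_occurrence):
        sim = similarity_matrix(planted_occurrence)
        adj = build_adjacency(sim, 0.03)
        part = detect_modules(
            tom(adj), min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        sizes = part.sizes().drop(GREY, errors="ignore")
        assert list(sizes.index) == ["turquoise", "blue", "brown"][: len(sizes)]
        assert sizes.is_monotonic_decreasing

    def test_planted_modules_recovered(self, planted_registry, planted_occurrence):
        from sklearn.metrics import adjusted_rand_score

        sim = similarity_matrix(planted_occurrence)
        adj = build_adjacency(sim, 0.03)
        part = detect_modules(
            tom(adj), min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        truth = planted_registry.truth[2000].reindex(part.labels.index)
        assert adjusted_rand_score(truth, part.labels) >= 0.9

    def test_independence_mostly_grey(self):
        reg = cn.generate(cn.independence_spec(0))
        occ = cn.build_yearly_occurrence(reg.records, 2000)
        sim = similarity_matrix(occ)
        adj = build_adjacency(sim, 0.03)
        part = detect_modules(
            tom(adj), min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        assert (part.labels == GREY).mean() >= 0.9


class TestEigenDisease:
    def test_identical_columns_perfectly_correlated(self):
        recs = []
        for p in range(20):
            if p % 2:
                recs += [
                    DiagnosisRecord(f"p{p:02d}", 2000, "A", "outpatient"),
                    DiagnosisRecord(f"p{p:02d}", 2000, "B", "outpatient"),
                ]
            else:
                recs.append(DiagnosisRecord(f"p{p:02d}", 2000, "C", "outpatient"))
        occ = build_yearly_occurrence(recs, 2000)
        eig = eigen_disease(occ, ["A", "B"])
        col = occ.incidence[:, occ.diseases.index("A")].astype(float)
        r = np.corrcoef(eig.scores, col)[0, 1]
        assert r == pytest.approx(1.0)

    def test_pc1_explains_most_variance(self, planted_registry, planted_occurrence):
        members = list(
            planted_registry.truth[2000].index[planted_registry.truth[2000] == "M1"]
        )
        eig = eigen_disease(planted_occurrence, members)
        assert eig.explained_variance_ratio[0] >= eig.explained_variance_ratio[1]

    def test_orientation_positive_mean_correlation(self, planted_registry, planted_occurrence):
        members = list(
            planted_registry.truth[2000].index[planted_registry.truth[2000] == "M2"]
        )
        eig = eigen_disease(planted_occurrence, members)
        idx = [planted_occurrence.diseases.index(m) for m in members]
        corrs = [
            np.corrcoef(eig.scores, planted_occurrence.incidence[:, i].astype(float))[0, 1]
            for i in idx
        ]
        assert np.mean(corrs) > 0

    def test_own_module_correlation_beats_other(self, planted_registry, planted_occurrence):
        truth = planted_registry.truth[2000]
        m1 = list(truth.index[truth == "M1"])
        m2 = list(truth.index[truth == "M2"])
        eig = eigen_disease(planted_occurrence, m1)

        def mean_corr(members):
            idx = [planted_occurrence.diseases.index(m) for m in members]
            return np.mean(
                [
                    np.corrcoef(eig.scores, planted_occurrence.incidence[:, i].astype(float))[0, 1]
                    for i in idx
                ]
            )

        assert mean_corr(m1) > mean_corr(m2)

    def test_fewer_than_two_members_rejected(self, planted_occurrence):
        with pytest.raises(ValueError, match="two member"):
            eigen_disease(planted_occurrence, ["100"])


class TestHubsAndIntramodular:
    def test_full_tie_breaks_lexicographically(self):
        recs = []
        for p in range(10):
            if p < 5:
                for c in ("B", "A", "C"):
                    recs.append(DiagnosisRecord(f"p{p}", 2000, c, "outpatient"))
            else:
                recs.append(DiagnosisRecord(f"p{p}", 2000, "Z", "outpatient"))
        occ = build_yearly_occurrence(recs, 2000)
        part = ModulePartition(
            labels=pd.Series(["blue", "blue", "blue", GREY], index=["A", "B", "C", "Z"])
        )
        hubs = identify_hubs(part, occ)
        assert hubs["blue"] == "A"

    def test_single_member_module_is_its_own_hub(self, planted_occurrence):
        part = ModulePartition(
            labels=pd.Series(
                ["blue"] + [GREY] * (len(planted_occurrence.diseases) - 1),
                index=planted_occurrence.diseases,
            )
        )
        assert identify_hubs(part, planted_occurrence)["blue"] == planted_occurrence.diseases[0]

    def test_hub_belongs_to_its_module(self, planted_occurrence):
        sim = similarity_matrix(planted_occurrence)
        adj = build_adjacency(sim, 0.03)
        part = detect_modules(
            tom(adj), min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        hubs = identify_hubs(part, planted_occurrence, adj=adj)
        for colour, hub in hubs.items():
            assert part.labels[hub] == colour

    def test_all_one_module_equals_K(self):
        rng = np.random.default_rng(3)
        n = 8
        A = rng.uniform(0, 1, (n, n))
        A = np.triu(A, 1) + np.triu(A, 1).T
        adj = adjacency_from(A)
        part = ModulePartition(labels=pd.Series(["blue"] * n, index=adj.diseases))
        intra = intramodular_connectivity(adj, part)
        assert np.allclose(intra, connectivity(adj))

    def test_grey_gets_missing_value(self):
        A = np.zeros((3, 3))
        adj = adjacency_from(A)
        part = ModulePartition(labels=pd.Series(["blue", "blue", GREY], index=adj.diseases))
        intra = intramodular_connectivity(adj, part)
        assert np.isnan(intra["d2"])
        assert intra["d0"] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        A = rng.uniform(0, 1, (n, n))
        A = np.triu(A, 1) + np.triu(A, 1).T
        adj = adjacency_from(A)
        labels = pd.Series(rng.choice(["blue", "red", GREY], n), index=adj.diseases)
        part = ModulePartition(labels=labels)
        intra = intramodular_connectivity(adj, part)
        for i, d in enumerate(adj.diseases):
            if labels[d] == GREY:
                assert np.isnan(intra[d])
            else:
                brute = sum(
                    A[i, j]
                    for j, e in enumerate(adj.diseases)
                    if j != i and labels[e] == labels[d]
                )
                assert intra[d] == pytest.approx(brute, abs=1e-12)
        # intramodular connectivity never exceeds whole-network connectivity
        K = connectivity(adj)
        mask = labels != GREY
        assert (intra[mask] <= K[mask] + 1e-12).all()


class TestEigenDendrogram:
    def _partition(self, occ, sim):
        adj = build_adjacency(sim, 0.03)
        part = detect_modules(
            tom(adj), min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        part.eigen = compute_eigen_diseases(part, occ)
        return part

    def test_two_modules_single_merge(self, planted_occurrence):
        sim = similarity_matrix(planted_occurrence)
        part = self._partition(planted_occurrence, sim)
        two = {c: part.eigen[c] for c in list(part.eigen)[:2]}
        dend = cluster_eigen_diseases(two)
        assert dend.linkage.shape == (1, 4)

    def test_identical_eigen_scores_merge_at_zero(self, planted_occurrence):
        from comorbnet.topology import EigenDisease

        s = np.sin(np.arange(planted_occurrence.N, dtype=float))
        eig = {c: EigenDisease(s.copy(), np.array([1.0])) for c in ("a", "b")}
        dend = cluster_eigen_diseases(eig)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_newick_has_all_module_labels(self, planted_occurrence):
        sim = similarity_matrix(planted_occurrence)
        part = self._partition(planted_occurrence, sim)
        nwk = cluster_eigen_diseases(part.eigen).to_newick()
        for colour in part.eigen:
            assert colour in nwk

    def test_shared_factor_modules_merge_first(self):
        """Two modules driven by one latent factor join before the third."""
        rng = np.random.default_rng(42)
        n_pat = 1000
        f1 = rng.random(n_pat) < 0.3
        f2 = rng.random(n_pat) < 0.3
        recs = []
        for m, (factor, codes) in enumerate(
            [(f1, ["a1", "a2", "a3"]), (f1, ["b1", "b2", "b3"]), (f2, ["c1", "c2", "c3"])]
        ):
            prob = np.where(factor, 0.5, 0.05)
            for c in codes:
                hit = rng.random(n_pat) < prob
                recs += [
                    DiagnosisRecord(f"p{i:04d}", 2000, c, "outpatient")
                    for i in np.nonzero(hit)[0]
                ]
        occ = build_yearly_occurrence(recs, 2000)
        eig = {
            name: eigen_disease(occ, codes)
            for name, codes in [("A", ["a1", "a2", "a3"]), ("B", ["b1", "b2", "b3"]), ("C", ["c1", "c2", "c3"])]
        }
        dend = cluster_eigen_diseases(eig)
        first = dend.linkage[0, :2].astype(int)
        assert set(first) == {dend.colours.index("A"), dend.colours.index("B")}


class TestConnectivityTable:
    def test_columns_and_hub_flags(self, planted_occurrence):
        sim = similarity_matrix(planted_occurrence)
        adj = build_adjacency(sim, 0.03)
        T = tom(adj)
        part = detect_modules(
            T, min_module_size=10, similarity=np.nan_to_num(sim.S, nan=0.0)
        )
        identify_hubs(part, planted_occurrence, adj=adj)
        table = connectivity_table(adj, T, part)
        assert {"module", "K", "k", "intramodular_K", "membership", "is_hub"} <= set(table.columns)
        assert table["is_hub"].sum() == part.n_modules()
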