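"""Subgraph construction, secondary structure, RSA, centrality, features."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from funcphos.graphs import (
    GraphConfig,
    LAYOUT,
    SS8_ALPHABET,
    assign_secondary_structure,
    build_site_subgraph,
    collapse_ss3,
    compute_rsa,
    contact_graph_adjacency,
    eigenvector_centrality,
    featurize_nodes,
)

from conftest import ideal_helix, make_protein, random_protein, straight_chain


# ---------------------------------------------------------------------------
# subgraph membership and edges
# ---------------------------------------------------------------------------

def test_knn_includes_residues_beyond_radius():
    # two residues 10 A apart: the neighbour exceeds the 8 A radius but is
    # pulled in as a nearest neighbour of the modification site
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    graph = build_site_subgraph(make_protein(coords, "SA"), 1)
    assert graph.node_ids.tolist() == [0, 1]
    assert ((0, 1) in graph.edges) and graph.edges[(0, 1)] == "knn"


def test_straight_chain_membership_matches_brute_force():
    protein = make_protein(straight_chain(11), "A" * 5 + "S" + "A" * 5)
    graph = build_site_subgraph(protein, 6)
    # radius rule admits indices 4..7 (3.8 and 7.6 A); kNN adds nothing new
    d = cdist(protein.ca_coords, protein.ca_coords[[5]]).ravel()
    expected = set(np.flatnonzero(d < 8.0)) | {5}
    knn = np.argsort(d, kind="stable")
    knn = [i for i in knn if i != 5][:3]
    expected |= set(knn)
    assert set(graph.node_ids) == expected
    assert set(graph.node_ids) == {3, 4, 5, 6, 7}


def test_multi_rule_pairs_carry_exactly_one_edge():
    protein = make_protein(straight_chain(5), "AASAA")
    graph = build_site_subgraph(protein, 3)
    # sequence-adjacent pairs are also within 8 A: one edge each, tagged by
    # the highest-priority rule that admitted it
    keys = list(graph.edges)
    assert len(keys) == len(set(keys))
    adj = graph.adjacency()
    assert np.array_equal(adj, adj.T)
    assert np.all(np.diag(adj) == 0)


def test_out_of_range_site_and_singleton():
    protein = make_protein(straight_chain(3), "ASA")
    with pytest.raises(IndexError):
        build_site_subgraph(protein, 4)
    single = make_protein(np.zeros((1, 3)), "S")
    graph = build_site_subgraph(single, 1)
    assert graph.n_nodes == 1 and graph.edges == {}


def test_membership_matches_brute_force_on_random_proteins():
    """Node sets equal an all-pairs distance oracle on random structures."""
    rng = np.random.default_rng(7)
    config = GraphConfig()
    for trial in range(100):
        n = int(rng.integers(2, 51))
        protein = random_protein(rng, n)
        site = int(rng.integers(1, n + 1))
        graph = build_site_subgraph(protein, site, config)
        d = np.linalg.norm(protein.ca_coords - protein.ca_coords[site - 1], axis=1)
        expected = set(np.flatnonzero(d < config.radius)) | {site - 1}
        order = [i for i in np.argsort(d, kind="stable") if i != site - 1]
        expected |= set(order[: config.knn_k])
        assert set(graph.node_ids) == expected
        # edge oracle: distance pair, peptide-adjacent pair, or center-kNN pair
        coords = protein.ca_coords[graph.node_ids]
        pair = cdist(coords, coords)
        knn_set = set(order[: config.knn_k])
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                ri, rj = int(graph.node_ids[i]), int(graph.node_ids[j])
                expected_edge = (
                    pair[i, j] < config.radius
                    or abs(ri - rj) == 1
                    or (ri == site - 1 and rj in knn_set)
                    or (rj == site - 1 and ri in knn_set)
                )
                assert ((i, j) in graph.edges) == expected_edge


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def test_ideal_helix_classified_helical():
    protein = make_protein(ideal_helix(15))
    ss = assign_secondary_structure(protein)
    assert np.all(ss[2:-2] == "H")


def test_extended_chain_never_helical():
    protein = make_protein(straight_chain(15))
    ss = assign_secondary_structure(protein)
    assert not np.any(ss == "H")


def test_short_chain_all_coil():
    assert assign_secondary_structure(make_protein(straight_chain(3))).tolist() == [
        "C", "C", "C"
    ]


def test_collapse_ss3():
    assert collapse_ss3(np.array(["H", "G", "E", "B", "T", "C"])).tolist() == [
        "H", "H", "E", "E", "C", "C"
    ]


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

def test_isolated_residue_fully_exposed():
    protein = make_protein(np.zeros((1, 3)), "A")
    assert compute_rsa(protein)[0] == 1.0


def test_buried_residue_in_dense_cluster():
    # 30 residues packed within 6 A of the central one
    rng = np.random.default_rng(1)
    shell = rng.standard_normal((30, 3))
    shell = 4.5 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
    coords = np.vstack([[0.0, 0, 0], shell])
    protein = make_protein(coords, "A" * 31)
    rsa = compute_rsa(protein, n_points=1000)
    assert rsa[0] < 0.2


def test_rsa_clipped_to_unit_interval(small_dataset):
    proteins, _, _ = small_dataset
    rsa = compute_rsa(proteins[0])
    assert rsa.min() >= 0.0 and rsa.max() <= 1.0


# ---------------------------------------------------------------------------
# eigenvector centrality
# ---------------------------------------------------------------------------

def _dense_oracle(a: np.ndarray) -> np.ndarray:
    """Principal eigenvector per connected component by full decomposition."""
    from scipy.sparse.csgraph import connected_components

    n = a.shape[0]
    _, labels = connected_components(a > 0, directed=False)
    out = np.zeros(n)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = a[np.ix_(idx, idx)]
        if sub.sum() == 0:
            out[idx] = 1.0 / np.sqrt(len(idx))
            continue
        w, v = np.linalg.eigh(sub)
        vec = v[:, np.argmax(w)]
        out[idx] = np.abs(vec)
    return out


def test_complete_graph_uniform_centrality():
    a = np.ones((4, 4)) - np.eye(4)
    scores = eigenvector_centrality(a)
    np.testing.assert_allclose(scores, scores[0])


def test_star_graph_hub_dominates():
    a = np.zeros((6, 6))
    a[0, 1:] = a[1:, 0] = 1
    scores = eigenvector_centrality(a)
    assert np.argmax(scores) == 0


def test_centrality_matches_dense_oracle_small_graphs():
    """Power iteration equals full eigendecomposition on every graph n<=5
    and on a seeded sweep of larger graphs (n = 6..8), bipartite included."""
    for n in range(1, 6):
        pairs = list(itertools.combinations(range(n), 2))
        for bits in range(2 ** len(pairs)):
            a = np.zeros((n, n))
            for b, (i, j) in enumerate(pairs):
                if bits >> b & 1:
                    a[i, j] = a[j, i] = 1
            np.testing.assert_allclose(
                eigenvector_centrality(a), _dense_oracle(a), atol=1e-6
            )
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(6, 9))
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        np.testing.assert_allclose(
            eigenvector_centrality(a), _dense_oracle(a), atol=1e-6
        )


def test_centrality_permutation_equivariance():
    rng = np.random.default_rng(9)
    a = (rng.random((7, 7)) < 0.5).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    perm = rng.permutation(7)
    scores = eigenvector_centrality(a)
    permuted = eigenvector_centrality(a[np.ix_(perm, perm)])
    np.testing.assert_allclose(permuted, scores[perm], atol=1e-8)


def test_centrality_rejects_bad_input():
    assert eigenvector_centrality(np.zeros((0, 0))).size == 0
    with pytest.raises(ValueError):
        eigenvector_centrality(np.array([[1.0]]))
    with pytest.raises(ValueError):
        eigenvector_centrality(np.array([[0.0, 1.0], [0.0, 0.0]]))


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def test_feature_vector_layout_and_onehots():
    protein = make_protein(straight_chain(9), "AGSAYTWCV", plddt=np.full(9, 60.0))
    graph = build_site_subgraph(protein, 3)
    x = featurize_nodes(graph, protein)
    assert x.shape == (graph.n_nodes, 35)
    assert np.isfinite(x).all()
    np.testing.assert_allclose(x[:, LAYOUT.aa_onehot].sum(axis=1), 1.0)
    np.testing.assert_allclose(x[:, LAYOUT.ss_onehot].sum(axis=1), 1.0)
    np.testing.assert_allclose(x[:, LAYOUT.plddt], 0.6)
    # glycine sidechain vector is the zero vector
    gly_local = list(graph.node_ids).index(1)
    np.testing.assert_array_equal(x[gly_local, LAYOUT.sidechain_vector], 0.0)
    # alanine sidechain pseudo-atom sits at Ca + (1, 0, 0)
    ala_local = list(graph.node_ids).index(0)
    np.testing.assert_allclose(x[ala_local, LAYOUT.sidechain_vector], [1.0, 0, 0])


def test_unknown_residue_warns_with_zero_onehot():
    protein = make_protein(straight_chain(4), "AXSA")
    graph = build_site_subgraph(protein, 3)
    with pytest.warns(UserWarning, match="unknown residue"):
        x = featurize_nodes(graph, protein)
    bad_local = list(graph.node_ids).index(1)
    assert x[bad_local, LAYOUT.aa_onehot].sum() == 0


def test_subgraph_scope_degree_matches_incident_edges():
    protein = make_protein(straight_chain(9), "AAASAAAAA")
    config = GraphConfig(centrality_scope="subgraph")
    graph = build_site_subgraph(protein, 4, config)
    x = featurize_nodes(graph, protein, config)
    from funcphos.graphs import DEGREE_FEATURE_SCALE

    np.testing.assert_allclose(
        x[:, LAYOUT.degree] * DEGREE_FEATURE_SCALE, graph.degrees()
    )


def test_whole_protein_scope_uses_contact_graph(small_dataset):
    proteins, sites, _ = small_dataset
    protein = proteins[0]
    site = next(s for s in sites if s.accession == protein.accession)
    graph = build_site_subgraph(protein, site.position)
    x = featurize_nodes(graph, protein)
    adj = contact_graph_adjacency(protein)
    from funcphos.graphs import DEGREE_FEATURE_SCALE

    expected_deg = adj.sum(axis=1)[graph.node_ids] / DEGREE_FEATURE_SCALE
    np.testing.assert_allclose(x[:, LAYOUT.degree], expected_deg)
    expected_cent = eigenvector_centrality(adj)[graph.node_ids]
    np.testing.assert_allclose(x[:, LAYOUT.eigenvector_centrality], expected_cent)


def test_feature_matrix_finite_on_random_fixtures():
    rng = np.random.default_rng(21)
    for _ in range(20):
        protein = random_protein(rng, int(rng.integers(4, 40)))
        graph = build_site_subgraph(protein, int(rng.integers(1, len(protein) + 1)))
        x = featurize_nodes(graph, protein)
        assert np.isfinite(x).all()
        assert x.shape[1] == 35
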