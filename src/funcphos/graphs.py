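"""Site-centered residue structure graphs and their 35-dim node features.

Each phosphorylation site becomes the center of a local subgraph: the node
set is the center plus every residue whose Cα lies within the contact radius
(8 Å by default), plus the center's k nearest residues (k = 3) so that a
site in an extended region is never isolated.  Edges combine three rules —
contact distance, center-kNN, and peptide bond — collapsed so that any node
pair carries at most one edge.

Node features (35 dims): amino-acid one-hot (20), relative solvent
accessibility (1), pLDDT (1), Cα→sidechain-center vector (3), 8-state
secondary structure one-hot (8), degree (1) and eigenvector centrality (1).
Degree and centrality are computed on the whole-protein contact graph by
default: they describe how embedded the residue is in the full residue
interaction network, not in the small excised subgraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .io import AMINO_ACIDS, ProteinRecord

# 8-state secondary-structure alphabet (DSSP order); the geometric backend
# fills only H/E/C, an external DSSP can fill all eight.
SS8_ALPHABET = "HGIEBTSC"

# Theoretical maximum accessible surface areas (Å^2), Tien et al. 2013.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 197.0,
}

# Effective sidechain-sphere radii (Å) for the coarse two-sphere residue
# model used by the SASA estimator; roughly tracks sidechain heavy-atom
# count.  Glycine has no sidechain sphere.
_SIDECHAIN_RADIUS_DEFAULT = 2.3
SIDECHAIN_RADIUS = {
    "G": 0.0, "A": 1.7, "S": 1.9, "C": 2.0, "T": 2.1, "V": 2.1,
    "P": 2.1, "D": 2.2, "N": 2.2, "I": 2.3, "L": 2.3, "E": 2.4,
    "Q": 2.4, "M": 2.4, "H": 2.5, "K": 2.6, "F": 2.6, "R": 2.7,
    "Y": 2.7, "W": 2.9, "X": 2.3,
}
_CA_SPHERE_RADIUS = 2.4
_PROBE_RADIUS = 1.4

N_NODE_FEATURES = 35
DEGREE_FEATURE_SCALE = 10.0  # typical Cα contact count at 8 Å


@dataclass(frozen=True)
class NodeFeatureLayout:
    """Slice map of the 35-dim node feature vector."""

    aa_onehot: slice = field(default_factory=lambda: slice(0, 20))
    rsa: int = 20
    plddt: int = 21
    sidechain_vector: slice = field(default_factory=lambda: slice(22, 25))
    ss_onehot: slice = field(default_factory=lambda: slice(25, 33))
    degree: int = 33
    eigenvector_centrality: int = 34


LAYOUT = NodeFeatureLayout()


@dataclass
class GraphConfig:
    radius: float = 8.0          # Å, contact cutoff (strict <)
    knn_k: int = 3               # nearest neighbours of the center
    feature_plddt_scale: str = "unit"      # "unit" | "raw"
    centrality_scope: str = "whole_protein"  # "whole_protein" | "subgraph"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.feature_plddt_scale not in ("unit", "raw"):
            raise ValueError(f"bad feature_plddt_scale {self.feature_plddt_scale!r}")
        if self.centrality_scope not in ("whole_protein", "subgraph"):
            raise ValueError(f"bad centrality_scope {self.centrality_scope!r}")


@dataclass
class ResidueGraph:
    """A featured site-centered subgraph.

    ``node_ids`` are 0-based residue indices into the parent protein,
    sorted ascending.  ``edges`` maps an (i, j) pair with i < j (positions
    into ``node_ids``) to the rule that created it, one of
    {"distance", "knn", "peptide"} with that priority when several apply.
    """

    node_ids: np.ndarray
    center: int                       # residue index (0-based) of the site
    edges: dict[tuple[int, int], str]
    node_features: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def center_local(self) -> int:
        return int(np.searchsorted(self.node_ids, self.center))

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)


# ---------------------------------------------------------------------------
# subgraph construction
# ---------------------------------------------------------------------------

def build_site_subgraph(
    protein: ProteinRecord, site_position: int, config: GraphConfig | None = None
) -> ResidueGraph:
    """Extract the local structure graph around a 1-based site position."""
    config = config or GraphConfig()
    n = len(protein)
    if not 1 <= site_position <= n:
        raise IndexError(f"site position {site_position} outside 1..{n}")
    center = site_position - 1

    dists = np.linalg.norm(protein.ca_coords - protein.ca_coords[center], axis=1)
    members = set(np.flatnonzero(dists < config.radius).tolist())
    members.add(center)
    others = np.argsort(dists, kind="stable")
    others = others[others != center]
    members.update(others[: config.knn_k].tolist())
    node_ids = np.array(sorted(members))

    local = {res: i for i, res in enumerate(node_ids)}
    edges: dict[tuple[int, int], str] = {}

    def add_edge(i: int, j: int, rule: str) -> None:
        if i == j:
            return
        key = (min(i, j), max(i, j))
        edges.setdefault(key, rule)  # first rule wins; callers order by priority

    coords = protein.ca_coords[node_ids]
    pair = cdist(coords, coords)
    for i in range(len(node_ids)):
        for j in range(i + 1, len(node_ids)):
            if pair[i, j] < config.radius:
                add_edge(i, j, "distance")
    for res in others[: config.knn_k]:
        add_edge(local[center], local[res], "knn")
    for i in range(len(node_ids)):
        for j in range(i + 1, len(node_ids)):
            if abs(int(node_ids[i]) - int(node_ids[j])) == 1:
                add_edge(i, j, "peptide")

    return ResidueGraph(node_ids=node_ids, center=center, edges=edges)


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def assign_secondary_structure(
    protein: ProteinRecord, backend: str = "psea"
) -> np.ndarray:
    """Per-residue secondary-structure class in the 8-letter alphabet.

    The built-in geometric backend (P-SEA on the Cα trace) assigns only
    H / E / C; ``backend="dssp"`` would require an external mkdssp binary
    and raises if unavailable.
    """
    if backend == "dssp":
        raise RuntimeError(
            "external DSSP backend requested but no mkdssp binary is wired in; "
            "use the built-in 'psea' backend"
        )
    if backend != "psea":
        raise ValueError(f"unknown secondary-structure backend {backend!r}")
    n = len(protein)
    if n < 4:
        return np.array(["C"] * n)
    arr = struc.AtomArray(n)
    arr.coord = protein.ca_coords.astype(np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, bool)
    sse = struc.annotate_sse(arr)
    mapping = {"a": "H", "b": "E", "c": "C"}
    return np.array([mapping.get(s, "C") for s in sse])


def collapse_ss3(ss8: np.ndarray) -> np.ndarray:
    """Collapse the 8-state alphabet to {H, E, C}."""
    out = np.full(len(ss8), "C")
    out[np.isin(ss8, ["H", "G", "I"])] = "H"
    out[np.isin(ss8, ["E", "B"])] = "E"
    return out


# ---------------------------------------------------------------------------
# relative solvent accessibility
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def compute_rsa(protein: ProteinRecord, n_points: int = 120) -> np.ndarray:
    """Relative solvent accessibility per residue, clipped to [0, 1].

    Shrake–Rupley on a coarse two-sphere residue model: one sphere at the
    Cα and one at the sidechain pseudo-center with a residue-specific
    radius.  ASA per residue is the summed accessible area of its spheres
    divided by the residue's theoretical maximum ASA.
    """
    n = len(protein)
    if n == 0:
        return np.zeros(0)
    centers, radii, owner = [], [], []
    for i in range(n):
        centers.append(protein.ca_coords[i])
        radii.append(_CA_SPHERE_RADIUS)
        owner.append(i)
        if protein.has_sidechain(i):
            r = SIDECHAIN_RADIUS.get(protein.sequence[i], _SIDECHAIN_RADIUS_DEFAULT)
            if r > 0:
                centers.append(protein.sidechain_centers[i])
                radii.append(r)
                owner.append(i)
    centers = np.asarray(centers)
    radii = np.asarray(radii) + _PROBE_RADIUS
    owner = np.asarray(owner)
    unit = _fibonacci_sphere(n_points)

    pair = cdist(centers, centers)
    asa = np.zeros(n)
    for s in range(len(centers)):
        # only spheres that can occlude this one
        near = np.flatnonzero((pair[s] < radii[s] + radii) & (np.arange(len(centers)) != s))
        pts = centers[s] + radii[s] * unit
        accessible = np.ones(n_points, bool)
        if len(near):
            d = cdist(pts, centers[near])
            accessible = np.all(d >= radii[near], axis=1)
        asa[owner[s]] += accessible.mean() * 4.0 * np.pi * radii[s] ** 2
    max_asa = np.array([MAX_ASA.get(a, MAX_ASA["X"]) for a in protein.sequence])
    return np.clip(asa / max_asa, 0.0, 1.0)


# ---------------------------------------------------------------------------
# network descriptors
# ---------------------------------------------------------------------------

def eigenvector_centrality(
    adjacency: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Principal-eigenvector centrality of an undirected binary graph.

    Power iteration from the uniform vector, run per connected component and
    L2-normalized within each component.  Iterating on A + I instead of A
    leaves the eigenvectors unchanged while shifting the spectrum positive,
    which guarantees convergence on bipartite components.  Components with
    no edges get the uniform normalized vector.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if n == 0:
        return np.zeros(0)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("self-loops are not allowed")
    n_comp, labels = connected_components(a > 0, directed=False)
    scores = np.zeros(n)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        sub = a[np.ix_(idx, idx)] + np.eye(len(idx))
        x = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
        for _ in range(max_iter):
            y = sub @ x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < tol:
                x = y
                break
            x = y
        scores[idx] = np.abs(x)
    return scores


def contact_graph_adjacency(protein: ProteinRecord, radius: float = 8.0) -> np.ndarray:
    """Whole-protein residue contact graph (Cα–Cα distance < radius)."""
    d = cdist(protein.ca_coords, protein.ca_coords)
    a = (d < radius).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

@dataclass
class ProteinFeatures:
    """Whole-protein per-residue descriptors shared across that protein's sites."""

    rsa: np.ndarray
    ss8: np.ndarray
    degree: np.ndarray
    centrality: np.ndarray


def compute_protein_features(
    protein: ProteinRecord, config: GraphConfig | None = None
) -> ProteinFeatures:
    config = config or GraphConfig()
    adj = contact_graph_adjacency(protein, config.radius)
    return ProteinFeatures(
        rsa=compute_rsa(protein),
        ss8=assign_secondary_structure(protein),
        degree=adj.sum(axis=1),
        centrality=eigenvector_centrality(adj),
    )


def featurize_nodes(
    graph: ResidueGraph,
    protein: ProteinRecord,
    config: GraphConfig | None = None,
    precomputed: ProteinFeatures | None = None,
) -> np.ndarray:
    """Fill ``graph.node_features`` with the 35-dim per-node vectors."""
    config = config or GraphConfig()
    feats = precomputed or compute_protein_features(protein, config)
    L = LAYOUT
    x = np.zeros((graph.n_nodes, N_NODE_FEATURES))
    if config.centrality_scope == "subgraph":
        sub_adj = graph.adjacency()
        degree = sub_adj.sum(axis=1)
        centrality = eigenvector_centrality(sub_adj)
    for local, res in enumerate(graph.node_ids):
        letter = protein.sequence[res]
        if letter in AMINO_ACIDS:
            x[local, L.aa_onehot][AMINO_ACIDS.index(letter)] = 1.0
        else:
            warnings.warn(
                f"{protein.accession}: unknown residue {letter!r} at {res + 1}, "
                "amino-acid one-hot left all-zero", stacklevel=2,
            )
        x[local, L.rsa] = feats.rsa[res]
        plddt = protein.plddt[res]
        x[local, L.plddt] = plddt / 100.0 if config.feature_plddt_scale == "unit" else plddt
        if protein.has_sidechain(res):
            x[local, L.sidechain_vector] = (
                protein.sidechain_centers[res] - protein.ca_coords[res]
            )
        x[local, L.ss_onehot][SS8_ALPHABET.index(feats.ss8[res])] = 1.0
        # degree is divided by a typical contact count so it enters the
        # encoder on the same O(1) scale as every other feature
        if config.centrality_scope == "whole_protein":
            x[local, L.degree] = feats.degree[res] / DEGREE_FEATURE_SCALE
            x[local, L.eigenvector_centrality] = feats.centrality[res]
        else:
            x[local, L.degree] = degree[local] / DEGREE_FEATURE_SCALE
            x[local, L.eigenvector_centrality] = centrality[local]
    graph.node_features = x
    return x
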