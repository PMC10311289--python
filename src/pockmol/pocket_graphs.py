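"""Binding-pocket parsing and spatial graph construction.

A pocket is viewed twice: as a residue-level graph (nodes = amino acids,
represented by their mass-weighted centroids) and as an atom-level graph
(nodes = heavy/backbone atoms). Both are K-nearest-neighbour graphs whose
edges carry Euclidean distances, expanded into Gaussian radial-basis
embeddings, and whose nodes carry spectral (normalized-Laplacian
eigenvector) positional features.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .nn.tensor import Tensor

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {name: i for i, name in enumerate(AMINO_ACIDS)}

ELEMENTS = ("H", "C", "N", "O", "S", "P")
ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})


class PocketParseError(ValueError):
    """Raised when a PDB text contains no usable atom records."""


@dataclass(frozen=True)
class Atom:
    element: str
    coords: tuple[float, float, float]
    mass: float
    is_backbone: bool

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atomic mass must be positive, got {self.mass}")
        if not all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class Residue:
    residue_type: str
    atoms: tuple[Atom, ...]
    chain_id: str = "A"
    seq_id: int = 1

    def __post_init__(self):
        if self.residue_type not in AA_INDEX:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        if len(self.atoms) == 0:
            raise ValueError("residue must contain at least one atom")


@dataclass(frozen=True)
class PocketStructure:
    residues: tuple[Residue, ...]

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError("pocket must contain at least one residue")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


@dataclass(frozen=True)
class GraphConfig:
    """Per-view graph construction settings.

    Defaults follow the published runs: residue view k=30, sigma=30 A,
    RBF span 0-25 A; atom view k=48, sigma=15 A, RBF span 0-15 A.
    """

    view: str = "residue"
    k_neighbors: int = 30
    rbf_count: int = 64
    rbf_min: float = 0.0
    rbf_max: float = 25.0
    laplacian_sigma: float = 30.0
    n_eigenvectors: int = 8
    include_trivial_eigenvector: bool = False

    def __post_init__(self):
        if self.view not in ("residue", "atom"):
            raise ValueError("view must be 'residue' or 'atom'")
        if self.rbf_min >= self.rbf_max:
            raise ValueError("rbf_min must be < rbf_max")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_eigenvectors < 1:
            raise ValueError("n_eigenvectors must be >= 1")


def residue_graph_config(**overrides) -> GraphConfig:
    base = dict(view="residue", k_neighbors=30, rbf_max=25.0, laplacian_sigma=30.0)
    base.update(overrides)
    return GraphConfig(**base)


def atom_graph_config(**overrides) -> GraphConfig:
    base = dict(view="atom", k_neighbors=48, rbf_max=15.0, laplacian_sigma=15.0)
    base.update(overrides)
    return GraphConfig(**base)


@dataclass
class SpatialGraph:
    """KNN graph over representative points.

    neighborhoods[i] lists, in ascending-distance order (ties broken by
    ascending node index), the min(k, n-1) nearest other nodes;
    edge_distances[i, j] is the Euclidean distance to neighborhoods[i][j].
    """

    node_features: np.ndarray  # (n, d_v) binary
    coords: np.ndarray  # (n, 3)
    neighborhoods: np.ndarray  # (n, k') int
    edge_distances: np.ndarray  # (n, k')

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.neighborhoods.shape[1]


@dataclass
class PositionalFeatures:
    vectors: np.ndarray  # (n, n_eigenvectors)
    eigenvalues: np.ndarray  # full ascending spectrum, length n


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def parse_pocket(pdb_text: str) -> PocketStructure:
    """Parse PDB coordinate records into a :class:`PocketStructure`.

    Residues are ordered by (chain, sequence number); backbone flags are
    assigned to atoms named N, CA, C, O. Atoms whose element lies outside
    {H, C, N, O, S, P} and residues outside the 20 standard amino acids are
    excluded with a warning.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:
        raise PocketParseError(f"could not parse PDB text: {exc}") from exc
    if atoms.array_length() == 0:
        raise PocketParseError("no parsable atom records found")

    residues: dict[tuple[str, int, str], list[Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for i in range(atoms.array_length()):
        res_name = str(atoms.res_name[i])
        element = str(atoms.element[i]).strip().upper()
        element = element[0] + element[1:].lower() if len(element) > 1 else element
        if res_name not in AA_INDEX:
            warnings.warn(f"skipping non-standard residue {res_name}")
            continue
        if element not in ELEMENT_INDEX:
            warnings.warn(f"excluding atom with unsupported element {element!r}")
            continue
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), res_name)
        if key not in residues:
            residues[key] = []
            order.append(key)
        atom_name = str(atoms.atom_name[i]).strip()
        residues[key].append(
            Atom(
                element=element,
                # PDB prints 3 decimals; rounding drops float32 artifacts
                coords=tuple(round(float(c), 3) for c in atoms.coord[i]),
                mass=ATOMIC_MASS[element],
                is_backbone=atom_name in BACKBONE_ATOM_NAMES,
            )
        )
    order.sort(key=lambda k: (k[0], k[1]))
    built = [
        Residue(residue_type=key[2], atoms=tuple(residues[key]),
                chain_id=key[0], seq_id=key[1])
        for key in order
        if residues[key]
    ]
    if not built:
        raise PocketParseError("no atoms with supported elements/residues found")
    return PocketStructure(residues=tuple(built))


def extract_pocket(structure: PocketStructure, ligand_coords: np.ndarray,
                   radius: float = 10.0) -> PocketStructure:
    """Keep residues with any atom within `radius` of any ligand atom."""
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    kept = []
    for res in structure.residues:
        coords = np.array([a.coords for a in res.atoms])
        if cdist(coords, ligand_coords).min() <= radius:
            kept.append(res)
    if not kept:
        raise ValueError(f"no residues within {radius} A of the ligand")
    return PocketStructure(residues=tuple(kept))


def pocket_to_json(pocket: PocketStructure) -> str:
    payload = {
        "residues": [
            {
                "residue_type": r.residue_type,
                "chain_id": r.chain_id,
                "seq_id": r.seq_id,
                "atoms": [
                    {
                        "element": a.element,
                        "coords": list(a.coords),
                        "mass": a.mass,
                        "is_backbone": a.is_backbone,
                    }
                    for a in r.atoms
                ],
            }
            for r in pocket.residues
        ]
    }
    return json.dumps(payload, indent=1)


def pocket_from_json(text: str) -> PocketStructure:
    payload = json.loads(text)
    residues = tuple(
        Residue(
            residue_type=r["residue_type"],
            chain_id=r.get("chain_id", "A"),
            seq_id=r.get("seq_id", 1),
            atoms=tuple(
                Atom(
                    element=a["element"],
                    coords=tuple(a["coords"]),
                    mass=a["mass"],
                    is_backbone=a["is_backbone"],
                )
                for a in r["atoms"]
            ),
        )
        for r in payload["residues"]
    )
    return PocketStructure(residues=residues)


# ---------------------------------------------------------------------------
# Node features and representative points
# ---------------------------------------------------------------------------

def residue_centroid(residue: Residue) -> np.ndarray:
    """Mass-weighted centroid c = sum(r_k * m_k) / sum(m_k)."""
    coords = np.array([a.coords for a in residue.atoms], dtype=float)
    masses = np.array([a.mass for a in residue.atoms], dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total residue mass must be positive")
    return (coords * masses[:, None]).sum(axis=0) / total


def residue_feature_vector(residue: Residue) -> np.ndarray:
    vec = np.zeros(len(AMINO_ACIDS))
    vec[AA_INDEX[residue.residue_type]] = 1.0
    return vec


def atom_feature_vector(atom: Atom) -> np.ndarray:
    """One-hot over (H, C, N, O, S, P) plus a trailing backbone bit."""
    if atom.element not in ELEMENT_INDEX:
        raise ValueError(f"unsupported element {atom.element!r}")
    vec = np.zeros(len(ELEMENTS) + 1)
    vec[ELEMENT_INDEX[atom.element]] = 1.0
    vec[-1] = 1.0 if atom.is_backbone else 0.0
    return vec


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(points: np.ndarray, node_features: np.ndarray,
                k_neighbors: int) -> SpatialGraph:
    """KNN graph over `points`; ties broken by ascending node index."""
    points = np.asarray(points, dtype=float)
    node_features = np.asarray(node_features, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to build a graph")
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")
    dist = cdist(points, points)
    np.fill_diagonal(dist, np.inf)
    k = min(k_neighbors, n - 1)
    idx = np.arange(n)
    neighborhoods = np.empty((n, k), dtype=np.int64)
    edge_distances = np.empty((n, k))
    for i in range(n):
        order = np.lexsort((idx, dist[i]))[:k]
        neighborhoods[i] = order
        edge_distances[i] = dist[i, order]
    return SpatialGraph(
        node_features=node_features,
        coords=points,
        neighborhoods=neighborhoods,
        edge_distances=edge_distances,
    )


def residue_graph(pocket: PocketStructure, config: GraphConfig) -> SpatialGraph:
    points = np.array([residue_centroid(r) for r in pocket.residues])
    feats = np.array([residue_feature_vector(r) for r in pocket.residues])
    return build_graph(points, feats, config.k_neighbors)


def atom_graph(pocket: PocketStructure, config: GraphConfig) -> SpatialGraph:
    atoms = pocket.all_atoms()
    points = np.array([a.coords for a in atoms])
    feats = np.array([atom_feature_vector(a) for a in atoms])
    return build_graph(points, feats, config.k_neighbors)


# ---------------------------------------------------------------------------
# Edge embeddings
# ---------------------------------------------------------------------------

def rbf_centers(config: GraphConfig) -> tuple[np.ndarray, float]:
    """Centers mu_t = rbf_min + t*w, t=0..count-1, with w the interval size."""
    width = (config.rbf_max - config.rbf_min) / config.rbf_count
    centers = config.rbf_min + width * np.arange(config.rbf_count)
    return centers, width


def rbf_encode(d, config: GraphConfig) -> np.ndarray:
    """Gaussian RBF expansion exp(-(d - mu_t)^2 / (2 w^2)) of distance(s) d."""
    centers, width = rbf_centers(config)
    d = np.asarray(d, dtype=float)
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * width**2))


# ---------------------------------------------------------------------------
# Laplacian positional features
# ---------------------------------------------------------------------------

def symmetrized_adjacency(graph: SpatialGraph, sigma: float) -> np.ndarray:
    """Gaussian edge weights on the symmetrized KNN edge set.

    A_ij = A_ji = exp(-d_ij^2 / (2 sigma^2)) whenever either direction is a
    KNN edge (keeps A symmetric for the normalized Laplacian).
    """
    n = graph.n_nodes
    A = np.zeros((n, n))
    w = np.exp(-(graph.edge_distances**2) / (2.0 * sigma**2))
    for i in range(n):
        A[i, graph.neighborhoods[i]] = w[i]
    return np.maximum(A, A.T)


def normalized_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """L = I - D^{-1/2} A D^{-1/2}; raises on isolated (degree-0) nodes."""
    A = np.asarray(adjacency, dtype=float)
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("graph contains an isolated node (zero degree)")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return np.eye(A.shape[0]) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            out[:, j] = -col
    return out


def _deterministic_order(eigvals: np.ndarray, vectors: np.ndarray):
    # within numerically-degenerate eigenvalues, order columns lexicographically
    key_vals = np.round(eigvals, 9)
    cols = list(range(len(eigvals)))
    cols.sort(key=lambda j: (key_vals[j], tuple(np.round(vectors[:, j], 9))))
    return eigvals[cols], vectors[:, cols]


def laplacian_positional_features(
        graph: SpatialGraph, config: GraphConfig,
        sign_flip_rng: np.random.Generator | None = None) -> PositionalFeatures:
    """Per-node components of low-frequency normalized-Laplacian eigenvectors.

    The trivial (lambda = 0) eigenvector is skipped by default since it
    carries no positional signal; columns beyond the available spectrum are
    zero-padded. Signs are fixed by forcing each eigenvector's
    largest-magnitude component positive; passing `sign_flip_rng` instead
    flips each retained column's sign at random (training augmentation,
    off by default).
    """
    A = symmetrized_adjacency(graph, config.laplacian_sigma)
    L = normalized_laplacian(A)
    eigvals, eigvecs = np.linalg.eigh(L)
    eigvecs = _fix_signs(eigvecs)
    eigvals, eigvecs = _deterministic_order(eigvals, eigvecs)
    start = 0 if config.include_trivial_eigenvector else 1
    selected = eigvecs[:, start : start + config.n_eigenvectors]
    norms = np.linalg.norm(selected, axis=0)
    selected = selected / np.where(norms > 0, norms, 1.0)
    n, got = selected.shape
    if got < config.n_eigenvectors:
        selected = np.hstack([selected, np.zeros((n, config.n_eigenvectors - got))])
    if sign_flip_rng is not None:
        flips = np.where(sign_flip_rng.random(selected.shape[1]) < 0.5, -1.0, 1.0)
        selected = selected * flips
    return PositionalFeatures(vectors=selected, eigenvalues=eigvals)


def save_graph_arrays(path, graph: SpatialGraph,
                      positional: PositionalFeatures | None = None):
    """Serialize a graph (and optional spectral features) as named arrays.

    Container keys: node_features, coords, neighbor_index, edge_distance,
    and eigvecs/eigvals when positional features are given.
    """
    arrays = {
        "node_features": graph.node_features,
        "coords": graph.coords,
        "neighbor_index": graph.neighborhoods,
        "edge_distance": graph.edge_distances,
    }
    if positional is not None:
        arrays["eigvecs"] = positional.vectors
        arrays["eigvals"] = positional.eigenvalues
    np.savez(path, **arrays)


def load_graph_arrays(path) -> tuple[SpatialGraph, PositionalFeatures | None]:
    with np.load(path) as data:
        graph = SpatialGraph(
            node_features=data["node_features"],
            coords=data["coords"],
            neighborhoods=data["neighbor_index"],
            edge_distances=data["edge_distance"],
        )
        positional = None
        if "eigvecs" in data:
            positional = PositionalFeatures(vectors=data["eigvecs"],
                                            eigenvalues=data["eigvals"])
    return graph, positional


# ---------------------------------------------------------------------------
# Node embedding (input to the encoder)
# ---------------------------------------------------------------------------

def embed_graph_nodes(graph: SpatialGraph, positional: PositionalFeatures,
                      w_node, w_pos):
    """h_i^(0) = x_i W_0 + U(i, 1:k) W_pos.

    Accepts NumPy arrays (returns an array) or autodiff Tensors (returns a
    Tensor participating in the graph).
    """
    x = graph.node_features
    u = positional.vectors
    if isinstance(w_node, Tensor) or isinstance(w_pos, Tensor):
        if x.shape[1] != w_node.shape[0] or u.shape[1] != w_pos.shape[0]:
            raise ValueError("weight shapes do not match node/positional features")
        return Tensor(x) @ w_node + Tensor(u) @ w_pos
    w_node = np.asarray(w_node, dtype=float)
    w_pos = np.asarray(w_pos, dtype=float)
    if x.shape[1] != w_node.shape[0] or u.shape[1] != w_pos.shape[0]:
        raise ValueError("weight shapes do not match node/positional features")
    return x @ w_node + u @ w_pos
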