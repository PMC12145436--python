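"""Spherical mesh domains: icosphere construction, great-circle geometry,
distances to vertex sets, and Laplace-Beltrami eigenmodes.

The spatial domain of the surface analyses is a triangulated unit sphere (the
spherical projection of a cortical hemisphere).  Vertices flagged invalid
(the medial wall on real surfaces) are excluded from fitting, evaluation and
spectral decomposition, but the sphere itself remains the geometric domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

__all__ = [
    "SphericalMesh",
    "EigenBasis",
    "build_icosphere",
    "great_circle_distance",
    "geodesic_to_set",
    "mesh_eigenmodes",
]


@dataclass
class SphericalMesh:
    """Triangulated unit sphere with a validity mask.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Unit vectors, one per vertex.
    triangles : (F, 3) int array
        Vertex-index triples.
    valid_mask : (V,) bool array
        False marks excluded vertices (medial wall).  Defaults to all-valid.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.vertex_coords), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        norms = np.linalg.norm(self.vertex_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex coordinates must lie on the unit sphere")
        if self.triangles.size and self.triangles.max() >= self.n_vertices:
            raise ValueError("triangle indices out of range")
        if len(self.valid_mask) != self.n_vertices:
            raise ValueError("valid_mask length does not match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid_mask)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2), sorted."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        e = self.edges()
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        a = a + a.T
        return a.tocsr()


@dataclass
class EigenBasis:
    """Eigenmodes of a mesh Laplacian restricted to valid vertices.

    ``modes`` has one row per mesh vertex (zeros on invalid vertices) and one
    column per mode; modes are orthonormal under ``vertex_weights`` (lumped
    vertex areas for the cotangent operator, ones for the graph Laplacian).
    """

    modes: np.ndarray          # (V, k)
    eigenvalues: np.ndarray    # (k,), ascending
    vertex_weights: np.ndarray  # (V,) mass weights; zero on invalid vertices

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def project(self, values: np.ndarray) -> np.ndarray:
        """Weighted coefficients <psi_k, values> of a per-vertex field."""
        return self.modes.T @ (self.vertex_weights * values)


# ---------------------------------------------------------------------------
# icosphere

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def build_icosphere(n_subdivisions: int) -> SphericalMesh:
    """Icosahedral sphere grid by repeated midpoint subdivision.

    Each subdivision splits every triangle in four and projects new vertices
    back to the unit sphere, giving ``10 * 4**n + 2`` vertices and
    ``20 * 4**n`` triangles.

    Parameters
    ----------
    n_subdivisions : int
        Number of subdivision rounds, 0 <= n <= 7.
    """
    n_subdivisions = int(n_subdivisions)
    if n_subdivisions < 0 or n_subdivisions > 7:
        raise ValueError("n_subdivisions must be between 0 and 7")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(n_subdivisions):
        verts, faces = _subdivide(verts, faces)
    return SphericalMesh(vertex_coords=verts, triangles=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    edge_mid: dict[tuple[int, int], int] = {}
    new_verts = [verts]
    next_idx = len(verts)

    def midpoint(i: int, j: int) -> int:
        nonlocal next_idx
        key = (i, j) if i < j else (j, i)
        if key not in edge_mid:
            m = verts[i] + verts[j]
            m /= np.linalg.norm(m)
            new_verts.append(m[None, :])
            edge_mid[key] = next_idx
            next_idx += 1
        return edge_mid[key]

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for f, (a, b, c) in enumerate(faces):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces[4 * f: 4 * f + 4] = [
            (a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)
        ]
    return np.vstack(new_verts), new_faces


# ---------------------------------------------------------------------------
# distances

def great_circle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle (arc) distance in radians between unit vectors.

    Uses the atan2 form, numerically stable near 0 and pi.  Broadcasts over
    leading dimensions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na < 1e-12) or np.any(nb < 1e-12):
        raise ValueError("zero-norm input to great_circle_distance")
    if not (np.allclose(na, 1.0, atol=1e-6) and np.allclose(nb, 1.0, atol=1e-6)):
        raise ValueError("inputs must be unit-norm")
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    return np.arctan2(cross, dot)


def arc_from_chord(chord: np.ndarray) -> np.ndarray:
    """Convert Euclidean chord length between unit vectors to arc length."""
    return 2.0 * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))


def chord_from_arc(arc: float) -> float:
    """Euclidean chord length subtending a given arc on the unit sphere."""
    return 2.0 * np.sin(min(float(arc), np.pi) / 2.0)


def geodesic_to_set(mesh: SphericalMesh, member_flags: np.ndarray) -> np.ndarray:
    """Great-circle distance from every vertex to the nearest member vertex.

    Members map to 0.  Raises if the member set is empty.
    """
    member_flags = np.asarray(member_flags, dtype=bool)
    if member_flags.shape != (mesh.n_vertices,):
        raise ValueError("member_flags length must match vertex count")
    if not member_flags.any():
        raise ValueError("member set is empty")
    members = mesh.vertex_coords[member_flags]
    # nearest chord distance via KD-tree, then convert to arc
    from scipy.spatial import cKDTree

    tree = cKDTree(members)
    chord, _ = tree.query(mesh.vertex_coords, k=1)
    d = arc_from_chord(chord)
    d[member_flags] = 0.0
    return d


# ---------------------------------------------------------------------------
# Laplacians and eigenmodes

def cotangent_laplacian(mesh: SphericalMesh):
    """Cotangent-weighted stiffness matrix and lumped vertex-area masses.

    Returns ``(L, mass)`` with ``L`` sparse positive semi-definite
    (L = sum of cotangent edge weights, row sums zero) and ``mass`` the
    barycentric lumped vertex areas.
    """
    v = mesh.vertex_coords
    t = mesh.triangles
    n = mesh.n_vertices
    ii, jj, ww = [], [], []
    mass = np.zeros(n)
    for k in range(3):
        i0 = t[:, k]
        i1 = t[:, (k + 1) % 3]
        i2 = t[:, (k + 2) % 3]
        # cotangent of the angle at i0, opposite edge (i1, i2)
        e1 = v[i1] - v[i0]
        e2 = v[i2] - v[i0]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.sum(e1 * e2, axis=1) / np.maximum(cross, 1e-300)
        ii.append(i1)
        jj.append(i2)
        ww.append(0.5 * cot)
        if k == 0:
            area = 0.5 * cross
            for idx in (t[:, 0], t[:, 1], t[:, 2]):
                np.add.at(mass, idx, area / 3.0)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    w = sparse.coo_matrix((ww, (ii, jj)), shape=(n, n))
    w = w + w.T
    lap = sparse.diags(np.asarray(w.sum(axis=1)).ravel()) - w
    return lap.tocsr(), mass


def graph_laplacian(mesh: SphericalMesh):
    """Unweighted graph Laplacian and unit masses."""
    a = mesh.adjacency()
    deg = np.asarray(a.sum(axis=1)).ravel()
    return (sparse.diags(deg) - a).tocsr(), np.ones(mesh.n_vertices)


def mesh_eigenmodes(
    mesh: SphericalMesh, k: int, laplacian: str = "cotangent"
) -> EigenBasis:
    """Lowest-``k`` eigenmodes of the mesh Laplacian on valid vertices.

    Solves the generalized problem ``L psi = lam M psi`` (M = lumped mass for
    the cotangent operator) restricted to valid vertices, returning ascending
    eigenvalues and M-orthonormal modes.  The first mode is constant with
    eigenvalue 0.  Deterministic up to the sign of each mode, which is fixed
    by making the largest-magnitude entry positive.

    Parameters
    ----------
    mesh : SphericalMesh
    k : int
        Number of modes, 1 <= k < number of valid vertices.
    laplacian : {"cotangent", "graph"}
        Discrete operator; cotangent Laplace-Beltrami is the default.
    """
    k = int(k)
    nv = mesh.n_valid
    if not 1 <= k < nv:
        raise ValueError(f"k must be in [1, {nv - 1}) for {nv} valid vertices")
    if laplacian == "cotangent":
        lap, mass = cotangent_laplacian(mesh)
    elif laplacian == "graph":
        lap, mass = graph_laplacian(mesh)
    else:
        raise ValueError("laplacian must be 'cotangent' or 'graph'")
    idx = mesh.valid_indices
    lap = lap[np.ix_(idx, idx)].tocsc()
    mass = mass[idx]

    # connectivity of the valid submesh
    adj = mesh.adjacency()[np.ix_(idx, idx)]
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"valid submesh is disconnected: {ncomp} components with sizes "
            f"{sizes.tolist()}"
        )

    # symmetrize with M^{-1/2}: solve (M^-1/2 L M^-1/2) u = lam u
    inv_sqrt_m = sparse.diags(1.0 / np.sqrt(mass))
    sym = (inv_sqrt_m @ lap @ inv_sqrt_m).tocsc()
    if k >= len(idx) - 1:
        # eigsh cannot return n-1 smallest via shift-invert reliably; dense
        vals, vecs = np.linalg.eigh(sym.toarray())
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        # fixed start vector: eigsh otherwise draws one from the global
        # RNG, making degenerate-subspace bases depend on call order
        v0 = np.random.default_rng(0).standard_normal(sym.shape[0])
        vals, vecs = eigsh(sym, k=k, sigma=-1e-8, which="LM", v0=v0)
    order = np.argsort(vals)
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    modes_valid = vecs / np.sqrt(mass)[:, None]
    # deterministic sign: largest-|entry| positive
    for j in range(modes_valid.shape[1]):
        col = modes_valid[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            modes_valid[:, j] = -col
    modes = np.zeros((mesh.n_vertices, k))
    modes[idx] = modes_valid
    weights = np.zeros(mesh.n_vertices)
    weights[idx] = mass
    return EigenBasis(modes=modes, eigenvalues=vals, vertex_weights=weights)
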