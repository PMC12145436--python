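"""Multiresolution compact-support lattices on the sphere and the plane.

A lattice is the kriging design: per level, a set of basis-node locations,
a Wendland basis range, and the neighbor graph used by the spatial
autoregressive (SAR) coefficient prior.  Levels get strictly denser and their
ranges strictly smaller; the per-level weight ``alpha`` sets each level's
share of process variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .mesh import arc_from_chord, build_icosphere, chord_from_arc

__all__ = [
    "LatticeLevel",
    "MultiresLattice",
    "build_sphere_lattice",
    "build_planar_lattice",
    "wendland",
    "basis_matrix",
    "sar_precision",
]


@dataclass
class LatticeLevel:
    node_coords: np.ndarray     # (m, 3) unit vectors or (m, 2) planar points
    basis_range: float          # radians (sphere) or pixels (plane)
    neighbor_pairs: np.ndarray  # (E, 2) lattice edges


@dataclass
class MultiresLattice:
    """Ordered basis levels plus per-level variance weights.

    ``domain_kind`` is "sphere" (nodes are unit 3-vectors, great-circle
    distances) or "plane" (2-D points, Euclidean distances).
    """

    domain_kind: str
    levels: list[LatticeLevel]
    alpha: np.ndarray

    def __post_init__(self) -> None:
        if self.domain_kind not in ("sphere", "plane"):
            raise ValueError("domain_kind must be 'sphere' or 'plane'")
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.alpha) != len(self.levels):
            raise ValueError(
                f"alpha length {len(self.alpha)} != number of levels "
                f"{len(self.levels)}"
            )
        if np.any(self.alpha < 0):
            raise ValueError("alpha weights must be nonnegative")
        ranges = [lv.basis_range for lv in self.levels]
        if any(r2 >= r1 for r1, r2 in zip(ranges, ranges[1:])):
            raise ValueError("basis ranges must be strictly decreasing")
        counts = [len(lv.node_coords) for lv in self.levels]
        if any(c2 <= c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("levels must be strictly denser than the last")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_nodes(self) -> int:
        return sum(len(lv.node_coords) for lv in self.levels)

    @property
    def level_sizes(self) -> list[int]:
        return [len(lv.node_coords) for lv in self.levels]

    def rotated(self, rotation: np.ndarray) -> "MultiresLattice":
        """Lattice with all node coordinates rotated (sphere only)."""
        if self.domain_kind != "sphere":
            raise ValueError("rotation only defined for sphere lattices")
        levels = [
            LatticeLevel(lv.node_coords @ rotation.T, lv.basis_range,
                         lv.neighbor_pairs)
            for lv in self.levels
        ]
        return MultiresLattice("sphere", levels, self.alpha.copy())

    def describe(self) -> dict:
        """JSON-serializable description (for config echo / export)."""
        return {
            "domain_kind": self.domain_kind,
            "n_levels": self.n_levels,
            "level_sizes": self.level_sizes,
            "basis_ranges": [lv.basis_range for lv in self.levels],
            "alpha": self.alpha.tolist(),
        }


def build_sphere_lattice(
    n_levels: int = 3,
    base_subdivision: int = 1,
    range_multiplier: float = 2.5,
    alpha: tuple = (1.0, 0.25, 0.01),
) -> MultiresLattice:
    """Multiresolution icosphere lattice.

    Level ``l`` uses the vertices of ``icosphere(base_subdivision + l)`` as
    basis nodes; its Wendland range is ``range_multiplier`` times the median
    nearest-node arc at that level, and its SAR neighbor graph is the
    icosphere edge set.  Defaults follow the three-level design with relative
    level weights (1, 0.25, 0.01).
    """
    n_levels = int(n_levels)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if len(alpha) != n_levels:
        raise ValueError(
            f"alpha length {len(alpha)} does not match n_levels {n_levels}"
        )
    levels = []
    for lv in range(n_levels):
        mesh = build_icosphere(base_subdivision + lv)
        coords = mesh.vertex_coords
        tree = cKDTree(coords)
        chord, _ = tree.query(coords, k=2)
        nearest_arc = float(np.median(arc_from_chord(chord[:, 1])))
        levels.append(
            LatticeLevel(
                node_coords=coords,
                basis_range=range_multiplier * nearest_arc,
                neighbor_pairs=mesh.edges(),
            )
        )
    return MultiresLattice("sphere", levels, alpha)


def build_planar_lattice(
    grid_shape: tuple,
    n_levels: int = 3,
    range_multiplier: float = 2.5,
    alpha: tuple = (1.0, 0.25, 0.01),
    base_spacing: float | None = None,
) -> MultiresLattice:
    """Regular 2-D lattice covering a pixel grid, spacing halving per level.

    Nodes at level ``l`` sit on a square grid with spacing
    ``base_spacing / 2**l``, padded one spacing beyond the image domain.
    ``base_spacing`` defaults to 1/8 of the smaller grid side.  Coordinates
    are (row, col) pixel positions; distances are Euclidean.
    """
    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    if rows < 8 or cols < 8:
        raise ValueError("grid must be at least 8x8")
    n_levels = int(n_levels)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if len(alpha) != n_levels:
        raise ValueError(
            f"alpha length {len(alpha)} does not match n_levels {n_levels}"
        )
    if base_spacing is None:
        base_spacing = min(rows, cols) / 8.0
    levels = []
    for lv in range(n_levels):
        spacing = base_spacing / (2 ** lv)
        if spacing < 1.0:
            raise ValueError(
                f"level {lv} spacing {spacing:.3f} px is below one pixel; "
                "reduce n_levels or increase base_spacing"
            )
        r = np.arange(-spacing, rows - 1 + 2 * spacing, spacing)
        c = np.arange(-spacing, cols - 1 + 2 * spacing, spacing)
        rr, cc = np.meshgrid(r, c, indexing="ij")
        coords = np.column_stack([rr.ravel(), cc.ravel()])
        # 4-neighbor grid edges
        nr, nc = len(r), len(c)
        idx = np.arange(nr * nc).reshape(nr, nc)
        horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
        vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
        levels.append(
            LatticeLevel(
                node_coords=coords,
                basis_range=range_multiplier * spacing,
                neighbor_pairs=np.vstack([horiz, vert]),
            )
        )
    return MultiresLattice("plane", levels, alpha)


def wendland(d, basis_range: float):
    """Wendland C4 compactly supported radial kernel.

    With ``r = d / basis_range``::

        w(r) = (1 - r)^6 (35 r^2 + 18 r + 3) / 3   for r < 1, else 0

    so ``w(0) = 1`` and the kernel vanishes continuously at ``r = 1``.
    """
    if basis_range <= 0:
        raise ValueError("basis_range must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    r = d / basis_range
    out = np.where(
        r < 1.0,
        (1.0 - r) ** 6 * (35.0 * r ** 2 + 18.0 * r + 3.0) / 3.0,
        0.0,
    )
    return out if out.ndim else float(out)


def basis_matrix(
    lattice: MultiresLattice, points: np.ndarray, warn_empty_rows: bool = True
) -> sparse.csr_matrix:
    """Sparse Wendland design matrix, points x total basis nodes.

    Entry (i, j) evaluates node j's kernel at point i, using great-circle
    distances on the sphere and Euclidean distances on the plane; columns are
    level-major (all level-0 nodes first).  Rows whose point lies outside the
    support of every node are all-zero; a warning is emitted for them.
    """
    points = np.asarray(points, dtype=float)
    if lattice.domain_kind == "sphere":
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("sphere lattice expects (n, 3) unit vectors")
        if not np.allclose(np.linalg.norm(points, axis=1), 1.0, atol=1e-6):
            raise ValueError("sphere lattice points must be unit-norm")
    else:
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("planar lattice expects (n, 2) points")
    blocks = []
    for lv in lattice.levels:
        tree = cKDTree(lv.node_coords)
        if lattice.domain_kind == "sphere":
            radius = chord_from_arc(lv.basis_range)
        else:
            radius = lv.basis_range
        neighbors = tree.query_ball_point(points, r=radius)
        rows = np.repeat(
            np.arange(len(points)), [len(nb) for nb in neighbors]
        )
        col_list = [nb for nb in neighbors if nb]
        cols = (
            np.concatenate(col_list) if col_list else np.empty(0, dtype=int)
        )
        if len(cols):
            diff = points[rows] - lv.node_coords[cols]
            d = np.linalg.norm(diff, axis=1)
            if lattice.domain_kind == "sphere":
                d = arc_from_chord(d)
            vals = wendland(d, lv.basis_range)
        else:
            vals = np.empty(0)
        blocks.append(
            sparse.coo_matrix(
                (vals, (rows, cols)), shape=(len(points), len(lv.node_coords))
            )
        )
    phi = sparse.hstack(blocks, format="csr")
    if warn_empty_rows:
        covered = np.diff(phi.indptr) > 0
        if not covered.all():
            warnings.warn(
                f"{int((~covered).sum())} point(s) outside every basis "
                "support; their prediction is the fixed part only",
                stacklevel=2,
            )
    return phi


def sar_precision(level: LatticeLevel, kappa2: float) -> sparse.csr_matrix:
    """Spatial autoregressive precision Q = B'B on one lattice level.

    ``B = diag(degree + kappa2) - adjacency`` over the level's neighbor
    graph; ``kappa2 > 0`` makes Q strictly positive definite (a proper
    prior).  Q is exactly symmetric by construction.
    """
    if kappa2 < 0:
        raise ValueError("kappa2 must be nonnegative")
    m = len(level.node_coords)
    e = np.asarray(level.neighbor_pairs, dtype=np.int64)
    a = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(m, m)
    )
    a = (a + a.T).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    b = sparse.diags(deg + kappa2) - a
    q = (b.T @ b).tocsr()
    return q
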