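"""Null models: spin-rotation permutations and eigenmode surrogates.

The spin test rotates a spherical label map by random proper rotations,
destroying its alignment with the data map while preserving its spatial
layout; refitting the network-prediction statistic on rotated labels yields
a null distribution of accuracies.

Eigenmode surrogates ("eigenstrapping") randomize a scalar map while
approximately preserving its spatial autocorrelation, by applying Haar-random
orthogonal rotations to its coefficients within groups of Laplacian
eigenmodes of similar eigenvalue and optionally rank-remapping the result
back onto the original value multiset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .mesh import EigenBasis, SphericalMesh
from .pipeline import SurfaceMap
from .specificity import network_prediction

__all__ = [
    "SpinEnsemble",
    "SurrogateEnsemble",
    "random_rotation",
    "spin_rotate",
    "spin_ensemble",
    "spin_null",
    "eigenstrap",
    "surrogate_pvalue",
    "binned_variogram",
]

GENERATOR_VERSION = "1"


@dataclass
class SpinEnsemble:
    n_rotations: int
    seed: int
    rotated_labels: np.ndarray  # (n, V) ints
    generator_version: str = GENERATOR_VERSION


@dataclass
class SurrogateEnsemble:
    n_surrogates: int
    seed: int
    surrogate_maps: np.ndarray  # (n, V)
    resample_flag: bool


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via sign-corrected QR."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation must be orthogonal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9):
        raise ValueError("rotation must be proper (det = +1)")
    return rotation


def spin_rotate(
    mesh: SphericalMesh, labels: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Carry a label map along a sphere rotation by nearest-vertex lookup.

    Vertex i receives the label of the vertex nearest (in great-circle
    distance) to its pre-image under the rotation.
    """
    rotation = _check_rotation(rotation)
    labels = np.asarray(labels)
    if len(labels) != mesh.n_vertices:
        raise ValueError("label length must match vertex count")
    tree = cKDTree(mesh.vertex_coords)
    preimage = mesh.vertex_coords @ rotation  # == R^{-1} applied to rows
    _, nearest = tree.query(preimage)
    return labels[nearest]


def spin_ensemble(
    mesh: SphericalMesh,
    labels: np.ndarray,
    n: int,
    seed: int,
    required_labels: np.ndarray | None = None,
    max_resample: int = 100,
) -> SpinEnsemble:
    """Ensemble of rotated label maps, reproducible from (mesh, labels, n, seed).

    Rotations whose result loses a required label entirely on the valid
    vertices (a degenerate rotated mask) are resampled and the event logged.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    if required_labels is None:
        u = np.unique(labels[mesh.valid_mask])
        required_labels = u[u > 0]
    tree = cKDTree(mesh.vertex_coords)  # shared across rotations
    out = np.empty((n, mesh.n_vertices), dtype=labels.dtype)
    for i in range(n):
        for attempt in range(max_resample):
            rot = random_rotation(rng)
            _, nearest = tree.query(mesh.vertex_coords @ rot)
            rotated = labels[nearest]
            present = np.unique(rotated[mesh.valid_mask])
            if np.all(np.isin(required_labels, present)):
                break
            warnings.warn(
                f"rotation {i} dropped a label; resampling "
                f"(attempt {attempt + 1})",
                stacklevel=2,
            )
        out[i] = rotated
    return SpinEnsemble(n_rotations=n, seed=seed, rotated_labels=out)


def _fast_network_stat(surface_map: SurfaceMap, lattice_config):
    """Precomputed dense refit closure for the spin loop.

    Solves the same penalized normal equations as the estimator but reuses
    the full-surface design and penalty across rotations.  Only available
    for a fixed lambda, intercept-only fixed part and no basis
    normalization; returns None otherwise.
    """
    from scipy import linalg as sla

    from .kriging import LatticeKriging
    from .lattice import basis_matrix
    from .pipeline import _resolve_lattice, _split_config, _spearman

    cfg = _split_config(lattice_config)
    if cfg["lam"] == "auto" or cfg["normalize"] or cfg["fixed"] != "intercept":
        return None
    lam = float(cfg["lam"])
    mesh = surface_map.mesh
    lattice = _resolve_lattice(cfg)
    est = LatticeKriging(lattice=lattice, lam=lam, kappa2=cfg["kappa2"])
    phi = basis_matrix(
        lattice, mesh.vertex_coords[mesh.valid_mask], warn_empty_rows=False
    ).toarray()
    design = np.column_stack([np.ones(phi.shape[0]), phi])
    pen = np.zeros((design.shape[1], design.shape[1]))
    pen[1:, 1:] = lam * est._penalty().toarray()
    y = surface_map.values[mesh.valid_mask]

    def stat(member: np.ndarray) -> float:
        dm = design[member]
        a = dm.T @ dm + pen
        try:
            theta = sla.solve(a, dm.T @ y[member], assume_a="pos")
        except np.linalg.LinAlgError:
            theta, *_ = np.linalg.lstsq(a, dm.T @ y[member], rcond=None)
        pred = design[~member] @ theta
        return _spearman(pred, y[~member])

    return stat


def spin_null(
    surface_map: SurfaceMap,
    labels: np.ndarray,
    n: int = 500,
    seed: int = 0,
    lattice_config: dict | None = None,
    networks: list | None = None,
    min_size: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Spin-permutation test of per-network prediction accuracy.

    The observed statistic is each network's out-of-network Spearman
    accuracy (see :func:`network_prediction`); the null refits it on ``n``
    rotated label maps.  One-sided p-values use the add-one estimator
    ``p = (1 + #{null >= observed}) / (n + 1)``; Benjamini-Hochberg FDR and
    Bonferroni corrected values are reported side by side.  ``networks``
    restricts the test to a subset of labels.

    Returns ``(table, null_distributions)``.
    """
    if n < 100:
        raise ValueError("need at least 100 rotations")
    mesh = surface_map.mesh
    obs = network_prediction(
        surface_map, labels, lattice_config, min_size=min_size
    )
    obs = obs[~obs["skipped"]]
    if networks is not None:
        obs = obs[obs["network"].isin(networks)]
    net_ids = obs["network"].to_numpy()
    observed = obs.set_index("network")["spearman_rho"]

    ensemble = spin_ensemble(
        mesh, labels, n, seed, required_labels=np.asarray(net_ids)
    )
    fast_stat = _fast_network_stat(surface_map, lattice_config)
    nulls = {int(k): np.full(n, np.nan) for k in net_ids}
    if fast_stat is not None:
        valid = mesh.valid_mask
        for i in range(n):
            rot = ensemble.rotated_labels[i][valid]
            for k in net_ids:
                member = rot == k
                if member.sum() >= min_size:
                    nulls[int(k)][i] = fast_stat(member)
    else:
        for i in range(n):
            stat = network_prediction(
                surface_map, ensemble.rotated_labels[i], lattice_config,
                min_size=min_size,
            )
            stat = stat[~stat["skipped"]].set_index(
                "network")["spearman_rho"]
            for k in net_ids:
                if int(k) in stat.index:
                    nulls[int(k)][i] = stat.loc[int(k)]
    rows = []
    for k in net_ids:
        null = nulls[int(k)]
        null = null[np.isfinite(null)]
        p = surrogate_pvalue(observed.loc[int(k)], null)
        rows.append(
            {
                "network": int(k),
                "observed_rho": float(observed.loc[int(k)]),
                "n_null": len(null),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return table, nulls


# ---------------------------------------------------------------------------
# eigenmode surrogates

def _eigengroups(eigenvalues: np.ndarray, rel_tol: float = 1e-3) -> list:
    """Mode groups sharing an eigenvalue, else spherical-harmonic blocks.

    Mode 0 (constant) forms its own group.  Consecutive eigenvalues within
    ``rel_tol`` relative spread are merged; unless that recovers the
    spherical-harmonic shell pattern (sizes 3, 5, 7, ...), fall back to
    fixed blocks of size 2l+1.  On irregular meshes the shell degeneracy is
    broken by more than any safe merge tolerance, and with ascending
    eigenvalues the fixed blocks still align with the true shells; rotating
    within shell-straddling groups would leak power across spatial scales.
    """
    k = len(eigenvalues)
    groups: list[list[int]] = [[0]]
    for i in range(1, k):
        lam = eigenvalues[i]
        prev = eigenvalues[groups[-1][-1]]
        if groups[-1] != [0] and abs(lam - prev) <= rel_tol * max(
            abs(prev), 1e-12
        ):
            groups[-1].append(i)
        else:
            groups.append([i])
    sizes = [len(g) for g in groups[1:]]
    harmonic = [2 * ell + 1 for ell in range(1, len(sizes) + 1)]
    if sizes[:-1] != harmonic[: len(sizes) - 1]:
        groups = [[0]]
        i, ell = 1, 1
        while i < k:
            size = min(2 * ell + 1, k - i)
            groups.append(list(range(i, i + size)))
            i += size
            ell += 1
    return groups


def _surrogate_values(
    values: np.ndarray,
    basis: EigenBasis,
    rotations: list[np.ndarray],
    groups: list,
    valid: np.ndarray,
) -> np.ndarray:
    """Reconstruct one surrogate from per-group coefficient rotations."""
    coeffs = basis.project(values)
    new_coeffs = coeffs.copy()
    for g, rot in zip(groups, rotations):
        if rot is not None:
            idx = np.asarray(g)
            new_coeffs[idx] = rot @ coeffs[idx]
    out = basis.modes @ new_coeffs
    out[~valid] = 0.0
    return out


def eigenstrap(
    surface_map: SurfaceMap,
    basis: EigenBasis,
    n: int = 200,
    seed: int = 0,
    resample: bool = True,
) -> SurrogateEnsemble:
    """Surrogate maps with approximately preserved spatial autocorrelation.

    The map is projected onto the eigenmode basis; within each eigengroup
    (excluding the constant mode, whose coefficient is kept) the coefficient
    vector is rotated by an independent Haar-random orthogonal matrix, and
    the map is reconstructed.  With ``resample`` the reconstructed values
    are rank-remapped onto the original value multiset, so every surrogate
    has exactly the original histogram.  Deterministic given ``seed``.
    """
    mesh = surface_map.mesh
    if basis.modes.shape[0] != mesh.n_vertices:
        raise ValueError("basis and map meshes do not match")
    if basis.n_modes < 50:
        raise ValueError("need at least 50 eigenmodes")
    rng = np.random.default_rng(seed)
    groups = _eigengroups(basis.eigenvalues)
    valid = mesh.valid_mask
    original_sorted = np.sort(surface_map.values[valid])
    out = np.zeros((n, mesh.n_vertices))
    for s in range(n):
        rotations: list = []
        for g in groups:
            if g == [0] or len(g) == 0:
                rotations.append(None)
                continue
            m = len(g)
            if m == 1:
                rotations.append(
                    np.array([[rng.choice([-1.0, 1.0])]])
                )
                continue
            a = rng.standard_normal((m, m))
            q, r = np.linalg.qr(a)
            rotations.append(q @ np.diag(np.sign(np.diag(r))))
        vals = _surrogate_values(
            surface_map.values, basis, rotations, groups, valid
        )
        if resample:
            ranks = np.empty(int(valid.sum()), dtype=int)
            ranks[np.argsort(vals[valid], kind="stable")] = np.arange(
                len(ranks)
            )
            remapped = np.zeros(mesh.n_vertices)
            remapped[valid] = original_sorted[ranks]
            vals = remapped
        out[s] = vals
    return SurrogateEnsemble(
        n_surrogates=n, seed=seed, surrogate_maps=out, resample_flag=resample
    )


def surrogate_pvalue(
    observed_stat: float, ensemble_stats: np.ndarray, two_sided: bool = False
) -> float:
    """Add-one permutation p-value: (1 + #{null >= obs}) / (n + 1)."""
    ensemble_stats = np.asarray(ensemble_stats, dtype=float).ravel()
    n = len(ensemble_stats)
    if n < 50:
        raise ValueError("need at least 50 ensemble values")
    if two_sided:
        count = np.sum(np.abs(ensemble_stats) >= abs(observed_stat))
    else:
        count = np.sum(ensemble_stats >= observed_stat)
    return float((1 + count) / (n + 1))


def binned_variogram(
    mesh: SphericalMesh,
    values: np.ndarray,
    bin_edges: np.ndarray,
    n_pairs: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical semivariogram over random valid-vertex pairs.

    Per distance bin: pair count and mean of 0.5 (v_i - v_j)^2 at
    great-circle separations within the bin.
    """
    from .mesh import great_circle_distance

    rng = np.random.default_rng(seed)
    idx = mesh.valid_indices
    i = rng.choice(idx, size=n_pairs)
    j = rng.choice(idx, size=n_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    d = great_circle_distance(
        mesh.vertex_coords[i], mesh.vertex_coords[j]
    )
    gamma = 0.5 * (values[i] - values[j]) ** 2
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        rows.append(
            {
                "bin_low": bin_edges[b],
                "bin_high": bin_edges[b + 1],
                "n": int(sel.sum()),
                "semivariance": (
                    float(gamma[sel].mean()) if sel.any() else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
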