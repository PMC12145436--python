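"""Synthetic inputs with known ground truth.

Every input the analysis consumes can be generated here: spatially
autocorrelated z-maps on a sphere (eigenmode synthesis with a power-law
spectrum, so the autocorrelation is analytically controlled and matches the
surrogate machinery), families of task maps sharing a common component,
multi-patch network parcellations, and planar image sequences with AR(1)
temporal structure.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calcium import ImageSeries
from .mesh import EigenBasis, SphericalMesh, mesh_eigenmodes
from .pipeline import SurfaceMap

__all__ = [
    "SynthesisSpec",
    "synth_map",
    "synth_task_family",
    "synth_networks",
    "synth_movie",
]


@dataclass
class SynthesisSpec:
    """Recipe for one synthetic map.

    ``spectrum_decay`` is the power-law exponent gamma: eigenmode k receives
    weight ``eigenvalue_k ** (-gamma / 2)``, so larger gamma concentrates
    variance in smooth modes (gamma >= 3 gives strongly autocorrelated maps;
    gamma = 0 gives a flat band-limited spectrum).  ``n_modes = 0`` with
    ``noise_sd > 0`` produces pure white noise.
    """

    spectrum_decay: float = 3.0
    n_modes: int = 100
    shared_weight: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectrum_decay < 0:
            raise ValueError("spectrum_decay must be nonnegative")
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValueError("shared_weight must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_modes == 0 and self.noise_sd == 0:
            raise ValueError("need n_modes > 0 or noise_sd > 0")


def _standardize(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    v = values[valid]
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) synthetic map")
    out = np.zeros_like(values)
    out[valid] = (v - v.mean()) / sd
    return out


def synth_map(
    mesh: SphericalMesh,
    spec: SynthesisSpec,
    basis: EigenBasis | None = None,
    rng: np.random.Generator | None = None,
) -> SurfaceMap:
    """Random autocorrelated z-map from the mesh eigenmode spectrum.

    map = sum_k a_k lambda_k^(-gamma/2) psi_k + eps with a_k iid standard
    normal (constant mode excluded), eps iid N(0, noise_sd^2); standardized
    to zero mean and unit variance over valid vertices.  Passing ``basis``
    avoids recomputing eigenmodes; passing ``rng`` overrides ``spec.seed``
    (used internally by the family generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    values = np.zeros(mesh.n_vertices)
    if spec.n_modes > 0:
        if basis is None:
            basis = mesh_eigenmodes(mesh, spec.n_modes + 1)
        if basis.n_modes < spec.n_modes + 1:
            raise ValueError(
                f"basis has {basis.n_modes} modes; need {spec.n_modes + 1}"
            )
        lam = basis.eigenvalues[1: spec.n_modes + 1]
        if np.any(lam <= 0):
            raise ValueError("nonconstant eigenvalues must be positive")
        weights = lam ** (-spec.spectrum_decay / 2.0)
        a = rng.standard_normal(spec.n_modes) * weights
        values = basis.modes[:, 1: spec.n_modes + 1] @ a
    if spec.noise_sd > 0:
        scale = values[mesh.valid_mask].std() if spec.n_modes > 0 else 1.0
        scale = scale if scale > 0 else 1.0
        values = values + rng.normal(
            0.0, spec.noise_sd * scale, mesh.n_vertices
        )
    values = _standardize(values, mesh.valid_mask)
    return SurfaceMap(values=values, mesh=mesh, name=f"synth_{spec.seed}")


def synth_task_family(
    mesh: SphericalMesh,
    n_tasks: int,
    shared_weight: float,
    spec: SynthesisSpec,
    basis: EigenBasis | None = None,
) -> list[SurfaceMap]:
    """Family of task maps with a shared plus task-unique decomposition.

    task_i = sqrt(w) * S + sqrt(1 - w) * U_i with S and the U_i independent
    draws from :func:`synth_map`; the expected pairwise correlation between
    tasks equals ``w = shared_weight``.
    """
    if not 2 <= n_tasks <= 12:
        raise ValueError("n_tasks must be between 2 and 12")
    if not 0.0 <= shared_weight <= 1.0:
        raise ValueError("shared_weight must be in [0, 1]")
    if basis is None and spec.n_modes > 0:
        basis = mesh_eigenmodes(mesh, spec.n_modes + 1)
    streams = np.random.SeedSequence(spec.seed).spawn(n_tasks + 1)
    shared = synth_map(
        mesh, spec, basis=basis, rng=np.random.default_rng(streams[0])
    )
    maps = []
    for i in range(n_tasks):
        unique = synth_map(
            mesh, spec, basis=basis, rng=np.random.default_rng(streams[i + 1])
        )
        mixed = (
            np.sqrt(shared_weight) * shared.values
            + np.sqrt(1.0 - shared_weight) * unique.values
        )
        if shared_weight == 1.0:
            values = shared.values.copy()
        else:
            values = _standardize(mixed, mesh.valid_mask)
        maps.append(SurfaceMap(values=values, mesh=mesh, name=f"task{i}"))
    return maps


def synth_networks(
    mesh: SphericalMesh,
    n_networks: int = 7,
    patches_per_network: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Random parcellation by balanced multi-source region growing.

    Each network starts from ``patches_per_network`` random seed vertices
    and the networks expand their breadth-first frontiers in round-robin
    turns until every valid vertex carries a label in 1..n_networks
    (0 marks invalid vertices).  More patches per network produce more
    spatially distributed networks of comparable total area.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if patches_per_network < 1:
        raise ValueError("patches_per_network must be >= 1")
    rng = np.random.default_rng(seed)
    valid_idx = mesh.valid_indices
    n_seeds = n_networks * patches_per_network
    if n_seeds > len(valid_idx):
        raise ValueError("more seed patches than valid vertices")
    seeds = rng.choice(valid_idx, size=n_seeds, replace=False)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    adj = mesh.adjacency()
    indptr, indices = adj.indptr, adj.indices
    valid = mesh.valid_mask

    from collections import deque

    frontiers = [deque() for _ in range(n_networks)]
    counts = np.zeros(n_networks, dtype=int)
    for k, s in enumerate(seeds):
        net = k % n_networks
        labels[s] = net + 1
        frontiers[net].append(int(s))
        counts[net] += 1
    remaining = int(valid.sum()) - len(seeds)
    # always grow the smallest network one vertex at a time: keeps areas
    # balanced regardless of where the seeds landed
    while remaining > 0:
        order = np.argsort(counts, kind="stable")
        net = next((n for n in order if frontiers[n]), None)
        if net is None:
            # valid vertices unreachable over edges: assign nearest label
            left = np.flatnonzero(valid & (labels == 0))
            from scipy.spatial import cKDTree

            labeled = np.flatnonzero(labels > 0)
            tree = cKDTree(mesh.vertex_coords[labeled])
            _, nn = tree.query(mesh.vertex_coords[left])
            labels[left] = labels[labeled[nn]]
            break
        grown = False
        while frontiers[net] and not grown:
            v = frontiers[net][0]
            nbrs = [
                int(u)
                for u in indices[indptr[v]: indptr[v + 1]]
                if valid[u] and labels[u] == 0
            ]
            if not nbrs:
                frontiers[net].popleft()
                continue
            u = nbrs[int(rng.integers(len(nbrs)))]
            labels[u] = net + 1
            frontiers[net].append(u)
            counts[net] += 1
            remaining -= 1
            grown = True
    return labels


def synth_movie(
    grid_shape: tuple,
    T: int,
    spatial_spec: SynthesisSpec,
    temporal_phi: float = 0.8,
) -> ImageSeries:
    """Planar image sequence: AR(1) in time on smooth spatial innovations.

    Spatial innovations are Gaussian random fields with isotropic power-law
    Fourier spectrum ``|k|^(-gamma)`` (gamma = ``spatial_spec.spectrum_decay``;
    gamma = 0 gives white noise), standardized per frame.  The latent field
    follows ``F_t = phi F_{t-1} + sqrt(1 - phi^2) innovation_t`` so the
    stationary lag-1 frame correlation is ``phi``.  Valid pixels form a
    centered ellipse (a cortical-window stand-in).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not 0.0 <= abs(temporal_phi) < 1.0:
        raise ValueError("temporal_phi must satisfy |phi| < 1")
    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    rng = np.random.default_rng(spatial_spec.seed)
    gamma = spatial_spec.spectrum_decay

    ky = np.fft.fftfreq(rows)[:, None]
    kx = np.fft.fftfreq(cols)[None, :]
    kr = np.sqrt(ky ** 2 + kx ** 2)
    amp = np.ones_like(kr)
    if gamma > 0:
        with np.errstate(divide="ignore"):
            amp = np.where(kr > 0, kr ** (-gamma), 0.0)
        amp[0, 0] = 0.0

    def innovation() -> np.ndarray:
        white = rng.standard_normal((rows, cols))
        f = np.fft.ifft2(np.fft.fft2(white) * amp).real
        sd = f.std()
        return f / sd if sd > 0 else f

    frames = np.empty((T, rows, cols))
    frames[0] = innovation()
    c = np.sqrt(1.0 - temporal_phi ** 2)
    for t in range(1, T):
        frames[t] = temporal_phi * frames[t - 1] + c * innovation()
    if spatial_spec.noise_sd > 0:
        frames += rng.normal(0.0, spatial_spec.noise_sd, frames.shape)

    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    mask = ((yy - cy) / (0.45 * rows)) ** 2 + (
        (xx - cx) / (0.45 * cols)
    ) ** 2 <= 1.0
    # keep the largest connected component, as in a real imaging window
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum(mask, lab, range(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ImageSeries(frames=frames, pixel_valid=mask)
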