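"""Task-specificity and network-architecture analyses.

Two questions about what the masked extreme actually encodes:

* Pairwise specificity — fit kriging on the *conjunction* of two tasks'
  bottom-quantile masks, once with each task's values, and ask which fit
  better predicts the first task's out-of-mask activity.  If prediction
  only exploited mask location, the two would tie.

* Network prediction — use all (unthresholded) values inside one network's
  vertices to predict the rest of the cortex, asking which intrinsic
  networks support out-of-mask prediction best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kriging import LatticeKriging
from .mesh import geodesic_to_set
from .pipeline import (
    SurfaceMap,
    VertexMask,
    _resolve_lattice,
    _spearman,
    _split_config,
    threshold_mask,
)

__all__ = [
    "PairwiseReport",
    "conjunction_mask",
    "pairwise_specificity",
    "pairwise_specificity_matrix",
    "network_prediction",
]

RESTRICTIONS = ("all", "min_distance", "observed_positive")


@dataclass
class PairwiseReport:
    """Outcome of one ordered true-vs-alternative comparison."""

    task_pair: tuple
    conjunction_size: int
    rho_true: dict
    rho_alt: dict
    winner: dict
    n: dict

    def __post_init__(self) -> None:
        for r in self.winner:
            dt, da = self.rho_true[r], self.rho_alt[r]
            expected = (
                "tie" if abs(dt - da) < 1e-12
                else ("true" if dt > da else "alt")
            )
            if self.winner[r] != expected:
                raise ValueError("winner inconsistent with recorded rho")


def conjunction_mask(
    mask_a: VertexMask, mask_b: VertexMask
) -> VertexMask:
    """Intersection of two same-tail masks on one mesh."""
    if mask_a.tail != mask_b.tail:
        raise ValueError("masks must share the same tail")
    if len(mask_a.member_flags) != len(mask_b.member_flags):
        raise ValueError("masks are not on a common mesh")
    inter = mask_a.member_flags & mask_b.member_flags
    if not inter.any():
        raise ValueError(
            f"empty conjunction (sizes {mask_a.n_members} and "
            f"{mask_b.n_members})"
        )
    # effective fraction relative to the valid-vertex universe of mask A
    n_valid = mask_a.n_members / mask_a.quantile
    return VertexMask(
        member_flags=inter,
        tail=mask_a.tail,
        quantile=float(inter.sum() / n_valid),
    )


def pairwise_specificity(
    map_a: SurfaceMap,
    map_b: SurfaceMap,
    quantile: float = 0.25,
    lattice_config: dict | None = None,
    min_distance: float = 0.1,
    min_conjunction: int = 50,
) -> PairwiseReport:
    """True-vs-alternative prediction comparison for an ordered task pair.

    Both fits use the conjunction of the two bottom-quantile masks as the
    predictor set — one with task A's values, one with task B's — and both
    predictions are scored against task A's observed values over the
    complement of A's mask, under three restrictions (all vertices; farther
    than ``min_distance`` radians from the conjunction; observed z > 0).
    Each restriction records a winner; identical maps tie exactly.
    """
    if map_a.mesh is not map_b.mesh and not np.array_equal(
        map_a.mesh.vertex_coords, map_b.mesh.vertex_coords
    ):
        raise ValueError("maps must share a mesh")
    mesh = map_a.mesh
    mask_a = threshold_mask(map_a, quantile=quantile, tail="low")
    mask_b = threshold_mask(map_b, quantile=quantile, tail="low")
    conj = conjunction_mask(mask_a, mask_b)
    if conj.n_members < min_conjunction:
        raise ValueError(
            f"conjunction mask has {conj.n_members} vertices "
            f"(< {min_conjunction})"
        )
    cfg = _split_config(lattice_config)
    lattice = _resolve_lattice(cfg)
    member = conj.member_flags
    coords = mesh.vertex_coords[member]

    def _fit_predict(values: np.ndarray) -> np.ndarray:
        est = LatticeKriging(
            lattice=lattice, lam=cfg["lam"], kappa2=cfg["kappa2"],
            fixed=cfg["fixed"], normalize=cfg["normalize"],
        )
        est.fit(coords, values[member])
        out = np.full(mesh.n_vertices, np.nan)
        out[mesh.valid_mask] = est.predict(
            mesh.vertex_coords[mesh.valid_mask]
        )
        return out

    pred_true = _fit_predict(map_a.values)
    pred_alt = _fit_predict(map_b.values)

    target = mesh.valid_mask & ~mask_a.member_flags
    dist = geodesic_to_set(mesh, member)
    selections = {
        "all": target,
        "min_distance": target & (dist > min_distance),
        "observed_positive": target & (map_a.values > 0),
    }
    rho_true, rho_alt, winner, n = {}, {}, {}, {}
    for name, sel in selections.items():
        rho_true[name] = _spearman(pred_true[sel], map_a.values[sel])
        rho_alt[name] = _spearman(pred_alt[sel], map_a.values[sel])
        n[name] = int(sel.sum())
        diff = rho_true[name] - rho_alt[name]
        winner[name] = (
            "tie" if abs(diff) < 1e-12 else ("true" if diff > 0 else "alt")
        )
    return PairwiseReport(
        task_pair=(map_a.name, map_b.name),
        conjunction_size=conj.n_members,
        rho_true=rho_true,
        rho_alt=rho_alt,
        winner=winner,
        n=n,
    )


def pairwise_specificity_matrix(
    maps: list[SurfaceMap],
    quantile: float = 0.25,
    lattice_config: dict | None = None,
    min_distance: float = 0.1,
    min_conjunction: int = 50,
) -> pd.DataFrame:
    """All ordered pairs (i != j) as one long table.

    Seven maps give 42 ordered comparisons.  Reports for (A, B) and (B, A)
    are computed independently.
    """
    rows = []
    for a in maps:
        for b in maps:
            if a is b:
                continue
            rep = pairwise_specificity(
                a, b, quantile=quantile, lattice_config=lattice_config,
                min_distance=min_distance, min_conjunction=min_conjunction,
            )
            for r in RESTRICTIONS:
                rows.append(
                    {
                        "task_true": a.name,
                        "task_alt": b.name,
                        "restriction": r,
                        "conjunction_size": rep.conjunction_size,
                        "n": rep.n[r],
                        "rho_true": rep.rho_true[r],
                        "rho_alt": rep.rho_alt[r],
                        "winner": rep.winner[r],
                    }
                )
    return pd.DataFrame(rows)


def network_prediction(
    maps: SurfaceMap | list[SurfaceMap],
    network_labels: np.ndarray,
    lattice_config: dict | None = None,
    min_size: int = 50,
) -> pd.DataFrame:
    """Out-of-network prediction accuracy for each labeled network.

    For every network label (> 0): fit kriging on that network's vertices
    using the raw (unthresholded) map values, predict the complement of the
    network over valid vertices, and record the Spearman correlation with
    the observed values.  Networks smaller than ``min_size`` vertices are
    flagged and skipped.  With several maps the result is a network x task
    table.
    """
    if isinstance(maps, SurfaceMap):
        maps = [maps]
    mesh = maps[0].mesh
    network_labels = np.asarray(network_labels, dtype=int)
    if len(network_labels) != mesh.n_vertices:
        raise ValueError("label length must match vertex count")
    labels = np.unique(network_labels[mesh.valid_mask])
    labels = labels[labels > 0]
    if len(labels) < 2:
        raise ValueError("need at least 2 networks")
    cfg = _split_config(lattice_config)
    lattice = _resolve_lattice(cfg)
    rows = []
    for lab in labels:
        member = (network_labels == lab) & mesh.valid_mask
        size = int(member.sum())
        if size < min_size:
            for m in maps:
                rows.append(
                    {
                        "network": int(lab), "task": m.name, "n_network": size,
                        "n_out": 0, "spearman_rho": float("nan"),
                        "skipped": True,
                    }
                )
            continue
        coords = mesh.vertex_coords[member]
        target = mesh.valid_mask & ~member
        target_coords = mesh.vertex_coords[target]
        for m in maps:
            est = LatticeKriging(
                lattice=lattice, lam=cfg["lam"], kappa2=cfg["kappa2"],
                fixed=cfg["fixed"], normalize=cfg["normalize"],
            )
            est.fit(coords, m.values[member])
            pred = est.predict(target_coords)
            rows.append(
                {
                    "network": int(lab),
                    "task": m.name,
                    "n_network": size,
                    "n_out": int(target.sum()),
                    "spearman_rho": _spearman(pred, m.values[target]),
                    "skipped": False,
                }
            )
    return pd.DataFrame(rows)
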