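"""Readers and writers for the formats the pipeline touches.

Surface geometry and per-vertex data travel as GIFTI (``.surf.gii``,
``.func.gii``/``.shape.gii``, ``.label.gii``) via nibabel, with plain
delimited-text fallbacks; image series as HDF5 stacks or directories of
text frames; fitted models and surrogate ensembles as HDF5.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .calcium import ImageSeries
from .kriging import LatticeKriging
from .lattice import LatticeLevel, MultiresLattice
from .mesh import SphericalMesh
from .pipeline import SurfaceMap

__all__ = [
    "read_surface_mesh",
    "write_surface_mesh",
    "read_surface_map",
    "write_surface_map",
    "read_labels",
    "write_labels",
    "read_series",
    "write_series",
    "save_model",
    "load_model",
    "save_ensemble",
    "load_ensemble",
]

_TEXT_EXT = (".csv", ".tsv", ".txt")


def _read_text_column(path: Path) -> np.ndarray:
    """One-column numeric text, optional single header line."""
    delim = "," if path.suffix == ".csv" else None
    try:
        return np.loadtxt(path, delimiter=delim, ndmin=1)
    except ValueError:
        return np.loadtxt(path, delimiter=delim, skiprows=1, ndmin=1)


def read_surface_mesh(path) -> SphericalMesh:
    """Spherical surface from ``.surf.gii`` or a text triple.

    GIFTI coordinates are projected to the unit sphere (fsLR spheres carry a
    100 mm radius).  The text form is a single ``.npzlike`` base path with
    ``<base>.coords.txt``, ``<base>.triangles.txt`` and optional
    ``<base>.valid.txt`` companions, or an ``.h5`` file with datasets
    ``coords``, ``triangles``, ``valid``.
    """
    path = Path(path)
    if path.name.endswith(".surf.gii") or path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        coords = img.darrays[0].data.astype(float)
        tris = img.darrays[1].data.astype(np.int64)
        norms = np.linalg.norm(coords, axis=1, keepdims=True)
        coords = coords / norms
        return SphericalMesh(coords, tris)
    if path.suffix == ".h5":
        with h5py.File(path, "r") as f:
            return SphericalMesh(
                f["coords"][...], f["triangles"][...],
                f["valid"][...].astype(bool) if "valid" in f else None,
            )
    raise ValueError(
        f"unrecognized surface format {path.name!r}; expected .surf.gii or .h5"
    )


def write_surface_mesh(mesh: SphericalMesh, path) -> None:
    path = Path(path)
    if path.name.endswith(".surf.gii"):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertex_coords.astype(np.float32),
                    intent="NIFTI_INTENT_POINTSET",
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32),
                    intent="NIFTI_INTENT_TRIANGLE",
                ),
            ]
        )
        nib.save(img, str(path))
    elif path.suffix == ".h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=mesh.vertex_coords)
            f.create_dataset("triangles", data=mesh.triangles)
            f.create_dataset("valid", data=mesh.valid_mask.astype(np.uint8))
    else:
        raise ValueError("mesh output must be .surf.gii or .h5")


def read_surface_map(path, mesh: SphericalMesh, name=None) -> SurfaceMap:
    """Per-vertex scalars from GIFTI metric or one-column text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.endswith((".func.gii", ".shape.gii")) or path.suffix == ".gii":
        import nibabel as nib

        values = nib.load(str(path)).darrays[0].data.astype(float)
    elif path.suffix in _TEXT_EXT:
        values = _read_text_column(path)
    else:
        raise ValueError(
            f"unrecognized map format {path.name!r}; expected "
            ".func.gii/.shape.gii or .csv/.tsv/.txt"
        )
    if len(values) != mesh.n_vertices:
        raise ValueError(
            f"map has {len(values)} values but mesh has "
            f"{mesh.n_vertices} vertices"
        )
    return SurfaceMap(values, mesh, name=name or path.stem.split(".")[0])


def write_surface_map(surface_map: SurfaceMap, path) -> None:
    path = Path(path)
    if path.name.endswith(".func.gii"):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    surface_map.values.astype(np.float32),
                    intent="NIFTI_INTENT_NONE",
                )
            ]
        )
        nib.save(img, str(path))
    elif path.suffix in _TEXT_EXT:
        np.savetxt(path, surface_map.values, fmt="%.17g")
    else:
        raise ValueError("map output must be .func.gii or text")


def read_labels(path, mesh: SphericalMesh | None = None) -> np.ndarray:
    """Integer labels per vertex from ``.label.gii`` or one-column text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.endswith(".label.gii") or path.suffix == ".gii":
        import nibabel as nib

        labels = nib.load(str(path)).darrays[0].data.astype(int)
    elif path.suffix in _TEXT_EXT:
        labels = _read_text_column(path).astype(int)
    else:
        raise ValueError(
            f"unrecognized label format {path.name!r}; expected .label.gii "
            "or text"
        )
    if mesh is not None and len(labels) != mesh.n_vertices:
        raise ValueError(
            f"labels have {len(labels)} entries but mesh has "
            f"{mesh.n_vertices} vertices"
        )
    return labels


def write_labels(labels: np.ndarray, path) -> None:
    path = Path(path)
    if path.name.endswith(".label.gii"):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    np.asarray(labels, dtype=np.int32),
                    intent="NIFTI_INTENT_LABEL",
                )
            ]
        )
        nib.save(img, str(path))
    elif path.suffix in _TEXT_EXT:
        np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")
    else:
        raise ValueError("label output must be .label.gii or text")


def read_series(path) -> ImageSeries:
    """Image stack from HDF5 (datasets ``frames``, ``pixel_valid``) or a
    directory of delimited-text frames (sorted by filename)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix in _TEXT_EXT
        )
        if not files:
            raise ValueError(f"no text frames found in {path}")
        frames = np.stack([np.loadtxt(f, delimiter=",") for f in files])
        valid = np.all(np.isfinite(frames), axis=0) & (
            np.ptp(frames, axis=0) > 0
        )
        return ImageSeries(frames=frames, pixel_valid=valid)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            valid = (
                f["pixel_valid"][...].astype(bool)
                if "pixel_valid" in f
                else np.ones(frames.shape[1:], dtype=bool)
            )
        return ImageSeries(frames=frames, pixel_valid=valid)
    raise ValueError(
        f"unrecognized series format {path.name!r}; expected .h5 or a "
        "directory of text frames"
    )


def write_series(series: ImageSeries, path) -> None:
    path = Path(path)
    if path.suffix not in (".h5", ".hdf5"):
        raise ValueError("series output must be .h5")
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=series.frames)
        f.create_dataset(
            "pixel_valid", data=series.pixel_valid.astype(np.uint8)
        )


# ---------------------------------------------------------------------------
# models and ensembles

def save_model(model: LatticeKriging, path) -> None:
    """Fitted model to HDF5: coefficients, lattice, lambda, config echo."""
    if not hasattr(model, "coef_"):
        raise ValueError("model is not fitted")
    with h5py.File(path, "w") as f:
        f.attrs["domain_kind"] = model.lattice.domain_kind
        f.attrs["lambda"] = model.lambda_
        f.attrs["kappa2"] = model.kappa2
        f.attrs["fixed"] = model.fixed
        f.attrs["normalize"] = model.normalize
        f.attrs["alpha"] = model.lattice.alpha
        f.attrs["config_json"] = json.dumps(model.lattice.describe())
        f.create_dataset("coef", data=model.coef_)
        f.create_dataset("fixed_coef", data=model.fixed_coef_)
        f.create_dataset("X_train", data=model.X_train_)
        f.create_dataset("y_train", data=model.y_train_)
        for i, lv in enumerate(model.lattice.levels):
            g = f.create_group(f"level{i}")
            g.create_dataset("node_coords", data=lv.node_coords)
            g.create_dataset("neighbor_pairs", data=lv.neighbor_pairs)
            g.attrs["basis_range"] = lv.basis_range


def load_model(path) -> LatticeKriging:
    with h5py.File(path, "r") as f:
        levels = []
        i = 0
        while f"level{i}" in f:
            g = f[f"level{i}"]
            levels.append(
                LatticeLevel(
                    node_coords=g["node_coords"][...],
                    basis_range=float(g.attrs["basis_range"]),
                    neighbor_pairs=g["neighbor_pairs"][...],
                )
            )
            i += 1
        lattice = MultiresLattice(
            str(f.attrs["domain_kind"]), levels, np.asarray(f.attrs["alpha"])
        )
        model = LatticeKriging(
            lattice=lattice,
            lam=float(f.attrs["lambda"]),
            kappa2=float(f.attrs["kappa2"]),
            fixed=str(f.attrs["fixed"]),
            normalize=bool(f.attrs["normalize"]),
        )
        model.coef_ = f["coef"][...]
        model.fixed_coef_ = f["fixed_coef"][...]
        model.lambda_ = float(f.attrs["lambda"])
        model.X_train_ = f["X_train"][...]
        model.y_train_ = f["y_train"][...]
        model.n_features_in_ = model.X_train_.shape[1]
    return model


def save_ensemble(ensemble, path) -> None:
    """Spin or surrogate ensemble to HDF5 with seed and config echo."""
    from .nulls import SpinEnsemble, SurrogateEnsemble

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = ensemble.seed
        if isinstance(ensemble, SpinEnsemble):
            f.attrs["kind"] = "spin"
            f.attrs["generator_version"] = ensemble.generator_version
            f.create_dataset("maps", data=ensemble.rotated_labels)
        elif isinstance(ensemble, SurrogateEnsemble):
            f.attrs["kind"] = "surrogate"
            f.attrs["resample"] = ensemble.resample_flag
            f.create_dataset("maps", data=ensemble.surrogate_maps)
        else:
            raise TypeError(f"cannot save {type(ensemble).__name__}")


def load_ensemble(path):
    from .nulls import SpinEnsemble, SurrogateEnsemble

    with h5py.File(path, "r") as f:
        kind = str(f.attrs["kind"])
        maps = f["maps"][...]
        seed = int(f.attrs["seed"])
        if kind == "spin":
            return SpinEnsemble(
                n_rotations=maps.shape[0], seed=seed, rotated_labels=maps,
                generator_version=str(f.attrs["generator_version"]),
            )
        if kind == "surrogate":
            return SurrogateEnsemble(
                n_surrogates=maps.shape[0], seed=seed, surrogate_maps=maps,
                resample_flag=bool(f.attrs["resample"]),
            )
    raise ValueError(f"unknown ensemble kind {kind!r}")
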