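"""Planar variant of the extreme-tail prediction for image time series.

Widefield calcium frames are analysed one time point at a time: the top
quantile of valid pixels forms the predictor mask, a 2-D multiresolution
lattice kriging model is fitted on those pixels, and agreement with the
observed out-of-mask pixels is scored overall and at a minimum Euclidean
distance (25 pixels by default) from the mask.  Across frames, Fisher-z
transformed correlations are tested against chance with both a one-sample
t-test and an AR(1)-adjusted test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .kriging import LatticeKriging
from .lattice import MultiresLattice, build_planar_lattice
from .pipeline import PredictionResult, VertexMask, evaluate

__all__ = [
    "ImageSeries",
    "SeriesReport",
    "frame_predict",
    "series_analyze",
    "group_inference",
    "DEFAULT_PLANAR_CONFIG",
]

DEFAULT_PLANAR_CONFIG: dict = {
    "n_levels": 3,
    "range_multiplier": 2.5,
    "alpha": (1.0, 0.25, 0.01),
    "base_spacing": None,
    "kappa2": 0.01,
    "lam": "auto",
    "fixed": "intercept",
    "normalize": False,
}


@dataclass
class ImageSeries:
    """T x rows x cols image stack with a per-pixel validity mask."""

    frames: np.ndarray
    pixel_valid: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, rows, cols) stack, T >= 1")
        self.pixel_valid = np.asarray(self.pixel_valid, dtype=bool)
        if self.pixel_valid.shape != self.frames.shape[1:]:
            raise ValueError("pixel_valid shape must match frame shape")
        _, ncomp = ndimage.label(self.pixel_valid)
        if ncomp > 1:
            warnings.warn(
                f"valid pixels form {ncomp} connected regions", stacklevel=2
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class SeriesReport:
    """Per-frame accuracies plus across-frame group inference."""

    per_frame: pd.DataFrame
    summary: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    n_failed: int = 0


def _planar_config(lattice_config: dict | None) -> dict:
    cfg = dict(DEFAULT_PLANAR_CONFIG)
    if lattice_config:
        unknown = set(lattice_config) - set(cfg) - {"lattice"}
        if unknown:
            raise ValueError(f"unknown lattice config keys: {sorted(unknown)}")
        cfg.update(lattice_config)
    return cfg


def _distance_to_mask(
    grid_shape: tuple, member_flags: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Per-pixel distance (in pixels) to the nearest mask pixel."""
    rows, cols = grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    members = coords[member_flags]
    if metric == "euclidean":
        tree = cKDTree(members)
        d, _ = tree.query(coords)
    elif metric == "chebyshev":
        tree = cKDTree(members)
        d, _ = tree.query(coords, p=np.inf)
    else:
        raise ValueError("metric must be 'euclidean' or 'chebyshev'")
    d[member_flags] = 0.0
    return d


def frame_predict(
    frame: np.ndarray,
    valid: np.ndarray,
    quantile: float = 0.25,
    tail: str = "high",
    lattice_config: dict | None = None,
    min_distance: float = 25.0,
    distance_metric: str = "euclidean",
) -> PredictionResult:
    """Predict one frame's valid pixels from its top-quantile extreme.

    The mask is the top ``quantile`` of valid pixels (``tail="high"``; the
    low tail is available for sign-flipped analyses); the kriging fit sees
    mask pixels only and the result is evaluated on all out-of-mask valid
    pixels and on those at least ``min_distance`` pixels from the mask.
    """
    frame = np.asarray(frame, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if frame.shape != valid.shape or frame.ndim != 2:
        raise ValueError("frame and valid must be matching 2-D arrays")
    if valid.sum() < 100:
        raise ValueError("need at least 100 valid pixels")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    cfg = _planar_config(lattice_config)
    rows, cols = frame.shape
    flat = frame.ravel()
    valid_flat = valid.ravel()
    valid_idx = np.flatnonzero(valid_flat)
    vals = flat[valid_idx]
    k = max(int(round(quantile * len(valid_idx))), 1)
    order = np.argsort(vals if tail == "low" else -vals, kind="stable")
    member = np.zeros(flat.size, dtype=bool)
    member[valid_idx[order[:k]]] = True

    lattice = cfg.get("lattice")
    if not isinstance(lattice, MultiresLattice):
        lattice = build_planar_lattice(
            (rows, cols),
            n_levels=cfg["n_levels"],
            range_multiplier=cfg["range_multiplier"],
            alpha=cfg["alpha"],
            base_spacing=cfg["base_spacing"],
        )
    yy, xx = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    est = LatticeKriging(
        lattice=lattice,
        lam=cfg["lam"],
        kappa2=cfg["kappa2"],
        fixed=cfg["fixed"],
        normalize=cfg["normalize"],
    )
    est.fit(coords[member], flat[member])
    predicted = np.full(flat.size, np.nan)
    predicted[valid_flat] = est.predict(coords[valid_flat])
    observed = np.where(valid_flat, flat, np.nan)
    dist = _distance_to_mask((rows, cols), member, metric=distance_metric)
    result = PredictionResult(
        predictor_mask=VertexMask(member, tail=tail, quantile=quantile),
        predicted=predicted,
        observed=observed,
        valid=valid_flat.copy(),
        distance_to_mask=dist,
        name="frame",
        config={
            "quantile": quantile,
            "tail": tail,
            "lattice": lattice.describe(),
            "lam": est.lambda_,
            "min_distance": min_distance,
            "distance_metric": distance_metric,
        },
    )
    result.metrics = pd.DataFrame(
        [
            evaluate(result, "none"),
            evaluate(result, "min_distance", min_distance=min_distance),
        ]
    )
    return result


def series_analyze(
    series: ImageSeries,
    quantile: float = 0.25,
    tail: str = "high",
    lattice_config: dict | None = None,
    min_distance: float = 25.0,
    distance_metric: str = "euclidean",
) -> SeriesReport:
    """Independent per-frame prediction and across-frame inference.

    Each time point gets its own kriging model (no information shared across
    frames).  The report collects per-frame Spearman correlations (all
    out-of-mask and distance-restricted), their Fisher-z values, fractions
    of positive frames, and t-test / AR(1) inference on each z-series.
    """
    cfg = _planar_config(lattice_config)
    if not isinstance(cfg.get("lattice"), MultiresLattice):
        cfg["lattice"] = build_planar_lattice(
            series.grid_shape,
            n_levels=cfg["n_levels"],
            range_multiplier=cfg["range_multiplier"],
            alpha=cfg["alpha"],
            base_spacing=cfg["base_spacing"],
        )
    rows = []
    n_failed = 0
    for t in range(series.n_frames):
        try:
            res = frame_predict(
                series.frames[t],
                series.pixel_valid,
                quantile=quantile,
                tail=tail,
                lattice_config=cfg,
                min_distance=min_distance,
                distance_metric=distance_metric,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"frame {t} failed: {err}", stacklevel=2)
            n_failed += 1
            continue
        m = res.metrics.set_index("restriction")
        rho_all = m.loc["none", "spearman_rho"]
        rho_dist = m.loc["min_distance", "spearman_rho"]
        rows.append(
            {
                "frame": t,
                "rho_all": rho_all,
                "rho_dist": rho_dist,
                "z_all": _fisher_z(rho_all),
                "z_dist": _fisher_z(rho_dist),
                "n_all": int(m.loc["none", "n"]),
                "n_dist": int(m.loc["min_distance", "n"]),
            }
        )
    per_frame = pd.DataFrame(rows)
    summary: dict = {}
    inference: dict = {}
    for key in ("all", "dist"):
        rho = per_frame[f"rho_{key}"].to_numpy()
        ok = np.isfinite(rho)
        summary[f"frac_positive_{key}"] = (
            float(np.mean(rho[ok] > 0)) if ok.any() else float("nan")
        )
        summary[f"mean_rho_{key}"] = (
            float(np.mean(rho[ok])) if ok.any() else float("nan")
        )
        if ok.sum() >= 10:
            inference[key] = group_inference(rho[ok])
    return SeriesReport(
        per_frame=per_frame, summary=summary, inference=inference,
        n_failed=n_failed,
    )


def _fisher_z(rho: float) -> float:
    if not np.isfinite(rho):
        return float("nan")
    return float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))


def group_inference(rhos: np.ndarray, ar_order: int = 1) -> dict:
    """Is the average correlation greater than chance across time points?

    Fisher-z transforms the per-frame correlations, then reports (i) a
    one-sided one-sample t-test of mean z > 0, and (ii) an AR(1)-adjusted
    test: an order-``ar_order`` autoregression with intercept is fitted to
    the z series and the process mean ``c / (1 - sum(phi))`` is tested
    against zero with a delta-method standard error, which accounts for
    temporal autocorrelation of the frame series.
    """
    rhos = np.asarray(rhos, dtype=float).ravel()
    if len(rhos) < 10:
        raise ValueError("need at least 10 frames for group inference")
    if np.any(np.abs(rhos) >= 1):
        warnings.warn(
            "|rho| = 1 entries clipped before Fisher transform", stacklevel=2
        )
        rhos = np.clip(rhos, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(rhos)
    n = len(z)
    mean_z = float(z.mean())
    sd = z.std(ddof=1)
    iid_se = float(sd / np.sqrt(n))
    if sd == 0:
        t_stat, t_p = (np.inf if mean_z > 0 else 0.0), (
            0.0 if mean_z > 0 else 1.0
        )
    else:
        t_res = stats.ttest_1samp(z, 0.0, alternative="greater")
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)

    from statsmodels.tsa.ar_model import AutoReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ar_fit = AutoReg(z, lags=ar_order, trend="c").fit()
    params = ar_fit.params
    cov = ar_fit.cov_params()
    c = float(params[0])
    phi = params[1:]
    denom = 1.0 - float(np.sum(phi))
    mu = c / denom
    grad = np.empty(len(params))
    grad[0] = 1.0 / denom
    grad[1:] = c / denom ** 2
    ar_var = float(grad @ cov @ grad)
    ar_se = float(np.sqrt(max(ar_var, 0.0)))
    if ar_se > 0:
        ar_stat = mu / ar_se
    else:
        ar_stat = 0.0 if mu == 0 else np.inf * np.sign(mu)
    ar_p = float(stats.norm.sf(ar_stat))
    return {
        "n": n,
        "mean_z": mean_z,
        "iid_se": iid_se,
        "t_stat": t_stat,
        "t_p": t_p,
        "ar_order": ar_order,
        "ar_phi": [float(p) for p in phi],
        "ar_mean": float(mu),
        "ar_se": ar_se,
        "ar_stat": float(ar_stat),
        "ar_p": ar_p,
    }
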