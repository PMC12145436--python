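"""The kriging estimator: dense-oracle equivalence, interpolation limit,
linearity, regularization selection and sklearn API conventions."""

import numpy as np
import pytest
from sklearn.base import clone

from brainkrig import (
    LatticeKriging,
    basis_matrix,
    build_planar_lattice,
    sar_precision,
    select_lambda,
)
from brainkrig.nulls import random_rotation


def _random_sphere_points(rng, n):
    pts = rng.standard_normal((n, 3))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _dense_penalized_solution(lattice, x, y, lam, kappa2=0.01):
    """Independent dense closed form: joint normal equations for
    (intercept, coefficients) of the penalized least squares problem."""
    phi = basis_matrix(lattice, x).toarray()
    blocks = [
        sar_precision(lv, kappa2).toarray() / a
        for lv, a in zip(lattice.levels, lattice.alpha)
    ]
    from scipy.linalg import block_diag

    q = block_diag(*blocks)
    d = np.column_stack([np.ones(len(x)), phi])
    pen = np.zeros((d.shape[1], d.shape[1]))
    pen[1:, 1:] = lam * q
    theta = np.linalg.solve(d.T @ d + pen, d.T @ y)
    return theta


class TestOracleEquivalence:
    def test_sphere_matches_dense_closed_form(self, lattice2, rng):
        x = _random_sphere_points(rng, 150)
        y = rng.standard_normal(150)
        lam = 0.7
        est = LatticeKriging(lattice=lattice2, lam=lam).fit(x, y)
        theta = _dense_penalized_solution(lattice2, x, y, lam)
        xq = _random_sphere_points(rng, 60)
        pred = est.predict(xq)
        oracle = theta[0] + basis_matrix(lattice2, xq).toarray() @ theta[1:]
        assert np.allclose(pred, oracle, rtol=1e-8, atol=1e-10)

    def test_plane_matches_dense_closed_form(self, rng):
        lat = build_planar_lattice((32, 32), n_levels=2, base_spacing=8.0,
                                   alpha=(1.0, 0.3))
        x = rng.uniform(0, 31, size=(120, 2))
        y = rng.standard_normal(120)
        est = LatticeKriging(lattice=lat, lam=0.3).fit(x, y)
        theta = _dense_penalized_solution(lat, x, y, 0.3)
        xq = rng.uniform(0, 31, size=(40, 2))
        oracle = theta[0] + basis_matrix(lat, xq).toarray() @ theta[1:]
        assert np.allclose(est.predict(xq), oracle, rtol=1e-8, atol=1e-10)


class TestInterpolationLimit:
    def test_tiny_lambda_reproduces_training_values(self, rng):
        from brainkrig import build_sphere_lattice

        lat = build_sphere_lattice(1, base_subdivision=2, alpha=(1.0,))
        x = _random_sphere_points(rng, 30)
        y = rng.standard_normal(30)
        est = LatticeKriging(lattice=lat, lam=1e-10).fit(x, y)
        assert np.max(np.abs(est.predict(x) - y)) < 1e-4

    def test_constant_field_reproduced_by_intercept(self, lattice1, rng):
        x = _random_sphere_points(rng, 40)
        y = np.full(40, 5.0)
        est = LatticeKriging(lattice=lattice1, lam=1.0).fit(x, y)
        assert np.allclose(est.predict(_random_sphere_points(rng, 30)), 5.0,
                           atol=1e-6)
        assert np.max(np.abs(est.coef_)) < 1e-6


class TestLinearity:
    def test_superposition_at_fixed_lambda(self, lattice1, rng):
        x = _random_sphere_points(rng, 60)
        y1 = rng.standard_normal(60)
        y2 = rng.standard_normal(60)
        kw = dict(lattice=lattice1, lam=0.2)
        p1 = LatticeKriging(**kw).fit(x, y1).predict(x)
        p2 = LatticeKriging(**kw).fit(x, y2).predict(x)
        p12 = LatticeKriging(**kw).fit(x, y1 + y2).predict(x)
        assert np.allclose(p12, p1 + p2, atol=1e-8)


def test_shrinkage_monotone_in_lambda(lattice1, rng):
    x = _random_sphere_points(rng, 80)
    y = rng.standard_normal(80)
    rss = []
    for lam in np.logspace(-6, 2, 9):
        est = LatticeKriging(lattice=lattice1, lam=lam).fit(x, y)
        rss.append(np.sum((est.predict(x) - y) ** 2))
    assert np.all(np.diff(rss) >= -1e-8)


def test_rotation_equivariance_on_sphere(lattice2, rng):
    x = _random_sphere_points(rng, 70)
    y = rng.standard_normal(70)
    xq = _random_sphere_points(rng, 25)
    r = random_rotation(rng)
    base = LatticeKriging(lattice=lattice2, lam=0.5).fit(x, y).predict(xq)
    rot = (
        LatticeKriging(lattice=lattice2.rotated(r), lam=0.5)
        .fit(x @ r.T, y)
        .predict(xq @ r.T)
    )
    assert np.allclose(base, rot, atol=1e-6)


class TestSelectLambda:
    def test_single_candidate_grid(self, lattice1, rng):
        x = _random_sphere_points(rng, 40)
        y = rng.standard_normal(40)
        assert select_lambda(y, x, lattice1, grid=[0.37]) == 0.37

    def test_deterministic(self, lattice1, rng):
        x = _random_sphere_points(rng, 50)
        y = rng.standard_normal(50)
        grid = np.logspace(-4, 1, 8)
        a = select_lambda(y, x, lattice1, grid=grid)
        b = select_lambda(y, x, lattice1, grid=grid)
        assert a == b

    @pytest.mark.parametrize("criterion", ["gcv", "profile_likelihood"])
    def test_noise_gets_heavier_smoothing_than_smooth_field(
        self, lattice1, criterion
    ):
        from brainkrig import basis_matrix as bm

        grid = np.logspace(-5, 3, 9)
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x = _random_sphere_points(r, 150)
            phi = bm(lattice1, x).toarray()
            c = r.standard_normal(phi.shape[1])
            smooth = phi @ c + 0.05 * r.standard_normal(150)
            noise = r.standard_normal(150) * np.std(smooth)
            lam_s = select_lambda(smooth, x, lattice1, grid=grid,
                                  criterion=criterion)
            lam_n = select_lambda(noise, x, lattice1, grid=grid,
                                  criterion=criterion)
            wins += lam_n > lam_s
        assert wins >= int(0.9 * n_rep)


class TestSklearnConventions:
    def test_get_params_clone_refit(self, lattice1, rng):
        est = LatticeKriging(lattice=lattice1, lam=0.1, kappa2=0.02)
        params = est.get_params()
        assert params["lam"] == 0.1 and params["kappa2"] == 0.02
        x = _random_sphere_points(rng, 30)
        y = rng.standard_normal(30)
        a = est.fit(x, y).predict(x)
        b = clone(est).fit(x, y).predict(x)
        assert np.array_equal(a, b)

    def test_unfitted_predict_raises(self, lattice1):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            LatticeKriging(lattice=lattice1, lam=0.1).predict(
                np.array([[0.0, 0.0, 1.0]])
            )

    def test_too_few_observations_rejected(self, lattice1, rng):
        x = _random_sphere_points(rng, 5)
        with pytest.raises(ValueError, match="10"):
            LatticeKriging(lattice=lattice1, lam=0.1).fit(
                x, np.zeros(5)
            )
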