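"""ADMM ring-elimination solver behaviour on small fixtures."""

import numpy as np
import pytest

import ringsparse.solvers as solvers_mod
from ringsparse.geometry import Image, Sinogram, build_geometry, forward_project
from ringsparse.metrics import radial_error_profile, rrmse
from ringsparse.priors import NormSpec, SmoothingSpec, prox
from ringsparse.simulate import make_phantom, make_study_case
from ringsparse.solvers import (
    SolverConfig,
    SolverDivergence,
    SolverState,
    gd_image_update,
    lambda_update,
    multiplier_update,
    solve_l2_baseline,
    solve_ring,
    suggest_alpha,
)


@pytest.fixture(scope="module")
def small_case():
    return make_study_case(1, 64, seed=2)


@pytest.fixture(scope="module")
def small_alpha(small_case):
    return suggest_alpha(small_case.geometry, rho=12.0, safety=1.8)


def _cfg(small_case, small_alpha, **kw):
    base = dict(norm=NormSpec("l1"), rho=12.0, alpha=small_alpha,
                outer_iters=50, inner_iters=2)
    base.update(kw)
    return SolverConfig(**base)


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------


def test_gd_update_stationary_at_solution(small_case, small_alpha):
    geom = small_case.geometry
    cfg = _cfg(small_case, small_alpha, inner_iters=3)
    zeros = np.zeros((geom.n_bins, geom.n_angles))
    state = SolverState(small_case.phantom, zeros, zeros)
    out = gd_image_update(state, small_case.clean, cfg)
    np.testing.assert_allclose(out.values, small_case.phantom.values, atol=1e-10)


def test_gd_single_step_from_zero_is_scaled_backprojection(small_case, small_alpha):
    geom = small_case.geometry
    cfg = _cfg(small_case, small_alpha, inner_iters=1)
    n = geom.n_pixels_side
    rng = np.random.default_rng(0)
    lam = rng.standard_normal((geom.n_bins, geom.n_angles))
    u = rng.standard_normal((geom.n_bins, geom.n_angles))
    state = SolverState(Image(np.zeros((n, n))), lam, u)
    out = gd_image_update(state, small_case.clean, cfg)
    target = (lam + small_case.clean.values + u).ravel()
    expected = cfg.alpha * cfg.rho * (geom.system_matrix_t() @ target)
    np.testing.assert_allclose(out.values.ravel(), expected, atol=1e-12)


def test_gd_decreases_quadratic_objective():
    geom = build_geometry(32, 47, 40, 360)
    phantom = make_phantom(32, "disk")
    sino = forward_project(phantom, geom)
    rho = 2.0
    alpha = suggest_alpha(geom, rho, safety=0.9)
    cfg = SolverConfig(norm=NormSpec("l1"), rho=rho, alpha=alpha,
                       outer_iters=1, inner_iters=1)
    rng = np.random.default_rng(1)
    x = rng.standard_normal(32 * 32)
    zeros = np.zeros((47, 40))
    b = sino.values.ravel()

    def D(xv):
        return 0.5 * rho * np.sum((b - geom.system_matrix() @ xv) ** 2)

    vals = [D(x)]
    state = SolverState(Image(x.reshape(32, 32)), zeros, zeros)
    for _ in range(8):
        img = gd_image_update(state, sino, cfg)
        state = SolverState(img, zeros, zeros)
        vals.append(D(img.values.ravel()))
    assert np.all(np.diff(vals) <= 1e-9)


def test_lambda_update_zero_residual_gives_zero(small_case, small_alpha):
    geom = small_case.geometry
    cfg = _cfg(small_case, small_alpha)
    # choose u = Ax − b so that d = 0
    x = small_case.phantom
    Ax = (geom.system_matrix() @ x.values.ravel()).reshape(
        geom.n_bins, geom.n_angles
    )
    u = Ax - small_case.clean.values
    state = SolverState(x, np.zeros_like(u), u)
    for kind, delta in (("l1", None), ("l0", None), ("hl1", 0.5), ("hl0", 0.5)):
        cfg2 = _cfg(small_case, small_alpha, norm=NormSpec(kind, delta))
        lam = lambda_update(state, small_case.clean, cfg2)
        np.testing.assert_allclose(lam, 0.0, atol=1e-12)


def test_lambda_update_soft_threshold_single_entry(small_case, small_alpha):
    geom = small_case.geometry
    R, T = geom.n_bins, geom.n_angles
    cfg = _cfg(small_case, small_alpha, rho=0.5)  # μ = 2
    n = geom.n_pixels_side
    # engineer d: x = 0, u = −b everywhere except one entry where u = −b − 5
    u = -small_case.clean.values.copy()
    u[10, 3] -= 5.0
    state = SolverState(Image(np.zeros((n, n))), np.zeros((R, T)), u)
    lam = lambda_update(state, small_case.clean, cfg)
    assert lam[10, 3] == pytest.approx(3.0)
    lam[10, 3] = 0.0
    np.testing.assert_allclose(lam, 0.0, atol=1e-12)


def test_lambda_update_angular_mean_cancellation(small_case, small_alpha):
    geom = small_case.geometry
    R, T = geom.n_bins, geom.n_angles
    cfg = _cfg(small_case, small_alpha, angular_constrained=True)
    balanced = np.zeros(T)
    balanced[: T // 2] = 4.0
    balanced[T // 2 : 2 * (T // 2)] = -4.0  # exact cancellation under the mean
    u = -small_case.clean.values.copy()
    u[7, :] -= balanced
    n = geom.n_pixels_side
    state = SolverState(Image(np.zeros((n, n))), np.zeros((R, T)), u)
    lam = lambda_update(state, small_case.clean, cfg)
    np.testing.assert_allclose(lam[7], 0.0, atol=1e-12)


def test_multiplier_update_rules(small_case):
    geom = small_case.geometry
    R, T = geom.n_bins, geom.n_angles
    n = geom.n_pixels_side
    # u = 0, λ = 0, x = 0 → u = b
    state = SolverState(Image(np.zeros((n, n))), np.zeros((R, T)), np.zeros((R, T)))
    u = multiplier_update(state, small_case.clean)
    np.testing.assert_allclose(u, small_case.clean.values, atol=1e-14)
    # constraint satisfied (λ = Ax − b) → unchanged
    Ax = (geom.system_matrix() @ small_case.phantom.values.ravel()).reshape(R, T)
    lam = Ax - small_case.clean.values
    u0 = np.random.default_rng(0).standard_normal((R, T))
    state = SolverState(small_case.phantom, lam, u0)
    np.testing.assert_allclose(multiplier_update(state, small_case.clean), u0, atol=1e-12)


# ---------------------------------------------------------------------------
# full solves
# ---------------------------------------------------------------------------


def test_single_iteration_matches_hand_computation(small_case, small_alpha):
    geom = small_case.geometry
    cfg = _cfg(small_case, small_alpha, outer_iters=1, inner_iters=1)
    res = solve_ring(small_case.corrupted, geom, cfg)
    A = geom.system_matrix()
    AT = geom.system_matrix_t()
    b = small_case.corrupted.values.ravel()
    x1 = cfg.alpha * cfg.rho * (AT @ b)  # one GD step from 0
    d = A @ x1 - b
    lam1 = prox(d, cfg.mu, cfg.norm)
    np.testing.assert_allclose(res.image.values.ravel(), x1, atol=1e-12)
    np.testing.assert_allclose(res.imperfect.ravel(), lam1, atol=1e-12)
    assert len(res.history) == 1


def test_solver_deterministic(small_case, small_alpha):
    cfg = _cfg(small_case, small_alpha, outer_iters=20)
    a = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    b = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    np.testing.assert_array_equal(a.image.values, b.image.values)
    np.testing.assert_array_equal(a.imperfect, b.imperfect)


def test_clean_sinogram_yields_negligible_lambda(small_case, small_alpha):
    """With no corruption the sparse component stays (essentially) empty and
    the reconstruction is at least as good as the ℓ2 baseline's."""
    geom = small_case.geometry
    cfg = _cfg(small_case, small_alpha, outer_iters=600)
    res = solve_ring(small_case.clean, geom, cfg, reference=small_case.phantom)
    bmax = np.abs(small_case.clean.values).max()
    assert np.max(np.abs(res.imperfect)) < 1e-2 * bmax
    assert np.mean(res.imperfect != 0) < 0.05  # λ stays sparse without corruption
    cfg2 = SolverConfig(norm=NormSpec("l2"), rho=1.0,
                        alpha=suggest_alpha(geom, 1.0, safety=1.8),
                        outer_iters=400, inner_iters=2)
    res2 = solve_l2_baseline(small_case.clean, geom, cfg2, reference=small_case.phantom)
    assert res.history[-1].rrmse <= res2.history[-1].rrmse * 1.2


def test_constrained_support_recovery(small_case, small_alpha):
    cfg = _cfg(small_case, small_alpha, outer_iters=200, angular_constrained=True)
    res = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    bad = np.sort(np.where(np.any(small_case.true_lambda != 0, axis=1))[0])
    top = np.sort(np.argsort(np.abs(res.imperfect[:, 0]))[-len(bad):])
    np.testing.assert_array_equal(top, bad)
    # sign convention: recovered λ matches the injected λ_true
    signs = np.sign(res.imperfect[bad, 0]) == np.sign(small_case.true_lambda[bad, 0])
    assert np.all(signs)


def test_constrained_lambda_bitwise_constant_across_angles(small_case, small_alpha):
    cfg = _cfg(small_case, small_alpha, outer_iters=30, angular_constrained=True)
    res = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    assert np.all(res.imperfect == res.imperfect[:, :1])


def test_primal_residual_converges(small_case, small_alpha):
    cfg = _cfg(small_case, small_alpha, outer_iters=600)
    res = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    bnorm = np.linalg.norm(small_case.corrupted.values)
    assert res.residuals[-1] / bnorm < 1e-3


def test_residual_tol_early_stop(small_case, small_alpha):
    cfg = _cfg(small_case, small_alpha, outer_iters=600, residual_tol=1e-2)
    res = solve_ring(small_case.corrupted, small_case.geometry, cfg)
    assert len(res.history) < 600


def test_variants_differ_only_in_prox(small_case, small_alpha, monkeypatch):
    """Running the ℓ0 config with the prox patched to soft thresholding
    reproduces the ℓ1 run exactly — the code paths are otherwise shared."""
    geom = small_case.geometry
    cfg_l1 = _cfg(small_case, small_alpha, outer_iters=15)
    ref = solve_ring(small_case.corrupted, geom, cfg_l1)

    def fake_prox(y, mu, spec):
        return prox(y, mu, NormSpec("l1"))

    monkeypatch.setattr(solvers_mod, "prox", fake_prox)
    cfg_l0 = _cfg(small_case, small_alpha, outer_iters=15, norm=NormSpec("l0"))
    out = solve_ring(small_case.corrupted, geom, cfg_l0)
    np.testing.assert_array_equal(out.image.values, ref.image.values)
    np.testing.assert_array_equal(out.imperfect, ref.imperfect)


def test_divergence_raises_with_alpha_hint(small_case):
    cfg = SolverConfig(norm=NormSpec("l1"), rho=2.0, alpha=1e150,
                       outer_iters=50, inner_iters=2)
    with pytest.raises(SolverDivergence, match="alpha"):
        solve_ring(small_case.corrupted, small_case.geometry, cfg)


# ---------------------------------------------------------------------------
# ℓ2 baseline
# ---------------------------------------------------------------------------


def test_l2_requires_l2_norm(small_case, small_alpha):
    with pytest.raises(ValueError):
        solve_l2_baseline(small_case.clean, small_case.geometry,
                          _cfg(small_case, small_alpha))


def test_l2_zero_data_zero_reconstruction(small_case):
    geom = small_case.geometry
    cfg = SolverConfig(norm=NormSpec("l2"), rho=1.0,
                       alpha=suggest_alpha(geom, 1.0), outer_iters=10, inner_iters=2)
    zero = Sinogram(np.zeros((geom.n_bins, geom.n_angles)), geom)
    res = solve_l2_baseline(zero, geom, cfg)
    assert np.all(res.image.values == 0.0)
    assert np.all(res.imperfect == 0.0)


def test_l2_monotone_rrmse_on_clean_data(small_case):
    geom = small_case.geometry
    cfg = SolverConfig(norm=NormSpec("l2"), rho=1.0,
                       alpha=suggest_alpha(geom, 1.0, safety=0.9),
                       outer_iters=100, inner_iters=2)
    res = solve_l2_baseline(small_case.clean, geom, cfg, reference=small_case.phantom)
    assert np.all(np.diff(res.rrmse_curve) <= 1e-10)


def test_l2_retains_ring_structure(small_case):
    geom = small_case.geometry
    cfg = SolverConfig(norm=NormSpec("l2"), rho=1.0,
                       alpha=suggest_alpha(geom, 1.0, safety=1.8),
                       outer_iters=300, inner_iters=2)
    res = solve_l2_baseline(small_case.corrupted, geom, cfg)
    prof = radial_error_profile(res.image, small_case.phantom)
    bad = np.where(np.any(small_case.true_lambda != 0, axis=1))[0]
    centre = (geom.n_bins - 1) / 2
    radii = [int(round(abs(b - centre))) for b in bad]
    radii = [r for r in radii if 0 < r < len(prof)]
    ring_err = max(prof[r] for r in radii)
    assert ring_err >= 3 * np.median(prof[prof > 0])
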