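import math

import numpy as np
import pytest

from hexbind.constants import rt
from hexbind.free_energy import (
    LambdaSeries,
    PMFProfile,
    UmbrellaWindow,
    UmbrellaWindowSet,
    bound_volume,
    combine_binding,
    dg_to_kd,
    kd_to_dg,
    symmetry_correction,
    ti_integrate,
    volume_correction,
    well_depth,
    wham_pmf,
)
from hexbind.synthetic import (
    PMFSpec,
    sample_bound_positions,
    sample_umbrella_windows,
)

RT300 = rt(300.0)


# ---------------------------------------------------------------------------
# thermodynamic integration


@pytest.mark.parametrize(
    "lambdas,dudl,expected",
    [
        (np.linspace(0, 1, 5), np.full(5, -3.7), -3.7),  # constant integrand
        (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 2.0]), 1.0),  # 2λ
    ],
)
def test_ti_trapezoid_exact_for_linear(lambdas, dudl, expected):
    dg, sigma = ti_integrate(LambdaSeries(lambdas, dudl, np.zeros_like(dudl)))
    assert dg == pytest.approx(expected, abs=1e-12)
    assert sigma == 0.0


def test_ti_exact_for_piecewise_linear_on_own_grid(rng):
    lam = np.sort(np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 9)]))
    vals = rng.normal(0, 5, lam.size)
    dg, _ = ti_integrate(LambdaSeries(lam, vals, np.zeros_like(vals)))
    exact = sum(
        (lam[i + 1] - lam[i]) * (vals[i] + vals[i + 1]) / 2.0
        for i in range(lam.size - 1)
    )
    assert dg == pytest.approx(exact, abs=1e-12)


def test_ti_sigma_propagates_through_weights():
    lam = np.linspace(0, 1, 3)
    sem = np.array([0.1, 0.2, 0.1])
    _, sigma = ti_integrate(LambdaSeries(lam, np.zeros(3), sem))
    weights = np.array([0.25, 0.5, 0.25])
    assert sigma == pytest.approx(np.sqrt(np.sum((weights * sem) ** 2)))


def test_ti_needs_two_points():
    with pytest.raises(ValueError):
        ti_integrate(LambdaSeries(np.array([0.0]), np.array([1.0]), np.array([0.0])))


def test_lambda_grid_validation():
    with pytest.raises(ValueError):
        LambdaSeries(np.array([0.0, 0.5, 0.5, 1.0]), np.zeros(4), np.zeros(4))


# ---------------------------------------------------------------------------
# WHAM


def test_unbiased_window_gives_flat_pmf(rng):
    """k = 0 and uniform samples: the PMF is flat within counting noise."""
    samples = rng.uniform(0.0, 1.0, 200_000)
    ws = UmbrellaWindowSet(
        windows=[UmbrellaWindow(center=0.5, spring_k=0.0, samples=samples)],
        temperature=300.0,
    )
    prof = wham_pmf(ws, n_bins=20)
    spread = np.nanmax(prof.free_energy) - np.nanmin(prof.free_energy)
    assert spread <= 2.0 * np.nanmax(prof.uncertainty) * 2.0


def test_wham_recovers_harmonic_pmf():
    spec = PMFSpec(form="harmonic", curvature=2.0, center=0.0)
    ws = sample_umbrella_windows(
        spec, np.linspace(-2, 2, 17), spring_k=10.0, n_per_window=20_000, seed=3
    )
    prof = wham_pmf(ws, n_bins=80)
    x, g = prof.bin_centers, prof.free_energy
    mask = (np.abs(x) < 1.5) & ~np.isnan(g)
    recovered = g - np.nanmin(g)
    assert np.nanmax(np.abs(recovered[mask] - 0.5 * 2.0 * x[mask] ** 2)) <= 0.1


def _brute_force_wham_shifts(windows, edges, kt, iters=200_000):
    """Plain-Python fixed-point iteration of the discrete WHAM equations,
    run far past convergence — the independent oracle."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    for w in windows:
        counts += np.histogram(w.samples, bins=edges)[0]
    f = [0.0 for _ in windows]
    for _ in range(iters):
        p = []
        for j, c in enumerate(centers):
            denom = 0.0
            for i, w in enumerate(windows):
                bias = 0.5 * w.spring_k * (c - w.center) ** 2
                denom += w.samples.size * math.exp((f[i] - bias) / kt)
            p.append(counts[j] / denom if denom > 0 else 0.0)
        f_new = []
        for w in windows:
            z = sum(
                pj * math.exp(-0.5 * w.spring_k * (c - w.center) ** 2 / kt)
                for pj, c in zip(p, centers)
            )
            f_new.append(-kt * math.log(z))
        f_new = [v - f_new[0] for v in f_new]
        if max(abs(a - b) for a, b in zip(f, f_new)) < 1e-15:
            f = f_new
            break
        f = f_new
    return np.array(f)


def test_wham_shifts_match_brute_force_fixed_point(rng):
    """Vectorised solver equals exact enumeration of the WHAM fixed point
    on a small two-window, 10-bin problem."""
    w1 = UmbrellaWindow(center=-0.3, spring_k=4.0, samples=rng.normal(-0.3, 0.4, 400))
    w2 = UmbrellaWindow(center=0.3, spring_k=4.0, samples=rng.normal(0.3, 0.4, 400))
    ws = UmbrellaWindowSet(windows=[w1, w2], temperature=300.0)
    prof = wham_pmf(ws, n_bins=10, tol=1e-14)
    allsamp = np.concatenate([w1.samples, w2.samples])
    edges = np.linspace(allsamp.min(), allsamp.max(), 11)
    oracle = _brute_force_wham_shifts([w1, w2], edges, rt(300.0))
    assert np.max(np.abs(prof.window_shifts - oracle)) <= 1e-10


def test_wham_nonconvergence_raises(rng):
    w1 = UmbrellaWindow(center=-1.0, spring_k=5.0, samples=rng.normal(-1, 0.3, 500))
    w2 = UmbrellaWindow(center=1.0, spring_k=5.0, samples=rng.normal(1, 0.3, 500))
    ws = UmbrellaWindowSet(windows=[w1, w2])
    with pytest.raises(RuntimeError, match="converge"):
        wham_pmf(ws, n_bins=30, tol=1e-14, max_iter=2)


def test_wham_translation_invariance(rng):
    """Shifting centers and samples by a constant translates the PMF's
    coordinate axis without changing its values."""
    spec = PMFSpec(form="harmonic", curvature=3.0, center=0.0)
    ws = sample_umbrella_windows(
        spec, np.linspace(-1, 1, 9), spring_k=12.0, n_per_window=4000, seed=11
    )
    shift = 7.0
    ws2 = UmbrellaWindowSet(
        windows=[
            UmbrellaWindow(w.center + shift, w.spring_k, w.samples + shift)
            for w in ws.windows
        ],
        temperature=ws.temperature,
    )
    p1 = wham_pmf(ws, n_bins=40)
    p2 = wham_pmf(ws2, n_bins=40)
    assert np.allclose(p2.bin_centers - shift, p1.bin_centers, atol=1e-9)
    assert np.allclose(p2.free_energy, p1.free_energy, equal_nan=True, atol=1e-9)


def test_wham_uncertainty_shrinks_with_sqrt_samples():
    spec = PMFSpec(form="harmonic", curvature=2.0, center=0.0)
    small = sample_umbrella_windows(
        spec, np.linspace(-1, 1, 9), spring_k=10.0, n_per_window=5000, seed=21
    )
    big = sample_umbrella_windows(
        spec, np.linspace(-1, 1, 9), spring_k=10.0, n_per_window=10000, seed=21
    )
    u_small = np.nanmedian(wham_pmf(small, n_bins=30).uncertainty)
    u_big = np.nanmedian(wham_pmf(big, n_bins=30).uncertainty)
    assert u_small / u_big == pytest.approx(np.sqrt(2.0), rel=0.10)


# ---------------------------------------------------------------------------
# well depth and corrections


def test_well_depth_examples():
    x = np.linspace(-2, 14, 100)
    g = np.zeros_like(x)
    g[(x > -1) & (x < 1)] = -1.83
    prof = PMFProfile(bin_centers=x, free_energy=g)
    w0 = well_depth(prof, (-1.5, 1.5), (10.0, 14.0))
    assert w0 == pytest.approx(-1.83)
    flat = PMFProfile(bin_centers=x, free_energy=np.zeros_like(x))
    assert well_depth(flat, (-1, 1), (10, 14)) == pytest.approx(0.0)
    shifted = PMFProfile(bin_centers=x, free_energy=g + 5.0)
    assert well_depth(shifted, (-1.5, 1.5), (10.0, 14.0)) == pytest.approx(-1.83)


def test_well_depth_empty_range_errors():
    prof = PMFProfile(bin_centers=np.linspace(0, 1, 10),
                      free_energy=np.zeros(10))
    with pytest.raises(ValueError):
        well_depth(prof, (5.0, 6.0), (0.0, 1.0))


def test_symmetry_correction():
    assert symmetry_correction(1) == 0.0
    assert symmetry_correction(3, 300.0) == pytest.approx(-RT300 * math.log(3))
    assert symmetry_correction(3, 300.0) == pytest.approx(-0.655, abs=0.001)
    assert symmetry_correction(3, override=-0.36) == -0.36
    with pytest.raises(ValueError):
        symmetry_correction(0)


def test_volume_correction():
    from hexbind.constants import V0_STANDARD_STATE

    assert volume_correction(V0_STANDARD_STATE, 300.0) == pytest.approx(0.0)
    assert volume_correction(164.1, 300.0) == pytest.approx(1.38, abs=0.005)
    assert volume_correction(V0_STANDARD_STATE / 2, 300.0) == pytest.approx(
        RT300 * math.log(2)
    )
    with pytest.raises(ValueError):
        volume_correction(0.0)


def test_bound_volume_gaussian_estimator():
    pos, analytic = sample_bound_positions(np.eye(3), 100_000, seed=7)
    v = bound_volume(pos)
    assert analytic == pytest.approx((2 * math.pi * math.e) ** 1.5)
    assert v == pytest.approx(analytic, rel=0.02)
    # scaling: doubling every axis multiplies the volume by 8
    assert bound_volume(pos * 2.0) == pytest.approx(8.0 * v, rel=1e-9)
    # anisotropic: det factorisation
    pos3, analytic3 = sample_bound_positions(np.diag([1.0, 4.0, 9.0]), 100_000, seed=8)
    assert analytic3 == pytest.approx(6.0 * (2 * math.pi * math.e) ** 1.5)
    assert bound_volume(pos3) == pytest.approx(analytic3, rel=0.02)


def test_bound_volume_degenerate_inputs():
    with pytest.raises(ValueError):
        bound_volume(np.zeros((5, 3)))
    flat = np.zeros((100, 3))
    flat[:, 0] = np.linspace(0, 1, 100)
    with pytest.raises(ValueError):
        bound_volume(flat)


# ---------------------------------------------------------------------------
# decomposition and K_d conversion


def test_combine_binding_arithmetic_is_exact():
    dec = combine_binding(-1.83, -0.36, 1.38, 300.0)
    assert dec.dg_total == pytest.approx(-0.81, abs=1e-12)
    assert dec.kd == pytest.approx(math.exp(-0.81 / RT300), rel=1e-12)
    zero = combine_binding(0.0, 0.0, 0.0, 300.0)
    assert zero.dg_total == 0.0 and zero.kd == pytest.approx(1.0)
    # plain addition even when printed sources round differently
    assert combine_binding(-6.23, -0.36, 3.2, 300.0).dg_total == pytest.approx(
        -3.39, abs=1e-12
    )


def test_combine_binding_uncertainty_quadrature():
    dec = combine_binding(-1.83, -0.36, 1.38, 300.0, sigma_w0=0.28, sigma_vol=0.22)
    assert dec.sigma_total == pytest.approx(math.hypot(0.28, 0.22))
    assert dec.sigma_kd == pytest.approx(dec.kd * dec.sigma_total / RT300)


def test_dg_kd_round_trip_and_monotonicity(rng):
    assert dg_to_kd(0.0) == 1.0
    for dg in rng.uniform(-10, 5, 20):
        assert kd_to_dg(dg_to_kd(dg)) == pytest.approx(dg, rel=1e-12, abs=1e-12)
    dgs = np.sort(rng.uniform(-10, 5, 20))
    kds = [dg_to_kd(v) for v in dgs]
    assert all(a < b for a, b in zip(kds, kds[1:]))


def test_full_umbrella_chain_recovers_analytic_kd():
    """wham_pmf -> well_depth -> combine_binding -> K_d reproduces the
    generator's closed-form K_d within 10% (Gaussian-well PMF)."""
    spec = PMFSpec(form="gaussian_well", depth=3.0, width=0.5, center=0.0)
    ws = sample_umbrella_windows(
        spec, np.linspace(-1.5, 6.0, 31), spring_k=8.0, n_per_window=50_000, seed=5
    )
    prof = wham_pmf(ws, n_bins=120, plateau_range=(4.0, 6.0))
    w0 = well_depth(prof, (-1.0, 1.0), (4.0, 6.0))
    dg_vol = volume_correction(164.1, 300.0)
    dec = combine_binding(w0, symmetry_correction(1), dg_vol, 300.0)
    kd_true = dg_to_kd(spec.analytic_well_depth() + dg_vol, 300.0)
    assert dec.kd == pytest.approx(kd_true, rel=0.10)
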