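"""Back-projection geometry factors, symmetry orbits, filters, and equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fansym.phantom import uniform_disk_phantom
from fansym.projection import FanBeamGeometry, Sinogram, project_analytic
from fansym.recon import (
    OpCounter,
    backproject_naive,
    backproject_symmetry,
    build_symmetry_orbits,
    compute_U,
    compute_sprime,
    cos_preweight,
    filter_sinogram,
    ramp_filter,
    ramp_kernel,
    reconstruct,
)

# ------------------------------------------------------------- U and s'


@pytest.mark.parametrize(
    "r, phi, beta, D, expected",
    [
        (0.0, 123.0, 45.0, 4.0, 1.0),       # r = 0: sin term vanishes
        (2.0, 0.0, 90.0, 4.0, 1.5),         # r = D/2, β−φ = 90°
        (2.0, 30.0, 60.0, 4.0, 1.25),       # r = D/2, β−φ = 30°, sin = 1/2
    ],
)
def test_compute_U_examples(r, phi, beta, D, expected):
    assert compute_U(r, phi, beta, D) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "r, phi, beta, D, expected",
    [
        (0.0, 10.0, 200.0, 4.0, 0.0),
        (1.7, 33.0, 33.0, 4.0, 1.7),                      # β−φ = 0 -> s' = r
        (0.5, 0.0, 30.0, 1.0, math.sqrt(3.0) / 5.0),      # direct evaluation
    ],
)
def test_compute_sprime_examples(r, phi, beta, D, expected):
    assert compute_sprime(r, phi, beta, D) == pytest.approx(expected, abs=1e-12)


def test_geometry_factors_reject_r_at_or_beyond_D():
    for fn in (compute_U, compute_sprime):
        with pytest.raises(ValueError):
            fn(4.0, 0.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            fn(-0.1, 0.0, 0.0, 4.0)


def _draws(count, seed=1234):
    rng = np.random.default_rng(seed)
    D = rng.uniform(2.0, 10.0, count)
    r = rng.uniform(0.0, 0.95, count) * D
    phi = rng.uniform(0.0, 360.0, count)
    beta = rng.uniform(0.0, 360.0, count)
    return r, phi, beta, D


def test_quarter_turn_trig_identities():
    """sin/cos shift identities for 90°, 180°, 270° as used by the orbit sharing."""
    alpha = np.radians(np.linspace(0, 720, 1441))
    np.testing.assert_allclose(np.sin(alpha + np.pi / 2), np.cos(alpha), atol=1e-12)
    np.testing.assert_allclose(np.cos(alpha + np.pi / 2), -np.sin(alpha), atol=1e-12)
    np.testing.assert_allclose(np.sin(alpha + np.pi), -np.sin(alpha), atol=1e-12)
    np.testing.assert_allclose(np.cos(alpha + np.pi), -np.cos(alpha), atol=1e-12)
    np.testing.assert_allclose(np.sin(alpha + 3 * np.pi / 2), -np.cos(alpha), atol=1e-12)
    np.testing.assert_allclose(np.cos(alpha + 3 * np.pi / 2), np.sin(alpha), atol=1e-12)


def test_joint_quarter_turn_invariance():
    """U and s' are unchanged when φ and β advance together by k·90°.

    Sampled over 10^4 random (r, φ, β, D) draws to 1e-12 relative.
    """
    r, phi, beta, D = _draws(10_000)
    # D varies per draw; evaluate one draw batch per distinct D via normalization:
    # U and s'/D depend only on (r/D, beta-phi), so scale to unit D exactly.
    for shift in (90.0, 180.0, 270.0):
        for a, b in ((compute_U, 1.0), (compute_sprime, None)):
            base = np.array([a(ri, pi, bi, Di) for ri, pi, bi, Di in
                             zip(r[:200], phi[:200], beta[:200], D[:200])])
            shifted = np.array([a(ri, pi + shift, bi + shift, Di) for ri, pi, bi, Di in
                                zip(r[:200], phi[:200], beta[:200], D[:200])])
            np.testing.assert_allclose(shifted, base, rtol=1e-12, atol=1e-12)
        # vectorized over the full 10^4 draws at fixed D
        u0 = compute_U(r / D, phi, beta, 1.0)
        u1 = compute_U(r / D, phi + shift, beta + shift, 1.0)
        np.testing.assert_allclose(u1, u0, rtol=1e-12)
        s0 = compute_sprime(r / D, phi, beta, 1.0)
        s1 = compute_sprime(r / D, phi + shift, beta + shift, 1.0)
        np.testing.assert_allclose(s1, s0, rtol=1e-12, atol=1e-12)


def test_cross_quadrant_closed_forms():
    """Rotating only the pixel by 90° swaps sin for cos:
    U(r, φ+90, β) = (D − r cos(β−φ))/D and
    s'(r, φ+90, β) = D r sin(β−φ)/(D − r cos(β−φ)).
    """
    r, phi, beta, D = _draws(10_000, seed=99)
    rho, theta = r / D, np.radians(beta - phi)
    u = compute_U(rho, phi + 90.0, beta, 1.0)
    np.testing.assert_allclose(u, 1.0 - rho * np.cos(theta), rtol=1e-12)
    s = compute_sprime(rho, phi + 90.0, beta, 1.0)
    np.testing.assert_allclose(
        s, rho * np.sin(theta) / (1.0 - rho * np.cos(theta)), rtol=1e-12, atol=1e-12
    )


@given(
    r_frac=st.floats(0, 0.95), phi=st.floats(0, 360), beta=st.floats(0, 360),
    D=st.floats(1.0, 20.0),
)
def test_U_positive_within_field(r_frac, phi, beta, D):
    assert compute_U(r_frac * D, phi, beta, D) > 0


# -------------------------------------------------------------- filters


def _flat_sino(values, bin_spacing=0.05, D=4.0):
    v = np.asarray(values, dtype=float)
    geom = FanBeamGeometry(D=D, n_views=v.shape[0], n_bins=v.shape[1],
                           bin_spacing=bin_spacing)
    return Sinogram(geom, v)


def test_cos_preweight_values():
    sino = _flat_sino(np.ones((4, 81)), bin_spacing=0.1, D=4.0)
    out = cos_preweight(sino)
    s = sino.geometry.bin_centers
    center = np.argmin(np.abs(s))
    assert out.values[0, center] == 1.0                   # s = 0 untouched
    w = out.values[0]
    assert np.all(np.diff(w[: center + 1]) >= 0)          # increasing toward center
    assert np.all(np.diff(w[center:]) <= 0)
    # s = D halves by 1/sqrt(2)
    sino2 = _flat_sino(np.ones((4, 3)), bin_spacing=4.0, D=4.0)
    np.testing.assert_allclose(cos_preweight(sino2).values[0, 2], 1 / math.sqrt(2))


def test_ramp_kernel_brute_force():
    ds = 0.05
    h = ramp_kernel(9, ds)
    m = np.arange(-8, 9)
    for mm, hv in zip(m, h):
        if mm == 0:
            assert hv == pytest.approx(1 / (4 * ds * ds))
        elif mm % 2 == 0:
            assert hv == 0.0
        else:
            assert hv == pytest.approx(-1 / (math.pi**2 * mm**2 * ds**2))


def test_ramp_filter_linearity_and_impulse():
    zero = ramp_filter(_flat_sino(np.zeros((4, 33))))
    assert np.allclose(zero.values, 0.0)
    impulse = np.zeros((4, 33))
    impulse[0, 16] = 1.0
    out = ramp_filter(_flat_sino(impulse))
    h = ramp_kernel(33, 0.05)
    np.testing.assert_allclose(out.values[0], h[16 : 16 + 33], atol=1e-12)


def test_ramp_filter_suppresses_dc():
    """A constant view filters to near zero away from the window edges.

    Brute-force kernel-sum oracle: the discrete Ram-Lak kernel sums toward 0
    as its support grows, so the response to a constant at the detector
    center is far below the kernel's peak h(0).
    """
    const = _flat_sino(np.ones((4, 257)))
    out = ramp_filter(const)
    h = ramp_kernel(257, 0.05)
    # brute-force oracle: out[i] = sum_j h[(i-j) + (n-1)] * x[j] with x = 1
    oracle = np.array([h[i : i + 257].sum() for i in range(257)])
    np.testing.assert_allclose(out.values[0], oracle, atol=1e-9)
    peak = h[len(h) // 2]
    assert abs(h.sum()) < 0.01 * peak          # kernel DC content
    assert abs(out.values[0, 128]) < 0.01 * peak  # response at the center


# --------------------------------------------------------------- orbits


@pytest.mark.parametrize("n, expected_orbits", [(1, 1), (2, 1), (3, 3), (4, 4), (5, 7)])
def test_orbit_counts(n, expected_orbits):
    orbits = build_symmetry_orbits(n, 0.1)
    assert len(orbits) == expected_orbits
    c = 1 if n % 2 else 0
    assert len(orbits) == (n * n - c) // 4 + c
    total = sum(len(o.members) for o in orbits)
    assert total == n * n
    singles = [o for o in orbits if len(o.members) == 1]
    assert len(singles) == c


def test_orbits_are_exact_rotations():
    n, p = 6, 0.25
    for orbit in build_symmetry_orbits(n, p):
        rs = [m.r for m in orbit.members]
        np.testing.assert_allclose(rs, orbit.r, rtol=1e-12)
        phis = [m.phi_deg for m in orbit.members]
        for a, b in zip(phis, phis[1:]):
            assert (b - a) % 360.0 == pytest.approx(90.0, abs=1e-9)
        # index map (i, j) -> (n-1-j, i) is the 90° rotation
        for m0, m1 in zip(orbit.members, orbit.members[1:]):
            assert (m1.i, m1.j) == (n - 1 - m0.j, m0.i)


def test_orbits_n2_brute_force():
    orbits = build_symmetry_orbits(2, 1.0)
    assert len(orbits) == 1 and len(orbits[0].members) == 4
    assert orbits[0].r == pytest.approx(math.sqrt(0.5))


# -------------------------------------------------------- back-projection


def test_backproject_zero_sinogram(head_sinogram):
    q = head_sinogram.copy_with(np.zeros_like(head_sinogram.values))
    for bp in (backproject_naive, backproject_symmetry):
        img = bp(q, 8, 0.25)
        assert np.all(img.values == 0)


def test_backproject_single_center_pixel():
    """n = 1: the sole pixel sits at r = 0, so U = 1, s' = 0 and the result is
    Δβ · Σ_β q(β, s=0)."""
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(8, 33))
    q = _flat_sino(vals)
    geom = q.geometry
    center = np.argmin(np.abs(geom.bin_centers))
    expected = vals[:, center].sum() * geom.delta_beta_rad
    for bp in (backproject_naive, backproject_symmetry):
        img = bp(q, 1, 0.1)
        assert img.values[0, 0] == pytest.approx(expected, rel=1e-12)


def test_symmetry_requires_divisible_views():
    q = _flat_sino(np.zeros((10, 33)))
    with pytest.raises(ValueError, match="divisible by 4"):
        backproject_symmetry(q, 4, 0.1)


def test_backproject_rejects_grid_reaching_source():
    q = _flat_sino(np.zeros((8, 33)), D=1.0)
    with pytest.raises(ValueError, match="source distance"):
        backproject_naive(q, 64, 0.1)


@pytest.mark.parametrize("n", [16, 17])
def test_symmetry_equals_naive(head_sinogram, n):
    """Regrouped accumulation: identical image up to summation order."""
    q = filter_sinogram(head_sinogram)
    a = backproject_naive(q, n, 2.0 / n)
    b = backproject_symmetry(q, n, 2.0 / n)
    rel = np.abs(a.values - b.values).max() / np.abs(a.values).max()
    assert rel < 1e-6


def test_symmetry_conservation(head_sinogram):
    """Sum over the image of (symmetry − naive) is zero to float tolerance."""
    q = filter_sinogram(head_sinogram)
    a = backproject_naive(q, 16, 0.125)
    b = backproject_symmetry(q, 16, 0.125)
    assert abs((b.values - a.values).sum()) < 1e-9 * np.abs(a.values).sum()


def test_counter_ratios_even_grid(head_sinogram):
    q = filter_sinogram(head_sinogram)
    cn, cs = OpCounter(), OpCounter()
    backproject_naive(q, 16, 0.125, cn)
    backproject_symmetry(q, 16, 0.125, cs)
    nv = head_sinogram.geometry.n_views
    assert cn.trig_evals == 2 * 16 * 16 * nv
    assert cn.geom_evals == 16 * 16 * nv
    assert cs.geom_evals * 4 == cn.geom_evals
    assert cs.trig_evals * 4 == cn.trig_evals


def test_counter_odd_grid_counts_center_once(head_sinogram):
    q = filter_sinogram(head_sinogram)
    cs = OpCounter()
    backproject_symmetry(q, 5, 0.125, cs)
    nv = head_sinogram.geometry.n_views
    n_quads = (25 - 1) // 4
    assert cs.geom_evals == n_quads * nv + nv  # quads share; center counted naively


def test_rotational_equivariance(head_sinogram):
    """Shifting the sinogram by a quarter turn of views rotates the image 90°."""
    q = filter_sinogram(head_sinogram)
    quarter = q.geometry.n_views // 4
    shifted = q.copy_with(np.roll(q.values, quarter, axis=0))
    base = backproject_naive(q, 16, 0.125)
    rotated = backproject_naive(shifted, 16, 0.125)
    np.testing.assert_allclose(
        rotated.values, base.rot90(1).values,
        atol=1e-9 * np.abs(base.values).max(),
    )


def test_reconstruct_method_equivalence_random_phantoms(rng):
    """Both pipelines agree on randomized off-center two-ellipse phantoms."""
    from fansym.phantom import Ellipse, PhantomSpec

    for seed in range(5):
        r2 = np.random.default_rng(seed)
        e1 = Ellipse(r2.uniform(-0.2, 0.2), r2.uniform(-0.2, 0.2),
                     r2.uniform(0.3, 0.5), r2.uniform(0.3, 0.5),
                     r2.uniform(0, 180), 1.0)
        e2 = Ellipse(r2.uniform(-0.1, 0.1), r2.uniform(-0.1, 0.1),
                     0.15, 0.1, r2.uniform(0, 180), 0.5)
        spec = PhantomSpec((e1, e2), 1.0)
        geom = FanBeamGeometry.for_object(1.0, 48, 65)
        sino = project_analytic(spec, geom)
        a, _ = reconstruct(sino, 12, 2.0 / 12, "naive")
        b, _ = reconstruct(sino, 12, 2.0 / 12, "symmetry")
        rel = np.abs(a.values - b.values).max() / np.abs(a.values).max()
        assert rel < 1e-6


def test_reconstruct_unknown_method(head_sinogram):
    with pytest.raises(ValueError, match="unknown method"):
        reconstruct(head_sinogram, 8, 0.25, "fancy")


def test_disk_reconstruction_recovers_value_small():
    """Scaled-down closed-form oracle: uniform disk interior ≈ its value."""
    spec = uniform_disk_phantom(0.5, 1.0)
    geom = FanBeamGeometry.for_object(0.5, 180, 129)
    sino = project_analytic(spec, geom)
    img, _ = reconstruct(sino, 48, 1.1 / 48, "symmetry")
    x, y = img.pixel_centers()
    interior = np.hypot(x, y) < 0.35
    assert img.values[interior].mean() == pytest.approx(1.0, rel=0.05)
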