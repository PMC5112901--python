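"""Reconstruction layer: sinc kernel, direction transport, Z0, and the SDF sum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcfp import (
    DiffeoMap,
    DirectionSet,
    DwiDataset,
    GradientScheme,
    Grid,
    ReconConfig,
    estimate_z0,
    reconstruct_sdf,
    sinc_kernel,
    transport_direction,
)
from lcfp.directions import icosphere_vertices
from lcfp.phantom import make_scheme


# ---------------------------------------------------------------- sinc kernel

@pytest.mark.parametrize(
    "arg,expected",
    [
        (0.0, 1.0),
        (np.pi, 0.0),
        (np.pi / 2, 2.0 / np.pi),
        (-np.pi / 2, 2.0 / np.pi),
    ],
)
def test_sinc_kernel_values(arg, expected):
    assert sinc_kernel(arg) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(st.floats(-1e4, 1e4, allow_nan=False))
def test_sinc_kernel_range(x):
    # global minimum of sin(x)/x is about -0.21723 at x ~ 4.4934
    v = sinc_kernel(x)
    assert -0.2173 <= v <= 1.0


def test_sinc_normalized_variant():
    # sin(pi x)/(pi x): zero at integers, 2/pi at x = 1/2
    assert sinc_kernel(1.0, normalized=True) == pytest.approx(0.0, abs=1e-12)
    assert sinc_kernel(0.5, normalized=True) == pytest.approx(2.0 / np.pi)


# --------------------------------------------------------- direction transport

def test_transport_identity_and_eigenvector():
    u = np.array([1.0, 0.0, 0.0])
    assert np.allclose(transport_direction(np.eye(3), u), u)
    assert np.allclose(transport_direction(np.diag([2.0, 1.0, 1.0]), u), u)


def test_transport_rotation():
    th = np.pi / 2
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    out = transport_direction(R, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-9)


def test_transport_degenerate_errors():
    J = np.outer([1.0, 0, 0], [1.0, 0, 0])  # rank 1: kills y
    with pytest.raises(ValueError, match="degenerate"):
        transport_direction(J, np.array([0.0, 1.0, 0.0]))


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 10**6))
def test_transport_returns_unit_norm(seed):
    rng = np.random.default_rng(seed)
    J = rng.normal(size=(3, 3))
    if abs(np.linalg.det(J)) < 1e-3:
        return
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    assert abs(np.linalg.norm(transport_direction(J, u)) - 1.0) < 1e-9


# ------------------------------------------------------------------- Z0

def test_z0_homogeneous_in_signal_scale(tiny_phantom, dirs321):
    scan, _ = tiny_phantom
    cfg = ReconConfig()
    z0 = estimate_z0(scan.dwi, cfg, dirs321)
    scaled = DwiDataset(
        signals=scan.dwi.signals * 10.0,
        scheme=scan.dwi.scheme,
        affine=scan.dwi.affine,
        brain_mask=scan.dwi.brain_mask,
        ventricle_mask=scan.dwi.ventricle_mask,
    )
    assert estimate_z0(scaled, cfg, dirs321) == pytest.approx(10.0 * z0, rel=1e-12)


def test_z0_matches_bruteforce_on_free_water(tiny_phantom, dirs321):
    """Pure free-water ventricle: Z0 equals the peak of the explicit sum."""
    scan, _ = tiny_phantom
    cfg = ReconConfig()
    z0 = estimate_z0(scan.dwi, cfg, dirs321)
    best = -np.inf
    for v in np.argwhere(scan.dwi.ventricle_mask):
        W = scan.dwi.signals[tuple(v)]
        for u in dirs321.units:
            total = 0.0
            for b, g, w in zip(scan.dwi.scheme.b_values, scan.dwi.scheme.directions, W):
                arg = cfg.sigma * math.sqrt(6.0 * cfg.d_free * b) * float(np.dot(g, u))
                total += w * (math.sin(arg) / arg if arg != 0 else 1.0)
            best = max(best, total)
    assert z0 == pytest.approx(best, rel=1e-12)


def test_z0_empty_ventricle_errors(tiny_phantom):
    scan, _ = tiny_phantom
    bare = DwiDataset(signals=scan.dwi.signals, scheme=scan.dwi.scheme, affine=scan.dwi.affine)
    with pytest.raises(ValueError, match="free-water reference"):
        estimate_z0(bare)


def test_z0_mean_estimator_below_max(tiny_phantom, dirs321):
    scan, _ = tiny_phantom
    z_max = estimate_z0(scan.dwi, ReconConfig(z0_estimator="max"), dirs321)
    z_mean = estimate_z0(scan.dwi, ReconConfig(z0_estimator="mean"), dirs321)
    assert 0 < z_mean <= z_max


# ------------------------------------------------------------- reconstruct_sdf

def _free_water_dwi(scheme, bval_scale=1.0):
    cfg = ReconConfig()
    shape = (3, 3, 3)
    sig = np.exp(-scheme.b_values * cfg.d_free)[None, None, None, :] * np.ones(shape + (1,))
    vent = np.zeros(shape, dtype=bool)
    vent[0, 0, 0] = True
    return DwiDataset(signals=sig, scheme=scheme, ventricle_mask=vent)


def test_isotropic_voxel_constant_sdf(dirs321):
    """Rotational symmetry: an isotropic voxel over a symmetric band-limited
    scheme reconstructs to a direction-independent SDF."""
    g = icosphere_vertices(2)  # 162 symmetric directions
    scheme = GradientScheme(
        np.concatenate([[0.0], np.full(len(g), 100.0)]), np.vstack([[0.0, 0.0, 0.0], g])
    )
    dwi = _free_water_dwi(scheme)
    cfg = ReconConfig(z0=estimate_z0(dwi, ReconConfig(), dirs321))
    sdf = reconstruct_sdf(dwi, None, cfg, dirs321)
    psi = sdf.values[1, 1, 1]
    assert psi.std() / psi.mean() < 1e-6


def test_isotropic_voxel_nearly_constant_at_high_b(dirs321, scheme64):
    """At clinical b-values the finite scheme leaves only per-mil anisotropy."""
    dwi = _free_water_dwi(scheme64)
    cfg = ReconConfig(z0=estimate_z0(dwi, ReconConfig(), dirs321))
    psi = reconstruct_sdf(dwi, None, cfg, dirs321).values[1, 1, 1]
    assert psi.std() / psi.mean() < 5e-3


def test_single_stick_argmax_within_5_degrees(dirs321, scheme64):
    """A z-axis stick voxel's SDF peaks within 5 degrees of the true axis."""
    d_a = 1.7e-3
    att = np.exp(-scheme64.b_values * d_a * (scheme64.directions @ [0.0, 0.0, 1.0]) ** 2)
    shape = (3, 3, 3)
    sig = np.tile(att, shape + (1,))
    vent = np.zeros(shape, dtype=bool)
    vent[0, 0, 0] = True
    sig[0, 0, 0] = np.exp(-scheme64.b_values * ReconConfig().d_free)
    dwi = DwiDataset(signals=sig, scheme=scheme64, ventricle_mask=vent)
    cfg = ReconConfig(z0=estimate_z0(dwi, ReconConfig(), dirs321))
    psi = reconstruct_sdf(dwi, None, cfg, dirs321).values[1, 1, 1]
    peak = dirs321.units[int(np.argmax(psi))]
    angle = np.degrees(np.arccos(min(1.0, abs(float(peak @ [0.0, 0.0, 1.0])))))
    assert angle < 5.0


def test_zero_dwi_signals_give_flat_sdf(dirs321, scheme64):
    """Only b0 terms survive: sinc(0)=1 for every direction."""
    shape = (3, 3, 3)
    sig = np.zeros(shape + (len(scheme64),))
    sig[..., scheme64.b0_mask] = 7.0
    dwi = DwiDataset(signals=sig, scheme=scheme64)
    cfg = ReconConfig(z0=3.0)
    psi = reconstruct_sdf(dwi, None, cfg, dirs321).values[1, 1, 1]
    assert np.allclose(psi, psi[0]) and psi[0] == pytest.approx(7.0 / 3.0)


def test_unresolved_z0_errors(tiny_phantom, dirs321):
    scan, _ = tiny_phantom
    with pytest.raises(ValueError, match="z0"):
        reconstruct_sdf(scan.dwi, None, ReconConfig(), dirs321)


def test_warp_outside_fov_becomes_background(tiny_phantom, tiny_cfg, dirs321):
    scan, _ = tiny_phantom
    grid = scan.dwi.grid
    disp = np.zeros(grid.shape + (3,))
    disp[4, 4, 4] = [1000.0, 0.0, 0.0]  # push one voxel far outside
    warp = DiffeoMap.from_displacement(grid, disp, jacobian=np.broadcast_to(np.eye(3), grid.shape + (3, 3)).copy())
    sdf = reconstruct_sdf(scan.dwi, warp, tiny_cfg, dirs321)
    assert np.all(sdf.values[4, 4, 4] == 0.0)
    assert np.any(sdf.values[0, 0, 0] > 0.0)


# -------------------------------------------------------- invariants of Eq.-sum

def test_gqi_reduction_identity_warp(tiny_phantom, tiny_cfg, dirs321):
    scan, _ = tiny_phantom
    explicit = reconstruct_sdf(scan.dwi, DiffeoMap.identity(scan.dwi.grid), tiny_cfg, dirs321)
    implicit = reconstruct_sdf(scan.dwi, None, tiny_cfg, dirs321)
    assert np.allclose(explicit.values, implicit.values, atol=1e-10)


def test_jacobian_scaling_cubes_density(tiny_phantom, tiny_cfg, dirs321):
    scan, _ = tiny_phantom
    c = 1.3
    base = reconstruct_sdf(scan.dwi, DiffeoMap.identity(scan.dwi.grid), tiny_cfg, dirs321)
    scaled = reconstruct_sdf(
        scan.dwi, DiffeoMap.identity(scan.dwi.grid).with_scaled_jacobian(c), tiny_cfg, dirs321
    )
    assert np.allclose(scaled.values, c**3 * base.values, rtol=1e-10, atol=1e-12)
    # argmax directions unchanged: transport is scale-invariant
    wm = np.argwhere(base.values.max(axis=-1) > 0)[:5]
    for v in wm:
        assert np.argmax(base.values[tuple(v)]) == np.argmax(scaled.values[tuple(v)])


def test_signal_scale_equivariance(tiny_phantom, dirs321):
    scan, _ = tiny_phantom
    base_cfg = ReconConfig(z0=estimate_z0(scan.dwi, ReconConfig(), dirs321))
    base = reconstruct_sdf(scan.dwi, None, base_cfg, dirs321)
    scaled_dwi = DwiDataset(
        signals=scan.dwi.signals * 37.0,
        scheme=scan.dwi.scheme,
        affine=scan.dwi.affine,
        brain_mask=scan.dwi.brain_mask,
        ventricle_mask=scan.dwi.ventricle_mask,
    )
    cfg = ReconConfig(z0=estimate_z0(scaled_dwi, ReconConfig(), dirs321))
    scaled = reconstruct_sdf(scaled_dwi, None, cfg, dirs321)
    assert np.allclose(scaled.values, base.values, atol=1e-10)


def test_antipodal_symmetry(tiny_phantom, tiny_cfg):
    """ψ(û) = ψ(−û): the kernel is even in the direction argument."""
    scan, _ = tiny_phantom
    units = DirectionSet.default().units
    both = DirectionSet(np.vstack([units, -units]), antipodal=False)
    sdf = reconstruct_sdf(scan.dwi, None, tiny_cfg, both)
    n = len(units)
    assert np.allclose(sdf.values[..., :n], sdf.values[..., n:], atol=1e-10)


def _trilinear(volume, p):
    """Independent scalar trilinear interpolation at fractional voxel p."""
    x0 = [int(math.floor(c)) for c in p]
    f = [c - i for c, i in zip(p, x0)]
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                xi, yi, zi = x0[0] + dx, x0[1] + dy, x0[2] + dz
                if not (0 <= xi < volume.shape[0] and 0 <= yi < volume.shape[1] and 0 <= zi < volume.shape[2]):
                    continue
                w = ((f[0] if dx else 1 - f[0]) * (f[1] if dy else 1 - f[1]) * (f[2] if dz else 1 - f[2]))
                total += w * volume[xi, yi, zi]
    return total


def test_oracle_equivalence_triple_loop(tiny_phantom, tiny_cfg, dirs321):
    """The vectorized reconstruction matches an explicit per-voxel,
    per-direction, per-volume loop over the defining sum, through a
    non-trivial warp."""
    scan, _ = tiny_phantom
    dwi = scan.dwi
    grid = dwi.grid
    rngless = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(float)
    disp = 0.3 * np.sin(rngless * 0.7)  # smooth small displacement, mm
    warp = DiffeoMap.from_displacement(grid, disp)

    cfg = tiny_cfg
    sub = DirectionSet(dirs321.units[::8])  # 41 axes keep the loop affordable
    got = reconstruct_sdf(dwi, warp, cfg, sub)

    b = dwi.scheme.b_values
    gvec = dwi.scheme.directions
    inv_aff = np.linalg.inv(dwi.affine)
    # stay off the +x/+y/+z faces: the positive displacement pushes those
    # voxels (fractionally) outside the subject FOV, which is background
    for v in [(0, 0, 0), (2, 2, 2), (1, 3, 2), (3, 1, 2), (2, 3, 3)]:
        phi = warp.phi[v]
        vox = inv_aff[:3, :3] @ phi + inv_aff[:3, 3]
        J = warp.jacobian[v]
        detJ = float(np.linalg.det(J))
        W = [
            _trilinear(dwi.signals[..., i], vox) for i in range(len(dwi.scheme))
        ]
        for m, u in enumerate(sub.units):
            tu = J @ u
            tu = tu / np.linalg.norm(tu)
            total = 0.0
            for i in range(len(b)):
                arg = cfg.sigma * math.sqrt(6.0 * cfg.d_free * b[i]) * float(gvec[i] @ tu)
                total += W[i] * (math.sin(arg) / arg if arg != 0.0 else 1.0)
            expect = max(0.0, detJ * total / cfg.z0)
            assert got.values[v][m] == pytest.approx(expect, rel=1e-10, abs=1e-12)


# ------------------------------------------------------------------ DiffeoMap

def test_identity_diffeo_invariants():
    grid = Grid((4, 4, 4), np.diag([2.0, 2.0, 2.0, 1.0]))
    d = DiffeoMap.identity(grid)
    assert np.allclose(d.jacobian, np.eye(3))
    assert np.allclose(d.jac_det, 1.0)
    assert np.allclose(d.phi[1, 2, 3], [2.0, 4.0, 6.0])


def test_diffeo_rejects_folding():
    grid = Grid((4, 4, 4))
    jac = np.broadcast_to(np.diag([-1.0, 1.0, 1.0]), grid.shape + (3, 3)).copy()
    phi = DiffeoMap.identity(grid).phi
    with pytest.raises(ValueError, match="positive"):
        DiffeoMap(grid=grid, phi=phi, jacobian=jac)


def test_finite_difference_jacobian_of_zero_displacement():
    grid = Grid((5, 5, 5), np.diag([1.5, 1.5, 1.5, 1.0]))
    d = DiffeoMap.from_displacement(grid, np.zeros(grid.shape + (3,)))
    assert np.allclose(d.jacobian, np.eye(3), atol=1e-9)
    assert np.allclose(d.jac_det, 1.0, atol=1e-9)


def test_gradient_scheme_validation():
    with pytest.raises(ValueError, match="unit"):
        GradientScheme(np.array([0.0, 1000.0]), np.array([[0, 0, 0], [1.0, 1.0, 0.0]]))
    with pytest.raises(ValueError, match="b0"):
        GradientScheme(np.array([1000.0]), np.array([[1.0, 0.0, 0.0]]))
    s = make_scheme(8, 2000.0, 2)
    assert int(s.b0_mask.sum()) == 2 and len(s) == 10
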