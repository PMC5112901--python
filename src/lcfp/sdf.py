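"""Spin distribution function (SDF) reconstruction in a common space.

The SDF ψ(û) of a voxel gives the density of diffusing spins displaced along
direction û.  Reconstruction is performed directly on a standard-space grid
through a diffeomorphic map φ (q-space diffeomorphic reconstruction): for each
standard-space voxel r the diffusion signals are sampled at the warped subject
coordinate φ(r), sampling directions are transported through the local
Jacobian J_φ(r), and the density is scaled by the Jacobian determinant,

    ψ(û) = |J_φ(r)| · Z0⁻¹ · Σ_i W_i(φ(r)) · sinc(σ·√(6·D·b_i) · ⟨ĝ_i, J_φ(r)û / ‖J_φ(r)û‖⟩)

where W_i is the signal of volume i (b-value b_i, gradient direction ĝ_i),
σ is the diffusion sampling ratio, D the free-water diffusivity, and Z0 a
normalization constant estimated from free-water diffusion in the ventricle.
With an identity warp the expression reduces to generalized q-sampling
imaging on the native grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .directions import default_direction_units
from .grids import Grid

__all__ = [
    "GradientScheme",
    "DwiDataset",
    "DiffeoMap",
    "ReconConfig",
    "DirectionSet",
    "SdfField",
    "sinc_kernel",
    "transport_direction",
    "estimate_z0",
    "reconstruct_sdf",
]

logger = logging.getLogger(__name__)

B0_THRESHOLD = 50.0  # s/mm^2; volumes at or below count as b=0


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weighting: b-values (s/mm^2) and unit directions."""

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values must be (n,), directions (n, 3)")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        dwi = b > B0_THRESHOLD
        if not np.any(~dwi):
            raise ValueError("gradient scheme must contain at least one b0 volume")
        norms = np.linalg.norm(g[dwi], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values <= B0_THRESHOLD


@dataclass
class DwiDataset:
    """A 4-D diffusion-weighted volume with its gradient scheme and masks."""

    signals: np.ndarray  # (x, y, z, volume)
    scheme: GradientScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    brain_mask: Optional[np.ndarray] = None
    ventricle_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 4:
            raise ValueError("signals must be 4-D (x, y, z, volume)")
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("signals must be finite and non-negative")
        if sig.shape[3] != len(self.scheme):
            raise ValueError("4th dimension must match the gradient scheme length")
        self.signals = sig
        self.affine = np.asarray(self.affine, dtype=float)
        if self.brain_mask is None:
            self.brain_mask = np.ones(sig.shape[:3], dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != sig.shape[:3]:
            raise ValueError("brain_mask shape must match the signal grid")
        if self.ventricle_mask is not None:
            self.ventricle_mask = np.asarray(self.ventricle_mask).astype(bool)
            if self.ventricle_mask.shape != sig.shape[:3]:
                raise ValueError("ventricle_mask shape must match the signal grid")

    @property
    def grid(self) -> Grid:
        return Grid(self.signals.shape[:3], self.affine)


@dataclass
class DiffeoMap:
    """Standard→subject coordinate map φ with its Jacobian field.

    ``phi`` holds, for every standard-space voxel, the subject-space position
    in mm; ``jacobian`` is ∂φ/∂r (3x3 per voxel) and ``jac_det`` its
    determinant, which must be positive (orientation-preserving map).
    """

    grid: Grid
    phi: np.ndarray  # (x, y, z, 3) subject-space mm
    jacobian: np.ndarray  # (x, y, z, 3, 3)
    jac_det: Optional[np.ndarray] = None  # (x, y, z)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        if self.phi.shape != self.grid.shape + (3,):
            raise ValueError("phi must be (grid shape, 3)")
        if self.jacobian.shape != self.grid.shape + (3, 3):
            raise ValueError("jacobian must be (grid shape, 3, 3)")
        det = np.linalg.det(self.jacobian)
        if self.jac_det is None:
            self.jac_det = det
        else:
            self.jac_det = np.asarray(self.jac_det, dtype=float)
            if not np.allclose(self.jac_det, det, atol=1e-6):
                raise ValueError("jac_det inconsistent with jacobian determinants")
        if np.any(self.jac_det <= 0):
            raise ValueError("Jacobian determinant must be positive everywhere")

    @classmethod
    def identity(cls, grid: Grid) -> "DiffeoMap":
        """The identity map on ``grid``: φ(r) = r, J = I, |J| = 1."""
        phi = grid.voxel_to_world(grid.voxel_coordinates()).reshape(grid.shape + (3,))
        jac = np.broadcast_to(np.eye(3), grid.shape + (3, 3)).copy()
        return cls(grid=grid, phi=phi, jacobian=jac)

    @classmethod
    def from_displacement(
        cls, grid: Grid, displacement_mm: np.ndarray, jacobian: Optional[np.ndarray] = None
    ) -> "DiffeoMap":
        """Build from a dense displacement field u(r) (mm): φ(r) = r + u(r).

        When no Jacobian volume is supplied it is computed by central finite
        differences of φ with respect to the world coordinate.
        """
        disp = np.asarray(displacement_mm, dtype=float)
        if disp.shape != grid.shape + (3,):
            raise ValueError("displacement must be (grid shape, 3)")
        base = grid.voxel_to_world(grid.voxel_coordinates()).reshape(grid.shape + (3,))
        phi = base + disp
        if jacobian is None:
            jacobian = _finite_difference_jacobian(phi, grid)
        return cls(grid=grid, phi=phi, jacobian=np.asarray(jacobian, dtype=float))

    def with_scaled_jacobian(self, c: float) -> "DiffeoMap":
        """Same φ with the Jacobian field multiplied by ``c`` (testing aid)."""
        return DiffeoMap(grid=self.grid, phi=self.phi.copy(), jacobian=c * self.jacobian)


def _finite_difference_jacobian(phi: np.ndarray, grid: Grid) -> np.ndarray:
    """∂φ/∂r by central differences along world axes (grid assumed axis-aligned)."""
    spacing = grid.voxel_size
    jac = np.empty(grid.shape + (3, 3), dtype=float)
    for axis in range(3):
        d = np.gradient(phi, spacing[axis], axis=axis)
        jac[..., :, axis] = d
    return jac


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    sigma
        Diffusion sampling ratio controlling the displacement range sampled
        by the SDF (dimensionless; lower values emphasize restricted
        diffusion).  Default 1.25.
    d_free
        Free-water diffusivity in mm^2/s; default 2.51e-3 (free water at
        body temperature).
    z0
        Free-water normalization constant in signal units; resolved by
        :func:`estimate_z0` when None.
    out_spacing
        Standard-space grid spacing in mm (default 1.0); used when building
        an output grid rather than inheriting one from a warp.
    sinc_normalized
        If True use sin(πx)/(πx) instead of the default sin(x)/x.
    z0_estimator
        "max" (peak free-water density over the ventricle) or "mean"
        (average over ventricle voxels of the per-voxel peak).
    """

    sigma: float = 1.25
    d_free: float = 2.51e-3
    z0: Optional[float] = None
    out_spacing: float = 1.0
    sinc_normalized: bool = False
    z0_estimator: str = "max"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.d_free <= 0 or self.out_spacing <= 0:
            raise ValueError("sigma, d_free and out_spacing must be positive")
        if self.z0 is not None and self.z0 <= 0:
            raise ValueError("z0 must be positive once resolved")
        if self.z0_estimator not in ("max", "mean"):
            raise ValueError("z0_estimator must be 'max' or 'mean'")


@dataclass(frozen=True)
class DirectionSet:
    """Unit sampling directions; with ``antipodal`` set they are axes û ≡ −û."""

    units: np.ndarray
    antipodal: bool = True

    def __post_init__(self) -> None:
        u = np.asarray(self.units, dtype=float)
        if u.ndim != 2 or u.shape[1] != 3:
            raise ValueError("units must be (m, 3)")
        if np.any(np.abs(np.linalg.norm(u, axis=1) - 1.0) > 1e-6):
            raise ValueError("direction vectors must be unit norm")
        if self.antipodal:
            dots = np.abs(u @ u.T)
            np.fill_diagonal(dots, 0.0)
            if np.any(dots > 1.0 - 1e-9):
                raise ValueError("duplicate axes in antipodal direction set")
        object.__setattr__(self, "units", u)

    def __len__(self) -> int:
        return self.units.shape[0]

    @classmethod
    def default(cls, n_subdiv: int = 3) -> "DirectionSet":
        return cls(default_direction_units(n_subdiv), antipodal=True)


@dataclass
class SdfField:
    """Per standard-space voxel, SDF magnitudes over a :class:`DirectionSet`."""

    values: np.ndarray  # (x, y, z, n_directions), >= 0
    grid: Grid
    direction_set: DirectionSet

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape + (len(self.direction_set),):
            raise ValueError("values must be (grid shape, n_directions)")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("SDF values must be finite and non-negative")
        self.values = v


def sinc_kernel(arg, normalized: bool = False):
    """sin(x)/x with the removable singularity at 0 handled.

    The default is the unnormalized kernel; ``normalized`` switches to
    numpy's sin(πx)/(πx) convention.
    """
    arg = np.asarray(arg, dtype=float)
    out = np.sinc(arg if normalized else arg / np.pi)
    return out if out.ndim else float(out)


def transport_direction(J: np.ndarray, u_hat: np.ndarray) -> np.ndarray:
    """Transport a sampling direction through a Jacobian: Jû/‖Jû‖."""
    v = np.asarray(J, dtype=float) @ np.asarray(u_hat, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate Jacobian direction")
    return v / n


def _sinc_matrix(scheme: GradientScheme, cfg: ReconConfig, units: np.ndarray) -> np.ndarray:
    """K[i, m] = sinc(σ·√(6·D·b_i)·⟨ĝ_i, û_m⟩) for transported units û_m."""
    L = cfg.sigma * np.sqrt(6.0 * cfg.d_free * scheme.b_values)  # (n_vol,)
    args = L[:, None] * (scheme.directions @ units.T)  # (n_vol, n_dir)
    return sinc_kernel(args, normalized=cfg.sinc_normalized)


def _unnormalized_sdf(signals_2d: np.ndarray, scheme: GradientScheme, cfg: ReconConfig,
                      units: np.ndarray) -> np.ndarray:
    """Σ_i W_i·sinc(...) for a (n_voxel, n_vol) signal block; no |J|, no Z0."""
    return signals_2d @ _sinc_matrix(scheme, cfg, units)


def estimate_z0(
    dwi: DwiDataset,
    cfg: Optional[ReconConfig] = None,
    dirs: Optional[DirectionSet] = None,
) -> float:
    """Estimate the free-water normalization constant Z0 from the ventricle.

    Evaluates the unnormalized SDF sum in every ventricle voxel over the
    sampling directions and returns the peak magnitude ("max" estimator,
    default: free water's peak density becomes 1 after normalization) or the
    ventricle average of the per-voxel peak ("mean" estimator).
    """
    if dwi.ventricle_mask is None or not np.any(dwi.ventricle_mask):
        raise ValueError("no free-water reference region (empty ventricle mask)")
    cfg = cfg or ReconConfig()
    dirs = dirs or DirectionSet.default()
    W = dwi.signals[dwi.ventricle_mask]  # (n_vox, n_vol)
    psi0 = _unnormalized_sdf(W, dwi.scheme, cfg, dirs.units)
    peaks = psi0.max(axis=1)
    z0 = float(peaks.max() if cfg.z0_estimator == "max" else peaks.mean())
    if z0 <= 0:
        raise ValueError("non-positive Z0 estimate; check ventricle signals")
    return z0


def reconstruct_sdf(
    dwi: DwiDataset,
    warp: Optional[DiffeoMap],
    cfg: ReconConfig,
    dirs: Optional[DirectionSet] = None,
    mask: Optional[np.ndarray] = None,
) -> SdfField:
    """Reconstruct SDFs on the standard grid defined by ``warp``.

    ``warp=None`` uses the identity map on the native grid.  ``mask``
    restricts reconstruction to a standard-space subset (default: all
    voxels).  Signals at warped subject coordinates are trilinearly
    interpolated; voxels warped outside the subject FOV become background
    (all-zero) and are logged.  Negative sums (the sinc kernel takes negative
    values) are clamped to zero; the clamp count is logged.
    """
    if cfg.z0 is None:
        raise ValueError("cfg.z0 unresolved: call estimate_z0 first or supply z0")
    dirs = dirs or DirectionSet.default()
    if warp is None:
        warp = DiffeoMap.identity(dwi.grid)
    grid = warp.grid
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape must match the standard grid")

    vox_idx = np.argwhere(mask)  # (n, 3)
    values = np.zeros(grid.shape + (len(dirs),), dtype=float)
    if vox_idx.size == 0:
        return SdfField(values=values, grid=grid, direction_set=dirs)

    # subject-space sampling positions, in subject voxel coordinates
    phi_mm = warp.phi[mask]  # (n, 3)
    subj_vox = dwi.grid.world_to_voxel(phi_mm)
    dims = np.asarray(dwi.signals.shape[:3], dtype=float)
    inside = np.all((subj_vox >= 0.0) & (subj_vox <= dims - 1.0), axis=1)
    n_out = int(np.sum(~inside))
    if n_out:
        logger.info("reconstruct_sdf: %d voxels warped outside the subject FOV -> background", n_out)

    coords = subj_vox[inside].T  # (3, n_in)
    n_in = coords.shape[1]
    n_vol = len(dwi.scheme)
    W = np.empty((n_in, n_vol), dtype=float)
    for i in range(n_vol):
        W[:, i] = ndimage.map_coordinates(dwi.signals[..., i], coords, order=1, mode="constant", cval=0.0)

    jac = warp.jacobian[mask][inside]  # (n_in, 3, 3)
    det = warp.jac_det[mask][inside]  # (n_in,)
    psi = np.empty((n_in, len(dirs)), dtype=float)

    # fast path: spatially constant Jacobian (identity warps, affine warps)
    if np.allclose(jac, jac[0][None], atol=1e-12):
        tu = (jac[0] @ dirs.units.T).T
        norms = np.linalg.norm(tu, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("degenerate Jacobian direction")
        psi[:] = _unnormalized_sdf(W, dwi.scheme, cfg, tu / norms[:, None])
    else:
        for k in range(n_in):
            tu = (jac[k] @ dirs.units.T).T
            norms = np.linalg.norm(tu, axis=1)
            if np.any(norms < 1e-12):
                raise ValueError("degenerate Jacobian direction")
            psi[k] = _unnormalized_sdf(W[k : k + 1], dwi.scheme, cfg, tu / norms[:, None])[0]

    psi *= det[:, None] / cfg.z0
    n_clamped = int(np.sum(psi < 0))
    if n_clamped:
        logger.info("reconstruct_sdf: clamped %d negative SDF values to 0", n_clamped)
    np.clip(psi, 0.0, None, out=psi)

    full = np.zeros((vox_idx.shape[0], len(dirs)), dtype=float)
    full[inside] = psi
    values[mask] = full
    return SdfField(values=values, grid=grid, direction_set=dirs)


def resolve_z0(dwi: DwiDataset, cfg: ReconConfig, dirs: Optional[DirectionSet] = None) -> ReconConfig:
    """Return a config with z0 filled in from the ventricle when unresolved."""
    if cfg.z0 is not None:
        return cfg
    return replace(cfg, z0=estimate_z0(dwi, cfg, dirs))
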