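"""Local connectome fingerprints.

A fingerprint is the flat vector of SDF magnitudes sampled, in every white
matter voxel, along the fiber directions of a common atlas, serialized in a
canonical anatomical voxel order and scaled to unit sample variance.  Because
the atlas supplies one shared set of (voxel, direction) sampling sites, the
entries of two fingerprints correspond one-to-one and can be compared
entrywise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import Grid
from .sdf import SdfField

__all__ = [
    "DirectionAtlas",
    "Fingerprint",
    "EntryDifferenceMap",
    "extract_fingerprint",
    "normalize_fingerprint",
    "subset_fingerprint",
    "difference_map",
]

# atlas directions further than this from every reconstruction direction are
# interpolated over the 3 nearest axes instead of using the single nearest
NEAREST_ANGLE_DEG = 4.0


@dataclass
class DirectionAtlas:
    """Per-voxel ordered fiber axes over a white-matter mask.

    ``fibers`` has shape (x, y, z, K, 3); absent ranks are all-zero rows.
    Rank 1 is the first (largest-volume-fraction) resolved fiber.
    """

    mask: np.ndarray
    fibers: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.fibers = np.asarray(self.fibers, dtype=float)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid")
        if self.fibers.shape[:3] != self.grid.shape or self.fibers.ndim != 5 or self.fibers.shape[4] != 3:
            raise ValueError("fibers must be (grid shape, K, 3)")
        norms = np.linalg.norm(self.fibers, axis=-1)
        present = norms > 0
        if np.any(np.abs(norms[present] - 1.0) > 1e-6):
            raise ValueError("fiber vectors must be unit norm")
        if np.any(present.any(axis=-1) & ~self.mask):
            raise ValueError("voxels with fibers must lie inside the mask")
        if np.any(self.mask & ~present.any(axis=-1)):
            raise ValueError("every mask voxel must carry at least one fiber")

    @property
    def k_max(self) -> int:
        return self.fibers.shape[3]

    @property
    def n_entries(self) -> int:
        return int(np.sum(np.linalg.norm(self.fibers, axis=-1) > 0))

    def content_hash(self) -> str:
        """SHA-256 of the canonicalized atlas content."""
        h = hashlib.sha256()
        h.update(np.asarray(self.grid.shape, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.grid.affine, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.mask, dtype=np.uint8).tobytes())
        h.update(np.ascontiguousarray(self.fibers, dtype=np.float64).tobytes())
        return h.hexdigest()

    def entry_table(self) -> np.ndarray:
        """Canonically ordered entries as an (n, 4) int array [x, y, z, rank].

        Entries are sorted lexicographically by voxel index — x slowest, then
        y, then z — with fiber rank (1-based) innermost.  On the canonical
        grid this traverses voxels from the left-posterior-inferior corner
        rightward/anteriorward/superiorward, independent of storage order.
        """
        present = np.linalg.norm(self.fibers, axis=-1) > 0
        xx, yy, zz, rr = np.nonzero(present)
        order = np.lexsort((rr, zz, yy, xx))
        return np.column_stack([xx[order], yy[order], zz[order], rr[order] + 1]).astype(np.int64)


@dataclass
class Fingerprint:
    """A flat vector of SDF density samples with its entry index and metadata."""

    values: np.ndarray
    index: np.ndarray  # (n, 4) int: voxel x, y, z, fiber rank (1-based)
    subject_id: str
    session_id: str
    days: float = 0.0
    atlas_hash: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.index = np.asarray(self.index, dtype=np.int64)
        if self.values.ndim != 1 or self.index.shape != (self.values.size, 4):
            raise ValueError("values must be (n,), index (n, 4)")
        if self.normalized and abs(np.var(self.values, ddof=1) - 1.0) > 1e-9:
            raise ValueError("normalized fingerprint must have unit sample variance")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry": np.arange(len(self)),
                "x": self.index[:, 0],
                "y": self.index[:, 1],
                "z": self.index[:, 2],
                "rank": self.index[:, 3],
                "value": self.values,
            }
        )


@dataclass
class EntryDifferenceMap:
    """Voxel map of mean absolute fingerprint-entry differences at one rank."""

    values: np.ndarray
    grid: Grid
    fiber_rank_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match grid")
        if np.any(self.values < 0):
            raise ValueError("difference map must be non-negative")


def _sample_directions(sdf: SdfField, atlas_dirs: np.ndarray) -> np.ndarray:
    """Column indices/weights for sampling SDF values at atlas directions.

    Returns the sampled matrix (n_entries,) given per-entry SDF rows.  The
    magnitude at an atlas direction is the value at the nearest
    reconstruction axis when the angular gap is at most NEAREST_ANGLE_DEG,
    otherwise the inverse-angular-distance interpolation over the 3 nearest
    axes.  Angles treat directions as axes (û ≡ −û).
    """
    units = sdf.direction_set.units
    cosang = np.abs(atlas_dirs @ units.T)
    np.clip(cosang, 0.0, 1.0, out=cosang)
    ang = np.arccos(cosang)  # (n, m)
    nearest = np.argmin(ang, axis=1)
    ang_min = ang[np.arange(ang.shape[0]), nearest]
    use_interp = ang_min > np.deg2rad(NEAREST_ANGLE_DEG)

    weights = np.zeros_like(ang)
    weights[np.arange(ang.shape[0]), nearest] = 1.0
    if np.any(use_interp):
        rows = np.nonzero(use_interp)[0]
        k3 = min(3, ang.shape[1])
        top3 = np.argpartition(ang[rows], k3 - 1, axis=1)[:, :k3]
        w = 1.0 / np.maximum(ang[rows[:, None], top3], 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        weights[rows] = 0.0
        weights[rows[:, None], top3] = w
    return weights


def extract_fingerprint(
    sdf: SdfField,
    atlas: DirectionAtlas,
    subject_id: str = "",
    session_id: str = "",
    days: float = 0.0,
) -> Fingerprint:
    """Sample SDF magnitudes along the atlas fiber directions.

    Emits one entry per (voxel, fiber rank) in canonical order; the result is
    unnormalized (arbitrary density units).
    """
    if not sdf.grid.same_as(atlas.grid):
        raise ValueError("SDF field and atlas must share the same grid")
    table = atlas.entry_table()
    if table.shape[0] == 0:
        raise ValueError("empty atlas")
    vx, vy, vz, rank = table.T
    dirs = atlas.fibers[vx, vy, vz, rank - 1]  # (n, 3)
    rows = sdf.values[vx, vy, vz]  # (n, m)
    weights = _sample_directions(sdf, dirs)
    values = np.einsum("nm,nm->n", rows, weights)
    return Fingerprint(
        values=values,
        index=table,
        subject_id=subject_id,
        session_id=session_id,
        days=days,
        atlas_hash=atlas.content_hash(),
        normalized=False,
    )


def normalize_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Scale to unit sample variance (the fingerprint's canonical scale)."""
    sd = float(np.std(fp.values, ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("degenerate fingerprint: zero variance")
    return replace(fp, values=fp.values / sd, normalized=True)


def subset_fingerprint(fp: Fingerprint, region_mask: np.ndarray) -> Fingerprint:
    """Restrict to entries whose voxel lies inside ``region_mask``.

    Order is preserved; a normalized input is re-normalized over the subset.
    """
    region_mask = np.asarray(region_mask).astype(bool)
    vx, vy, vz = fp.index[:, 0], fp.index[:, 1], fp.index[:, 2]
    keep = region_mask[vx, vy, vz]
    if not np.any(keep):
        raise ValueError("region mask selects no fingerprint entries")
    sub = replace(fp, values=fp.values[keep], index=fp.index[keep], normalized=False)
    return normalize_fingerprint(sub) if fp.normalized else sub


def difference_map(
    pairs: Sequence[tuple[Fingerprint, Fingerprint]],
    atlas: DirectionAtlas,
    rank: int = 1,
) -> EntryDifferenceMap:
    """Mean absolute entry difference per voxel, at one fiber rank.

    For each pair the absolute entrywise difference is taken; per voxel the
    entry at the requested rank is averaged over pairs.  Voxels without that
    rank remain background (0).
    """
    if not pairs:
        raise ValueError("no fingerprint pairs supplied")
    ref_hash = atlas.content_hash()
    acc = np.zeros(atlas.grid.shape, dtype=float)
    for a, b in pairs:
        if a.atlas_hash != ref_hash or b.atlas_hash != ref_hash:
            raise ValueError("fingerprint atlas hash does not match the atlas")
        sel = a.index[:, 3] == rank
        d = np.abs(a.values[sel] - b.values[sel])
        vx, vy, vz = a.index[sel, 0], a.index[sel, 1], a.index[sel, 2]
        acc[vx, vy, vz] += d
    acc /= len(pairs)
    return EntryDifferenceMap(values=acc, grid=atlas.grid, fiber_rank_used=rank)
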