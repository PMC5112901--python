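"""End-to-end convenience chains: scans → SDFs → fingerprints → reports."""

from __future__ import annotations

from typing import Optional, Sequence

from .fingerprint import DirectionAtlas, Fingerprint, extract_fingerprint, normalize_fingerprint
from .identify import DistanceMatrix, distance_matrix
from .phantom import ScanRecord
from .sdf import DiffeoMap, DirectionSet, DwiDataset, ReconConfig, reconstruct_sdf, resolve_z0

__all__ = ["fingerprint_scan", "fingerprints_from_scans", "cohort_distance_matrix"]


def fingerprint_scan(
    dwi: DwiDataset,
    atlas: DirectionAtlas,
    cfg: Optional[ReconConfig] = None,
    dirs: Optional[DirectionSet] = None,
    warp: Optional[DiffeoMap] = None,
    subject_id: str = "",
    session_id: str = "",
    days: float = 0.0,
    normalize: bool = True,
) -> Fingerprint:
    """Reconstruct one scan and sample its fingerprint on the atlas.

    Z0 is estimated from the scan's own ventricle when the config leaves it
    unresolved.  Reconstruction is restricted to the atlas mask.
    """
    cfg = resolve_z0(dwi, cfg or ReconConfig(), dirs)
    sdf = reconstruct_sdf(dwi, warp, cfg, dirs, mask=atlas.mask)
    fp = extract_fingerprint(sdf, atlas, subject_id=subject_id, session_id=session_id, days=days)
    return normalize_fingerprint(fp) if normalize else fp


def fingerprints_from_scans(
    scans: Sequence[ScanRecord],
    atlas: DirectionAtlas,
    cfg: Optional[ReconConfig] = None,
    dirs: Optional[DirectionSet] = None,
    normalize: bool = True,
) -> list[Fingerprint]:
    return [
        fingerprint_scan(
            rec.dwi, atlas, cfg=cfg, dirs=dirs,
            subject_id=rec.subject_id, session_id=rec.session_id, days=rec.days,
            normalize=normalize,
        )
        for rec in scans
    ]


def cohort_distance_matrix(
    scans: Sequence[ScanRecord],
    atlas: DirectionAtlas,
    cfg: Optional[ReconConfig] = None,
    dirs: Optional[DirectionSet] = None,
) -> tuple[DistanceMatrix, list[Fingerprint]]:
    fps = fingerprints_from_scans(scans, atlas, cfg=cfg, dirs=dirs)
    return distance_matrix(fps), fps
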