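"""Spatial clustering of islet centroids and high-density-region analysis.

Islets whose centroids lie within a cutoff distance (300 µm by default) of
each other are linked; connected components of the resulting graph are the
clusters (single linkage — equivalently, cutting a minimum spanning tree
at the cutoff).  A cluster with strictly more than 100 members is a high
islet density region (HIDR); all others are low islet density regions
(LIDR).

Density inside and outside HIDRs is compared with cubic regions of
interest (ROIs) of 48 voxels edge (≈ 1 mm at 21 µm voxels): one ROI is
centred on each HIDR centroid, and reference ROIs are placed uniformly at
random in the cuboid; islet volume and count are normalized by the ROI
volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from scipy.spatial import cKDTree

from .core import ClusterRecord, IsletRecord

__all__ = [
    "ClusterConfig",
    "single_linkage_clusters",
    "classify_clusters",
    "attach_cluster_ids",
    "roi_quantify",
    "make_rois",
    "hidr_fraction",
]


@dataclass
class ClusterConfig:
    """Clustering and ROI parameters.

    ``linkage_cutoff_um`` (300): two islets are linked iff their centroid
    distance is ≤ cutoff.  ``hidr_min_count`` (100): HIDR iff member count
    is *strictly* greater.  ``roi_edge_voxels`` (48) with 21 µm voxels is a
    ≈1 mm cube.
    """

    linkage_cutoff_um: float = 300.0
    hidr_min_count: int = 100
    roi_edge_voxels: int = 48
    n_random_rois: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.linkage_cutoff_um > 0:
            raise ValueError("linkage_cutoff_um must be positive")
        if self.roi_edge_voxels < 1:
            raise ValueError("roi_edge_voxels must be >= 1")

    def roi_edge_um(self, voxel_size_um: float) -> float:
        return self.roi_edge_voxels * voxel_size_um


def single_linkage_clusters(centroids_um: np.ndarray, cutoff_um: float) -> np.ndarray:
    """Single-linkage cluster labels for an (n, 3) array of centroids.

    An edge links any two centroids at Euclidean distance ≤ cutoff; labels
    are the connected components, numbered 0..K-1 in order of each
    component's minimum member index (deterministic and independent of
    point order up to that canonical relabelling).
    """
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    n = len(pts) if pts.size else 0
    if n == 0:
        return np.zeros(0, dtype=int)
    if not np.all(np.isfinite(pts)):
        raise ValueError("centroids must be finite")
    ds = DisjointSet(range(n))
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=cutoff_um):
        ds.merge(i, j)
    labels = np.empty(n, dtype=int)
    roots = {}
    for i in range(n):
        r = ds[i]  # canonical root
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]
    return labels


def classify_clusters(
    labels: np.ndarray,
    centroids_um: np.ndarray,
    cfg: ClusterConfig | None = None,
    islet_ids: Optional[Sequence[int]] = None,
) -> list[ClusterRecord]:
    """Build :class:`ClusterRecord` objects with HIDR/LIDR classes.

    A cluster is a HIDR iff its member count strictly exceeds
    ``hidr_min_count`` (count 100 → LIDR, count 101 → HIDR).
    """
    cfg = cfg or ClusterConfig()
    labels = np.asarray(labels)
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if islet_ids is None:
        islet_ids = np.arange(len(labels))
    islet_ids = np.asarray(islet_ids)
    records = []
    for cid in np.unique(labels):
        sel = labels == cid
        members = pts[sel]
        records.append(
            ClusterRecord(
                cluster_id=int(cid),
                member_ids=[int(i) for i in islet_ids[sel]],
                count=int(sel.sum()),
                cls="HIDR" if int(sel.sum()) > cfg.hidr_min_count else "LIDR",
                centroid_um=tuple(members.mean(axis=0)),
                bbox_min_um=tuple(members.min(axis=0)),
                bbox_max_um=tuple(members.max(axis=0)),
            )
        )
    return records


def attach_cluster_ids(records: list[IsletRecord], labels: np.ndarray) -> None:
    """Write cluster ids back onto islet records, in order."""
    if len(records) != len(labels):
        raise ValueError("records and labels differ in length")
    for rec, lab in zip(records, labels):
        rec.cluster_id = int(lab)


def make_rois(
    clusters: Iterable[ClusterRecord],
    bounds_um: tuple[float, float, float],
    cfg: ClusterConfig,
    voxel_size_um: float,
) -> pd.DataFrame:
    """ROI table: one cube per HIDR centroid + seeded random reference cubes.

    Each row holds the cube's lower corner, edge length and kind
    ("hidr" | "random").  Cubes are kept inside ``bounds_um`` by clamping
    their corner (a warning is raised when a HIDR-centred cube had to be
    shifted).
    """
    edge = cfg.roi_edge_um(voxel_size_um)
    bounds = np.asarray(bounds_um, dtype=float)
    if np.any(edge > bounds):
        raise ValueError("ROI edge exceeds the cuboid extent")
    rows = []

    def clamp_corner(corner: np.ndarray, kind: str) -> np.ndarray:
        clamped = np.clip(corner, 0.0, bounds - edge)
        if kind == "hidr" and not np.allclose(clamped, corner):
            warnings.warn("HIDR ROI clipped to the cuboid bounds", stacklevel=3)
        return clamped

    for c in clusters:
        if c.cls != "HIDR":
            continue
        corner = np.asarray(c.centroid_um) - edge / 2.0
        corner = clamp_corner(corner, "hidr")
        rows.append({"kind": "hidr", "cluster_id": c.cluster_id,
                     "x0_um": corner[0], "y0_um": corner[1], "z0_um": corner[2],
                     "edge_um": edge})
    rng = np.random.default_rng(cfg.rng_seed)
    for _ in range(cfg.n_random_rois):
        corner = rng.uniform(0.0, 1.0, size=3) * (bounds - edge)
        rows.append({"kind": "random", "cluster_id": None,
                     "x0_um": corner[0], "y0_um": corner[1], "z0_um": corner[2],
                     "edge_um": edge})
    return pd.DataFrame(rows, columns=["kind", "cluster_id", "x0_um", "y0_um",
                                       "z0_um", "edge_um"])


def roi_quantify(records: Iterable[IsletRecord], rois: pd.DataFrame) -> pd.DataFrame:
    """Islet volume density and count density inside each ROI cube.

    An islet belongs to a cube iff its (local) centroid lies inside
    ``[corner, corner + edge)``.  Volume density is Σ islet volume / ROI
    volume (dimensionless); count density is islets per mm³.
    """
    records = list(records)
    if records:
        pts = np.array([r.centroid_local_um for r in records], dtype=float)
        vols = np.array([r.volume_um3 for r in records], dtype=float)
    else:
        pts = np.zeros((0, 3))
        vols = np.zeros(0)
    out = []
    for _, roi in rois.iterrows():
        corner = np.array([roi.x0_um, roi.y0_um, roi.z0_um])
        edge = float(roi.edge_um)
        inside = np.all((pts >= corner) & (pts < corner + edge), axis=1) if len(records) else np.zeros(0, bool)
        roi_vol_um3 = edge**3
        roi_vol_mm3 = roi_vol_um3 / 1e9
        out.append(
            {
                "kind": roi.kind,
                "cluster_id": roi.cluster_id,
                "islet_count": int(inside.sum()),
                "islet_volume_um3": float(vols[inside].sum()),
                "volume_density": float(vols[inside].sum()) / roi_vol_um3,
                "count_per_mm3": float(inside.sum()) / roi_vol_mm3,
            }
        )
    return pd.DataFrame(out, columns=["kind", "cluster_id", "islet_count",
                                      "islet_volume_um3", "volume_density",
                                      "count_per_mm3"])


def hidr_fraction(clusters: Iterable[ClusterRecord]) -> float:
    """Fraction of the total islet count contributed by HIDRs (NaN if empty)."""
    clusters = list(clusters)
    total = sum(c.count for c in clusters)
    if total == 0:
        return float("nan")
    return sum(c.count for c in clusters if c.cls == "HIDR") / total
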