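"""Size-category binning, density normalization and grouped sphericity.

Islets are sorted into size categories either by volume (µm³) or by mean
3D diameter (µm), with left-open/right-closed intervals — the semantics of
``pandas.cut``, which the category edges were designed for.  The default
volume edges double from 25·10³ to 102.4·10⁶ µm³; the default diameter
edges run from 62.5 to 328.4 µm.

Densities are referenced to one of two volumes:

``outline``
    the full specimen envelope, including non-tissue-filled space —
    comparable across species and to stereological literature;
``tissue``
    the envelope minus hypointense (non-tissue) regions — the actual
    parenchymal volume, always ≤ the outline volume, hence tissue-mode
    densities ≥ outline-mode densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import IsletRecord

__all__ = [
    "VOLUME_EDGES_UM3",
    "DIAMETER_EDGES_UM",
    "SizeCategorySpec",
    "DensityReport",
    "assign_size_category",
    "aggregate_densities",
    "reference_volumes",
    "sphericity_by_group",
]

#: default volume-category edges, µm³ (left-open/right-closed intervals)
VOLUME_EDGES_UM3: tuple[float, ...] = (
    0, 25_000, 50_000, 100_000, 200_000, 400_000, 800_000, 1_600_000,
    3_200_000, 6_400_000, 12_800_000, 25_600_000, 51_200_000, 102_400_000,
)

#: default mean-3D-diameter category edges, µm
DIAMETER_EDGES_UM: tuple[float, ...] = (
    0, 62.5, 78.1, 93.7, 109.3, 140.6, 171.9, 203.2, 234.5, 265.8, 297.1, 328.4,
)


@dataclass
class SizeCategorySpec:
    """Binning rule: ``mode`` selects the islet attribute, ``edges`` the bins.

    Intervals are ``(edges[k], edges[k+1]]``: a value equal to an edge
    falls in the lower category; zero and values above the last edge are
    unbinned.  ``drop_unbinned`` drops unbinned values silently (plain
    ``pd.cut`` behaviour); when False (default) they are reported in an
    explicit overflow row.
    """

    mode: str = "volume"  # "volume" | "diameter"
    edges: Sequence[float] = VOLUME_EDGES_UM3
    drop_unbinned: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("volume", "diameter"):
            raise ValueError("mode must be 'volume' or 'diameter'")
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        if e[0] != 0:
            raise ValueError("first edge must be 0")
        self.edges = tuple(float(v) for v in e)

    @classmethod
    def diameter(cls, **kw) -> "SizeCategorySpec":
        return cls(mode="diameter", edges=DIAMETER_EDGES_UM, **kw)

    def value_of(self, record: IsletRecord) -> float:
        return record.volume_um3 if self.mode == "volume" else record.mean_diameter_um

    @property
    def n_categories(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        e = self.edges
        return [f"({e[k]:g}, {e[k + 1]:g}]" for k in range(self.n_categories)]


def assign_size_category(value: float, spec: SizeCategorySpec) -> Optional[int]:
    """Category index k with ``edges[k] < value <= edges[k+1]``, else None.

    Zero (the open lower bound of the first interval) and values above the
    last edge return None.  Negative values are an error.
    """
    if value < 0:
        raise ValueError("size values must be non-negative")
    edges = np.asarray(spec.edges)
    if value <= edges[0] or value > edges[-1]:
        return None
    k = int(np.searchsorted(edges, value, side="left")) - 1
    return k


def reference_volumes(
    outline: np.ndarray, tissue: np.ndarray, voxel_size_um: float
) -> tuple[float, float]:
    """(outline, tissue) volumes in mm³ from the two masks."""
    outline = np.asarray(outline, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if outline.shape != tissue.shape:
        raise ValueError("masks must be aligned")
    if (tissue & ~outline).any():
        raise ValueError("tissue mask is not contained in the outline mask")
    to_mm3 = (voxel_size_um**3) / 1e9
    return float(outline.sum() * to_mm3), float(tissue.sum() * to_mm3)


@dataclass
class DensityReport:
    """Per-region islet density aggregate.

    ``per_category`` has one row per size category (plus an ``overflow``
    row unless the binning spec is strict): volume sum (µm³), islet count,
    volume density (µm³ islet per µm³ reference, dimensionless) and count
    per mm³ of reference volume.
    """

    region_id: str
    normalization: str  # "outline" | "tissue"
    reference_volume_mm3: float
    total_islet_volume_um3: float
    islet_count: int
    volume_density: float  # dimensionless fraction of the reference volume
    count_per_mm3: float
    per_category: pd.DataFrame = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        header = pd.DataFrame(
            {
                "region_id": [self.region_id],
                "normalization": [self.normalization],
                "reference_volume_mm3": [self.reference_volume_mm3],
                "total_islet_volume_um3": [self.total_islet_volume_um3],
                "islet_count": [self.islet_count],
                "volume_density": [self.volume_density],
                "count_per_mm3": [self.count_per_mm3],
            }
        )
        with open(path, "w") as fh:
            header.to_csv(fh, index=False)
            self.per_category.to_csv(fh, index=False)


def aggregate_densities(
    records: Iterable[IsletRecord],
    reference_volume_mm3: float,
    normalization: str = "outline",
    spec: SizeCategorySpec | None = None,
    region_id: str = "",
) -> DensityReport:
    """Aggregate islet records into per-category densities.

    Volume density is Σ islet volume / reference volume (dimensionless);
    count density is N / reference volume (mm⁻³); per-category likewise
    via ``pd.cut`` on the spec's edges.
    """
    if not reference_volume_mm3 > 0:
        raise ValueError("reference volume must be positive")
    spec = spec or SizeCategorySpec()
    records = list(records)
    ref_um3 = reference_volume_mm3 * 1e9

    values = np.array([spec.value_of(r) for r in records], dtype=float)
    volumes = np.array([r.volume_um3 for r in records], dtype=float)
    cats = pd.cut(values, list(spec.edges)) if len(records) else pd.Categorical([])

    rows = []
    labels = spec.labels()
    intervals = pd.IntervalIndex.from_breaks(list(spec.edges))
    for k in range(spec.n_categories):
        in_cat = np.asarray(cats == intervals[k]) if len(records) else np.zeros(0, bool)
        vol_sum = float(volumes[in_cat].sum())
        n = int(in_cat.sum())
        rows.append(
            {
                "category": labels[k],
                "volume_sum_um3": vol_sum,
                "count": n,
                "volume_density": vol_sum / ref_um3,
                "count_per_mm3": n / reference_volume_mm3,
            }
        )
    if not spec.drop_unbinned:
        unbinned = (
            np.asarray(pd.isna(cats)) if len(records) else np.zeros(0, bool)
        )
        rows.append(
            {
                "category": "overflow",
                "volume_sum_um3": float(volumes[unbinned].sum()),
                "count": int(unbinned.sum()),
                "volume_density": float(volumes[unbinned].sum()) / ref_um3,
                "count_per_mm3": int(unbinned.sum()) / reference_volume_mm3,
            }
        )
        total_vol = float(volumes.sum())
        total_n = len(records)
    else:
        binned = ~np.asarray(pd.isna(cats)) if len(records) else np.zeros(0, bool)
        total_vol = float(volumes[binned].sum())
        total_n = int(binned.sum())

    per_category = pd.DataFrame(
        rows, columns=["category", "volume_sum_um3", "count",
                       "volume_density", "count_per_mm3"]
    )
    return DensityReport(
        region_id=region_id,
        normalization=normalization,
        reference_volume_mm3=reference_volume_mm3,
        total_islet_volume_um3=total_vol,
        islet_count=total_n,
        volume_density=total_vol / ref_um3,
        count_per_mm3=total_n / reference_volume_mm3,
        per_category=per_category,
    )


def sphericity_by_group(
    records: Iterable[IsletRecord],
    spec: SizeCategorySpec | None = None,
    volume_split_um3: Optional[float] = None,
) -> pd.DataFrame:
    """Mean/SD/n of sphericity per size group.

    Either groups by the size-category spec, or — when
    ``volume_split_um3`` is given (the comparison of large vs small islets
    uses 9×10⁶ µm³) — by a single volume threshold.  Empty groups report
    n=0 with NaN statistics; single-member groups report NaN SD.
    """
    records = list(records)
    psi = np.array([r.sphericity for r in records], dtype=float)
    if volume_split_um3 is not None:
        volumes = np.array([r.volume_um3 for r in records], dtype=float)
        groups = {
            f"<= {volume_split_um3:g} um3": psi[volumes <= volume_split_um3],
            f"> {volume_split_um3:g} um3": psi[volumes > volume_split_um3],
        }
    else:
        spec = spec or SizeCategorySpec()
        values = np.array([spec.value_of(r) for r in records], dtype=float)
        intervals = pd.IntervalIndex.from_breaks(list(spec.edges))
        cats = pd.cut(values, intervals) if len(records) else pd.Categorical([])
        groups = {
            lab: psi[np.asarray(cats == iv)] if len(records) else psi[:0]
            for lab, iv in zip(spec.labels(), intervals)
        }
    rows = []
    for name, vals in groups.items():
        rows.append(
            {
                "group": name,
                "n": int(vals.size),
                "mean_sphericity": float(vals.mean()) if vals.size else float("nan"),
                "sd_sphericity": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean_sphericity", "sd_sphericity"])
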