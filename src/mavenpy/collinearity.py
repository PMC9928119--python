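"""Multicollinearity diagnostics and correlation-based region ranking.

Variegated transgene expression induces strong positive correlation between
region signals: larvae differ in global construct silencing, so regions load
on a shared per-animal factor.  Before sparse modeling, this module
quantifies that structure (pairwise Pearson correlations with a
Ward-clustering display order), and afterwards it ranks the regions most
correlated with a focal region — excluding regions that anatomically contain
the focal region, since "the whole hindbrain" is not a useful alternative
candidate to a nucleus inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .core_io import RegionAtlas, RegionSignalMatrix
from .errors import UnknownRegionError, ValidationError

__all__ = [
    "CorrelationReport",
    "correlation_matrix",
    "region_overlap_fraction",
    "strongest_correlated_regions",
]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations plus a clustering display order.

    ``ordering`` is the leaf permutation of a Ward-linkage dendrogram built
    on the dissimilarity ``1 - r``, mirroring the convention of ordering
    correlation heatmaps by hierarchical clustering.
    """

    region_ids: list[str]
    r: np.ndarray
    ordering: np.ndarray
    linkage_method: str = "ward"
    dissimilarity: str = "1-r"

    def __post_init__(self) -> None:
        k = len(self.region_ids)
        if self.r.shape != (k, k):
            raise ValidationError(f"correlation matrix shape {self.r.shape} != ({k},{k})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValidationError("correlation diagonal != 1")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValidationError("|r| > 1")
        if sorted(self.ordering.tolist()) != list(range(k)):
            raise ValidationError("ordering is not a permutation")

    def focal_row(self, focal: str) -> np.ndarray:
        try:
            i = self.region_ids.index(focal)
        except ValueError:
            raise UnknownRegionError(f"unknown focal region {focal!r}") from None
        return self.r[i]


def correlation_matrix(m: RegionSignalMatrix) -> CorrelationReport:
    """Pearson correlation of every region pair, with Ward display ordering.

    Requires at least 3 subjects and no zero-variance column (constant
    columns have undefined correlation; remove them with
    ``drop_uninformative_regions`` first).
    """
    values = m.values
    n, k = values.shape
    if n < 3:
        raise ValidationError(f"need >= 3 subjects for correlations, got {n}")
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [r for r, s in zip(m.regions, sd) if s == 0]
        raise ValidationError(f"zero-variance region(s): {bad}")
    r = np.corrcoef(values, rowvar=False)
    # numerical guards so the report's invariants hold exactly
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if k >= 3:
        dist = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        order = leaves_list(linkage(squareform(dist, checks=False), method="ward"))
    else:
        order = np.arange(k)
    return CorrelationReport(region_ids=m.regions, r=r, ordering=np.asarray(order))


def region_overlap_fraction(atlas: RegionAtlas, a: str, b: str) -> float:
    """Fraction of region ``a``'s voxels that lie inside region ``b``.

    Equals 1.0 when ``a`` is physically contained in ``b``, 0.0 when the
    masks are disjoint.
    """
    idx_a = atlas.region(a).indices
    idx_b = atlas.region(b).indices
    shared = np.intersect1d(idx_a, idx_b, assume_unique=True).size
    return shared / idx_a.size


def strongest_correlated_regions(
    report: CorrelationReport,
    focal: str,
    k: int,
    atlas: RegionAtlas | None = None,
    containment_threshold: float = 0.99,
) -> list[tuple[str, float]]:
    """Top-``k`` regions by Pearson r with a focal region.

    The focal region itself is excluded.  When an atlas is supplied, any
    candidate that physically contains the focal region — overlap fraction
    of the focal mask inside the candidate at or above
    ``containment_threshold`` — is excluded too, so containing super-regions
    do not crowd out genuinely distinct candidates.  Ties are broken by
    region-table order; negative correlations are kept (they simply rank
    last).  Returns at most ``min(k, eligible)`` ``(region_id, r)`` pairs in
    descending r.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    row = report.focal_row(focal)
    eligible: list[tuple[str, float]] = []
    for rid, r in zip(report.region_ids, row):
        if rid == focal:
            continue
        if atlas is not None:
            if region_overlap_fraction(atlas, focal, rid) >= containment_threshold:
                continue
        eligible.append((rid, float(r)))
    # stable sort preserves table order among exact ties
    eligible.sort(key=lambda t: -t[1])
    return eligible[:k]
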