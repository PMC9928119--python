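"""Per-region signal quantification of registered brain stacks.

Turns a set of registered stacks plus an atlas into the subjects × regions
signal matrix.  The per-region statistic is the arithmetic mean over mask
voxels by default (so region size does not dominate); integrated signal
(sum) and median are available as alternatives.

Normalization absorbs subject-level staining/imaging gain.  The default,
``per_brain_mean``, divides each subject's region values by that subject's
whole-stack mean intensity, which makes rows invariant to any global
per-subject intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BrainStack, RegionAtlas, RegionSignalMatrix
from .errors import (
    AllRegionsDroppedError,
    DuplicateSubjectError,
    ShapeMismatchError,
    ValidationError,
)

__all__ = [
    "NormalizationSpec",
    "quantify_region_signals",
    "build_signal_matrix",
    "drop_uninformative_regions",
]

_METHODS = ("none", "per_brain_mean", "per_region_unit_interval", "zscore_per_region")
_STATISTICS = ("mean", "sum", "median")


@dataclass(frozen=True)
class NormalizationSpec:
    """How raw per-region statistics are normalized into the signal matrix.

    method
        ``none`` — raw values;
        ``per_brain_mean`` — each row divided by its subject's whole-stack
        mean intensity (default for stack input);
        ``per_region_unit_interval`` — each column mapped affinely to [0, 1];
        ``zscore_per_region`` — each column standardized to mean 0, sd 1.
    statistic
        per-region summary of mask voxels: ``mean`` (default), ``sum`` or
        ``median``.
    """

    method: str = "per_brain_mean"
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(
                f"unknown normalization method {self.method!r}; choose from {_METHODS}"
            )
        if self.statistic not in _STATISTICS:
            raise ValidationError(
                f"unknown region statistic {self.statistic!r}; choose from {_STATISTICS}"
            )

    @property
    def tag(self) -> str:
        return f"{self.method}[{self.statistic}]"


def quantify_region_signals(
    stack: BrainStack, atlas: RegionAtlas, statistic: str = "mean"
) -> np.ndarray:
    """Raw per-region statistic (no normalization), one entry per atlas region.

    Overlapping regions are computed independently: each region's value
    depends only on its own mask voxels.
    """
    if stack.shape != atlas.shape:
        raise ShapeMismatchError(
            f"stack {stack.subject_id!r} shape {stack.shape} != atlas shape {atlas.shape}"
        )
    if statistic not in _STATISTICS:
        raise ValidationError(f"unknown region statistic {statistic!r}")
    flat = stack.voxels.ravel()
    out = np.empty(atlas.n_regions, dtype=np.float64)
    reducer = {"mean": np.mean, "sum": np.sum, "median": np.median}[statistic]
    for j, region in enumerate(atlas.regions):
        out[j] = reducer(flat[region.indices])
    return out


def _normalize(values: np.ndarray, method: str, stack_means: np.ndarray | None) -> np.ndarray:
    if method == "none":
        return values
    if method == "per_brain_mean":
        if stack_means is None:
            raise ValidationError("per_brain_mean requires whole-stack means")
        if (stack_means <= 0).any():
            raise ValidationError("per_brain_mean undefined for all-zero stacks")
        return values / stack_means[:, None]
    if method == "per_region_unit_interval":
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        span = np.where(span == 0, 1.0, span)
        return (values - lo) / span
    if method == "zscore_per_region":
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValidationError(
                "zscore_per_region undefined for constant columns; "
                "drop them first (drop_uninformative_regions)"
            )
        return (values - mu) / sd
    raise ValidationError(f"unknown normalization method {method!r}")


def build_signal_matrix(
    stacks: list[BrainStack],
    atlas: RegionAtlas,
    norm: NormalizationSpec = NormalizationSpec(),
) -> RegionSignalMatrix:
    """Quantify every stack and assemble the normalized signal matrix.

    Rows are ordered as the input stacks; the applied normalization is
    recorded in ``normalization_tag``.
    """
    ids = [s.subject_id for s in stacks]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateSubjectError(f"duplicate subject_id(s): {dups}")
    raw = np.empty((len(stacks), atlas.n_regions), dtype=np.float64)
    stack_means = np.empty(len(stacks), dtype=np.float64)
    for i, stack in enumerate(stacks):
        raw[i] = quantify_region_signals(stack, atlas, norm.statistic)
        stack_means[i] = stack.voxels.mean()
    values = _normalize(raw, norm.method, stack_means)
    return RegionSignalMatrix.from_arrays(ids, atlas.region_ids, values, norm.tag)


def drop_uninformative_regions(
    m: RegionSignalMatrix, min_variance: float = 0.0
) -> tuple[RegionSignalMatrix, list[str]]:
    """Remove regions whose sample variance is ``<= min_variance``.

    Variegated constructs leave a few regions nearly always on and a few
    nearly always off; (near-)constant columns carry no between-subject
    information and break per-region standardization, so they are removed
    before modeling.  Returns the reduced matrix and the dropped region ids.
    """
    if min_variance < 0:
        raise ValidationError("min_variance must be >= 0")
    values = m.values
    var = values.var(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1])
    # a literally constant column can show variance ~1e-33 from round-off in
    # the mean; range == 0 identifies it exactly
    constant = np.ptp(values, axis=0) == 0
    dropped = [
        r for r, v, c in zip(m.regions, var, constant) if c or v <= min_variance
    ]
    if len(dropped) == m.shape[1]:
        raise AllRegionsDroppedError(
            f"all {m.shape[1]} regions have variance <= {min_variance}; nothing to model"
        )
    out = m.drop_regions(dropped)
    return RegionSignalMatrix(out.data, m.normalization_tag), dropped
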