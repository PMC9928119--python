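"""Data model and file I/O for atlas-registered brain-stack analysis.

The pipeline's central objects are defined here:

* :class:`RegionAtlas` — named voxel masks (possibly overlapping) in a common
  registered space, the quantification units.
* :class:`BrainStack` — one subject's registered 3D intensity volume.
* :class:`RegionSignalMatrix` — the subjects × regions table of per-region
  signal, the object every downstream statistical stage consumes.
* :class:`PhenotypeTable` — per-subject binary phenotype plus genotype class.

Voxel indices are 0-based ``(z, y, x)``; world-coordinate transforms are out
of scope because registration happens upstream.  Volumes are read from
multi-page TIFF (one page per z-slice, via tifffile) or NRRD (via SimpleITK
when available).  Tabular formats are plain UTF-8 CSV/TSV with mandatory
headers so that write→read round-trips are exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRegionError,
    DuplicateSubjectError,
    EmptyRegionError,
    MatrixFormatError,
    PhenotypeLevelsError,
    ShapeMismatchError,
    UnknownRegionError,
    ValidationError,
)

__all__ = [
    "Region",
    "RegionAtlas",
    "BrainStack",
    "RegionSignalMatrix",
    "PhenotypeTable",
    "read_volume",
    "write_volume",
    "read_atlas",
    "read_subjects",
    "read_signal_matrix",
    "write_signal_matrix",
]


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | os.PathLike) -> np.ndarray:
    """Read a 3D volume from multi-page TIFF or NRRD.

    Returns a ``(z, y, x)`` array.  2D images are promoted to a single-slice
    volume.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        vol = np.asarray(tifffile.imread(path))
    elif suffix == ".nrrd":
        try:
            import SimpleITK as sitk
        except ImportError as exc:  # pragma: no cover
            raise ValidationError(
                "reading NRRD requires SimpleITK (install extra 'nrrd')"
            ) from exc
        vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")
    if vol.ndim == 2:
        vol = vol[None, :, :]
    if vol.ndim != 3:
        raise ValidationError(f"{path.name}: expected a 3D volume, got ndim={vol.ndim}")
    return vol


def write_volume(path: str | os.PathLike, vol: np.ndarray) -> None:
    """Write a ``(z, y, x)`` volume as multi-page TIFF or NRRD."""
    path = Path(path)
    suffix = path.suffix.lower()
    vol = np.asarray(vol)
    if suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, vol)
    elif suffix == ".nrrd":
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(vol), str(path))
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# atlas


@dataclass(frozen=True)
class Region:
    """One named atlas region with its voxel mask.

    ``indices`` are flat (raveled, C-order) voxel indices into the atlas
    shape — a compact representation that makes per-region means a single
    ``take``/``mean``.
    """

    region_id: str
    region_name: str
    indices: np.ndarray  # int64, flat voxel indices, sorted, unique

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def coords(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Mask voxels as an ``(n, 3)`` array of (z, y, x) indices."""
        return np.stack(np.unravel_index(self.indices, shape), axis=1)


@dataclass
class RegionAtlas:
    """Ordered collection of (possibly overlapping) region masks.

    Overlap is permitted because anatomical atlases contain nested regions
    (a rhombomere inside the whole rhombencephalon); the ranking stage uses
    :func:`mavenpy.collinearity.region_overlap_fraction` to exclude regions
    that physically contain a focal region.
    """

    shape: tuple[int, int, int]
    regions: list[Region]
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValidationError(f"atlas shape must be 3 positive ints, got {self.shape}")
        n_flat = int(np.prod(self.shape))
        seen: set[str] = set()
        for reg in self.regions:
            if reg.region_id in seen:
                raise DuplicateRegionError(f"duplicate region_id {reg.region_id!r}")
            seen.add(reg.region_id)
            if reg.indices.size == 0:
                raise EmptyRegionError(f"region {reg.region_id!r} has an empty mask")
            if reg.indices.min() < 0 or reg.indices.max() >= n_flat:
                raise ValidationError(
                    f"region {reg.region_id!r} has voxels outside shape {self.shape}"
                )
        self._index = {reg.region_id: i for i, reg in enumerate(self.regions)}

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region(self, region_id: str) -> Region:
        try:
            return self.regions[self._index[region_id]]
        except KeyError:
            raise UnknownRegionError(f"unknown region_id {region_id!r}") from None

    def mask_volume(self, region_id: str) -> np.ndarray:
        """Boolean ``(z, y, x)`` mask for one region."""
        out = np.zeros(int(np.prod(self.shape)), dtype=bool)
        out[self.region(region_id).indices] = True
        return out.reshape(self.shape)

    @classmethod
    def from_masks(
        cls,
        shape: Sequence[int],
        masks: Iterable[tuple[str, str, np.ndarray]],
        voxel_size: Sequence[float] | None = None,
    ) -> "RegionAtlas":
        """Build an atlas from ``(region_id, region_name, boolean volume)`` triples."""
        shape = tuple(int(s) for s in shape)
        regions = []
        for rid, rname, mask in masks:
            mask = np.asarray(mask)
            if mask.shape != shape:
                raise ShapeMismatchError(
                    f"mask for region {rid!r} has shape {mask.shape}, atlas is {shape}"
                )
            idx = np.flatnonzero(mask.astype(bool).ravel()).astype(np.int64)
            regions.append(Region(rid, rname, idx))
        vs = tuple(float(v) for v in voxel_size) if voxel_size is not None else None
        return cls(shape=shape, regions=regions, voxel_size=vs)


def _read_region_table(region_table_path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(region_table_path, sep="\t", dtype=str)
    required = {"region_id", "region_name"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"region table missing columns: {sorted(missing)}")
    if table["region_id"].duplicated().any():
        dups = table["region_id"][table["region_id"].duplicated()].tolist()
        raise DuplicateRegionError(f"duplicate region_id(s) in table: {dups}")
    return table


def read_atlas(
    label_volume_path: str | os.PathLike,
    region_table_path: str | os.PathLike,
) -> RegionAtlas:
    """Read a :class:`RegionAtlas` from a label volume or a mask directory.

    Two on-disk layouts are supported:

    * **Label volume** (fast path, no overlaps): ``label_volume_path`` is a
      TIFF/NRRD of integer labels.  The TSV region table has columns
      ``region_id``, ``region_name``, ``label_value`` — where ``label_value``
      may list several integers separated by ``,`` or ``;`` so one region can
      claim multiple labels.
    * **Mask directory** (allows overlap): ``label_volume_path`` is a
      directory containing one binary mask volume per region.  The table
      needs a ``mask_file`` column naming each region's file; all masks must
      share one shape.

    Regions are ordered exactly as in the table.
    """
    table = _read_region_table(region_table_path)
    path = Path(label_volume_path)

    if path.is_dir():
        if "mask_file" not in table.columns:
            raise ValidationError(
                "mask-directory atlas requires a 'mask_file' column in the region table"
            )
        shape: tuple[int, int, int] | None = None
        triples = []
        for row in table.itertuples(index=False):
            vol = read_volume(path / row.mask_file)
            if shape is None:
                shape = vol.shape
            elif vol.shape != shape:
                raise ShapeMismatchError(
                    f"mask file {row.mask_file!r} has shape {vol.shape}, "
                    f"expected {shape}"
                )
            mask = vol > 0
            if not mask.any():
                raise EmptyRegionError(f"region {row.region_id!r}: mask file is empty")
            triples.append((row.region_id, row.region_name, mask))
        assert shape is not None
        return RegionAtlas.from_masks(shape, triples)

    labels = read_volume(path)
    if "label_value" not in table.columns:
        raise ValidationError("label-volume atlas requires a 'label_value' column")
    regions = []
    flat = labels.ravel()
    for row in table.itertuples(index=False):
        values = [
            int(tok) for tok in str(row.label_value).replace(";", ",").split(",") if tok.strip()
        ]
        idx = np.flatnonzero(np.isin(flat, values)).astype(np.int64)
        if idx.size == 0:
            raise EmptyRegionError(
                f"region {row.region_id!r}: no voxels carry label value(s) {values}"
            )
        regions.append(Region(row.region_id, row.region_name, idx))
    return RegionAtlas(shape=labels.shape, regions=regions)


# ---------------------------------------------------------------------------
# stacks


@dataclass
class BrainStack:
    """One subject's registered intensity volume."""

    subject_id: str
    voxels: np.ndarray  # (z, y, x), finite, >= 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"stack {self.subject_id!r}: expected 3D voxels, got ndim={self.voxels.ndim}"
            )
        if not np.isfinite(self.voxels).all():
            raise ValidationError(f"stack {self.subject_id!r}: non-finite intensities")
        if (self.voxels < 0).any():
            raise ValidationError(f"stack {self.subject_id!r}: negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @classmethod
    def from_file(cls, subject_id: str, path: str | os.PathLike) -> "BrainStack":
        return cls(subject_id=subject_id, voxels=read_volume(path))


# ---------------------------------------------------------------------------
# signal matrix


@dataclass
class RegionSignalMatrix:
    """Subjects × regions table of per-region signal.

    Backed by a pandas DataFrame (rows = subjects, columns = regions) so the
    statistical stages can use label-based alignment; ``normalization_tag``
    records which normalization produced the values.
    """

    data: pd.DataFrame
    normalization_tag: str = "none"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateSubjectError(f"duplicate subject_id(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateRegionError(f"duplicate region column(s): {dups}")
        values = self.data.to_numpy(dtype=np.float64, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixFormatError(
                f"non-finite value at subject {self.data.index[bad[0]]!r}, "
                f"region {self.data.columns[bad[1]]!r}"
            )

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, region_id: str) -> np.ndarray:
        if region_id not in self.data.columns:
            raise UnknownRegionError(f"unknown region_id {region_id!r}")
        return self.data[region_id].to_numpy(dtype=np.float64)

    def subset_regions(self, region_ids: Sequence[str]) -> "RegionSignalMatrix":
        missing = [r for r in region_ids if r not in self.data.columns]
        if missing:
            raise UnknownRegionError(f"unknown region_id(s): {missing}")
        return RegionSignalMatrix(self.data[list(region_ids)].copy(), self.normalization_tag)

    def drop_regions(self, region_ids: Sequence[str]) -> "RegionSignalMatrix":
        keep = [r for r in self.regions if r not in set(region_ids)]
        return self.subset_regions(keep)

    @classmethod
    def from_arrays(
        cls,
        subjects: Sequence[str],
        regions: Sequence[str],
        values: np.ndarray,
        normalization_tag: str = "none",
    ) -> "RegionSignalMatrix":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(subjects), len(regions)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(subjects)} subjects x {len(regions)} regions"
            )
        df = pd.DataFrame(values, index=list(subjects), columns=list(regions))
        df.index.name = "subject_id"
        return cls(df, normalization_tag)


def _meta_path(path: str | os.PathLike) -> Path:
    return Path(str(path) + ".meta.json")


def write_signal_matrix(m: RegionSignalMatrix, path: str | os.PathLike) -> None:
    """Write a signal matrix as CSV (first column ``subject_id``).

    Floats are written with ``repr`` precision so that ``read(write(m))``
    reproduces the matrix bit-exactly.  The normalization tag travels in a
    small ``<name>.meta.json`` sidecar so provenance survives the round trip.
    """
    import json

    df = m.data.copy()
    df.index.name = "subject_id"
    df.to_csv(path)  # pandas writes repr-precision floats: exact round-trip
    _meta_path(path).write_text(
        json.dumps({"normalization_tag": m.normalization_tag}) + "\n"
    )


def read_signal_matrix(
    path: str | os.PathLike, normalization_tag: str | None = None
) -> RegionSignalMatrix:
    """Read a signal matrix CSV written by :func:`write_signal_matrix`.

    The normalization tag comes from the sidecar when present, else from the
    ``normalization_tag`` argument (default ``"none"``).  Blank or
    non-numeric cells raise :class:`MatrixFormatError` naming the row/column
    of the first offending cell.
    """
    import json

    if normalization_tag is None:
        meta = _meta_path(path)
        if meta.is_file():
            normalization_tag = json.loads(meta.read_text()).get(
                "normalization_tag", "none"
            )
        else:
            normalization_tag = "none"
    raw = pd.read_csv(path, dtype=str)
    if raw.columns[0] != "subject_id":
        raise MatrixFormatError(
            f"first column must be 'subject_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("subject_id")
    cells = raw.to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=np.float64)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            try:
                # Python float(): correctly-rounded parse, so write->read
                # round-trips bit-exactly (pandas' fast parser does not)
                values[i, j] = float(cells[i, j])
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"blank or non-numeric cell at subject {raw.index[i]!r}, "
                    f"region {raw.columns[j]!r}"
                ) from None
    df = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns)
    df.index.name = "subject_id"
    return RegionSignalMatrix(df, normalization_tag)


# ---------------------------------------------------------------------------
# phenotype table


@dataclass
class PhenotypeTable:
    """Per-subject binary phenotype (0 = typical/unrescued, 1 = shifted/rescued)
    and a free categorical genotype label."""

    data: pd.DataFrame  # index subject_id; columns phenotype (int), genotype (str)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateSubjectError(f"duplicate subject_id(s): {dups}")
        levels = sorted(set(self.data["phenotype"].tolist()))
        if not set(levels) <= {0, 1}:
            raise PhenotypeLevelsError(
                f"phenotype must be binary 0/1, got levels {levels}"
            )

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotype(self) -> np.ndarray:
        return self.data["phenotype"].to_numpy(dtype=np.int64)

    @property
    def genotype(self) -> np.ndarray:
        return self.data["genotype"].to_numpy(dtype=object)

    def aligned_to(self, m: RegionSignalMatrix) -> "PhenotypeTable":
        """Rows reordered to match a signal matrix; every matrix subject must
        have exactly one phenotype row."""
        missing = [s for s in m.subjects if s not in self.data.index]
        if missing:
            raise ValidationError(f"subjects missing from phenotype table: {missing}")
        return PhenotypeTable(self.data.loc[m.subjects].copy())

    @classmethod
    def from_arrays(
        cls,
        subjects: Sequence[str],
        phenotype: Sequence[int],
        genotype: Sequence[str] | None = None,
    ) -> "PhenotypeTable":
        if genotype is None:
            genotype = ["wt"] * len(list(subjects))
        df = pd.DataFrame(
            {
                "phenotype": np.asarray(phenotype, dtype=np.int64),
                "genotype": list(genotype),
            },
            index=list(subjects),
        )
        df.index.name = "subject_id"
        return cls(df)

    def to_csv(self, path: str | os.PathLike) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.data.to_csv(path, sep=sep)


def read_subjects(
    table_path: str | os.PathLike,
    positive_level: str | None = None,
) -> PhenotypeTable:
    """Read a subject table (CSV or TSV by extension) with columns
    ``subject_id``, ``phenotype``, ``genotype``.

    The phenotype column may hold ``{0, 1}`` or exactly two string levels; in
    the latter case ``positive_level`` names the level coded 1 (defaults to
    the lexicographically larger level, and the coercion is recorded nowhere
    else, so declare it explicitly for real data).
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    # keep_default_na: genotype labels like "NA" are real categories here
    df = pd.read_csv(table_path, sep=sep, dtype=str, keep_default_na=False)
    required = {"subject_id", "phenotype", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"subject table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df["subject_id"][df["subject_id"].duplicated()].tolist()
        raise DuplicateSubjectError(f"duplicate subject_id(s): {dups}")
    levels = sorted(df["phenotype"].unique().tolist())
    if set(levels) <= {"0", "1"}:
        phen = df["phenotype"].astype(int)
    elif len(levels) == 2:
        pos = positive_level if positive_level is not None else levels[1]
        if pos not in levels:
            raise PhenotypeLevelsError(
                f"positive_level {pos!r} not among phenotype levels {levels}"
            )
        phen = (df["phenotype"] == pos).astype(int)
    else:
        raise PhenotypeLevelsError(
            f"phenotype must have exactly 2 levels, got {levels}"
        )
    out = pd.DataFrame(
        {"phenotype": phen.to_numpy(), "genotype": df["genotype"].tolist()},
        index=df["subject_id"].tolist(),
    )
    out.index.name = "subject_id"
    return PhenotypeTable(out)
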