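"""Read/write ion-count stacks, ROI label maps and result tables.

On-disk layout of a measurement session::

    session_dir/
      manifest.json      # species_files, pixel_size_nm, planes, raster, ...
      CN14.tif           # one multi-page TIFF per secondary-ion species
      CN15.tif
      S32.tif
      S34.tif

Stacks are stored as unsigned-integer multi-page TIFFs (16-bit when the
counts fit, 32-bit otherwise); pixel coordinates are 0-based, row-major,
origin top-left.  ROI label maps are an integer-label TIFF (label 0 = "no
ROI") paired with a CSV class table.  All round trips are lossless for
integer data; float tables are written with 6 significant digits.

Readers validate rather than coerce: negative or fractional pixel values,
manifest/file dimension mismatches, orphan labels and off-vocabulary class
names each raise a dedicated error from :mod:`nanosip.errors`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ConsistencyError,
    DimensionError,
    FormatError,
    InvalidArgumentError,
    MissingFileError,
    OrphanLabelError,
)
from .organelles import OrganelleClass, parse_class

__all__ = [
    "Species",
    "IonCountStack",
    "MeasurementSession",
    "ROILabelMap",
    "write_session",
    "read_session",
    "write_label_map",
    "read_label_map",
    "write_table",
]

CONDITIONS = ("dysoxic", "anoxic", "natural")

MANIFEST_NAME = "manifest.json"
LABEL_TABLE_COLUMNS = ("label", "roi_id", "class", "condition", "chamber")


class Species(str, Enum):
    """Secondary-ion species measured by the multicollector.

    ``C12``/``C13`` are accepted tags (they are acquired alongside the CN
    pair) but are not used by any downstream quantification.
    """

    C12 = "C12"
    C13 = "C13"
    CN14 = "CN14"  # 12C14N-
    CN15 = "CN15"  # 12C15N-
    S32 = "S32"  # 32S-
    S34 = "S34"  # 34S-

    def __str__(self) -> str:
        return self.value


def _as_species(tag) -> Species:
    try:
        return Species(str(tag))
    except ValueError:
        raise InvalidArgumentError(
            f"unknown species tag {tag!r}; accepted: {[s.value for s in Species]}"
        ) from None


@dataclass
class IonCountStack:
    """A planes × rows × cols stack of non-negative integer ion counts."""

    species: Species
    counts: np.ndarray
    pixel_size_nm: float

    def __post_init__(self):
        self.species = _as_species(self.species)
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise DimensionError(
                f"stack must be planes×rows×cols, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise FormatError("ion counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError("ion counts must be non-negative")
        self.counts = counts

    @property
    def planes(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple:
        return self.counts.shape[1:]


@dataclass
class MeasurementSession:
    """Co-registered stacks for one analyzed field, with acquisition metadata."""

    stacks: dict
    pixel_size_nm: float
    condition: str
    specimen_id: str = "phantom"
    seed: int | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidArgumentError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        self.stacks = {_as_species(k): v for k, v in self.stacks.items()}
        shapes = {s.counts.shape for s in self.stacks.values()}
        if len(shapes) > 1:
            raise DimensionError(f"stacks disagree in shape: {sorted(shapes)}")

    @property
    def planes(self) -> int:
        return next(iter(self.stacks.values())).planes

    @property
    def raster(self) -> int:
        return next(iter(self.stacks.values())).counts.shape[1]

    @property
    def shape(self) -> tuple:
        return next(iter(self.stacks.values())).counts.shape[1:]

    @property
    def field_size_um(self) -> float:
        return self.raster * self.pixel_size_nm / 1000.0


@dataclass
class ROILabelMap:
    """Integer label image plus the table mapping labels to ROI metadata.

    ``labels`` is rows×cols with 0 meaning "no ROI"; ``table`` has columns
    (label, roi_id, class, condition, chamber).  Labels need not be
    contiguous, but every nonzero label must have a table row and every
    class name must be canonical.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise DimensionError(f"label map must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(np.mod(labels, 1) == 0):
                raise FormatError("labels must be integer-valued")
            labels = labels.astype(np.int64)
        if np.any(labels < 0):
            raise FormatError("labels must be non-negative")
        self.labels = labels

        table = pd.DataFrame(self.table)
        missing_cols = set(LABEL_TABLE_COLUMNS) - set(table.columns)
        if missing_cols:
            raise FormatError(f"label table missing columns {sorted(missing_cols)}")
        table = table.loc[:, list(LABEL_TABLE_COLUMNS)].copy()
        table["label"] = table["label"].astype(int)
        table["class"] = [parse_class(c).value for c in table["class"]]
        self.table = table

        present = set(np.unique(labels)) - {0}
        known = set(table["label"])
        orphans = present - known
        if orphans:
            raise OrphanLabelError(orphans)

    def class_of(self) -> dict:
        """Mapping label -> OrganelleClass."""
        return {
            int(row.label): OrganelleClass(row["class"])
            for _, row in self.table.iterrows()
        }

    def downsample(self, factor: int) -> "ROILabelMap":
        """Stride-subsample the label image (for coarser rasters)."""
        if factor < 1:
            raise InvalidArgumentError("downsample factor must be >= 1")
        return ROILabelMap(self.labels[::factor, ::factor], self.table)


# ---------------------------------------------------------------------------
# Sessions


def _tiff_dtype(counts: np.ndarray):
    return np.uint16 if counts.max(initial=0) < 2**16 else np.uint32


def write_session(session: MeasurementSession, directory) -> Path:
    """Write a session as per-species multi-page TIFFs plus a JSON manifest.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    species_files = {}
    for species, stack in session.stacks.items():
        fname = f"{species.value}.tif"
        tifffile.imwrite(
            directory / fname, stack.counts.astype(_tiff_dtype(stack.counts))
        )
        species_files[species.value] = fname
    manifest = {
        "species_files": species_files,
        "pixel_size_nm": session.pixel_size_nm,
        "planes": session.planes,
        "raster": session.raster,
        "condition": session.condition,
        "specimen_id": session.specimen_id,
    }
    if session.seed is not None:
        manifest["seed"] = int(session.seed)
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_session(directory) -> MeasurementSession:
    """Read a session written by :func:`write_session`, validating invariants."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise MissingFileError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    stacks = {}
    for tag, fname in manifest["species_files"].items():
        species = _as_species(tag)
        path = directory / fname
        if not path.exists():
            raise MissingFileError(f"manifest lists {fname} but file is missing")
        counts = tifffile.imread(path)
        if counts.ndim == 2:  # single-plane stacks round-trip as 2-D pages
            counts = counts[None, :, :]
        if np.issubdtype(counts.dtype, np.floating):
            if np.any(np.mod(counts, 1) != 0):
                raise FormatError(f"{fname}: non-integer pixel values")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError(f"{fname}: negative pixel values")
        if counts.shape[0] != manifest["planes"]:
            raise ConsistencyError(
                f"{fname}: {counts.shape[0]} planes, manifest says {manifest['planes']}"
            )
        if counts.shape[1] != manifest["raster"] or counts.shape[2] != manifest["raster"]:
            raise ConsistencyError(
                f"{fname}: raster {counts.shape[1:]} != manifest {manifest['raster']}"
            )
        stacks[species] = IonCountStack(
            species=species, counts=counts, pixel_size_nm=manifest["pixel_size_nm"]
        )
    return MeasurementSession(
        stacks=stacks,
        pixel_size_nm=manifest["pixel_size_nm"],
        condition=manifest["condition"],
        specimen_id=manifest.get("specimen_id", "unknown"),
        seed=manifest.get("seed"),
    )


# ---------------------------------------------------------------------------
# Label maps


def write_label_map(label_map: ROILabelMap, prefix) -> tuple:
    """Write ``<prefix>_labels.tif`` and ``<prefix>_classes.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tif_path = prefix.parent / (prefix.name + "_labels.tif")
    csv_path = prefix.parent / (prefix.name + "_classes.csv")
    tifffile.imwrite(tif_path, label_map.labels.astype(np.int32))
    label_map.table.to_csv(csv_path, index=False)
    return tif_path, csv_path


def read_label_map(prefix) -> ROILabelMap:
    """Read a label map written by :func:`write_label_map`."""
    prefix = Path(prefix)
    tif_path = prefix.parent / (prefix.name + "_labels.tif")
    csv_path = prefix.parent / (prefix.name + "_classes.csv")
    for p in (tif_path, csv_path):
        if not p.exists():
            raise MissingFileError(str(p))
    labels = tifffile.imread(tif_path)
    table = pd.read_csv(csv_path)
    # ROILabelMap.__post_init__ enforces orphan/vocabulary invariants
    if "chamber" in table.columns:
        table["chamber"] = table["chamber"].astype(object).where(table["chamber"].notna(), "")
    return ROILabelMap(labels=labels, table=table)


# ---------------------------------------------------------------------------
# Result tables


def write_table(rows, path, columns=None) -> Path:
    """Write homogeneous rows as an RFC-4180 CSV (UTF-8, '.' decimal).

    ``rows`` may be a DataFrame, a sequence of dataclass instances, or a
    sequence of dicts; dataclass field order (or ``columns``) fixes the
    column order.  Floats are serialized with 6 significant digits.  An
    empty sequence with ``columns`` given yields a header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows and dataclasses.is_dataclass(rows[0]):
            order = [f.name for f in dataclasses.fields(rows[0])]
            frame = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=order)
        else:
            frame = pd.DataFrame(rows)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    frame.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
    return path
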