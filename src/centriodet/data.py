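"""Data layer: fields of view, datasets, and annotation I/O.

A *field of view* is a multi-channel z-stack stored as 16-bit OME-TIFF
with canonical axis order ``(channel, z, row, col)``. Focus annotations
travel as CSV files with an ``x,y`` header, origin at the top-left of
the image, ``x`` being the column and ``y`` the row. Nucleus annotations
are integer label masks (16-bit PNG or TIFF).

Internally every coordinate is ``(row, col)``, 0-based; the ``x,y``
order exists only at the CSV boundary.
"""

from __future__ import annotations

import csv
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Lateral pixel pitch assumed when a file carries no calibration (nm/px).
DEFAULT_PIXEL_SIZE_NM = 102.5
#: Axial step between z-sections assumed by default (nm).
DEFAULT_Z_STEP_NM = 300.0

CANONICAL_AXES = "CZYX"


class DataError(ValueError):
    """Raised for unreadable or malformed dataset files."""


@dataclass
class FieldStack:
    """One field of view: intensities indexed as (channel, z, row, col)."""

    name: str
    intensities: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_step_nm: float = DEFAULT_Z_STEP_NM

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 4:
            raise DataError(f"field '{self.name}': expected 4-D (c,z,y,x), got {a.ndim}-D")
        if a.dtype != np.uint16:
            if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 65535:
                a = a.astype(np.uint16)
            else:
                raise DataError(f"field '{self.name}': expected unsigned 16-bit intensities")
        if min(a.shape) < 1:
            raise DataError(f"field '{self.name}': empty dimension in shape {a.shape}")
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise DataError("pixel_size_nm and z_step_nm must be positive")
        self.intensities = a

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.intensities.shape


@dataclass
class Projection:
    """Per-channel maximum-intensity projection of a FieldStack."""

    name: str
    planes: np.ndarray  # (channel, row, col) uint16

    def __post_init__(self) -> None:
        a = np.asarray(self.planes)
        if a.ndim != 3:
            raise DataError(f"projection '{self.name}': expected 3-D (c,y,x)")
        self.planes = a.astype(np.uint16, copy=False)


@dataclass
class FociList:
    """Sub-pixel point detections/annotations for one field and channel.

    ``points`` is an (n, 2) float array of (row, col); ``scores`` is an
    optional per-point confidence in [0, 1], sorted to match ``points``.
    """

    field: str = ""
    channel: int = 0
    points: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 2)))
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts
        if self.scores is not None:
            s = np.asarray(self.scores, dtype=float).ravel()
            if s.size != len(pts):
                raise DataError("scores length must match points")
            self.scores = s

    def __len__(self) -> int:
        return len(self.points)


def max_project(stack: FieldStack) -> Projection:
    """Collapse the z-axis by per-pixel maximum, channel by channel."""
    return Projection(stack.name, stack.intensities.max(axis=1))


# ---------------------------------------------------------------------------
# image I/O

def _axes_to_canonical(data: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper()
    if sorted(axes) != sorted(CANONICAL_AXES):
        raise DataError(f"cannot normalise axes '{axes}' to {CANONICAL_AXES}")
    return np.transpose(data, [axes.index(a) for a in CANONICAL_AXES])


def _pixel_size_from_ome(xml_text: str) -> float | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
            size = float(el.attrib["PhysicalSizeX"])
            unit = el.attrib.get("PhysicalSizeXUnit", "µm")
            scale = {"nm": 1.0, "µm": 1e3, "um": 1e3, "mm": 1e6}.get(unit)
            return size * scale if scale else None
    return None


def read_field(path, axes: str | None = None,
               pixel_size_nm: float | None = None,
               z_step_nm: float | None = None) -> FieldStack:
    """Read a z-stack TIFF into canonical (channel, z, row, col) order.

    ``axes`` overrides the on-file axis order (e.g. ``"ZCYX"``) when the
    file metadata is absent or wrong. Pixel size is taken from OME-XML
    when present, else from the override, else the package default with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cannot read field: no such file {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            file_axes = getattr(series, "axes", "") or ""
            ome = tif.ome_metadata
    except (tifffile.TiffFileError, OSError) as exc:
        raise DataError(f"unreadable TIFF {path}: {exc}") from exc

    if data.ndim == 3:  # single z-slice or single channel: promote
        data = data[:, None, :, :] if axes in (None, "CYX") else data[None]
        file_axes = ""
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 4-D stack, got shape {data.shape}")

    order = (axes or "").upper() or file_axes.upper()
    if sorted(order) != sorted(CANONICAL_AXES):
        if axes is None and data.shape[0] <= 8 <= data.shape[-1]:
            order = CANONICAL_AXES  # heuristically already canonical
        else:
            raise DataError(
                f"{path}: ambiguous axis order '{order or '?'}'; pass axes='CZYX'-style override")
    data = _axes_to_canonical(data, order)

    px = pixel_size_nm
    if px is None and ome:
        px = _pixel_size_from_ome(ome)
    if px is None:
        logger.warning("%s: no pixel-size metadata; assuming %.1f nm/px",
                       path.name, DEFAULT_PIXEL_SIZE_NM)
        px = DEFAULT_PIXEL_SIZE_NM
    name = path.name
    for suffix in (".ome.tif", ".ome.tiff", ".tif", ".tiff"):
        if name.lower().endswith(suffix):
            name = name[: -len(suffix)]
            break
    return FieldStack(name, data, pixel_size_nm=px,
                      z_step_nm=z_step_nm or DEFAULT_Z_STEP_NM)


def write_field(stack: FieldStack, path) -> None:
    """Write a FieldStack as OME-TIFF with CZYX axes and pixel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, stack.intensities, ome=True,
        metadata={
            "axes": CANONICAL_AXES,
            "PhysicalSizeX": stack.pixel_size_nm / 1e3,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_nm / 1e3,
            "PhysicalSizeYUnit": "µm",
        },
    )


def write_projection(proj: Projection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, proj.planes, photometric="minisblack")


def read_projection(path) -> Projection:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return Projection(path.stem, data)


# ---------------------------------------------------------------------------
# foci CSV I/O — dialect: comma-separated, header "x,y", origin top-left

def write_foci(foci: FociList, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write("x,y\n")
        for r, c in foci.points:
            fh.write(f"{_fmt(c)},{_fmt(r)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_foci(path, field: str = "", channel: int = 0) -> FociList:
    """Read an x,y CSV; integer and sub-pixel coordinates both accepted."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such foci file {path}")
    points = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["x", "y"]:
            raise DataError(f"{path}: expected 'x,y' header, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                x, y = float(row[0]), float(row[1])
            except (ValueError, IndexError) as exc:
                raise DataError(f"{path}:{lineno}: malformed row {row!r}") from exc
            points.append((y, x))
    return FociList(field=field or path.stem, channel=channel, points=np.array(points).reshape(-1, 2))


# ---------------------------------------------------------------------------
# label-mask I/O (16-bit single-channel PNG or TIFF)

def write_mask(labels, path) -> None:
    """Write an integer label image (0 = background). Accepts an ndarray
    or any object with a ``labels`` attribute."""
    grid = np.asarray(getattr(labels, "labels", labels))
    if grid.ndim != 2:
        raise DataError("label mask must be 2-D")
    if grid.min() < 0 or grid.max() > 65535:
        raise DataError("label values must fit unsigned 16-bit")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = grid.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out, extension=path.suffix or ".png")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such mask file {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
    else:
        grid = iio.imread(path)
    if grid.ndim != 2 or not np.issubdtype(grid.dtype, np.integer):
        raise DataError(f"{path}: expected a 2-D integer label image, got "
                        f"{grid.dtype} with shape {grid.shape}")
    return grid.astype(np.int32)


# ---------------------------------------------------------------------------
# dataset layout and train/test split

@dataclass
class Dataset:
    """A directory of fields with annotations and a train/test split.

    Layout under ``root``::

        raw/<field>.ome.tif
        projections/<field>.tif
        annotations/centrioles/<field>_C<ch>.csv
        annotations/cells/<field>.png
        predictions/
        train.txt, test.txt      (lines "field,channel")

    By convention the nuclei live in channel 0 and the remaining
    channels carry centriolar/procentriolar/PCM markers.
    """

    root: Path
    fields: list[str] = dc_field(default_factory=list)
    nuclei_channel: int = 0
    marker_channels: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    # -- paths ----------------------------------------------------------
    @property
    def raw_dir(self) -> Path:
        return self.root / "raw"

    @property
    def projections_dir(self) -> Path:
        return self.root / "projections"

    @property
    def predictions_dir(self) -> Path:
        return self.root / "predictions"

    def raw_path(self, field: str) -> Path:
        return self.raw_dir / f"{field}.ome.tif"

    def projection_path(self, field: str) -> Path:
        return self.projections_dir / f"{field}.tif"

    def foci_annotation_path(self, field: str, channel: int) -> Path:
        return self.root / "annotations" / "centrioles" / f"{field}_C{channel}.csv"

    def mask_annotation_path(self, field: str) -> Path:
        return self.root / "annotations" / "cells" / f"{field}.png"

    # -- discovery ------------------------------------------------------
    @classmethod
    def discover(cls, root, **kwargs) -> "Dataset":
        root = Path(root)
        raw = root / "raw"
        if not raw.is_dir():
            raise DataError(f"dataset root {root} has no raw/ directory")
        names = sorted({p.name.split(".")[0] for p in raw.iterdir()
                        if p.suffix.lower() in (".tif", ".tiff")})
        if not names:
            raise DataError(f"no TIFF fields found under {raw}")
        ds = cls(root=root, fields=names, **kwargs)
        return ds

    # -- split ----------------------------------------------------------
    def make_split(self, seed: int, test_fraction: float = 0.1
                   ) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
        """Deterministic train/test split with even marker representation.

        Fields are shuffled with ``seed``; one marker channel per field is
        assigned round-robin over ``marker_channels`` so every marker is
        represented nearly equally; within each marker the first
        ~``test_fraction`` of fields go to the test set. Each field lands
        on exactly one side with exactly one centriolar channel.
        """
        rng = np.random.default_rng(seed)
        order = [self.fields[i] for i in rng.permutation(len(self.fields))]
        assigned = [(f, self.marker_channels[i % len(self.marker_channels)])
                    for i, f in enumerate(order)]
        train: list[tuple[str, int]] = []
        test: list[tuple[str, int]] = []
        for ch in self.marker_channels:
            group = [(f, c) for f, c in assigned if c == ch]
            n_test = int(np.floor(len(group) * test_fraction + 0.5))
            n_test = min(max(n_test, 1 if len(group) > 1 else 0), len(group) - 1)
            test.extend(group[:n_test])
            train.extend(group[n_test:])
        train.sort()
        test.sort()
        self._write_split(train, test)
        return train, test

    def _split_file(self, which: str) -> Path:
        return self.root / f"{which}.txt"

    def _write_split(self, train, test) -> None:
        for which, items in (("train", train), ("test", test)):
            with open(self._split_file(which), "w") as fh:
                for f, c in items:
                    fh.write(f"{f},{c}\n")

    def load_split(self, which: str) -> list[tuple[str, int]]:
        path = self._split_file(which)
        if not path.exists():
            raise DataError(f"{path} missing; run make_split first")
        items = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    f, c = line.rsplit(",", 1)
                    items.append((f, int(c)))
        return items

    # -- convenience loaders -------------------------------------------
    def load_plane(self, field: str, channel: int) -> np.ndarray:
        """Max-projected plane of one channel, projecting on the fly if
        no cached projection exists."""
        proj_path = self.projection_path(field)
        if proj_path.exists():
            return read_projection(proj_path).planes[channel]
        return max_project(read_field(self.raw_path(field))).planes[channel]

    def load_annotation(self, field: str, channel: int) -> FociList:
        return read_foci(self.foci_annotation_path(field, channel),
                         field=field, channel=channel)
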