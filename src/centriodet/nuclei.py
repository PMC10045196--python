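"""Nucleus segmentation from the DNA channel and visibility filtering.

The field-resolution DNA projection is mean-binned to ~256x256 before
segmentation (nuclei are huge relative to foci, so resolution is cheap
to give away), segmented, and the label grid is upscaled back by
nearest neighbour. Nuclei touching the image border are flagged so that
partially visible cells can be excluded from per-cell counting.

Two backends exist: ``"pretrained"`` adapts the published star-convex
fluorescence model when that package is importable, and ``"classical"``
is a self-contained Otsu-threshold + distance-transform watershed that
needs no model download.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .data import DataError


@dataclass
class NucleusRecord:
    label: int
    centroid: tuple[float, float]  # (row, col) at full resolution
    area: int
    touches_border: bool


@dataclass
class NucleiLabels:
    """Integer label mask (0 = background, labels contiguous 1..N)."""

    labels: np.ndarray
    records: list[NucleusRecord] = dc_field(default_factory=list)

    @classmethod
    def from_labels(cls, grid: np.ndarray) -> "NucleiLabels":
        grid = np.asarray(grid)
        if grid.ndim != 2 or not np.issubdtype(grid.dtype, np.integer):
            raise DataError("label grid must be a 2-D integer image")
        grid = _relabel_contiguous(grid.astype(np.int32))
        records = []
        h, w = grid.shape
        for prop in measure.regionprops(grid):
            (r0, c0, r1, c1) = prop.bbox
            records.append(NucleusRecord(
                label=prop.label,
                centroid=tuple(prop.centroid),
                area=int(prop.area),
                touches_border=bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
            ))
        return cls(labels=grid, records=records)

    @property
    def n_nuclei(self) -> int:
        return len(self.records)

    def centroids(self) -> np.ndarray:
        return np.array([rec.centroid for rec in self.records]).reshape(-1, 2)


def _relabel_contiguous(grid: np.ndarray) -> np.ndarray:
    present = np.unique(grid)
    present = present[present > 0]
    lut = np.zeros(int(grid.max()) + 1 if grid.size else 1, np.int32)
    for new, old in enumerate(present, start=1):
        lut[old] = new
    return lut[grid]


def _mean_bin(plane: np.ndarray, factor: int) -> np.ndarray:
    h, w = plane.shape
    hc, wc = h - h % factor, w - w % factor
    x = plane[:hc, :wc].astype(np.float32)
    return x.reshape(hc // factor, factor, wc // factor, factor).mean(axis=(1, 3))


def _classical_segment(binned: np.ndarray, min_area: int, smoothing: float,
                       marker_min_distance: int) -> np.ndarray:
    sm = ndimage.gaussian_filter(binned.astype(np.float32), smoothing)
    if sm.max() <= sm.min():
        return np.zeros(binned.shape, np.int32)
    thr = filters.threshold_otsu(sm)
    fg = sm > thr
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        return np.zeros(binned.shape, np.int32)
    dist = ndimage.distance_transform_edt(fg)
    # marker per distance peak; plateaus collapse to one marker each
    from skimage.feature import peak_local_max
    peaks = peak_local_max(dist, min_distance=marker_min_distance,
                           labels=fg, exclude_border=False)
    markers = np.zeros(binned.shape, np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    lab = segmentation.watershed(-dist, markers, mask=fg)
    return lab.astype(np.int32)


def segment_nuclei(dna_plane: np.ndarray, backend: str = "classical",
                   bin_target: int = 256, min_area_binned: int = 30,
                   smoothing: float = 2.0, marker_min_distance: int = 8
                   ) -> NucleiLabels:
    """Segment nuclei in a max-projected DNA plane.

    The plane is mean-binned so its larger side is ~``bin_target``
    pixels, segmented by the chosen backend, and upscaled back to full
    resolution (nearest neighbour). ``min_area_binned`` is in binned
    pixels.
    """
    plane = np.asarray(dna_plane)
    if plane.ndim != 2:
        raise DataError("segment_nuclei expects a single-channel 2-D plane")
    factor = max(1, int(round(max(plane.shape) / bin_target)))
    binned = _mean_bin(plane, factor)

    if backend == "classical":
        lab_binned = _classical_segment(binned, min_area_binned, smoothing,
                                        marker_min_distance)
    elif backend == "pretrained":
        lab_binned = _stardist_segment(binned)
    else:
        raise ValueError(f"unknown backend '{backend}' (use 'pretrained' or 'classical')")

    full = np.kron(lab_binned, np.ones((factor, factor), np.int32))
    h, w = plane.shape
    out = np.zeros((h, w), np.int32)
    fh, fw = min(h, full.shape[0]), min(w, full.shape[1])
    out[:fh, :fw] = full[:fh, :fw]
    return NucleiLabels.from_labels(out)


def _stardist_segment(binned: np.ndarray) -> np.ndarray:
    try:
        from csbdeep.utils import normalize  # type: ignore
        from stardist.models import StarDist2D  # type: ignore
    except ImportError as exc:
        raise RuntimeError(
            "the 'pretrained' backend needs the stardist/csbdeep packages and "
            "a model download; use backend='classical' for a self-contained "
            "segmentation") from exc
    model = StarDist2D.from_pretrained("2D_versatile_fluo")
    lab, _ = model.predict_instances(normalize(binned, 1, 99.8))
    return lab.astype(np.int32)


def filter_visible(nuclei: NucleiLabels) -> NucleiLabels:
    """Drop partially visible (border-touching) nuclei and relabel 1..N,
    preserving the original label order."""
    drop = {rec.label for rec in nuclei.records if rec.touches_border}
    grid = nuclei.labels.copy()
    for lab in drop:
        grid[grid == lab] = 0
    return NucleiLabels.from_labels(grid)
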