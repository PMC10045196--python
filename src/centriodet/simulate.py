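"""Seeded generator of synthetic immunofluorescence fields.

Emulates the data regime the detector is built for: a dim DNA channel
with large smooth nuclei, and a marker channel with sparse, bright,
diffraction-limited foci arranged in centriole-procentriole pairs ~3 px
apart, on a 16-bit noisy background (signal-dependent counting noise
plus Gaussian read noise). Exact ground truth (focus coordinates and
nucleus label masks) is returned alongside the pixels, making every
pipeline stage testable without any external download.

Geometry is scaled down relative to a real 2048-px field — the default
side is 256 px and nuclei are drawn smaller than life — but the pixel
pitch and the 3-px pair separation, the quantities detection accuracy
hinges on, are kept at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data import (DEFAULT_PIXEL_SIZE_NM, DEFAULT_Z_STEP_NM, Dataset,
                   FieldStack, FociList, max_project, write_field, write_foci,
                   write_mask, write_projection)
from .nuclei import NucleiLabels


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic field; reproducible per ``seed``.

    ``foci_per_nucleus`` may be a single even count or a sequence of
    counts sampled per nucleus (0 models the Centrinone-like depleted
    condition). With ``n_nuclei == 0`` the field is a pure foci field:
    ``free_pairs`` pairs (int or inclusive (lo, hi) range) are scattered
    uniformly with a minimum spacing between pairs.
    """

    side: int = 256
    n_nuclei: int = 4
    foci_per_nucleus: int | tuple[int, ...] = 4
    free_pairs: int | tuple[int, int] = (2, 8)
    pair_separation: float = 3.0
    spot_sigma: float = 1.5
    spot_peak: float = 2000.0
    background: float = 500.0
    photons_per_adu: float = 0.05
    read_noise: float = 50.0
    nucleus_radius: tuple[float, float] = (14.0, 22.0)
    nucleus_intensity: float = 3000.0
    n_z: int = 3
    n_marker_channels: int = 1
    min_pair_spacing: float = 12.0
    noise: bool = True
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_step_nm: float = DEFAULT_Z_STEP_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 32 or self.n_nuclei < 0 or self.pair_separation < 0:
            raise ValueError("invalid synthetic spec")
        counts = (self.foci_per_nucleus,) if np.isscalar(self.foci_per_nucleus) \
            else tuple(self.foci_per_nucleus)
        if any(c < 0 or c % 2 for c in counts):
            raise ValueError("foci_per_nucleus entries must be even and >= 0")


def _z_profile(n_z: int) -> np.ndarray:
    """Out-of-focus attenuation per slice; the central slice is in focus."""
    z = np.arange(n_z) - (n_z - 1) / 2.0
    return np.exp(-(z ** 2) / (2.0 * max(n_z / 3.0, 0.8) ** 2))


def _add_spot(img: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    rad = int(np.ceil(5 * sigma))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    img[r0:r1, c0:c1] += amp * np.exp(-(rr ** 2 + cc ** 2) / (2.0 * sigma ** 2))


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse nuclei; labels 1..N."""
    rmin, rmax = spec.nucleus_radius
    margin = 2.0
    centers, axes, angles = [], [], []
    for _ in range(spec.n_nuclei):
        for attempt in range(200):
            a = rng.uniform(rmin, rmax)
            b = rng.uniform(rmin, rmax)
            if rng.random() < 0.25:
                # a minority of nuclei crosses the field border
                r = rng.uniform(-0.05 * spec.side, 1.05 * spec.side)
                c = rng.uniform(-0.05 * spec.side, 1.05 * spec.side)
            else:
                lo, hi = rmax + 2.0, spec.side - rmax - 2.0
                r = rng.uniform(lo, hi)
                c = rng.uniform(lo, hi)
            if all(np.hypot(r - rc, c - cc) > (max(a, b) + max(ax) + margin)
                   for (rc, cc), ax in zip(centers, axes)):
                centers.append((r, c))
                axes.append((a, b))
                angles.append(rng.uniform(0, np.pi))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_nuclei} nuclei of radius {spec.nucleus_radius} "
                f"in a {spec.side}-px field; reduce the count or the radii")
    labels = np.zeros((spec.side, spec.side), np.int32)
    yy, xx = np.mgrid[0:spec.side, 0:spec.side]
    for i, ((r, c), (a, b), th) in enumerate(zip(centers, axes, angles), start=1):
        dy, dx = yy - r, xx - c
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        labels[inside] = i
    present = [i for i in range(1, spec.n_nuclei + 1) if (labels == i).any()]
    relabel = np.zeros(spec.n_nuclei + 1, np.int32)
    for new, old in enumerate(present, start=1):
        relabel[old] = new
    return relabel[labels], [centers[i - 1] for i in present], [axes[i - 1] for i in present]


def _sample_pair(center_r, center_c, spec: SyntheticSpec, rng) -> np.ndarray:
    phi = rng.uniform(0, 2 * np.pi)
    d = spec.pair_separation / 2.0
    dr, dc = d * np.sin(phi), d * np.cos(phi)
    return np.array([[center_r - dr, center_c - dc], [center_r + dr, center_c + dc]])


def generate_field(spec: SyntheticSpec, return_counts: bool = False):
    """Return ``(FieldStack, FociList truth, NucleiLabels truth)``.

    Channel 0 holds nuclei, channel 1 (and up) the foci markers. Truth
    foci are the sub-pixel Gaussian centres of channel 1; with a
    noise-free render (``spec.noise = False``) they coincide with the
    local maxima of that channel up to pixel rounding. With
    ``return_counts`` a fourth element is returned: the planted focus
    count per nucleus label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1E1D]))
    side = spec.side
    clean_nuc = np.zeros((side, side), np.float64)
    if spec.n_nuclei > 0:
        labels, centers, axes = _place_nuclei(spec, rng)
        from scipy import ndimage
        clean_nuc = ndimage.gaussian_filter((labels > 0).astype(float), 2.0)
        clean_nuc *= spec.nucleus_intensity * rng.uniform(0.7, 1.0)
    else:
        labels = np.zeros((side, side), np.int32)
        centers, axes = [], []

    counts = (spec.foci_per_nucleus,) if np.isscalar(spec.foci_per_nucleus) \
        else tuple(spec.foci_per_nucleus)
    truth_pts: list[np.ndarray] = []
    planted_counts: dict[int, int] = {}
    if spec.n_nuclei > 0:
        for lab, ((r, c), (a, b)) in enumerate(zip(centers, axes), start=1):
            n_foci = int(counts[rng.integers(len(counts))])
            planted_counts[lab] = 0
            for _ in range(n_foci // 2):
                for attempt in range(100):
                    phi = rng.uniform(0, 2 * np.pi)
                    rad = max(a, b) + rng.uniform(3.0, 10.0)
                    pr, pc = r + rad * np.sin(phi), c + rad * np.cos(phi)
                    lo = 2 + spec.pair_separation
                    if not (lo <= pr <= side - 1 - lo and lo <= pc <= side - 1 - lo):
                        continue
                    pair = _sample_pair(pr, pc, spec, rng)
                    if _far_enough(pair, truth_pts, spec.min_pair_spacing):
                        truth_pts.append(pair)
                        planted_counts[lab] += 2
                        break
    else:
        if np.isscalar(spec.free_pairs):
            n_pairs = int(spec.free_pairs)
        else:
            lo, hi = spec.free_pairs
            n_pairs = int(rng.integers(lo, hi + 1))
        for _ in range(n_pairs):
            for attempt in range(200):
                m = 4 + spec.pair_separation
                pr = rng.uniform(m, side - 1 - m)
                pc = rng.uniform(m, side - 1 - m)
                pair = _sample_pair(pr, pc, spec, rng)
                if _far_enough(pair, truth_pts, spec.min_pair_spacing):
                    truth_pts.append(pair)
                    break

    points = np.concatenate(truth_pts, axis=0) if truth_pts else np.empty((0, 2))
    clean_foci = np.zeros((side, side), np.float64)
    for r, c in points:
        _add_spot(clean_foci, r, c, spec.spot_peak * rng.uniform(0.7, 1.3), spec.spot_sigma)

    profile = _z_profile(spec.n_z)
    n_ch = 1 + spec.n_marker_channels
    stack = np.zeros((n_ch, spec.n_z, side, side), np.uint16)
    for z, att in enumerate(profile):
        stack[0, z] = _shoot(att * clean_nuc + spec.background, spec, rng)
        for ch in range(1, n_ch):
            stack[ch, z] = _shoot(att * clean_foci + spec.background, spec, rng)

    name = f"synthetic_{spec.seed:05d}"
    field = FieldStack(name, stack, pixel_size_nm=spec.pixel_size_nm,
                       z_step_nm=spec.z_step_nm)
    foci = FociList(field=name, channel=1, points=points)
    truth_nuclei = NucleiLabels.from_labels(labels)
    if return_counts:
        return field, foci, truth_nuclei, planted_counts
    return field, foci, truth_nuclei


def _far_enough(pair: np.ndarray, placed: list[np.ndarray], spacing: float) -> bool:
    if not placed:
        return True
    prev = np.concatenate(placed, axis=0)
    d = np.hypot(prev[:, 0][:, None] - pair[:, 0], prev[:, 1][:, None] - pair[:, 1])
    return bool(d.min() > spacing)


def _shoot(clean: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply counting + read noise and quantise to unsigned 16-bit."""
    if not spec.noise:
        return np.clip(np.round(clean), 0, 65535).astype(np.uint16)
    lam = np.clip(clean, 0, None) * spec.photons_per_adu
    counts = rng.poisson(lam) / spec.photons_per_adu
    noisy = counts + rng.normal(0.0, spec.read_noise, clean.shape)
    return np.clip(noisy, 0, 65535).astype(np.uint16)


def generate_dataset(spec: SyntheticSpec, root, n_fields: int = 25,
                     split_seed: int | None = None, test_fraction: float = 0.1,
                     write_raw: bool = True) -> Dataset:
    """Write ``n_fields`` synthetic fields in the standard dataset layout.

    Per-field seeds are spawned deterministically from ``spec.seed``.
    Ground-truth foci CSVs and nucleus masks are written as annotations,
    and a train/test split file is produced.
    """
    root = Path(root)
    marker_channels = tuple(range(1, 1 + spec.n_marker_channels))
    ds = Dataset(root=root, fields=[], marker_channels=marker_channels)
    for i in range(n_fields):
        fspec = replace(spec, seed=int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0] % (2 ** 31)))
        field, foci, nuclei = generate_field(fspec)
        name = f"field_{i:03d}"
        field.name = name
        foci.field = name
        if write_raw:
            write_field(field, ds.raw_path(name))
        write_projection(max_project(field), ds.projection_path(name))
        for ch in marker_channels:
            write_foci(foci, ds.foci_annotation_path(name, ch))
        write_mask(nuclei, ds.mask_annotation_path(name))
        ds.fields.append(name)
    ds.make_split(seed=split_seed if split_seed is not None else spec.seed,
                  test_fraction=test_fraction)
    return ds
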