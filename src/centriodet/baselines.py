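"""Reference detectors the multiscale model is compared against.

Three methods sharing the FociList output frame so the same evaluation
applies unchanged: a Laplacian-of-Gaussian scale ladder, an 8-bit
threshold-sweep blob detector with an area filter, and a shallow
four-layer CNN ("FociDetector"-style) whose probability map is
multiplied by the unit-scaled input before peak extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_log
from skimage.measure import label as cc_label, regionprops

from .data import FociList
from .nn import SGD, Conv2d, ReLU, sigmoid
from .nn.losses import weighted_bce_with_logits
from .spot_model import (SpotModelConfig, extract_peaks, make_target_maps,
                      normalize_plane)


# ---------------------------------------------------------------------------
# Laplacian of Gaussian

@dataclass
class LoGConfig:
    """Scale ladder of 10 sigmas from 1 to 2 px, i.e. blob radii of
    sigma*sqrt(2) ~ 1.4 to 2.8 px."""

    sigma_min: float = 1.0
    sigma_max: float = 2.0
    num_sigma: int = 10
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max or self.num_sigma < 1:
            raise ValueError("invalid LoG scale ladder")


def log_blob_radius(sigma: float) -> float:
    """Radius of the blob best detected at scale sigma: sigma * sqrt(2)."""
    return float(sigma * np.sqrt(2.0))


def log_detect(plane: np.ndarray, config: LoGConfig | None = None,
               field: str = "", channel: int = 0) -> FociList:
    """Scale-space LoG maxima over the sigma ladder; radii discarded."""
    config = config or LoGConfig()
    img = np.asarray(plane)
    if np.issubdtype(img.dtype, np.integer):
        img = normalize_plane(img)
    blobs = blob_log(img, min_sigma=config.sigma_min, max_sigma=config.sigma_max,
                     num_sigma=config.num_sigma, threshold=config.threshold)
    pts = blobs[:, :2] if len(blobs) else np.empty((0, 2))
    return FociList(field=field, channel=channel, points=pts)


# ---------------------------------------------------------------------------
# threshold-sweep blob detector (8-bit)

@dataclass
class BlobConfig:
    """Blob detection on the 8-bit image across a threshold sweep,
    keeping blobs of 5-100 px area, over the full 0-255 brightness
    range."""

    min_area: float = 5.0
    max_area: float = 100.0
    min_threshold: float = 0.0
    max_threshold: float = 255.0
    threshold_step: float = 10.0
    min_repeatability: int = 2
    min_dist_between: float = 4.0
    conversion: str = "minmax"  # or "shift8": fixed divide-by-256

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")


def to_8bit(plane16: np.ndarray, mode: str = "minmax") -> np.ndarray:
    x = np.asarray(plane16).astype(np.float64)
    if mode == "shift8":
        return np.clip(x / 256.0, 0, 255).astype(np.uint8)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.shape, np.uint8)
    return np.round((x - lo) / (hi - lo) * 255.0).astype(np.uint8)


def blob_detect(plane16: np.ndarray, config: BlobConfig | None = None,
                field: str = "", channel: int = 0) -> FociList:
    """Bright-blob detection by binary threshold sweep.

    Connected components are extracted at each threshold; a blob's
    centres across thresholds are merged when closer than
    ``min_dist_between``, and a blob is kept when it appears at
    ``min_repeatability`` thresholds or more with an admissible area.
    Returns the mean centre of each kept blob.
    """
    config = config or BlobConfig()
    img8 = to_8bit(plane16, config.conversion)
    thresholds = np.arange(config.min_threshold, config.max_threshold,
                           config.threshold_step)
    # centres[i] accumulates (sum_r, sum_c, hits) of merged blob i
    merged: list[list[float]] = []
    for thr in thresholds:
        mask = img8 > thr
        if not mask.any() or mask.all():
            continue
        lab = cc_label(mask, connectivity=2)
        for prop in regionprops(lab):
            if not (config.min_area <= prop.area <= config.max_area):
                continue
            r, c = prop.centroid
            for m in merged:
                if np.hypot(m[0] / m[2] - r, m[1] / m[2] - c) < config.min_dist_between:
                    m[0] += r
                    m[1] += c
                    m[2] += 1
                    break
            else:
                merged.append([r, c, 1])
    pts = np.array([[m[0] / m[2], m[1] / m[2]] for m in merged
                    if m[2] >= config.min_repeatability]).reshape(-1, 2)
    return FociList(field=field, channel=channel, points=pts)


# ---------------------------------------------------------------------------
# FociDetector-style shallow CNN

@dataclass
class FociDetectorConfig:
    """Four 5x5 convolutions of 10 filters (ReLU) plus a 1x1 sigmoid
    head, trained with plain BCE and SGD (lr 0.01, momentum 0.9, weight
    decay 1e-4). The 1x1 head is an interpretation: a 10-filter stack
    cannot emit a single-channel map on its own."""

    n_layers: int = 4
    kernel: int = 5
    filters: int = 10
    epochs: int = 100
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    spread_sigma: float = 1.5
    patch_size: int = 128
    peak_threshold: float = 0.5
    min_distance: float = 2.0
    seed: int = 42


class FociDetectorModel:
    def __init__(self, config: FociDetectorConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0C1]))
        self.layers = []
        in_ch = 1
        for _ in range(config.n_layers):
            self.layers += [Conv2d(in_ch, config.filters, config.kernel, rng), ReLU()]
            in_ch = config.filters
        self.head = Conv2d(in_ch, 1, 1, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x[None] if x.ndim == 2 else x
        for layer in self.layers:
            h = layer.forward(h, train)
        return self.head.forward(h, train)[0]

    def backward(self, g: np.ndarray) -> None:
        h = self.head.backward(g[None])
        for layer in reversed(self.layers):
            h = layer.backward(h)

    def zero_grad(self) -> None:
        for layer in [*self.layers, self.head]:
            layer.zero_grad()


def foci_detector_train(items, config: FociDetectorConfig | None = None
                        ) -> FociDetectorModel:
    """Train the shallow CNN on (plane, points) pairs against
    full-resolution Gaussian targets (the same supervision the
    multiscale model receives at its finest level)."""
    config = config or FociDetectorConfig()
    if not items:
        raise ValueError("empty training set")
    model = FociDetectorModel(config)
    opt = SGD([*model.layers, model.head], lr=config.learning_rate,
              momentum=config.momentum, weight_decay=config.weight_decay)
    target_cfg = SpotModelConfig(depth=1, spread_sigma=config.spread_sigma,
                                 patch_size=config.patch_size, pool_kernel=1)
    prepped = [(normalize_plane(np.asarray(p)), np.asarray(q, float).reshape(-1, 2))
               for p, q in items]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0C2]))
    from .spot_model import _random_patch
    for epoch in range(config.epochs):
        for i in rng.permutation(len(prepped)):
            plane, pts = prepped[i]
            patch, ppts = _random_patch(plane, pts, config.patch_size, rng)
            target = make_target_maps(ppts, patch.shape, target_cfg).full
            logits = model.forward(patch, train=True)
            loss, g = weighted_bce_with_logits(logits, target, 1.0)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            model.backward(g)
            opt.step()
            model.zero_grad()
    return model


def foci_detector_detect(model: FociDetectorModel, plane: np.ndarray,
                         field: str = "", channel: int = 0) -> FociList:
    """Probability map times the unit-mapped input, then peak extraction."""
    raw = np.asarray(plane).astype(np.float64)
    lo, hi = raw.min(), raw.max()
    unit = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    prob = sigmoid(model.forward(normalize_plane(np.asarray(plane)), train=False))
    density = prob * unit
    return extract_peaks(density, threshold=model.config.peak_threshold,
                         min_distance=model.config.min_distance,
                         field=field, channel=channel)
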