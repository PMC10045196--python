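"""Multiscale U-Net spot detector for sparse fluorescent foci.

The detector regresses Gaussian probability maps at several resolution
levels simultaneously. Each annotated focus is rendered as an
unnormalised Gaussian (peak 1) in the full-resolution target; coarser
targets are 4x4 max-pool reductions so the sparse signal keeps its peak
value — and therefore its gradient — at every scale. Deep supervision
through one sigmoid head per level is what lets the network converge on
images where positives occupy a few dozen of ~10^5 pixels.

Foci are read out of the predicted full-resolution map by local-maximum
extraction with a Euclidean minimum-separation rule, chosen below the
3-pixel centriole-procentriole spacing so the members of a pair survive
as distinct detections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field as dc_field, replace as dataclasses_replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import Dataset, FociList
from .nn import Adam, Conv2d, ConvBlock, MaxPool2d, UpsampleNearest, sigmoid
from .nn.losses import mae, weighted_bce_with_logits

logger = logging.getLogger(__name__)


@dataclass
class SpotModelConfig:
    """Architecture and training hyper-parameters of the spot detector.

    ``depth`` is the number of supervised resolution levels; level k
    predicts at side ``patch_size / pool_kernel**k``. ``spread_sigma``
    is the standard deviation (px) of the Gaussian painted around each
    annotated focus. ``positive_weight_initial`` is the starting loss
    weight on positive pixels, decaying linearly to ~1 over training to
    avoid the all-black local optimum early without inducing false
    positives late.
    """

    depth: int = 3
    conv_kernel: int = 3
    pool_kernel: int = 4
    spread_sigma: float = 1.5
    patch_size: int = 512
    epochs: int = 100
    learning_rate: float = 3e-4
    loss_name: str = "bce"
    base_filters: int = 32
    positive_weight_initial: float = 10.0
    weight_schedule: str = "linear"
    seed: int = 42
    num_heads: int | None = None  # losses on the first k levels only (None = depth)
    lr_schedule: str = "constant"  # or "linear_decay": to 10% over the final third
    ema_decay: float | None = None  # weight EMA used for inference (e.g. 0.999)
    peak_threshold: float = 0.5
    min_distance: float = 2.0
    tile_size: int = 512
    tile_overlap: int = 64
    augment: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.spread_sigma <= 0:
            raise ValueError("spread_sigma must be positive")
        if self.patch_size % self.pool_kernel ** self.depth:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by "
                f"pool_kernel**depth = {self.pool_kernel ** self.depth}")
        if self.loss_name not in ("bce", "mae"):
            raise ValueError(f"unknown loss '{self.loss_name}'")
        if self.lr_schedule not in ("constant", "linear_decay"):
            raise ValueError(f"unknown lr_schedule '{self.lr_schedule}'")
        if self.num_heads is not None and not (1 <= self.num_heads <= self.depth):
            raise ValueError("num_heads must lie in [1, depth]")

    @property
    def n_heads(self) -> int:
        return self.num_heads if self.num_heads is not None else self.depth


@dataclass
class TargetMaps:
    """Gaussian probability maps, one per resolution level (finest first)."""

    maps: list[np.ndarray]

    @property
    def full(self) -> np.ndarray:
        return self.maps[0]


# ---------------------------------------------------------------------------
# target construction

def make_target_maps(points, image_shape, config: SpotModelConfig) -> TargetMaps:
    """Render foci as peak-1 Gaussians and max-pool to coarser levels.

    Overlapping Gaussians combine by pixelwise maximum, so two foci a
    pair-distance apart keep two unit peaks with a saddle between them.
    """
    pts = points.points if isinstance(points, FociList) else np.asarray(points, float).reshape(-1, 2)
    h, w = image_shape
    for r, c in pts:
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"focus (row={r}, col={c}) outside {h}x{w} image")
    full = np.zeros((h, w), np.float32)
    sig = config.spread_sigma
    rad = int(np.ceil(5.0 * sig))
    for r, c in pts:
        r0, r1 = max(0, int(np.floor(r)) - rad), min(h, int(np.ceil(r)) + rad + 1)
        c0, c1 = max(0, int(np.floor(c)) - rad), min(w, int(np.ceil(c)) + rad + 1)
        rr = np.arange(r0, r1, dtype=np.float64)[:, None] - r
        cc = np.arange(c0, c1, dtype=np.float64)[None, :] - c
        g = np.exp(-(rr * rr + cc * cc) / (2.0 * sig * sig))
        np.maximum(full[r0:r1, c0:c1], g, out=full[r0:r1, c0:c1])
    maps = [full]
    k = config.pool_kernel
    for _ in range(1, config.depth):
        prev = maps[-1]
        ph, pw = prev.shape
        if ph % k or pw % k:
            raise ValueError(
                f"image shape {image_shape} not divisible by pool_kernel**(depth-1)")
        maps.append(prev.reshape(ph // k, k, pw // k, k).max(axis=(1, 3)))
    return TargetMaps(maps)


# ---------------------------------------------------------------------------
# network

class MultiscaleUNet:
    """U-Net backbone with a sigmoid prediction head at every level.

    Encoder level k applies two 3x3 convolutions (ReLU) and a 4x4
    max-pool, caching the pre-pool features as a skip connection. The
    decoder mirrors the steps, concatenating the cached features after
    nearest-neighbour upsampling. ``forward`` returns one logit map per
    level, finest first.
    """

    def __init__(self, config: SpotModelConfig, rng: np.random.Generator):
        d, f, ker = config.depth, config.base_filters, config.conv_kernel
        pool = config.pool_kernel
        self.depth = d
        self.enc = [ConvBlock(1 if k == 0 else f * 2 ** (k - 1), f * 2 ** k, ker, rng)
                    for k in range(d)]
        self.pools = [MaxPool2d(pool) for _ in range(d - 1)]
        self.ups = [UpsampleNearest(pool) for _ in range(d - 1)]
        # decoder block at level k consumes upsampled level-(k+1) features
        # (f*2^(k+1) channels) concatenated with the skip (f*2^k channels)
        self.dec = [ConvBlock(f * 2 ** (k + 1) + f * 2 ** k, f * 2 ** k, ker, rng)
                    for k in range(d - 1)]
        self.heads = [Conv2d(f * 2 ** k, 1, 1, rng) for k in range(d)]
        self._skip_channels = [f * 2 ** k for k in range(d)]

    @property
    def layers(self) -> list:
        return [*self.enc, *self.pools, *self.ups, *self.dec, *self.heads]

    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        if x.ndim == 2:
            x = x[None]
        skips: list[np.ndarray] = []
        h = x.astype(np.float32, copy=False)
        for k in range(self.depth - 1):
            h = self.enc[k].forward(h, train)
            skips.append(h)
            h = self.pools[k].forward(h, train)
        h = self.enc[self.depth - 1].forward(h, train)
        feats: list[np.ndarray | None] = [None] * self.depth
        feats[self.depth - 1] = h
        for k in range(self.depth - 2, -1, -1):
            up = self.ups[k].forward(h, train)
            h = np.concatenate([up, skips[k]], axis=0)
            h = self.dec[k].forward(h, train)
            feats[k] = h
        return [self.heads[k].forward(feats[k], train)[0] for k in range(self.depth)]

    def backward(self, glogits: list[np.ndarray | None]) -> None:
        d = self.depth
        gskips: list[np.ndarray | None] = [None] * d
        gfeat_up: np.ndarray | None = None  # gradient arriving from the finer decoder level
        for k in range(d - 1):
            g = self.heads[k].backward(glogits[k][None]) if glogits[k] is not None else 0.0
            if gfeat_up is not None:
                g = g + gfeat_up
            if np.isscalar(g):  # no gradient reaches this level's features
                g = np.zeros_like(self.dec[k].relu2._mask, dtype=np.float32)
            gcat = self.dec[k].backward(g)
            n_up = gcat.shape[0] - self._skip_channels[k]
            gskips[k] = gcat[n_up:]
            gfeat_up = self.ups[k].backward(gcat[:n_up])
        g = self.heads[d - 1].backward(glogits[d - 1][None]) if glogits[d - 1] is not None else 0.0
        if gfeat_up is not None:
            g = g + gfeat_up
        h = self.enc[d - 1].backward(g)
        for k in range(d - 2, -1, -1):
            h = self.pools[k].backward(h)
            h = h + gskips[k]
            h = self.enc[k].backward(h)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- (de)serialisation ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            stack = [(f"layer{i}", layer)]
            while stack:
                prefix, l = stack.pop()
                if isinstance(l, ConvBlock):
                    stack.extend((f"{prefix}.sub{j}", s) for j, s in enumerate(l.sublayers))
                else:
                    for k, v in l.params.items():
                        state[f"{prefix}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("checkpoint does not match architecture")
        for k, v in own.items():
            v[...] = state[k]


@dataclass
class TrainedSpotModel:
    """A network plus its config snapshot and per-epoch training history."""

    net: MultiscaleUNet
    config: SpotModelConfig
    history: list[dict] = dc_field(default_factory=list)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        np.savez(directory / "weights.npz", **self.net.state_dict())
        if self.history:
            keys = list(self.history[0])
            with open(directory / "history.csv", "w") as fh:
                fh.write(",".join(keys) + "\n")
                for row in self.history:
                    fh.write(",".join(f"{row[k]:.8g}" for k in keys) + "\n")

    @classmethod
    def load(cls, directory) -> "TrainedSpotModel":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            config = SpotModelConfig(**json.load(fh))
        model = build_model(config)
        with np.load(directory / "weights.npz") as npz:
            model.net.load_state_dict(dict(npz))
        hist_path = directory / "history.csv"
        if hist_path.exists():
            lines = hist_path.read_text().strip().splitlines()
            keys = lines[0].split(",")
            model.history = [dict(zip(keys, map(float, ln.split(",")))) for ln in lines[1:]]
        return model


def build_model(config: SpotModelConfig) -> TrainedSpotModel:
    """Construct an untrained (He-initialised) model from a config."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    return TrainedSpotModel(MultiscaleUNet(config, rng), config)


# ---------------------------------------------------------------------------
# normalisation and augmentation

def normalize_plane(plane: np.ndarray, low: float = 1.0, high: float = 99.8) -> np.ndarray:
    """Percentile normalisation to [0, 1], robust to staining-intensity
    variation across channels and experiments."""
    plane = plane.astype(np.float32)
    lo, hi = np.percentile(plane, [low, high])
    if hi <= lo:
        return np.zeros_like(plane)
    return np.clip((plane - lo) / (hi - lo), 0.0, 1.0)


def augment_pair(img: np.ndarray, pts: np.ndarray, rng: np.random.Generator):
    """Random flip, affine, brightness-contrast and gamma, keeping the
    point annotations consistent with the warped image."""
    h, w = img.shape
    if rng.random() < 0.5:
        img = img[::-1].copy()
        pts = pts.copy()
        pts[:, 0] = h - 1 - pts[:, 0]
    if rng.random() < 0.5:
        img = img[:, ::-1].copy()
        pts = pts.copy()
        pts[:, 1] = w - 1 - pts[:, 1]
    if rng.random() < 0.5:
        theta = np.deg2rad(rng.uniform(-15.0, 15.0))
        scale = rng.uniform(0.9, 1.1)
        shift = rng.uniform(-0.05, 0.05, size=2) * (h, w)
        cos, sin = np.cos(theta), np.sin(theta)
        m = scale * np.array([[cos, -sin], [sin, cos]])
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        minv = np.linalg.inv(m)
        offset = center - minv @ (center + shift)
        img = ndimage.affine_transform(img, minv, offset=offset, order=1,
                                       mode="constant", cval=float(np.median(img)))
        if len(pts):
            pts = (m @ (pts - center).T).T + center + shift
            keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= h - 1)
                    & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1))
            pts = pts[keep]
    if rng.random() < 0.5:
        img = np.clip(img * rng.uniform(0.9, 1.1) + rng.uniform(-0.1, 0.1), 0.0, 1.0)
    if rng.random() < 0.5:
        img = np.clip(img, 0.0, 1.0) ** rng.uniform(0.75, 1.33)
    return img.astype(np.float32), pts


def _random_patch(img: np.ndarray, pts: np.ndarray, size: int, rng: np.random.Generator):
    h, w = img.shape
    if h < size or w < size:
        pad_h, pad_w = max(0, size - h), max(0, size - w)
        img = np.pad(img, ((0, pad_h), (0, pad_w)))
        h, w = img.shape
    r0 = int(rng.integers(0, h - size + 1))
    c0 = int(rng.integers(0, w - size + 1))
    patch = img[r0:r0 + size, c0:c0 + size]
    if len(pts):
        shifted = pts - (r0, c0)
        keep = ((shifted[:, 0] >= 0) & (shifted[:, 0] <= size - 1)
                & (shifted[:, 1] >= 0) & (shifted[:, 1] <= size - 1))
        shifted = shifted[keep]
    else:
        shifted = pts
    return patch, shifted


# ---------------------------------------------------------------------------
# training

def learning_rate(epoch: int, config: SpotModelConfig) -> float:
    """Per-epoch learning rate. ``linear_decay`` ramps from the base
    rate down to 10% of it across the final third of training — with
    single-image steps the late gradient noise is otherwise large
    enough to keep the weights jittering around the optimum."""
    base = config.learning_rate
    if config.lr_schedule == "constant":
        return base
    start = 2 * config.epochs // 3
    if epoch < start or config.epochs <= start + 1:
        return base
    frac = (epoch - start) / max(config.epochs - 1 - start, 1)
    return base * (1.0 - 0.9 * frac)


def positive_weight(epoch: int, config: SpotModelConfig) -> float:
    """Loss weight on positive pixels at a given epoch: w0 decaying
    linearly towards 1 across the epoch budget."""
    w0 = config.positive_weight_initial
    if config.weight_schedule == "constant":
        return w0
    return 1.0 + (w0 - 1.0) * (1.0 - epoch / max(config.epochs, 1))


def _step(net: MultiscaleUNet, opt: Adam, img: np.ndarray, targets: TargetMaps,
          w_pos: float, config: SpotModelConfig) -> list[float]:
    logits = net.forward(img[None], train=True)
    losses, grads = [], []
    for k in range(config.depth):
        if k >= config.n_heads:
            losses.append(0.0)
            grads.append(None)
            continue
        t = targets.maps[k]
        weight = 1.0 + (w_pos - 1.0) * (t > 0.5)
        if config.loss_name == "bce":
            loss, g = weighted_bce_with_logits(logits[k], t, weight)
        else:
            p = sigmoid(logits[k])
            loss, gp = mae(p, t)
            g = gp * p * (1.0 - p)
        losses.append(loss)
        grads.append(g)
    net.backward(grads)
    opt.step()
    net.zero_grad()
    return losses


def train_on_arrays(model: TrainedSpotModel, items, config: SpotModelConfig | None = None,
                    ) -> TrainedSpotModel:
    """Train on in-memory ``(plane, points)`` pairs.

    ``plane`` is a raw single-channel image (any dtype); ``points`` an
    (n, 2) array of (row, col) foci. Planes are percentile-normalised,
    augmented, cropped to ``patch_size`` and supervised with the summed
    multi-level weighted BCE. Deterministic for a fixed config seed.
    """
    config = config or model.config
    if not items:
        raise ValueError("empty training set")
    items = [(normalize_plane(np.asarray(p)), np.asarray(q, float).reshape(-1, 2))
             for p, q in items]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA06]))
    opt = Adam(model.net.layers, lr=config.learning_rate)
    ema: dict[str, np.ndarray] | None = None
    if config.ema_decay is not None:
        ema = {k: v.copy() for k, v in model.net.state_dict().items()}
    for epoch in range(config.epochs):
        w_pos = positive_weight(epoch, config)
        opt.lr = learning_rate(epoch, config)
        order = rng.permutation(len(items))
        sums = np.zeros(config.depth)
        for i in order:
            plane, pts = items[i]
            if config.augment:
                plane, pts = augment_pair(plane, pts, rng)
            patch, ppts = _random_patch(plane, pts, config.patch_size, rng)
            targets = make_target_maps(ppts, patch.shape, config)
            losses = _step(model.net, opt, patch, targets, w_pos, config)
            if not all(np.isfinite(losses)):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {losses}")
            sums += losses
            if ema is not None:
                d = config.ema_decay
                for k, v in model.net.state_dict().items():
                    ema[k] *= d
                    ema[k] += (1.0 - d) * v
        row = {"epoch": float(epoch), "loss": float(sums.sum() / len(items))}
        row.update({f"loss_l{k}": float(sums[k] / len(items)) for k in range(config.depth)})
        model.history.append(row)
        logger.info("epoch %d/%d loss %.5f (w_pos %.2f)",
                    epoch + 1, config.epochs, row["loss"], w_pos)
    if ema is not None:
        model.net.load_state_dict(ema)
    return model


def train_with_validation(model: TrainedSpotModel, items,
                          config: SpotModelConfig | None = None,
                          val_fraction: float = 0.1, target_f1: float = 0.92,
                          round_epochs: int = 25, max_rounds: int = 2,
                          tolerance: float = 3.0):
    """Train with validation-gated extension rounds.

    A validation split is carved from the *training* items (never from
    any held-out test data). After the configured epochs, training
    continues in short warm-restart rounds — each restarting the
    positive-weight and learning-rate schedules — while the mean
    validation F1 at ``tolerance`` stays below ``target_f1``, up to
    ``max_rounds`` extra rounds. Adapts the budget to unlucky
    initialisations while keeping a hard step cap; deterministic given
    the config seed.

    Returns ``(model, validation_f1, rounds_used)``.
    """
    from .metrics import match_points

    config = config or model.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A11D]))
    idx = rng.permutation(len(items))
    n_val = max(1, int(round(len(items) * val_fraction)))
    val_items = [items[i] for i in idx[:n_val]]
    train_items = [items[i] for i in idx[n_val:]]

    def val_f1() -> float:
        f1s = [match_points(detect(model, plane), pts, tolerance=tolerance).f1
               for plane, pts in val_items]
        return float(np.mean(f1s))

    train_on_arrays(model, train_items, config)
    score = val_f1()
    rounds = 0
    while score < target_f1 and rounds < max_rounds:
        rounds += 1
        logger.info("validation F1 %.3f < %.3f: extending training (round %d)",
                    score, target_f1, rounds)
        extra = dataclasses_replace(config, epochs=round_epochs,
                                    seed=(config.seed + 7919 * rounds) % (2 ** 31))
        train_on_arrays(model, train_items, extra)
        score = val_f1()
    return model, score, rounds


def train(model: TrainedSpotModel, dataset: Dataset,
          config: SpotModelConfig | None = None) -> TrainedSpotModel:
    """Train on the dataset's train split (one annotated channel per field)."""
    config = config or model.config
    split = dataset.load_split("train")
    if not split:
        raise ValueError("train split is empty")
    items = [(dataset.load_plane(f, c), dataset.load_annotation(f, c).points)
             for f, c in split]
    return train_on_arrays(model, items, config)


# ---------------------------------------------------------------------------
# inference

def _taper(n: int, ramp: int, lo_edge: bool, hi_edge: bool) -> np.ndarray:
    w = np.ones(n, np.float32)
    r = min(ramp, n)
    if r > 0:
        up = np.linspace(1.0 / (r + 1), 1.0, r, dtype=np.float32)
        if not lo_edge:
            w[:r] = up
        if not hi_edge:
            w[-r:] = np.minimum(w[-r:], up[::-1])
    return w


def predict(model: TrainedSpotModel, plane: np.ndarray) -> TargetMaps:
    """Probability maps for an arbitrary-size single-channel image.

    The image is percentile-normalised, padded to a pooling-compatible
    size and, when larger than the tile size, processed as overlapping
    tiles blended with a linear taper so stitching is seam-free.
    """
    config = model.config
    img = normalize_plane(np.asarray(plane))
    h, w = img.shape
    mult = config.pool_kernel ** config.depth
    hp = -(-h // mult) * mult
    wp = -(-w // mult) * mult
    if (hp, wp) != (h, w):
        logger.debug("padding %dx%d image to %dx%d for prediction", h, w, hp, wp)
        img = np.pad(img, ((0, hp - h), (0, wp - w)), mode="reflect")
    tile, overlap = config.tile_size, config.tile_overlap
    if hp <= tile and wp <= tile:
        logits = model.net.forward(img[None], train=False)
        maps = [sigmoid(l) for l in logits]
    else:
        step = tile - overlap
        # keep tile origins on multiples of `mult` so every level stitches
        step = max(mult, (step // mult) * mult)
        r_starts = sorted({min(r, hp - tile) for r in range(0, hp, step) if r < hp})
        c_starts = sorted({min(c, wp - tile) for c in range(0, wp, step) if c < wp})
        num = [np.zeros((hp // config.pool_kernel ** k, wp // config.pool_kernel ** k),
                        np.float64) for k in range(config.depth)]
        den = [np.zeros_like(n) for n in num]
        for r0 in r_starts:
            for c0 in c_starts:
                logits = model.net.forward(img[None, r0:r0 + tile, c0:c0 + tile], train=False)
                wr = _taper(tile, overlap, r0 == 0, r0 + tile == hp)
                wc = _taper(tile, overlap, c0 == 0, c0 + tile == wp)
                wgt_full = wr[:, None] * wc[None, :]
                for k in range(config.depth):
                    s = config.pool_kernel ** k
                    wgt = wgt_full[::s, ::s]
                    p = sigmoid(logits[k])
                    num[k][r0 // s:(r0 + tile) // s, c0 // s:(c0 + tile) // s] += wgt * p
                    den[k][r0 // s:(r0 + tile) // s, c0 // s:(c0 + tile) // s] += wgt
        maps = [(n / np.maximum(d, 1e-12)).astype(np.float32) for n, d in zip(num, den)]
    # crop padding back off at every level
    out = []
    for k, m in enumerate(maps):
        s = config.pool_kernel ** k
        out.append(np.ascontiguousarray(m[: -(-h // s), : -(-w // s)]))
    return TargetMaps(out)


def extract_peaks(prob_map: np.ndarray, threshold: float = 0.5,
                  min_distance: float = 2.0, field: str = "", channel: int = 0
                  ) -> FociList:
    """Local maxima of a probability map above ``threshold``.

    A 3x3 maximum filter finds candidate maxima; candidates are then
    thinned greedily by descending map value so that no two returned
    peaks are within ``min_distance`` (Euclidean) of each other. The
    Euclidean rule matters: a square suppression window of half-size 2
    would merge diagonal 3-px centriole-procentriole pairs.
    """
    m = np.asarray(prob_map, dtype=np.float32)
    if m.size == 0:
        return FociList(field=field, channel=channel)
    mf = ndimage.maximum_filter(m, size=3, mode="nearest")
    rr, cc = np.nonzero((m >= mf) & (m >= threshold))
    if len(rr) == 0:
        return FociList(field=field, channel=channel)
    vals = m[rr, cc]
    order = np.lexsort((cc, rr, -vals))
    pts = np.stack([rr[order], cc[order]], axis=1).astype(float)
    vals = vals[order]
    kept_idx: list[int] = []
    kept = np.empty((0, 2))
    for i, p in enumerate(pts):
        if len(kept_idx) == 0 or np.min(np.hypot(*(kept - p).T)) > min_distance:
            kept_idx.append(i)
            kept = pts[kept_idx]
    return FociList(field=field, channel=channel, points=pts[kept_idx],
                    scores=np.clip(vals[kept_idx], 0.0, 1.0))


def predict_tta(model: TrainedSpotModel, plane: np.ndarray) -> np.ndarray:
    """Full-resolution probability map averaged over the four axis
    flips (test-time augmentation): foci are flip-equivariant, so
    averaging the unflipped predictions suppresses orientation-
    dependent prediction noise."""
    plane = np.asarray(plane)
    acc = np.zeros(plane.shape, np.float64)
    for flip_r in (False, True):
        for flip_c in (False, True):
            view = plane[::-1 if flip_r else 1, ::-1 if flip_c else 1]
            p = predict(model, view).full
            acc += p[::-1 if flip_r else 1, ::-1 if flip_c else 1]
    return (acc / 4.0).astype(np.float32)


def detect(model: TrainedSpotModel, plane: np.ndarray, field: str = "",
           channel: int = 0, tta: bool = False) -> FociList:
    """predict + extract_peaks with the model's configured defaults."""
    prob = predict_tta(model, plane) if tta else predict(model, plane).full
    return extract_peaks(prob, threshold=model.config.peak_threshold,
                         min_distance=model.config.min_distance,
                         field=field, channel=channel)


def as_detector(model: TrainedSpotModel):
    """Wrap a model as a ``plane -> FociList`` callable for evaluation."""
    return lambda plane: detect(model, plane)
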