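"""RAKI: scan-specific CNN k-space interpolation.

Small three-layer convolutional networks, trained only on the subject's ACS
block, replace GRAPPA's linear kernels:

    f(s) = w3 * ReLU(w2 * ReLU(w1 * s)),    ReLU(x) = max(x, 0)

with no bias terms anywhere. The complex k-space is mapped to the real field
(``2 nc`` channels). Two output-head layouts are provided:

* **CBC (coil-by-coil)** — one network per real-field channel ``j``; the
  head has ``R - 1`` outputs, one per missing line offset. ``2 nc`` networks
  in total.
* **LBL (line-by-line)** — one network per missing offset ``m``; the head
  has ``2 nc`` outputs, one per channel. Only ``R - 1`` networks, a large
  reduction (16-fold for ``R = 5``, ``nc = 32``).

Geometry. Convolutions run on the acquired-line subgrid (every R-th ky
line), which is equivalent to dilation-R kernels on the full grid. Kernel
sizes are fixed at ``(5, 2)`` -> ``(1, 1)`` -> ``(3, 2)`` in (kx, subgrid-ky)
with 32 and 8 hidden channels; layer 3's ky taps are additionally dilated by
2 on the subgrid, so the composite receptive field spans 7 kx taps by 4
acquired lines - the same 4-line window, with the target between lines 2 and
3, as the package's 5x4 GRAPPA kernel. This makes the linear and CNN
interpolators directly comparable, and the CNN function class provably
contains the GRAPPA linear maps.

Training minimizes full-batch mean squared error with Adam
(alpha 1e-3, beta1 0.9, beta2 0.999, eps 1e-8), stopping after at most 1000
epochs or earlier once the normalized loss change over 100 epochs drops
below 1e-4. Each network's weight initialization is seeded by a stable hash
of ``(master_seed, task index)``, so concurrent and sequential training give
bitwise-identical results.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .kspace import (
    ReconResult,
    SamplingScheme,
    ScaleRecord,
    extract_acs,
    from_real_field,
    ifft2c,
    rss_combine,
    scale_to_training_range,
    to_real_field,
    validate_kspace,
)

__all__ = [
    "RakiArchitecture",
    "NetworkWeights",
    "AdamConfig",
    "TrainingConfig",
    "TrainingPairSet",
    "Adam",
    "build_training_pairs",
    "forward",
    "train_network",
    "train_cbc",
    "train_lbl",
    "raki_apply",
    "raki_reconstruct",
    "should_stop",
    "task_seed",
]

# layer-3 ky taps are dilated by this factor on the acquired-line subgrid,
# stretching the composite footprint to 4 acquired lines (matching GRAPPA)
_L3_KY_DILATION = 2

# composite receptive field: input minus output extent, (kx, subgrid-ky)
_RF_KX = 6   # (5-1) + (1-1) + (3-1)
_RF_KY = 3   # (2-1) + (1-1) + (2-1)*2


@dataclass(frozen=True)
class RakiArchitecture:
    """Fixed three-layer network shape for a given coil count and rate."""

    kind: str  # "cbc" | "lbl"
    nc: int
    R: int
    n1: int = 32
    n2: int = 8
    k1: tuple[int, int] = (5, 2)
    k2: tuple[int, int] = (1, 1)
    k3: tuple[int, int] = (3, 2)

    def __post_init__(self) -> None:
        if self.kind not in ("cbc", "lbl"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.R < 2:
            raise ValueError("nothing to interpolate at R = 1")
        if self.nc < 1:
            raise ValueError("need at least one coil")

    @property
    def head(self) -> int:
        """Output channels per network: R - 1 (CBC) or 2 nc (LBL)."""
        return self.R - 1 if self.kind == "cbc" else 2 * self.nc

    @property
    def n_networks(self) -> int:
        return 2 * self.nc if self.kind == "cbc" else self.R - 1

    def weight_shapes(self) -> list[tuple[int, int, int, int]]:
        """(kx, ky, in, out) per layer; weight counts are the element sums."""
        return [
            (*self.k1, 2 * self.nc, self.n1),
            (*self.k2, self.n1, self.n2),
            (*self.k3, self.n2, self.head),
        ]

    def indices(self) -> range:
        """Task indices: real-field channel j (CBC) or offset m (LBL)."""
        return range(2 * self.nc) if self.kind == "cbc" else range(1, self.R)


@dataclass
class NetworkWeights:
    """Kernel stack of one trained (or hand-set) network."""

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    arch: RakiArchitecture
    index: int
    history: np.ndarray | None = None  # per-epoch training loss

    def __post_init__(self) -> None:
        for w, shape in zip((self.w1, self.w2, self.w3), self.arch.weight_shapes()):
            if w.shape != shape:
                raise ValueError(f"weight shape {w.shape} != architecture {shape}")
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite network weights")


@dataclass(frozen=True)
class AdamConfig:
    alpha: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")
        if self.alpha <= 0 or self.eps <= 0:
            raise ValueError("alpha and eps must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 1000
    plateau_window: int = 100
    plateau_tol: float = 1e-4
    init_std: float = 0.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < self.plateau_window:
            raise ValueError("max_epochs must be >= plateau_window")


class Adam:
    """Adaptive moment estimation with bias correction, updating in place.

    One step with gradient g:
        m <- beta1 m + (1 - beta1) g
        v <- beta2 v + (1 - beta2) g^2
        p <- p - alpha * (m / (1 - beta1^t)) / (sqrt(v / (1 - beta2^t)) + eps)
    """

    def __init__(self, params: list[np.ndarray], cfg: AdamConfig | None = None):
        self.cfg = cfg or AdamConfig()
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * np.square(g)
            p -= c.alpha * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def should_stop(history: list[float], cfg: TrainingConfig) -> bool:
    """Stopping rule: epoch cap, or loss plateau over ``plateau_window`` epochs.

    The normalized change ``|L[t - W] - L[t]| / L[t - W]`` (absolute value,
    to handle oscillation) is compared with ``plateau_tol``; a loss that is
    exactly zero over the window also counts as converged.
    """
    t = len(history)
    if t >= cfg.max_epochs:
        return True
    if t <= cfg.plateau_window:
        return False
    prev = history[-cfg.plateau_window - 1]
    cur = history[-1]
    if prev == 0.0:
        return cur == 0.0
    return abs(prev - cur) / abs(prev) < cfg.plateau_tol


def task_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Stable per-task seed: ``SeedSequence([master_seed, index])``.

    numpy's SeedSequence entropy mixing is documented-stable, so concurrent
    and sequential training of the same task list are bitwise identical.
    """
    return np.random.SeedSequence([int(master_seed), int(index)])


# --- convolution ----------------------------------------------------------


def _conv2d(x: np.ndarray, w: np.ndarray, dilation: tuple[int, int] = (1, 1)):
    """Valid 2-D multi-channel correlation: x (cin, H, W), w (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"input has {x.shape[0]} channels, kernel expects {cin}")
    dh, dw = dilation
    span_h = (kh - 1) * dh + 1
    span_w = (kw - 1) * dw + 1
    if x.shape[1] < span_h or x.shape[2] < span_w:
        raise ValueError("input smaller than (dilated) kernel extent")
    v = sliding_window_view(x, (span_h, span_w), axis=(1, 2))[..., ::dh, ::dw]
    return np.einsum("chwij,ijco->ohw", v, w, optimize=True)


def forward(net: NetworkWeights, source: np.ndarray) -> np.ndarray:
    """Network forward pass on an acquired-line subgrid block.

    ``source`` has shape ``(2 nc, H, W)``; the output has shape
    ``(head, H - 6, W - 3)`` (valid convolutions, ReLU after layers 1 and 2,
    no biases).
    """
    a1 = np.maximum(_conv2d(source, net.w1), 0.0)
    a2 = np.maximum(_conv2d(a1, net.w2), 0.0)
    return _conv2d(a2, net.w3, dilation=(1, _L3_KY_DILATION))


# --- training pairs -------------------------------------------------------


@dataclass
class TrainingPairSet:
    """ACS-derived training data for one network.

    The ACS block is split into its ``R`` ky-residue subgrids, emulating the
    acquired-line spacing. ``sources[r]`` has shape ``(2 nc, Nx, W_r)``;
    ``targets[r]`` has shape ``(head, n_kx_valid, n_windows_r)``, aligned
    with the network output on that subgrid: window ``p`` covers ACS rows
    ``{a, a+R, a+2R, a+3R}`` with ``a = r + p R``, and its targets are the
    rows ``a + R + m`` (CBC: offsets ``m = 1..R-1`` of channel ``index``;
    LBL: offset ``m = index`` of all ``2 nc`` channels) at the 7-tap-centered
    kx positions.
    """

    arch: RakiArchitecture
    index: int
    sources: list[np.ndarray]
    targets: list[np.ndarray]

    @property
    def n_kx_valid(self) -> int:
        return self.sources[0].shape[1] - _RF_KX

    @property
    def n_windows(self) -> int:
        return sum(t.shape[2] for t in self.targets)

    @property
    def n_samples(self) -> int:
        """Total scalar targets (head x kx x windows over all subgrids)."""
        return sum(t.size for t in self.targets)


def build_training_pairs(
    acs_real: np.ndarray,
    s: SamplingScheme,
    arch: RakiArchitecture,
    index: int,
) -> TrainingPairSet:
    """Construct source subgrids and aligned targets from a real-field ACS."""
    acs_real = np.asarray(acs_real)
    two_nc, nx, width = acs_real.shape
    R = s.R
    if two_nc != 2 * arch.nc:
        raise ValueError(f"ACS has {two_nc} channels, architecture expects {2 * arch.nc}")
    if arch.R != R:
        raise ValueError(f"architecture R={arch.R} vs scheme R={R}")
    min_width = 3 * R + 1
    if width < min_width:
        raise ValueError(
            f"ACS too narrow: acs_width={width} < 3R+1={min_width} "
            "(need at least one 4-line training window)"
        )
    if nx < _RF_KX + 1:
        raise ValueError(f"Nx={nx} too small for the 7-tap kx receptive field")
    if index not in arch.indices():
        raise ValueError(f"index {index} invalid for {arch.kind} with nc={arch.nc}, R={R}")

    sources: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    kx_sel = slice(_RF_KX // 2, nx - _RF_KX // 2)
    for r in range(R):
        src = acs_real[:, :, r::R]
        n_win = src.shape[2] - _RF_KY
        if n_win < 1:
            continue
        # target ACS rows for window p = r + (p+1) R + m
        base = r + (np.arange(n_win) + 1) * R
        if arch.kind == "cbc":
            rows = base[None, :] + np.arange(1, R)[:, None]     # (R-1, n_win)
            tgt = acs_real[index, kx_sel, :][:, rows]           # (nkx, R-1, n_win)
            tgt = tgt.transpose(1, 0, 2)                        # (head, nkx, n_win)
        else:
            tgt = acs_real[:, kx_sel, base + index]             # (2nc, nkx, n_win)
        sources.append(np.ascontiguousarray(src))
        targets.append(np.ascontiguousarray(tgt))
    return TrainingPairSet(arch=arch, index=index, sources=sources, targets=targets)


# --- training -------------------------------------------------------------


def _im2col(x_hwc: np.ndarray, kh: int, kw: int, dw: int = 1) -> np.ndarray:
    """Patches of an (H, W, C) array as rows ordered (i, j, c), for matmul
    against a kernel flattened as ``w.reshape(kh * kw * cin, cout)``."""
    span_w = (kw - 1) * dw + 1
    v = sliding_window_view(x_hwc, (kh, span_w), axis=(0, 1))[..., ::dw]
    h, w_, c = v.shape[0], v.shape[1], v.shape[2]
    return v.transpose(0, 1, 3, 4, 2).reshape(h * w_, kh * kw * c)


def train_network(
    pairs: TrainingPairSet,
    adam: AdamConfig | None = None,
    cfg: TrainingConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[NetworkWeights, np.ndarray]:
    """Train one network by full-batch Adam on the mean-squared error.

    Weights are initialized i.i.d. normal(0, ``cfg.init_std``) from ``seed``.
    Returns the final weights and the per-epoch loss history. Raises if the
    loss becomes non-finite ("training diverged").
    """
    adam = adam or AdamConfig()
    cfg = cfg or TrainingConfig()
    arch = pairs.arch
    if not pairs.sources or pairs.n_samples == 0:
        raise ValueError("empty training pair set")
    dtype = pairs.sources[0].dtype
    if dtype not in (np.float32, np.float64):
        dtype = np.dtype(np.float32)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    shapes = arch.weight_shapes()
    ws = [rng.normal(0.0, cfg.init_std, s).astype(dtype) for s in shapes]
    (k1h, k1w, cin, n1), (_, _, _, n2), (k3h, k3w, _, head) = shapes
    w1m = ws[0].reshape(k1h * k1w * cin, n1)
    w2m = ws[1].reshape(n1, n2)
    w3m = ws[2].reshape(k3h * k3w * n2, head)

    # the layer-1 input never changes: fold it to one patch matrix up front;
    # the R residue subgrids are stacked so layers 1-2 run as single GEMMs
    x1_blocks, tgts, shapes_hw, row_slices = [], [], [], []
    start = 0
    for src, tgt in zip(pairs.sources, pairs.targets):
        x = src.transpose(1, 2, 0)                        # (Nx, W_r, 2nc)
        x1_blocks.append(_im2col(x, k1h, k1w).astype(dtype))
        # match Y = X3 @ w3m row order (kx, window)
        tgts.append(np.ascontiguousarray(tgt.transpose(1, 2, 0)).reshape(-1, head).astype(dtype))
        h1, wd1 = src.shape[1] - (k1h - 1), src.shape[2] - (k1w - 1)
        shapes_hw.append((h1, wd1))
        row_slices.append(slice(start, start + h1 * wd1))
        start += h1 * wd1
    x1 = np.concatenate(x1_blocks, axis=0)
    n_total = float(sum(t.size for t in tgts))

    opt = Adam([w1m, w2m, w3m], adam)
    history: list[float] = []
    while True:
        z1 = x1 @ w1m
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ w2m
        a2 = np.maximum(z2, 0.0)
        g3 = np.zeros_like(w3m)
        da2 = np.empty_like(a2)
        loss = 0.0
        for t, (h1, wd1), rows in zip(tgts, shapes_hw, row_slices):
            x3 = _im2col(a2[rows].reshape(h1, wd1, n2), k3h, k3w, dw=_L3_KY_DILATION)
            d = x3 @ w3m
            d -= t
            loss += float(np.vdot(d, d))
            d *= 2.0 / n_total
            g3 += x3.T @ d
            dx3 = (d @ w3m.T).reshape(
                h1 - (k3h - 1), wd1 - (k3w - 1) * _L3_KY_DILATION, k3h, k3w, n2
            )
            da2_r = da2[rows].reshape(h1, wd1, n2)
            da2_r[:] = 0.0
            oh, ow = dx3.shape[0], dx3.shape[1]
            for i in range(k3h):
                for j in range(k3w):
                    da2_r[i : i + oh, j * _L3_KY_DILATION : j * _L3_KY_DILATION + ow] += (
                        dx3[:, :, i, j]
                    )
        loss /= n_total
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged: non-finite loss")
        history.append(loss)
        if should_stop(history, cfg):
            break
        dz2 = np.where(z2 > 0, da2, 0.0)
        g2 = a1.T @ dz2
        dz1 = np.where(z1 > 0, dz2 @ w2m.T, 0.0)
        g1 = x1.T @ dz1
        opt.step([g1, g2, g3])

    hist = np.asarray(history)
    net = NetworkWeights(
        w1=w1m.reshape(shapes[0]),
        w2=w2m.reshape(shapes[1]),
        w3=w3m.reshape(shapes[2]),
        arch=arch,
        index=pairs.index,
        history=hist,
    )
    return net, hist


def _train_many(
    acs: np.ndarray,
    s: SamplingScheme,
    arch: RakiArchitecture,
    adam: AdamConfig,
    cfg: TrainingConfig,
    workers: int,
    dtype,
) -> list[NetworkWeights]:
    acs = validate_kspace(acs, min_ny=1)
    acs_real = to_real_field(acs).astype(dtype)

    def run(index: int) -> NetworkWeights:
        pairs = build_training_pairs(acs_real, s, arch, index)
        net, _ = train_network(pairs, adam, cfg, seed=task_seed(cfg.master_seed, index))
        return net

    indices = list(arch.indices())
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            return list(pool.map(run, indices))
    return [run(i) for i in indices]


def train_cbc(
    acs: np.ndarray,
    s: SamplingScheme,
    adam: AdamConfig | None = None,
    cfg: TrainingConfig | None = None,
    workers: int = 1,
    dtype=np.float32,
) -> list[NetworkWeights]:
    """Train the 2 nc coil-by-coil networks (network j targets channel j).

    Tasks are independent; ``workers > 1`` trains them concurrently with
    results bitwise identical to sequential execution (per-task seeding).
    """
    arch = RakiArchitecture("cbc", nc=acs.shape[0], R=s.R)
    return _train_many(acs, s, arch, adam or AdamConfig(), cfg or TrainingConfig(),
                       workers, dtype)


def train_lbl(
    acs: np.ndarray,
    s: SamplingScheme,
    adam: AdamConfig | None = None,
    cfg: TrainingConfig | None = None,
    workers: int = 1,
    dtype=np.float32,
) -> list[NetworkWeights]:
    """Train the R - 1 line-by-line networks (network m targets offset m)."""
    if s.R < 2:
        raise ValueError("nothing to interpolate at R = 1")
    arch = RakiArchitecture("lbl", nc=acs.shape[0], R=s.R)
    return _train_many(acs, s, arch, adam or AdamConfig(), cfg or TrainingConfig(),
                       workers, dtype)


# --- inference ------------------------------------------------------------


def raki_apply(
    k_us: np.ndarray,
    networks: list[NetworkWeights],
    arch: RakiArchitecture,
    s: SamplingScheme,
    scale: ScaleRecord,
) -> np.ndarray:
    """Fill the missing lines of an undersampled k-space with trained networks.

    The acquired lattice lines are extracted onto the subgrid, scaled by the
    training scale factor, zero-padded ((3,3) in kx; (1,2) in subgrid-ky for
    the default phase offset 0) so every missing position receives a
    prediction, and passed through each network. Predictions are un-scaled
    by ``1 / factor``; acquired lines and the measured ACS block are then
    reinserted verbatim.
    """
    k_us = validate_kspace(k_us)
    nc, nx, ny = k_us.shape
    R, off = s.R, s.phase_offset
    if arch.nc != nc or arch.R != R:
        raise ValueError(
            f"architecture (nc={arch.nc}, R={arch.R}) does not match data "
            f"(nc={nc}, R={R})"
        )
    if len(networks) != arch.n_networks:
        raise ValueError(
            f"{arch.kind} at R={R}, nc={nc} needs {arch.n_networks} networks, "
            f"got {len(networks)}"
        )
    for net in networks:
        if net.arch != arch:
            raise ValueError("network architecture mismatch")

    dtype = networks[0].w1.dtype
    rf = to_real_field(k_us) * scale.factor
    sub = np.ascontiguousarray(rf[:, :, off::R]).astype(dtype)
    G = sub.shape[2]
    pad_left = 1 if off == 0 else 2  # off > 0: one extra window for leading lines
    padded = np.pad(sub, ((0, 0), (3, 3), (pad_left, 2)))

    rf_out = np.zeros((2 * nc, nx, ny), dtype=np.float64)
    # output ky position p predicts full-grid lines off + q R + m, q = p - pad_left + 1
    q = np.arange(padded.shape[2] - _RF_KY) - pad_left + 1
    for net in networks:
        out = forward(net, padded).astype(np.float64)
        for m in range(1, R):
            ky = off + q * R + m
            ok = (ky >= 0) & (ky < ny)
            if arch.kind == "cbc":
                # scalar + slice + array indexing puts the ky axis first
                rf_out[net.index, :, ky[ok]] = out[m - 1][:, ok].T
            elif net.index == m:
                rf_out[:, :, ky[ok]] = out[:, :, ok]
    rf_out /= scale.factor

    k_out = from_real_field(rf_out)
    mask = s.acquired_mask(ny)
    k_out[:, :, mask] = k_us[:, :, mask]
    return k_out


def raki_reconstruct(
    k_us: np.ndarray,
    s: SamplingScheme,
    kind: str = "cbc",
    adam: AdamConfig | None = None,
    cfg: TrainingConfig | None = None,
    workers: int = 1,
    target_max: float = 0.015,
) -> ReconResult:
    """End-to-end RAKI: scale, train on the ACS, interpolate, combine coils.

    The real-field data are scaled so their maximum absolute value is
    ``target_max`` (default 0.015) before training; the same factor is used
    at inference and inverted on the predictions.
    """
    k_us = validate_kspace(k_us)
    cfg = cfg or TrainingConfig()
    adam = adam or AdamConfig()
    _, scale = scale_to_training_range(to_real_field(k_us), target_max)
    acs_scaled = extract_acs(k_us, s) * scale.factor
    trainer = train_cbc if kind == "cbc" else train_lbl
    nets = trainer(acs_scaled, s, adam=adam, cfg=cfg, workers=workers)
    arch = nets[0].arch
    filled = raki_apply(k_us, nets, arch, s, scale)
    image = rss_combine(ifft2c(filled))
    info = {
        "method": f"raki-{kind}",
        "R": s.R,
        "master_seed": cfg.master_seed,
        "workers": workers,
        "epochs": [len(n.history) for n in nets],
        "final_loss": [float(n.history[-1]) for n in nets],
    }
    return ReconResult(kspace=filled, image=image, scale=scale, info=info)
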