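"""GRAPPA: linear autocalibrated k-space interpolation.

Missing phase-encoding lines are predicted as shift-invariant linear
combinations of acquired samples. With the default 5x4 kernel, the sources
for a missing sample at ``(kx, ky = a + R + m)`` are the 5 kx taps centered
on ``kx`` of the 4 nearest acquired lattice lines ``{a, a+R, a+2R, a+3R}``,
i.e. the target sits between the 2nd and 3rd source lines. The kernel
weights are estimated by (optionally ridge-regularized) least squares on the
fully sampled ACS block, where the acquired-line pattern is emulated by
taking ACS rows spaced ``R`` apart.

The source-window geometry deliberately matches the receptive field of the
RAKI networks (same 4-line footprint, same target placement) so that the
linear and nonlinear interpolators are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .kspace import (
    ReconResult,
    SamplingScheme,
    extract_acs,
    ifft2c,
    rss_combine,
    validate_kspace,
)

__all__ = ["GrappaKernel", "grappa_calibrate", "grappa_apply", "grappa_reconstruct"]


@dataclass
class GrappaKernel:
    """Complex interpolation weights.

    ``weights[j, m-1, c, dx, dy]`` maps source coil ``c``, kx tap ``dx`` and
    source line ``dy`` to target coil ``j`` at line offset ``m`` (in
    ``1..R-1``).
    """

    weights: np.ndarray
    R: int
    kernel_size: tuple[int, int] = (5, 4)

    def __post_init__(self) -> None:
        nkx, nky = self.kernel_size
        nc = self.weights.shape[0]
        expect = (nc, self.R - 1, nc, nkx, nky)
        if self.weights.shape != expect:
            raise ValueError(
                f"kernel weights shape {self.weights.shape} != expected {expect}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")


def _window_starts(
    acs_width: int, R: int, nky: int, align_offset: int | None
) -> np.ndarray:
    last = acs_width - 1 - (nky - 1) * R
    if last < 0:
        raise ValueError(
            f"insufficient ACS: need acs_width >= {(nky - 1) * R + 1}, got {acs_width}"
        )
    starts = np.arange(0, last + 1)
    if align_offset is not None:
        starts = starts[starts % R == align_offset % R]
    return starts


def grappa_calibrate(
    acs: np.ndarray,
    R: int,
    kernel_size: tuple[int, int] = (5, 4),
    lamda: float = 0.0,
    align_offset: int | None = None,
) -> GrappaKernel:
    """Estimate GRAPPA weights from the fully sampled ACS block.

    For every (target coil j, line offset m) a least-squares problem
    ``min ||A w - b||^2 + lamda ||w||^2`` is solved, where the rows of ``A``
    are the kernel-footprint samples of all calibration windows and ``b``
    holds the corresponding ACS target samples.

    Parameters
    ----------
    acs:
        Fully sampled block, shape ``(nc, Nx, acs_width)``.
    R:
        Acceleration the kernel will be applied at.
    lamda:
        Tikhonov ridge weight. With ``lamda = 0`` the system must be
        overdetermined (at least ``nc * nkx * nky`` equations), otherwise an
        "insufficient ACS" error is raised.
    align_offset:
        If given, restrict calibration windows to starts ``a`` with
        ``a % R == align_offset % R``. The default (``None``) slides over all
        shifts, which is standard practice on measured data; the aligned
        variant emulates the acquired pattern exactly and recovers a planted
        kernel from linearly consistent data.
    """
    acs = validate_kspace(acs, min_ny=1)
    if R < 2:
        raise ValueError("calibration needs R >= 2")
    nc, nx, width = acs.shape
    nkx, nky = kernel_size
    if nkx % 2 != 1:
        raise ValueError("kx kernel size must be odd")
    hw = nkx // 2
    starts = _window_starts(width, R, nky, align_offset)
    t_src = nky // 2 - 1  # target lies between source lines t_src and t_src + 1

    n_x = nx - 2 * hw
    if n_x < 1:
        raise ValueError("Nx too small for the kx kernel extent")
    rows = []
    targets = []
    dy_taps = np.arange(nky) * R
    for a in starts:
        block = acs[:, :, a + dy_taps]                       # (nc, Nx, nky)
        sw = sliding_window_view(block, nkx, axis=1)         # (nc, n_x, nky, nkx)
        # row order (c, dx, dy) to match grappa_apply
        rows.append(
            sw.transpose(1, 0, 3, 2).reshape(n_x, nc * nkx * nky)
        )
        t_rows = acs[:, hw : nx - hw, a + t_src * R + 1 : a + t_src * R + R]
        # column order (j, m) to match the reshape below
        targets.append(t_rows.transpose(1, 0, 2).reshape(n_x, nc * (R - 1)))
    A = np.concatenate(rows, axis=0)
    B = np.concatenate(targets, axis=0)

    n_unknown = nc * nkx * nky
    if lamda == 0.0:
        if A.shape[0] < n_unknown:
            raise ValueError(
                f"insufficient ACS: {A.shape[0]} calibration equations for "
                f"{n_unknown} unknowns; widen the ACS block or use ridge "
                "regularization"
            )
        W, *_ = np.linalg.lstsq(A, B, rcond=None)
    else:
        AhA = A.conj().T @ A + lamda * np.eye(n_unknown)
        W = np.linalg.solve(AhA, A.conj().T @ B)

    # W columns are ordered (j, m); reshape to [j, m, c, dx, dy]
    weights = (
        W.T.reshape(nc, R - 1, nc, nkx, nky)
    )
    return GrappaKernel(weights=weights, R=R, kernel_size=kernel_size)


def grappa_apply(
    k_us: np.ndarray,
    kernel: GrappaKernel,
    s: SamplingScheme,
    boundary: str = "clamp",
) -> np.ndarray:
    """Fill missing ky lines of an undersampled k-space with a GRAPPA kernel.

    ``boundary`` controls edge handling:

    * ``"clamp"`` (default, for measured data): kx edges are zero-padded and
      the 4-line ky source window is shifted to the nearest fully valid
      window at the top/bottom of k-space.
    * ``"wrap"``: circular boundary in kx and on the acquired-line lattice
      (requires ``Ny % R == 0``); matches the planted-kernel simulator so
      exactness tests are free of edge effects.

    Acquired lines (lattice and measured ACS block) are reinserted verbatim
    afterwards.
    """
    k_us = validate_kspace(k_us)
    if kernel.R != s.R:
        raise ValueError(f"kernel trained at R={kernel.R}, scheme has R={s.R}")
    if boundary not in ("clamp", "wrap"):
        raise ValueError(f"unknown boundary mode {boundary!r}")
    nc, nx, ny = k_us.shape
    R, off = s.R, s.phase_offset
    if R == 1:
        return k_us.copy()
    nkx, nky = kernel.kernel_size
    hw = nkx // 2
    t_src = nky // 2 - 1

    lattice = s.lattice_lines(ny)
    G = lattice.size
    lat = k_us[:, :, lattice]                                # (nc, Nx, G)
    if boundary == "wrap":
        if ny % R != 0:
            raise ValueError("wrap boundary requires Ny divisible by R")
        latp = np.concatenate([lat[:, -hw:], lat, lat[:, :hw]], axis=1)
    else:
        if G < nky:
            raise ValueError("fewer acquired lattice lines than ky kernel taps")
        latp = np.pad(lat, ((0, 0), (hw, hw), (0, 0)))
    sw = sliding_window_view(latp, nkx, axis=1)              # (nc, Nx, G, nkx)

    out = k_us.copy()
    ky = np.arange(ny)
    for m in range(1, R):
        ts = ky[ky % R == (off + m) % R]
        if ts.size == 0:
            continue
        if boundary == "wrap":
            q = ((ts - off - m) % ny) // R
            gidx = (q[:, None] - t_src + np.arange(nky)) % G
        else:
            q = (ts - off - m) // R
            base = np.clip(q - t_src, 0, G - nky)
            gidx = base[:, None] + np.arange(nky)
        win = sw[:, :, gidx, :]                              # (nc, Nx, T, nky, nkx)
        pred = np.einsum(
            "cxtyd,jcdy->jxt", win, kernel.weights[:, m - 1], optimize=True
        )
        out[:, :, ts] = pred

    mask = s.acquired_mask(ny)
    out[:, :, mask] = k_us[:, :, mask]
    return out


def grappa_reconstruct(
    k_us: np.ndarray,
    s: SamplingScheme,
    kernel_size: tuple[int, int] = (5, 4),
    lamda: float = 0.0,
) -> ReconResult:
    """Calibrate on the ACS block of ``k_us``, interpolate, and combine coils."""
    acs = extract_acs(k_us, s)
    kernel = grappa_calibrate(acs, s.R, kernel_size=kernel_size, lamda=lamda)
    filled = grappa_apply(k_us, kernel, s)
    image = rss_combine(ifft2c(filled))
    info = {"method": "grappa", "R": s.R, "kernel_size": kernel_size, "lamda": lamda}
    return ReconResult(kspace=filled, image=image, scale=None, info=info)
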