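"""Synthetic multi-coil Cartesian MRI data with known ground truth.

The generator emulates a single-slice 2-D acquisition: a piecewise-smooth
magnitude phantom, ``nc`` smooth complex receive-coil sensitivity maps, the
forward model ``kspace_c = F(sensitivity_c * image)`` with a centered
orthonormal FFT, uniform ky undersampling with a centered contiguous ACS
block, and additive complex Gaussian noise in k-space (equivalent to
image-space noise by unitarity).

A second, "planted linear kernel" mode produces k-space in which every
missing lattice line is an *exact* linear combination of the acquired
neighbors under a known GRAPPA kernel (with circular boundaries, so the
relation holds everywhere). It serves as an exactness oracle for the
calibration and interpolation code paths.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grappa import GrappaKernel, grappa_apply
from .kspace import SamplingScheme, fft2c, ifft2c, undersample

__all__ = [
    "SyntheticDataset",
    "make_phantom",
    "make_coil_sensitivities",
    "forward_model",
    "add_noise",
    "sigma_for_snr",
    "make_dataset",
    "make_linear_consistent_kspace",
]


@dataclass
class SyntheticDataset:
    """Ground-truth bundle: image, sensitivities, full k-space, sampling."""

    truth_image: np.ndarray
    sensitivities: np.ndarray
    kspace_full: np.ndarray
    scheme: SamplingScheme
    noise_sigma: float
    seed: int

    def undersampled(self) -> np.ndarray:
        """Retrospectively undersampled k-space under ``self.scheme``."""
        return undersample(self.kspace_full, self.scheme)


# --- phantom ---------------------------------------------------------------

# (cx, cy, a, b, angle_deg, additive value) in [-1, 1]^2 coordinates
_ELLIPSES = [
    (0.0, 0.0, 0.84, 0.92, 0.0, 0.80),
    (0.0, 0.02, 0.74, 0.84, 0.0, -0.30),
    (-0.26, 0.18, 0.24, 0.40, -18.0, -0.20),
    (0.26, 0.18, 0.20, 0.36, 18.0, -0.25),
    (0.0, -0.38, 0.30, 0.20, 0.0, 0.35),
    (0.0, 0.35, 0.06, 0.06, 0.0, 0.30),
    (-0.08, -0.08, 0.05, 0.09, 0.0, 0.25),
    (0.08, -0.08, 0.04, 0.08, 0.0, 0.25),
    (0.45, -0.45, 0.10, 0.07, -40.0, 0.30),
]

_BLOCKS = [
    (-0.8, 0.8, -0.8, 0.8, 0.45),
    (-0.55, -0.05, -0.6, 0.2, 0.35),
    (0.1, 0.6, -0.35, 0.45, -0.25),
    (-0.3, 0.35, 0.5, 0.72, 0.4),
    (0.3, 0.5, -0.72, -0.5, 0.3),
]


def make_phantom(Nx: int, Ny: int, kind: str = "ellipses") -> np.ndarray:
    """Deterministic piecewise-smooth test image with values in [0, 1].

    ``kind="ellipses"`` stacks a fixed set of overlapping ellipses (a
    head-like resolution object); ``kind="blocks"`` stacks axis-aligned
    rectangles. Both have sharp edges and flat interiors.
    """
    if Nx < 32 or Ny < 32:
        raise ValueError("phantom requires Nx, Ny >= 32")
    x = np.linspace(-1.0, 1.0, Nx)[:, None]
    y = np.linspace(-1.0, 1.0, Ny)[None, :]
    img = np.zeros((Nx, Ny))
    if kind == "ellipses":
        for cx, cy, a, b, ang, val in _ELLIPSES:
            t = np.deg2rad(ang)
            xr = (x - cx) * np.cos(t) + (y - cy) * np.sin(t)
            yr = -(x - cx) * np.sin(t) + (y - cy) * np.cos(t)
            img += val * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    elif kind == "blocks":
        for x0, x1, y0, y1, val in _BLOCKS:
            img += val * ((x >= x0) & (x <= x1) & (y >= y0) & (y <= y1))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return np.clip(img, 0.0, 1.0)


# --- coil sensitivities ----------------------------------------------------


def make_coil_sensitivities(
    nc: int,
    Nx: int,
    Ny: int,
    smoothness: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Smooth random complex coil sensitivity maps, shape ``(nc, Nx, Ny)``.

    Each map is the inverse FFT of random complex coefficients confined to a
    central low-frequency block of half-width ``int(smoothness * N)`` per
    axis, plus a distinct complex constant per coil that keeps the
    sum-of-squares sensitivity bounded away from zero. With the default
    ``smoothness`` the entire spectral content lies inside the central 1/8
    frequency band.
    """
    if nc < 2:
        raise ValueError("parallel imaging needs at least 2 coils")
    rng = np.random.default_rng(np.random.SeedSequence([0x5E45, seed]))
    bx = max(1, int(smoothness * Nx))
    by = max(1, int(smoothness * Ny))
    spec = np.zeros((nc, Nx, Ny), dtype=np.complex128)
    coeffs = rng.standard_normal((nc, 2 * bx + 1, 2 * by + 1, 2))
    cx, cy = Nx // 2, Ny // 2
    spec[:, cx - bx : cx + bx + 1, cy - by : cy + by + 1] = (
        coeffs[..., 0] + 1j * coeffs[..., 1]
    )
    maps = ifft2c(spec)
    # normalize fluctuation power, then anchor each coil with a distinct
    # constant (DC term, so smoothness is preserved exactly)
    rms = np.sqrt(np.mean(np.abs(maps) ** 2))
    maps *= 0.4 / (np.sqrt(nc) * rms)
    phases = np.exp(2j * np.pi * np.arange(nc) / nc)
    maps += (0.8 / np.sqrt(nc)) * phases[:, None, None]
    return maps


def forward_model(image: np.ndarray, sensitivities: np.ndarray) -> np.ndarray:
    """Noiseless multi-coil k-space: ``fft2c(sensitivity_c * image)`` per coil."""
    image = np.asarray(image)
    sens = np.asarray(sensitivities)
    if sens.ndim != 3 or sens.shape[1:] != image.shape:
        raise ValueError(
            f"shape mismatch: sensitivities {sens.shape} vs image {image.shape}"
        )
    return fft2c(sens * image[None])


def add_noise(k: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. complex Gaussian noise (std ``sigma`` per real component)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    k = np.asarray(k, dtype=np.complex128)
    if sigma == 0:
        return k.copy()
    rng = np.random.default_rng(np.random.SeedSequence([0x4015E, seed]))
    noise = rng.standard_normal(k.shape + (2,))
    return k + sigma * (noise[..., 0] + 1j * noise[..., 1])


def sigma_for_snr(image: np.ndarray, sensitivities: np.ndarray, snr: float) -> float:
    """Per-component k-space noise std giving a per-coil image SNR of ``snr``.

    SNR is defined as the RMS coil-image signal magnitude divided by the RMS
    complex noise magnitude (``sigma * sqrt(2)``, identical in image and
    k-space by unitarity of the centered orthonormal FFT).
    """
    signal_rms = np.sqrt(np.mean(np.abs(sensitivities * image[None]) ** 2))
    return float(signal_rms / (snr * np.sqrt(2.0)))


def make_dataset(
    nc: int = 8,
    Nx: int = 128,
    Ny: int = 128,
    R: int = 4,
    acs_width: int = 32,
    snr: float | None = None,
    noise_sigma: float | None = None,
    seed: int = 0,
    kind: str = "ellipses",
    phase_offset: int = 0,
) -> SyntheticDataset:
    """Full synthetic acquisition with the package's default geometry.

    The defaults (8 coils, 128x128 matrix, 32 ACS lines, i.e. ACS = Ny/8)
    scale down a typical head acquisition (32 coils, 320x320 matrix, 40 ACS
    lines) while keeping the ACS-to-matrix ratio. Noise is specified either
    directly (``noise_sigma``) or via a per-coil image SNR (``snr``);
    omitting both gives noiseless data.
    """
    truth = make_phantom(Nx, Ny, kind=kind)
    sens = make_coil_sensitivities(nc, Nx, Ny, seed=seed)
    k = forward_model(truth, sens)
    if snr is not None and noise_sigma is not None:
        raise ValueError("give either snr or noise_sigma, not both")
    sigma = float(noise_sigma) if noise_sigma is not None else (
        sigma_for_snr(truth, sens, snr) if snr is not None else 0.0
    )
    if sigma > 0:
        k = add_noise(k, sigma, seed=seed)
    scheme = SamplingScheme.centered(Ny, R, acs_width, phase_offset=phase_offset)
    scheme.validate(Ny)
    return SyntheticDataset(
        truth_image=truth,
        sensitivities=sens,
        kspace_full=k,
        scheme=scheme,
        noise_sigma=sigma,
        seed=seed,
    )


# --- planted linear kernel -------------------------------------------------


def make_linear_consistent_kspace(
    nc: int,
    Nx: int,
    Ny: int,
    scheme: SamplingScheme,
    seed: int = 0,
    kernel_size: tuple[int, int] = (5, 4),
) -> tuple[np.ndarray, GrappaKernel]:
    """K-space whose missing lines exactly obey a known GRAPPA kernel.

    Acquired lattice lines are drawn as smooth random complex data; every
    missing line is then synthesized by applying a randomly drawn kernel with
    circular boundaries in kx and on the ky lattice (``Ny`` must be a
    multiple of ``R``). Returns the fully populated k-space and the planted
    kernel; re-applying the kernel (wrap boundary) reproduces the missing
    samples to machine precision by construction.
    """
    from scipy.ndimage import gaussian_filter

    R = scheme.R
    if R < 2:
        raise ValueError("planted-kernel mode needs R >= 2")
    if Ny % R != 0:
        raise ValueError(f"Ny={Ny} must be a multiple of R={R}")
    rng = np.random.default_rng(np.random.SeedSequence([0x9141A, seed]))
    G = Ny // R

    raw = rng.standard_normal((nc, Nx, G, 2))
    lat = raw[..., 0] + 1j * raw[..., 1]
    # mild smoothing ("smooth random" lines) with periodic boundaries;
    # conditioning of the calibration system stays benign at sigma = 1
    lat = gaussian_filter(lat.real, sigma=(0, 1.0, 1.0), mode="wrap") + 1j * (
        gaussian_filter(lat.imag, sigma=(0, 1.0, 1.0), mode="wrap")
    )

    nkx, nky = kernel_size
    wraw = rng.standard_normal((nc, R - 1, nc, nkx, nky, 2))
    weights = (wraw[..., 0] + 1j * wraw[..., 1]) / np.sqrt(2.0 * nc * nkx * nky)
    kernel = GrappaKernel(weights=weights, R=R, kernel_size=kernel_size)

    k_lattice_only = np.zeros((nc, Nx, Ny), dtype=np.complex128)
    k_lattice_only[:, :, scheme.lattice_lines(Ny)] = lat
    pure_lattice = SamplingScheme(
        R=R, acs_start=0, acs_width=0, phase_offset=scheme.phase_offset
    )
    k_full = grappa_apply(k_lattice_only, kernel, pure_lattice, boundary="wrap")
    return k_full, kernel
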