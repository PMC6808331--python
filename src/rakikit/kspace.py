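"""Cartesian multi-coil k-space model.

Conventions used throughout the package:

* Multi-coil k-space is a complex ``numpy`` array of shape ``(nc, Nx, Ny)``
  where ``nc`` is the number of receiver coils, ``kx`` (axis 1) is the fully
  sampled frequency-encoding direction and ``ky`` (axis 2) is the
  phase-encoding direction that is undersampled. Indices are 0-based and the
  grid step is one in both directions.
* The *real field* representation interleaves real and imaginary parts into
  ``2 nc`` real channels: channel ``2c`` holds ``Re`` and channel ``2c + 1``
  holds ``Im`` of coil ``c``. This is the input format for the real-valued
  interpolation networks.
* Fourier transforms are centered (DC at the array center) and orthonormal,
  so Parseval's identity holds exactly and ``fft2c``/``ifft2c`` are inverse
  pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingScheme",
    "ScaleRecord",
    "ReconResult",
    "validate_kspace",
    "to_real_field",
    "from_real_field",
    "scale_to_training_range",
    "undersample",
    "extract_acs",
    "fft2c",
    "ifft2c",
    "rss_combine",
]


def validate_kspace(k: np.ndarray, min_ny: int = 8) -> np.ndarray:
    """Check and normalize a multi-coil k-space array.

    Returns the input as a contiguous complex array of shape ``(nc, Nx, Ny)``.
    Raises ``ValueError`` for wrong rank, undersized grids, or non-finite
    values. ``min_ny`` can be lowered for narrow blocks (e.g. an extracted
    ACS strip).
    """
    k = np.asarray(k)
    if k.ndim != 3:
        raise ValueError(f"k-space must have shape (nc, Nx, Ny); got {k.shape}")
    nc, nx, ny = k.shape
    if nc < 1:
        raise ValueError("need at least one coil")
    if nx < 8 or ny < min_ny:
        raise ValueError(f"grid too small: ({nx}, {ny}); need Nx >= 8, Ny >= {min_ny}")
    if not np.all(np.isfinite(k)):
        raise ValueError("k-space contains non-finite values")
    return np.ascontiguousarray(k, dtype=np.complex128)


@dataclass(frozen=True)
class SamplingScheme:
    """Uniform ky undersampling lattice plus a contiguous central ACS block.

    The acquired line set is
    ``{ky : ky mod R == phase_offset} ∪ [acs_start, acs_start + acs_width)``.

    Parameters
    ----------
    R:
        Acceleration rate; every R-th phase-encoding line is acquired.
    acs_start, acs_width:
        First index and width of the fully sampled autocalibration block.
        ``acs_width = 0`` means no ACS block (pure lattice sampling).
    phase_offset:
        Residue of the acquired lattice, in ``[0, R)``.
    """

    R: int
    acs_start: int
    acs_width: int
    phase_offset: int = 0

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("acceleration R must be >= 1")
        if not (0 <= self.phase_offset < self.R):
            raise ValueError("phase_offset must lie in [0, R)")
        if self.acs_width < 0 or self.acs_start < 0:
            raise ValueError("ACS block indices must be nonnegative")

    @classmethod
    def centered(
        cls, Ny: int, R: int, acs_width: int, phase_offset: int = 0
    ) -> "SamplingScheme":
        """Scheme with the ACS block centered: acs_start = (Ny - acs_width) // 2."""
        return cls(R=R, acs_start=(Ny - acs_width) // 2, acs_width=acs_width,
                   phase_offset=phase_offset)

    def validate(self, Ny: int) -> None:
        if self.acs_width > 0 and self.acs_start + self.acs_width > Ny:
            raise ValueError(
                f"ACS block [{self.acs_start}, {self.acs_start + self.acs_width}) "
                f"out of range for Ny={Ny}"
            )

    def lattice_lines(self, Ny: int) -> np.ndarray:
        """ky indices of the regularly acquired lattice."""
        return np.arange(self.phase_offset, Ny, self.R)

    def acs_lines(self) -> np.ndarray:
        return np.arange(self.acs_start, self.acs_start + self.acs_width)

    def acquired_mask(self, Ny: int) -> np.ndarray:
        """Boolean mask over ky of all acquired lines (lattice ∪ ACS)."""
        self.validate(Ny)
        mask = np.zeros(Ny, dtype=bool)
        mask[self.lattice_lines(Ny)] = True
        if self.acs_width > 0:
            mask[self.acs_start : self.acs_start + self.acs_width] = True
        return mask

    def acquired_lines(self, Ny: int) -> np.ndarray:
        return np.nonzero(self.acquired_mask(Ny))[0]


@dataclass(frozen=True)
class ScaleRecord:
    """Multiplicative factor applied to the real-field data before training."""

    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("scale factor must be positive")


def to_real_field(k: np.ndarray) -> np.ndarray:
    """Map complex ``(nc, Nx, Ny)`` k-space to ``(2nc, Nx, Ny)`` real channels.

    Channel ``2c`` holds the real part of coil ``c`` and channel ``2c + 1``
    its imaginary part. The mapping is a lossless bijection inverted by
    :func:`from_real_field`.
    """
    k = np.asarray(k)
    nc, nx, ny = k.shape
    rf = np.empty((2 * nc, nx, ny), dtype=np.float64)
    rf[0::2] = k.real
    rf[1::2] = k.imag
    return rf


def from_real_field(rf: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_real_field`."""
    rf = np.asarray(rf)
    if rf.ndim != 3 or rf.shape[0] % 2:
        raise ValueError("real-field tensor must have shape (2nc, Nx, Ny)")
    return rf[0::2].astype(np.complex128) + 1j * rf[1::2]


def scale_to_training_range(
    rf: np.ndarray, target_max: float = 0.015
) -> tuple[np.ndarray, ScaleRecord]:
    """Scale data so its maximum absolute value equals ``target_max``.

    The stated range ``[0, 0.015]`` is read as a bound on the absolute value:
    real-field data contain negatives, and a multiplicative scaling is the
    only invertible realization. Returns the scaled array and the
    :class:`ScaleRecord` needed to undo the scaling after reconstruction.
    """
    peak = float(np.max(np.abs(rf)))
    if peak == 0.0:
        raise ValueError("cannot scale zero data")
    factor = target_max / peak
    return rf * factor, ScaleRecord(factor=factor)


def undersample(k: np.ndarray, s: SamplingScheme) -> np.ndarray:
    """Zero every ky line not in the acquired set; acquired lines copied verbatim."""
    k = validate_kspace(k)
    mask = s.acquired_mask(k.shape[2])
    out = np.zeros_like(k)
    out[:, :, mask] = k[:, :, mask]
    return out


def extract_acs(k: np.ndarray, s: SamplingScheme) -> np.ndarray:
    """Copy of the contiguous fully sampled ACS block, shape ``(nc, Nx, acs_width)``."""
    k = validate_kspace(k)
    if s.acs_width < 1:
        raise ValueError("scheme has no ACS block")
    s.validate(k.shape[2])
    return k[:, :, s.acs_start : s.acs_start + s.acs_width].copy()


_AX = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2-D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AX), axes=_AX, norm="ortho"), axes=_AX
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2-D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AX), axes=_AX, norm="ortho"), axes=_AX
    )


def rss_combine(images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination: ``sqrt(sum_c |image_c|^2)``."""
    images = np.asarray(images)
    return np.sqrt(np.sum(np.abs(images) ** 2, axis=0))


@dataclass
class ReconResult:
    """Outcome of a reconstruction.

    Attributes
    ----------
    kspace:
        Fully populated complex k-space, shape ``(nc, Nx, Ny)``.
    image:
        Root-sum-of-squares magnitude image, shape ``(Nx, Ny)``.
    scale:
        Scale applied to the real-field data before training, or ``None``
        for methods that operate on unscaled complex data (GRAPPA).
    info:
        Method-specific diagnostics: method name, R, seeds, per-network
        epoch counts and final losses, timings.
    """

    kspace: np.ndarray
    image: np.ndarray
    scale: ScaleRecord | None
    info: dict
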