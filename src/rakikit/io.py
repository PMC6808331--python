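"""HDF5 file I/O.

A dataset file holds a complex ``"kspace"`` array of shape ``(nc, Nx, Ny)``
or the fastMRI-style ``(n_slices, nc, Nx, Ny)`` (read with a slice
selector), optional ``"truth_image"`` and ``"sensitivities"`` arrays, and
sampling/provenance attributes (``R``, ``acs_width``, ``phase_offset``,
``seed``, ``noise_sigma``, ...). Complex data are written natively; a
trailing real/imaginary axis of length 2 is also accepted on read.

All objects are created with ``track_times=False`` so identical content
produces byte-identical files (required for the concurrency contract).
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version

import h5py
import numpy as np

from .grappa import GrappaKernel
from .kspace import SamplingScheme
from .raki import NetworkWeights, RakiArchitecture

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_kernel",
    "load_kernel",
    "save_networks",
    "load_networks",
]

_SCHEME_ATTRS = ("R", "acs_start", "acs_width", "phase_offset")


def _package_version() -> str:
    try:
        return version("rakikit")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def _as_complex(arr: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(arr):
        return np.asarray(arr, dtype=np.complex128)
    arr = np.asarray(arr)
    if arr.shape[-1] == 2 and np.issubdtype(arr.dtype, np.floating):
        return arr[..., 0] + 1j * arr[..., 1]
    raise ValueError(
        "expected complex data or a trailing real/imaginary axis of length 2"
    )


def write_dataset(
    path,
    kspace: np.ndarray,
    scheme: SamplingScheme | None = None,
    truth_image: np.ndarray | None = None,
    sensitivities: np.ndarray | None = None,
    attrs: dict | None = None,
) -> None:
    """Write a dataset file (see module docstring for the layout)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace, dtype=np.complex128),
                         track_times=False)
        if truth_image is not None:
            f.create_dataset("truth_image", data=np.asarray(truth_image, dtype=np.float64),
                             track_times=False)
        if sensitivities is not None:
            f.create_dataset(
                "sensitivities", data=np.asarray(sensitivities, dtype=np.complex128),
                track_times=False,
            )
        if scheme is not None:
            for name in _SCHEME_ATTRS:
                f.attrs[name] = int(getattr(scheme, name))
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        f.attrs["rakikit_version"] = _package_version()


def read_dataset(path, slice: int | None = None):
    """Read a dataset file.

    Returns ``(kspace, scheme, extras)`` where ``scheme`` is ``None`` when
    the file carries no sampling attributes and ``extras`` holds any other
    datasets and attributes. A 4-D (fastMRI-style) ``kspace`` requires the
    ``slice`` selector.
    """
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise ValueError(
                f"{path}: no 'kspace' dataset; expected layout: complex "
                "'kspace' of shape (nc, Nx, Ny) or (n_slices, nc, Nx, Ny)"
            )
        k = _as_complex(f["kspace"][()])
        if k.ndim == 4:
            if slice is None:
                raise ValueError(
                    f"{path}: 4-D k-space with {k.shape[0]} slices; "
                    "a --slice selector is required"
                )
            k = k[slice]
        elif k.ndim != 3:
            raise ValueError(f"{path}: k-space must be 3-D or 4-D, got {k.ndim}-D")
        scheme = None
        if all(a in f.attrs for a in _SCHEME_ATTRS):
            scheme = SamplingScheme(
                **{a: int(f.attrs[a]) for a in _SCHEME_ATTRS}
            )
        extras = {key: f.attrs[key] for key in f.attrs if key not in _SCHEME_ATTRS}
        for name in ("truth_image", "sensitivities"):
            if name in f:
                extras[name] = f[name][()]
    return k, scheme, extras


def save_kernel(path, kernel: GrappaKernel, attrs: dict | None = None) -> None:
    """Serialize a GRAPPA kernel (complex weights + metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=kernel.weights, track_times=False)
        f.attrs["R"] = kernel.R
        f.attrs["kernel_size"] = list(kernel.kernel_size)
        f.attrs["rakikit_version"] = _package_version()
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_kernel(path) -> GrappaKernel:
    with h5py.File(path, "r") as f:
        return GrappaKernel(
            weights=f["weights"][()],
            R=int(f.attrs["R"]),
            kernel_size=tuple(int(v) for v in f.attrs["kernel_size"]),
        )


def save_networks(path, networks: list[NetworkWeights], attrs: dict | None = None) -> None:
    """Serialize trained networks: per-layer tensors, architecture, loss history."""
    if not networks:
        raise ValueError("no networks to save")
    arch = networks[0].arch
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = arch.kind
        f.attrs["nc"] = arch.nc
        f.attrs["R"] = arch.R
        f.attrs["rakikit_version"] = _package_version()
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for net in networks:
            g = f.create_group(f"network_{net.index:03d}", track_order=False)
            g.attrs["index"] = net.index
            for name in ("w1", "w2", "w3"):
                g.create_dataset(name, data=getattr(net, name), track_times=False)
            if net.history is not None:
                g.create_dataset("loss_history", data=net.history, track_times=False)
                g.attrs["epochs"] = int(len(net.history))
                g.attrs["final_loss"] = float(net.history[-1])


def load_networks(path) -> list[NetworkWeights]:
    with h5py.File(path, "r") as f:
        arch = RakiArchitecture(
            kind=str(f.attrs["kind"]), nc=int(f.attrs["nc"]), R=int(f.attrs["R"])
        )
        nets = []
        for name in sorted(k for k in f if k.startswith("network_")):
            g = f[name]
            nets.append(
                NetworkWeights(
                    w1=g["w1"][()],
                    w2=g["w2"][()],
                    w3=g["w3"][()],
                    arch=arch,
                    index=int(g.attrs["index"]),
                    history=g["loss_history"][()] if "loss_history" in g else None,
                )
            )
    return nets
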