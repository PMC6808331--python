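"""Reconstruction quality metrics and architecture parameter counting.

NMSE and SSIM are computed on root-sum-of-squares magnitude images, the
convention used when comparing accelerated reconstructions against the fully
sampled reference. SSIM uses the Wang et al. defaults (11x11 Gaussian window
with sigma 1.5, K1 = 0.01, K2 = 0.03) with the data range set by the
reference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .grappa import grappa_reconstruct
from .kspace import SamplingScheme, ifft2c, rss_combine, undersample
from .raki import AdamConfig, RakiArchitecture, TrainingConfig, raki_reconstruct
from .simulate import SyntheticDataset

__all__ = ["ParamCount", "nmse", "ssim", "count_parameters", "benchmark"]


def nmse(x: np.ndarray, ref: np.ndarray) -> float:
    """Normalized mean squared error ``||x - ref||^2 / ||ref||^2``."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    denom = float(np.sum(ref**2))
    if denom == 0.0:
        raise ValueError("reference image has zero norm")
    return float(np.sum((x - ref) ** 2) / denom)


def ssim(x: np.ndarray, ref: np.ndarray) -> float:
    """Mean local structural similarity of ``x`` against reference ``ref``."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    data_range = float(ref.max())
    if data_range <= 0.0:
        raise ValueError("degenerate reference image (constant zero)")
    return float(
        structural_similarity(
            ref,
            x,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
    )


@dataclass(frozen=True)
class ParamCount:
    """Exact weight-element counts for one architecture instance."""

    arch: str
    per_network: int
    n_networks: int

    @property
    def total(self) -> int:
        return self.per_network * self.n_networks


def count_parameters(arch: str, nc: int, R: int) -> ParamCount:
    """Count weights by enumerating the instantiated kernel tensors.

    There are no bias terms, so the count is the sum of kernel element
    products per layer. For CBC this equals the closed form
    ``640 nc + 208 + 48 R`` per network (2 nc networks); for LBL the
    enumeration gives ``736 nc + 256`` per network (R - 1 networks).
    """
    a = RakiArchitecture(arch, nc=nc, R=R)
    per_network = int(sum(int(np.prod(s)) for s in a.weight_shapes()))
    return ParamCount(arch=arch, per_network=per_network, n_networks=a.n_networks)


def benchmark(
    dataset: SyntheticDataset,
    methods: list[str],
    rates: list[int],
    seeds: list[int],
    adam: AdamConfig | None = None,
    cfg: TrainingConfig | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Reconstruction-quality sweep over methods, acceleration rates and seeds.

    The dataset's full k-space is retrospectively undersampled at each rate
    (keeping the dataset's ACS width and phase offset) and reconstructed
    with every method; NMSE and SSIM are measured against the RSS image of
    the fully sampled data. One row per (method, R, seed); GRAPPA is
    deterministic, so its rows do not vary with the seed.

    Returns a DataFrame with columns
    ``method, arch, R, seed, nmse, ssim, epochs, final_loss``.
    """
    if not methods or not seeds or not rates:
        raise ValueError("need at least one method, rate and seed")
    known = {"grappa", "raki-cbc", "raki-lbl"}
    bad = set(methods) - known
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}; choose from {sorted(known)}")
    ny = dataset.kspace_full.shape[2]
    reference = rss_combine(ifft2c(dataset.kspace_full))
    base_cfg = cfg or TrainingConfig()

    rows = []
    for R in rates:
        scheme = SamplingScheme.centered(
            ny, R, dataset.scheme.acs_width, phase_offset=dataset.scheme.phase_offset
        )
        k_us = undersample(dataset.kspace_full, scheme)
        for method in methods:
            for seed in seeds:
                if method == "grappa":
                    res = grappa_reconstruct(k_us, scheme)
                    epochs, final_loss = 0, np.nan
                else:
                    run_cfg = TrainingConfig(
                        max_epochs=base_cfg.max_epochs,
                        plateau_window=base_cfg.plateau_window,
                        plateau_tol=base_cfg.plateau_tol,
                        init_std=base_cfg.init_std,
                        master_seed=seed,
                    )
                    res = raki_reconstruct(
                        k_us, scheme, kind=method.removeprefix("raki-"),
                        adam=adam, cfg=run_cfg, workers=workers,
                    )
                    epochs = int(np.mean(res.info["epochs"]))
                    final_loss = float(np.mean(res.info["final_loss"]))
                rows.append(
                    {
                        "method": method,
                        "arch": method.removeprefix("raki-") if method != "grappa" else "linear",
                        "R": R,
                        "seed": seed,
                        "nmse": nmse(res.image, reference),
                        "ssim": ssim(res.image, reference),
                        "epochs": epochs,
                        "final_loss": final_loss,
                    }
                )
    return pd.DataFrame(rows)
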