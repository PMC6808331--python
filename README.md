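# rakikit

Scan-specific k-space interpolation for accelerated parallel MRI.

Uniformly undersampled Cartesian acquisitions keep every R-th
phase-encoding line of multi-coil k-space plus a small fully sampled
autocalibration (ACS) block; the missing lines must be interpolated before
the coil images are combined. This package implements, behind one sampling
geometry:

* **GRAPPA** — the classical linear baseline: each missing sample is a
  complex-linear combination of acquired samples in a 5×4 footprint, with
  weights estimated from the ACS by (optionally ridge-regularized) least
  squares.
* **RAKI** — scan-specific nonlinear interpolation: tiny three-layer CNNs
  `f(s) = w3 ∗ ReLU(w2 ∗ ReLU(w1 ∗ s))` (no biases), trained only on the
  subject's ACS by full-batch Adam, operating on the real-field mapping
  (2n_c channels) of the complex data. Two head layouts are provided:
  **coil-by-coil** (CBC; 2n_c networks, one per real-field channel, R−1
  outputs each) and **line-by-line** (LBL; only R−1 networks, one per
  missing offset, 2n_c outputs each — e.g. 4 instead of 64 networks at
  R = 5 with 32 coils).
* a **synthetic-data simulator** (phantom, smooth complex coil
  sensitivities, k-space noise, and a planted-linear-kernel mode in which
  GRAPPA is exact by construction), and **NMSE/SSIM** evaluation with an
  architecture parameter-count report.

It is aimed at reconstruction researchers who want a dependency-light,
fully tested NumPy reference of these methods with deterministic seeding
and exact oracles. See `docs/methods.md` for the model, geometry and
numerical details.

## Worked example

```python
import numpy as np
from rakikit import (SamplingScheme, ifft2c, nmse, raki_reconstruct,
                     rss_combine, undersample)
from rakikit.grappa import grappa_reconstruct
from rakikit.simulate import make_dataset

# 8-coil 128x128 acquisition, 32 ACS lines, per-coil SNR ~ 20, R = 5
ds = make_dataset(nc=8, Nx=128, Ny=128, R=5, acs_width=32, snr=20, seed=0)
k_us = ds.undersampled()                       # retrospective undersampling
ref = rss_combine(ifft2c(ds.kspace_full))      # fully sampled RSS reference

grappa = grappa_reconstruct(k_us, ds.scheme)
cbc = raki_reconstruct(k_us, ds.scheme, kind="cbc")   # 16 networks
lbl = raki_reconstruct(k_us, ds.scheme, kind="lbl")   # 4 networks

print(f"GRAPPA   NMSE {nmse(grappa.image, ref):.4f}")
print(f"RAKI-CBC NMSE {nmse(cbc.image, ref):.4f}")
print(f"RAKI-LBL NMSE {nmse(lbl.image, ref):.4f}")
```

Output:

```
GRAPPA   NMSE 0.0298
RAKI-CBC NMSE 0.0127
RAKI-LBL NMSE 0.0131
```

At this high acceleration both RAKI variants cut the image error of the
linear baseline by more than half: the CNNs' nonlinearity suppresses the
noise amplification GRAPPA suffers when the interpolation problem becomes
ill-conditioned, and the LBL variant reaches that quality with a quarter of
the networks. `ReconResult.info` carries per-network epoch counts and final
losses; `ReconResult.kspace` keeps acquired lines bitwise intact.

The same pipeline is available from the shell:

```sh
rakikit simulate --coils 8 --nx 128 --ny 128 -R 5 --acs 32 --snr 20 -o data.h5
rakikit reconstruct --method raki-lbl --seed 0 --workers 4 -i data.h5 -o rec.h5
rakikit evaluate -i rec.h5 -r data.h5
rakikit params --arch lbl --coils 32 -R 5
```

`--workers 4` trains the independent networks concurrently and is
guaranteed byte-identical to `--workers 1` under the same seed.

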