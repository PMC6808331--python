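# Methods

## Problem and model

Uniformly undersampled Cartesian parallel MRI keeps every R-th
phase-encoding line of multi-coil k-space, plus a fully sampled central
autocalibration (ACS) block. The R−1 missing lines between each pair of
acquired lattice lines must be interpolated before coil combination.

Two interpolators are implemented behind the same sampling geometry:

**GRAPPA.** Each missing sample S(kx, ky = a + R + m, j), m ∈ {1, …, R−1},
is a shift-invariant complex-linear combination of the acquired samples in a
5 × 4 footprint: 5 kx taps centered on the target and the 4 nearest acquired
lines {a, a+R, a+2R, a+3R}, so the target lies between source lines 2 and 3.
Weights are estimated per (target coil, offset m) by least squares on
calibration windows slid over the ACS, optionally with a Tikhonov ridge
λ‖w‖² (off by default). Windows slide over all ACS shifts by default; an
`align_offset` option restricts them to one residue class mod R, which
emulates the acquired pattern exactly and is what makes the planted-kernel
oracle (below) recover a kernel to machine precision.

**RAKI.** The linear kernel is replaced by a scan-specific three-layer CNN
trained only on the subject's ACS:

    f(s) = w3 ∗ ReLU(w2 ∗ ReLU(w1 ∗ s)),   ReLU(x) = max(x, 0)

with no bias terms in any layer. Complex k-space is first mapped to the real
field (2nc channels, Re/Im interleaved) and scaled so its maximum absolute
value is 0.015 — the stated range [0, 0.015] is read as a bound on the
absolute value, since real-field data contain negatives and a multiplicative
scale is the only invertible realization; the factor is recorded and
inverted on the predictions.

Two output-head layouts:

* coil-by-coil (CBC): one network per real-field channel j, head size R−1;
  2nc networks per reconstruction;
* line-by-line (LBL): one network per missing offset m, head size 2nc; only
  R−1 networks (for R = 5, nc = 32: 4 instead of 64, a 16-fold reduction).

## Network geometry

Convolutions run on the acquired-line subgrid (every R-th ky line), which is
identical to dilation-R kernels on the full grid but simpler. Kernel sizes
are (kx, subgrid-ky): layer 1 (5, 2) with 32 output channels, layer 2 (1, 1)
with 8, layer 3 (3, 2) with the head. Layer 3's ky taps are dilated by 2 on
the subgrid (taps {0, 2}), so the composite receptive field spans 7 kx taps
by 4 acquired lines — the same 4-line window, with the target between lines
2 and 3, as the 5 × 4 GRAPPA kernel. This choice keeps the two interpolators
geometrically comparable and, together with the absence of biases, makes the
per-network weight counts exactly 640nc + 208 + 48R (CBC) and 736nc + 256
(LBL); `count_parameters` reports these by enumerating the kernel tensors.
With ReLUs bypassed through the decomposition x = ReLU(x) − ReLU(−x), the
CBC class provably contains every GRAPPA linear map with R ≤ 3 (4(R−1) ≤ 8
hidden channels needed); the test suite verifies this constructively.

Training pairs slide a 4-line window over all shifts of the ACS: window
starts a ∈ [0, acs_width − 1 − 3R] (hence the requirement
acs_width ≥ 3R + 1), giving acs_width − 3R windows and Nx − 6 valid kx
positions per window. At inference the subgrid is zero-padded by (3, 3) in
kx and (1, 2) in subgrid-ky so that every missing position receives a
prediction; with a nonzero lattice phase offset the left pad grows to 2 so
the leading lines are covered too. Acquired lines and the measured ACS block
are reinserted verbatim afterwards (data consistency).

## Optimization

Full-batch Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on the
mean-squared error, mean taken over all target scalars (this only rescales
the effective α relative to a sum convention). Weights are initialized
i.i.d. normal(0, 0.1). Training stops at 1000 epochs, or earlier when the
normalized loss change |L[t−100] − L[t]| / L[t−100] falls below 1e−4
(absolute value to tolerate oscillation; an exactly zero loss over the
window also counts as converged). Forward/backward passes are hand-written
im2col/GEMM operations; a finite-difference gradient check and a loop-based
convolution oracle in the test suite pin their correctness. Training runs in
single precision (float32); the Adam implementation itself is
dtype-generic, and the analytic single-step check runs in float64.

Per-task weight initialization is seeded by `SeedSequence([master_seed,
task_index])`, so training the independent networks concurrently (thread
pool; the GEMMs release the GIL) is bitwise identical to sequential
execution — reconstruction outputs are byte-reproducible from the master
seed regardless of `--workers`.

## Synthetic data

The simulator emulates a single-slice 2-D acquisition with known ground
truth: a deterministic piecewise-smooth phantom (overlapping ellipses or
blocks, values in [0, 1]); nc smooth complex coil sensitivities built from
random spectral coefficients confined to a low-frequency block (entirely
inside the central 1/8 band) plus distinct per-coil DC anchors that keep
Σ|S_c|² bounded away from zero; the forward model F(S_c · image) with a
centered orthonormal FFT; and i.i.d. complex Gaussian k-space noise
(equivalent to image noise by unitarity). SNR is specified as RMS coil-image
signal over RMS complex noise magnitude.

The default test geometry is nc = 8, 128 × 128, 32 ACS lines — a
scaled-down version of a typical 32-coil, 320 × 320, 40-ACS-line head
acquisition that preserves the ACS-to-matrix ratio while keeping a full CBC
training (16 networks, ≤ 1000 epochs each) around a minute on one CPU core.
The noisy benchmark condition uses per-coil SNR ≈ 20.

A second generator plants an exact linear structure: acquired lattice lines
are drawn as smoothed random complex data, and every missing line is
synthesized with a randomly drawn 5 × 4 kernel using circular boundaries in
kx and on the ky lattice. GRAPPA calibration on its ACS (lattice-aligned
windows, λ = 0) then recovers the planted kernel up to the conditioning of
an exactly consistent least-squares system, and wrap-boundary application
refills k-space to machine precision — an end-to-end oracle with no edge
effects.

What the simulator does not model: pulse-sequence contrast, non-Cartesian
trajectories, 3-D/multi-slice volumes, coil coupling, motion, or measured
noise correlations. Passing quality tests on this data therefore shows
method correctness and the expected ordering between methods under
controlled conditions, not clinical image quality.

## Evaluation

NMSE ‖x − ref‖²/‖ref‖² and SSIM (11 × 11 Gaussian window, σ = 1.5,
K1 = 0.01, K2 = 0.03, data range = max of the reference) are computed on
root-sum-of-squares magnitude images against the RSS image of the fully
sampled (noisy) data — the convention for retrospective undersampling
studies. The benchmark sweep reports one row per (method, R, seed) plus
mean ± std across seeds; GRAPPA rows are seed-invariant.

On the default noisy dataset the reproduced ordering matches expectations
for these methods: RAKI-CBC at R = 5 beats GRAPPA on mean NMSE, and LBL
stays within 25% of CBC at R = 4 (the acceptance suite runs this over five
training seeds; the acceptance script reports two-seed means at R ∈ {4, 5}
to stay lightweight).

## Design choices on open points

* Lattice phase offset (position of acquired lines relative to the ACS
  center) is exposed as a parameter with default 0; acquisitions differ and
  no single convention is canonical.
* GRAPPA ky-edge handling: the source window is clamped to the nearest valid
  4-line window at the top/bottom of k-space; kx edges are zero-padded. The
  wrap-boundary path exists for the simulator's exactness oracle.
* Ridge regularization defaults to 0; it is exposed for ill-conditioned ACS.
* Loss normalization is the mean (not sum) over samples; target placement is
  symmetric (between lines 2 and 3); weight init σ = 0.1 — all exposed in
  the config dataclasses.

## Known limitations

* Quality claims are validated on synthetic data only; no measured phantom
  or in-vivo data ship with the package (the HDF5 reader accepts
  fastMRI-style files for real-data use).
* The hand-set linear-network construction covers R ≤ 3; for larger R the
  8-channel second layer cannot carry all ± pairs, so the containment of
  GRAPPA in the CBC class is only verified constructively in that regime.
* Throughput engineering (GPU execution, process pools) is out of scope; the
  concurrency interface guarantees determinism, not speed-up.
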