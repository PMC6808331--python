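"""RAKI networks: geometry, forward/backward, Adam, training, inference."""

import numpy as np
import pytest
from _naive import naive_forward

from rakikit import (
    Adam,
    AdamConfig,
    NetworkWeights,
    RakiArchitecture,
    SamplingScheme,
    ScaleRecord,
    TrainingConfig,
    build_training_pairs,
    forward,
    ifft2c,
    nmse,
    raki_apply,
    raki_reconstruct,
    rss_combine,
    scale_to_training_range,
    to_real_field,
    train_cbc,
    train_lbl,
    train_network,
    undersample,
)
from rakikit.raki import should_stop, task_seed
from rakikit.simulate import make_dataset, make_linear_consistent_kspace


def _tiny_pairs(rng, kind="cbc", index=None, dtype=np.float64):
    """Smallest trainable problem: nc=1, R=2, narrow hidden layers."""
    arch = RakiArchitecture(kind, nc=1, R=2, n1=3, n2=2)
    s = SamplingScheme.centered(16, 2, 8)
    acs_real = rng.normal(size=(2, 12, 8)).astype(dtype)
    if index is None:
        index = 0 if kind == "cbc" else 1
    return build_training_pairs(acs_real, s, arch, index), arch


class TestArchitecture:
    def test_head_and_network_counts(self):
        cbc = RakiArchitecture("cbc", nc=32, R=5)
        lbl = RakiArchitecture("lbl", nc=32, R=5)
        assert cbc.head == 4 and cbc.n_networks == 64
        assert lbl.head == 64 and lbl.n_networks == 4
        assert cbc.n_networks // lbl.n_networks == 16

    def test_weight_shapes(self):
        a = RakiArchitecture("cbc", nc=8, R=4)
        assert a.weight_shapes() == [(5, 2, 16, 32), (1, 1, 32, 8), (3, 2, 8, 3)]

    def test_invalid(self):
        with pytest.raises(ValueError):
            RakiArchitecture("dense", nc=4, R=2)
        with pytest.raises(ValueError, match="interpolate"):
            RakiArchitecture("cbc", nc=4, R=1)


class TestTrainingPairs:
    def test_window_enumeration(self, rng):
        # acs_width=40, R=5, Nx=64: 25 windows, 58 valid kx positions
        arch = RakiArchitecture("cbc", nc=2, R=5)
        s = SamplingScheme.centered(128, 5, 40)
        acs_real = rng.normal(size=(4, 64, 40))
        pairs = build_training_pairs(acs_real, s, arch, 0)
        assert pairs.n_windows == 25
        assert pairs.n_kx_valid == 58
        # 1450 scalar samples per (offset, channel); CBC head = R-1 of them
        assert pairs.n_samples == 25 * 58 * 4

    def test_width_boundary(self, rng):
        arch = RakiArchitecture("cbc", nc=1, R=2)
        s = SamplingScheme.centered(16, 2, 6)
        with pytest.raises(ValueError, match="3R\\+1"):
            build_training_pairs(rng.normal(size=(2, 12, 6)), s, arch, 0)

    @pytest.mark.parametrize("kind,head", [("cbc", 2), ("lbl", 8)])
    def test_head_sizes(self, rng, kind, head):
        arch = RakiArchitecture(kind, nc=4, R=3)
        s = SamplingScheme.centered(32, 3, 12)
        pairs = build_training_pairs(rng.normal(size=(8, 16, 12)), s, arch, 1)
        assert all(t.shape[0] == head for t in pairs.targets)

    def test_targets_match_direct_indexing(self, rng):
        """Window/target geometry against a direct enumeration oracle."""
        R, nc, width, nx = 3, 2, 11, 12
        arch = RakiArchitecture("cbc", nc=nc, R=R)
        s = SamplingScheme.centered(32, R, width)
        acs = rng.normal(size=(2 * nc, nx, width))
        j = 2
        pairs = build_training_pairs(acs, s, arch, j)
        seen = 0
        for src, tgt in zip(pairs.sources, pairs.targets):
            # recover the residue class of this subgrid
            for r0 in range(R):
                if src.shape[2] == acs[:, :, r0::R].shape[2] and np.array_equal(
                    src, acs[:, :, r0::R]
                ):
                    r = r0
                    break
            for p in range(tgt.shape[2]):
                a = r + p * R
                for m in range(1, R):
                    np.testing.assert_array_equal(
                        tgt[m - 1, :, p], acs[j, 3 : nx - 3, a + R + m]
                    )
                    seen += 1
        assert seen == pairs.n_windows * (R - 1)

    def test_lbl_targets_all_channels(self, rng):
        R, nc = 2, 2
        arch = RakiArchitecture("lbl", nc=nc, R=R)
        s = SamplingScheme.centered(16, R, 8)
        acs = rng.normal(size=(2 * nc, 12, 8))
        pairs = build_training_pairs(acs, s, arch, 1)
        src, tgt = pairs.sources[0], pairs.targets[0]  # residue 0
        np.testing.assert_array_equal(tgt[:, :, 0], acs[:, 3:9, 0 + R + 1])


class TestForward:
    def test_zero_input_zero_output(self, rng):
        arch = RakiArchitecture("cbc", nc=2, R=2)
        ws = [rng.normal(size=s) for s in arch.weight_shapes()]
        net = NetworkWeights(*ws, arch=arch, index=0)
        out = forward(net, np.zeros((4, 16, 8)))
        assert np.all(out == 0)

    def test_output_shape(self, rng):
        arch = RakiArchitecture("cbc", nc=2, R=4)
        ws = [rng.normal(size=s) for s in arch.weight_shapes()]
        net = NetworkWeights(*ws, arch=arch, index=0)
        out = forward(net, rng.normal(size=(4, 64, 25)))
        assert out.shape == (3, 58, 22)

    def test_matches_naive_convolution(self, rng):
        arch = RakiArchitecture("lbl", nc=1, R=3, n1=4, n2=3)
        ws = [rng.normal(size=s) for s in arch.weight_shapes()]
        net = NetworkWeights(*ws, arch=arch, index=1)
        src = rng.normal(size=(2, 13, 9))
        assert np.max(np.abs(forward(net, src) - naive_forward(net, src))) < 1e-10


class TestAdam:
    def test_analytic_single_step(self):
        """L(w) = w^2 at w0 = 1: one update lands at 1 - a*2/(2 + eps)."""
        w = np.array([1.0])
        opt = Adam([w], AdamConfig())
        opt.step([np.array([2.0 * w[0]])])
        expect = 1.0 - 0.001 * 2.0 / (2.0 + 1e-8)
        assert abs(w[0] - expect) < 1e-12
        assert abs(w[0] - 0.999) < 1e-9

    def test_converges_on_quadratic(self):
        w = np.array([1.0])
        opt = Adam([w], AdamConfig())
        for _ in range(3000):
            opt.step([2.0 * w])
        assert abs(w[0]) < 1e-3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdamConfig(beta1=1.0)
        with pytest.raises(ValueError):
            AdamConfig(alpha=0.0)


class TestStoppingRule:
    def test_plateau_after_k(self):
        cfg = TrainingConfig()
        k = 37
        history = []
        for t in range(1, 2001):
            history.append(1.0 / t if t <= k else 1.0 / k)
            if should_stop(history, cfg):
                break
        assert k < len(history) <= k + 101

    def test_slowly_decaying_loss_hits_epoch_cap(self):
        cfg = TrainingConfig()
        history = []
        for t in range(1, 5000):
            history.append(0.999**t)  # 10% drop per 100 epochs: never plateaus
            if should_stop(history, cfg):
                break
        assert len(history) == cfg.max_epochs

    def test_zero_loss_counts_as_converged(self):
        cfg = TrainingConfig()
        assert should_stop([0.0] * 101, cfg)

    def test_constant_loss_training_run(self, rng):
        """Zero-init weights give a constant loss; training stops at 101 epochs."""
        pairs, _ = _tiny_pairs(rng)
        cfg = TrainingConfig(init_std=0.0)
        _, hist = train_network(pairs, cfg=cfg, seed=0)
        assert len(hist) == 101
        assert np.all(hist == hist[0])


class TestTrainNetwork:
    def test_first_loss_matches_forward(self, rng):
        """The batched trainer evaluates the same loss as the public forward()."""
        pairs, arch = _tiny_pairs(rng)
        cfg = TrainingConfig(max_epochs=2, plateau_window=2)
        net, hist = train_network(pairs, cfg=cfg, seed=3)
        init_rng = np.random.default_rng(np.random.SeedSequence(3))
        ws = [init_rng.normal(0.0, 0.1, s) for s in arch.weight_shapes()]
        net0 = NetworkWeights(*ws, arch=arch, index=pairs.index)
        tot = sum(
            float(np.sum((forward(net0, s) - t) ** 2))
            for s, t in zip(pairs.sources, pairs.targets)
        )
        assert hist[0] == pytest.approx(tot / pairs.n_samples, rel=1e-12)

    @pytest.mark.parametrize("kind", ["cbc", "lbl"])
    def test_one_step_matches_numerical_gradient(self, rng, kind):
        """Backprop check: one Adam step equals the update built from
        central-difference gradients of the forward-based loss."""
        pairs, arch = _tiny_pairs(rng, kind=kind)
        cfg = TrainingConfig(max_epochs=2, plateau_window=1, init_std=0.1)
        adam = AdamConfig()
        net, _ = train_network(pairs, adam, cfg, seed=11)

        init_rng = np.random.default_rng(np.random.SeedSequence(11))
        ws0 = [init_rng.normal(0.0, 0.1, s) for s in arch.weight_shapes()]

        def loss_of(ws):
            n = NetworkWeights(*ws, arch=arch, index=pairs.index)
            tot = sum(
                float(np.sum((forward(n, s) - t) ** 2))
                for s, t in zip(pairs.sources, pairs.targets)
            )
            return tot / pairs.n_samples

        h = 1e-5
        c = adam
        for li, (w0, w_trained) in enumerate(zip(ws0, (net.w1, net.w2, net.w3))):
            g = np.zeros_like(w0)
            for idx in np.ndindex(w0.shape):
                wp = [w.copy() for w in ws0]
                wp[li][idx] += h
                up = loss_of(wp)
                wp[li][idx] -= 2 * h
                dn = loss_of(wp)
                g[idx] = (up - dn) / (2 * h)
            expected = w0 - c.alpha * g / (np.abs(g) + c.eps)
            np.testing.assert_allclose(w_trained, expected, atol=1e-6)

    def test_deterministic(self, rng):
        pairs, _ = _tiny_pairs(rng)
        cfg = TrainingConfig(max_epochs=150)
        a, _ = train_network(pairs, cfg=cfg, seed=5)
        b, _ = train_network(pairs, cfg=cfg, seed=5)
        for wa, wb in zip((a.w1, a.w2, a.w3), (b.w1, b.w2, b.w3)):
            np.testing.assert_array_equal(wa, wb)

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_decreases(self, rng, seed):
        pairs, _ = _tiny_pairs(rng)
        _, hist = train_network(pairs, cfg=TrainingConfig(max_epochs=150), seed=seed)
        assert hist[-1] <= hist[0]

    def test_empty_pairs_rejected(self, rng):
        pairs, _ = _tiny_pairs(rng)
        pairs.sources, pairs.targets = [], []
        with pytest.raises(ValueError, match="empty"):
            train_network(pairs)


class TestTrainMany:
    def _setup(self, rng, ny=32, nc=2, R=2, acs=8):
        k = rng.normal(size=(nc, 32, ny)) + 1j * rng.normal(size=(nc, 32, ny))
        s = SamplingScheme.centered(ny, R, acs)
        return k[:, :, s.acs_start : s.acs_start + s.acs_width], s

    def test_cbc_network_count_and_heads(self, rng):
        acs, s = self._setup(rng)
        nets = train_cbc(acs, s, cfg=TrainingConfig(max_epochs=110))
        assert len(nets) == 4  # 2 nc
        assert all(n.w3.shape[-1] == s.R - 1 for n in nets)
        assert [n.index for n in nets] == list(range(4))

    def test_lbl_network_count_and_heads(self, rng):
        acs, s = self._setup(rng)
        nets = train_lbl(acs, s, cfg=TrainingConfig(max_epochs=110))
        assert len(nets) == 1  # R - 1
        assert nets[0].w3.shape[-1] == 4  # 2 nc
        assert nets[0].index == 1

    def test_concurrent_equals_sequential(self, rng):
        acs, s = self._setup(rng)
        cfg = TrainingConfig(max_epochs=120, master_seed=9)
        seq = train_cbc(acs, s, cfg=cfg, workers=1)
        par = train_cbc(acs, s, cfg=cfg, workers=4)
        for a, b in zip(seq, par):
            np.testing.assert_array_equal(a.w1, b.w1)
            np.testing.assert_array_equal(a.w2, b.w2)
            np.testing.assert_array_equal(a.w3, b.w3)

    def test_distinct_tasks_get_distinct_seeds(self):
        a = np.random.default_rng(task_seed(0, 0)).normal(size=4)
        b = np.random.default_rng(task_seed(0, 1)).normal(size=4)
        assert np.max(np.abs(a - b)) > 0


class TestApply:
    def test_zero_networks_fill_nothing(self, rng):
        nc, R = 2, 2
        arch = RakiArchitecture("cbc", nc=nc, R=R)
        nets = [
            NetworkWeights(*[np.zeros(s) for s in arch.weight_shapes()], arch=arch, index=j)
            for j in range(2 * nc)
        ]
        k = rng.normal(size=(nc, 32, 32)) + 1j * rng.normal(size=(nc, 32, 32))
        s = SamplingScheme.centered(32, R, 8)
        k_us = undersample(k, s)
        out = raki_apply(k_us, nets, arch, s, ScaleRecord(1.0))
        mask = s.acquired_mask(32)
        np.testing.assert_array_equal(out[:, :, mask], k_us[:, :, mask])
        assert np.all(out[:, :, ~mask] == 0)

    def test_architecture_mismatch_rejected(self, rng):
        arch = RakiArchitecture("cbc", nc=2, R=2)
        nets = [
            NetworkWeights(*[np.zeros(s) for s in arch.weight_shapes()], arch=arch, index=j)
            for j in range(4)
        ]
        k = np.zeros((2, 32, 32), dtype=complex)
        with pytest.raises(ValueError, match="match"):
            raki_apply(k, nets, arch, SamplingScheme.centered(32, 3, 10), ScaleRecord(1.0))
        with pytest.raises(ValueError, match="networks"):
            raki_apply(k, nets[:2], arch, SamplingScheme.centered(32, 2, 8), ScaleRecord(1.0))


def _linear_cbc_networks(kernel, nc, R):
    """Hand-set CBC networks that realize a complex 5x4 GRAPPA kernel.

    ReLUs are bypassed with the +/- decomposition x = ReLU(x) - ReLU(-x),
    so the composite is exactly the linear map (needs 4 (R-1) <= n2 hidden
    channels, i.e. R <= 3 with the standard 8-channel layer 2).
    """
    arch = RakiArchitecture("cbc", nc=nc, R=R)
    nets = []
    for j_real in range(2 * nc):
        w1, w2, w3 = (np.zeros(s) for s in arch.weight_shapes())
        coil, is_imag = divmod(j_real, 2)
        for m in range(1, R):
            h = m - 1
            b = 4 * h
            W = kernel.weights[coil, h]  # (nc, 5, 4) complex
            G = np.zeros((5, 4, 2 * nc))
            if not is_imag:
                G[:, :, 0::2] = W.real.transpose(1, 2, 0)
                G[:, :, 1::2] = -W.imag.transpose(1, 2, 0)
            else:
                G[:, :, 0::2] = W.imag.transpose(1, 2, 0)
                G[:, :, 1::2] = W.real.transpose(1, 2, 0)
            w1[:, :, :, b + 0] = G[:, 0:2, :]
            w1[:, :, :, b + 1] = -G[:, 0:2, :]
            w1[:, :, :, b + 2] = G[:, 2:4, :]
            w1[:, :, :, b + 3] = -G[:, 2:4, :]
            w2[0, 0, b + 0, b + 0] = 1.0
            w2[0, 0, b + 1, b + 0] = -1.0
            w2[0, 0, b + 0, b + 1] = -1.0
            w2[0, 0, b + 1, b + 1] = 1.0
            w2[0, 0, b + 2, b + 2] = 1.0
            w2[0, 0, b + 3, b + 2] = -1.0
            w2[0, 0, b + 2, b + 3] = -1.0
            w2[0, 0, b + 3, b + 3] = 1.0
            w3[1, 0, b + 0, h] = 1.0
            w3[1, 0, b + 1, h] = -1.0
            w3[1, 1, b + 2, h] = 1.0
            w3[1, 1, b + 3, h] = -1.0
        nets.append(NetworkWeights(w1, w2, w3, arch=arch, index=j_real))
    return nets, arch


class TestLinearEquivalence:
    def test_cbc_networks_realize_planted_kernel(self):
        """The CBC function class contains the GRAPPA linear map: networks
        hand-set from a planted kernel reproduce the missing lines."""
        nc, nx, ny, R = 4, 64, 60, 3
        s = SamplingScheme(R=R, acs_start=0, acs_width=0)
        k, kernel = make_linear_consistent_kspace(nc, nx, ny, s, seed=21)
        nets, arch = _linear_cbc_networks(kernel, nc, R)
        k_us = undersample(k, s)
        _, scale = scale_to_training_range(to_real_field(k_us))
        filled = raki_apply(k_us, nets, arch, s, scale)
        # interior comparison: the generator wraps at edges, inference zero-pads
        G = ny // R
        err = np.abs(filled - k)
        interior_ky = [
            q * R + m for q in range(1, G - 2) for m in range(1, R)
        ]
        assert np.max(err[:, 2 : nx - 2][:, :, interior_ky]) < 1e-8


class TestEndToEnd:
    def test_noiseless_cbc_small(self, small_dataset):
        """Noiseless smooth data, R=2: CBC image error below 5%."""
        ds = small_dataset
        res = raki_reconstruct(ds.undersampled(), ds.scheme, kind="cbc")
        ref = rss_combine(ifft2c(ds.kspace_full))
        assert nmse(res.image, ref) < 0.05
        # acquired lines bitwise preserved, scale recorded
        mask = ds.scheme.acquired_mask(64)
        np.testing.assert_array_equal(
            res.kspace[:, :, mask], ds.undersampled()[:, :, mask]
        )
        assert res.scale.factor > 0
        assert all(e <= 1000 for e in res.info["epochs"])
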