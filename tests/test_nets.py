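import numpy as np
import pytest

from octpre import losses, nets, nn
from octpre.nets import NetSpec, build_network, forward_probs, parameter_count, predict


class TestNetSpec:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            NetSpec(kernel=(4, 3))

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            NetSpec(arch="SegNet")

    def test_round_trip(self):
        spec = NetSpec(arch="LFUNet", kernel=(3, 9), init_features=8)
        assert NetSpec.from_dict(spec.to_dict()) == spec


class TestForwardContract:
    @pytest.mark.parametrize("arch", nets.ARCHS)
    def test_shapes_and_softmax(self, arch, rng):
        spec = NetSpec(arch=arch, init_features=4, in_channels=2, seed=1,
                       kernel=(7, 3) if arch == "ReLayNet" else (3, 3))
        model = build_network(spec)
        x = rng.normal(size=(2, 48, 48)).astype(np.float32)
        probs, mask = predict(model, x)
        assert probs.shape == (4, 48, 48)
        assert mask.shape == (48, 48)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_arbitrary_input_size_padded_and_cropped(self, rng):
        model = build_network(NetSpec(init_features=4, seed=0))
        x = rng.normal(size=(1, 76, 50)).astype(np.float32)  # not /16
        probs, mask = predict(model, x)
        assert probs.shape == (4, 76, 50) and mask.shape == (76, 50)

    def test_channel_mismatch_rejected(self, rng):
        model = build_network(NetSpec(in_channels=1, init_features=4))
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 32, 32)).astype(np.float32))

    def test_first_conv_channels_and_output_classes(self):
        model = build_network(NetSpec(in_channels=2, init_features=4))
        assert model.enc[0].c1.w.data.shape[1] == 2
        assert model.head.w.data.shape[0] == 4

    def test_relaynet_has_three_pooling_stages(self, rng):
        model = build_network(NetSpec(arch="ReLayNet", init_features=4,
                                      kernel=(7, 3)))
        assert len(model.enc) == 3
        # 640 rows pool down by 2^3 to a bottleneck height of 80
        assert 640 // 2 ** 3 == 80

    def test_parameter_count_increases_with_kernel_area(self):
        for arch in nets.ARCHS:
            counts = [parameter_count(build_network(
                NetSpec(arch=arch, init_features=4, kernel=k)))
                for k in ((3, 3), (5, 3), (3, 7), (5, 5), (7, 7))]
            areas = [9, 15, 21, 25, 49]
            assert all(c2 > c1 for a1, c1, a2, c2 in
                       zip(areas, counts, areas[1:], counts[1:]) if a2 > a1)

    def test_argmax_invariant_to_renormalization(self, rng):
        probs = rng.uniform(0.01, 1, (4, 6, 6))
        scale = rng.uniform(0.5, 2.0, (1, 6, 6))
        assert np.array_equal(probs.argmax(axis=0), (probs * scale).argmax(axis=0))

    def test_deterministic_init_given_seed(self):
        m1 = build_network(NetSpec(init_features=4, seed=9))
        m2 = build_network(NetSpec(init_features=4, seed=9))
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)


class TestBackprop:
    @pytest.mark.parametrize("arch", nets.ARCHS)
    def test_gradients_flow_to_all_parameters(self, arch, rng):
        spec = NetSpec(arch=arch, init_features=4, in_channels=1, seed=2,
                       kernel=(3, 3))
        model = build_network(spec)
        x = rng.normal(size=(1, 16, 16)).astype(np.float32)
        probs = forward_probs(model, x, training=True)
        probs.backward(rng.normal(size=probs.shape).astype(np.float32))
        grads = [p.grad for p in model.parameters()]
        assert all(g is not None for g in grads)
        assert any(np.abs(g).max() > 0 for g in grads)

    def test_single_training_step_reduces_loss(self, rng):
        model = build_network(NetSpec(init_features=4, seed=3))
        x = rng.normal(size=(1, 32, 32)).astype(np.float32)
        mask = np.zeros((32, 32), dtype=int)
        mask[8:12] = 1
        mask[12:24] = 2
        mask[24:] = 3
        gt = losses.one_hot(mask)
        cfg = losses.LossConfig()
        w = losses.pixel_weight_map(gt, cfg.q1, cfg.q2)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        vals = []
        for _ in range(25):
            pt = forward_probs(model, x, training=True)
            p = pt.data[0].astype(np.float64)
            vals.append(losses.total_loss(gt, p, cfg, w))
            grad = losses.total_loss_grad(gt, p, cfg, w)
            opt.zero_grad()
            pt.backward(grad[None].astype(np.float32))
            opt.step()
        assert vals[-1] < vals[0]


class TestEngine:
    def test_conv_matches_scipy_correlate(self, rng):
        from scipy import ndimage

        x = rng.normal(size=(1, 1, 12, 10)).astype(np.float32)
        w = nn.Parameter(rng.normal(size=(1, 1, 3, 5)).astype(np.float32))
        b = nn.Parameter(np.zeros(1))
        out = nn.conv2d(nn.Tensor(x), w, b).data[0, 0]
        ref = ndimage.correlate(x[0, 0].astype(np.float64),
                                w.data[0, 0].astype(np.float64),
                                mode="constant")
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_maxpool_unpool_round_trip(self, rng):
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        t = nn.Tensor(x)
        pooled, idx = nn.maxpool2x2(t)
        up = nn.maxunpool2x2(pooled, idx)
        # unpooled values sit exactly at the argmax positions
        restored = up.data[up.data != 0]
        assert np.isin(restored, pooled.data).all()

    def test_pad_reflect_backward_conserves_gradient_mass(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 1, 5, 5)).astype(np.float32))
        x.requires_grad = True
        y = nn.pad_reflect(x, (2, 2, 2, 2))
        g = np.ones_like(y.data)
        y.backward(g)
        assert x.grad.sum() == pytest.approx(g.sum())


class TestCapacity:
    @pytest.mark.parametrize("arch", nets.ARCHS)
    def test_overfits_single_noiseless_phantom(self, arch):
        from octpre import phantom, pipeline

        cfg = phantom.PhantomConfig.for_size(64, 64, seed=6, case_type="VMT",
                                             pcv_visibility=1.0,
                                             speckle_shape=None)
        img, mask, _ = phantom.generate_phantom(cfg)
        x = pipeline.normalize(img)[None].astype(np.float32)
        gt = losses.one_hot(mask)
        lcfg = losses.LossConfig(lambda_c=losses.class_weights(gt.sum(axis=(1, 2))))
        w = losses.pixel_weight_map(gt, lcfg.q1, lcfg.q2)
        spec = NetSpec(arch=arch, init_features=8, in_channels=1, seed=0,
                       kernel=(7, 3) if arch == "ReLayNet" else (3, 3))
        model = build_network(spec)
        # ReLayNet's batch norm tolerates (and needs) a larger step to fit
        # within the 200-step budget
        opt = nn.Adam(model.parameters(), lr=2e-3 if arch == "ReLayNet" else 1e-3)
        for _ in range(200):
            pt = forward_probs(model, x, training=True)
            grad = losses.total_loss_grad(gt, pt.data[0].astype(np.float64),
                                          lcfg, w)
            opt.zero_grad()
            pt.backward(grad[None].astype(np.float32))
            opt.step()
        _, pred = predict(model, x)
        assert (pred == mask).mean() > 0.99, arch
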