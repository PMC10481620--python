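import numpy as np
import pytest

from cysgan import objectives as obj
from cysgan.errors import TrainingError, UsageError
from cysgan.nn import Tensor
from cysgan.nn.core import mean_all


def t(arr, grad=False):
    return Tensor(np.asarray(arr, dtype=np.float64), requires_grad=grad)


class TestLSGAN:
    def test_generator_loss_identities(self, rng):
        assert float(obj.lsgan_g_loss(t(np.ones((2, 3)))).data) == 0.0
        assert float(obj.lsgan_g_loss(t(np.zeros((2, 3)))).data) == 1.0
        s = rng.normal(size=(4, 5))
        assert float(obj.lsgan_g_loss(t(s)).data) == pytest.approx(
            np.mean((s - 1.0) ** 2))

    def test_discriminator_loss_conventions(self):
        zeros = t(np.zeros((3, 3)))
        # printed equation form: fake target -1
        assert float(obj.lsgan_d_loss(zeros, zeros,
                                      fake_label=-1.0).data) == 2.0
        # reference-implementation form: fake target 0
        assert float(obj.lsgan_d_loss(zeros, zeros,
                                      fake_label=0.0).data) == 1.0
        # perfect discrimination
        assert float(obj.lsgan_d_loss(t(np.ones((2,))), t(-np.ones((2,))),
                                      fake_label=-1.0).data) == 0.0

    def test_discriminator_pools_fake_streams(self, rng):
        real = t(rng.normal(size=(8,)))
        f1, f2 = t(rng.normal(size=(8,))), t(rng.normal(size=(4,)))
        got = float(obj.lsgan_d_loss(real, [f1, f2]).data)
        pooled = np.concatenate([f1.data, f2.data])
        want = np.mean((real.data - 1) ** 2) + np.mean(pooled ** 2)
        assert got == pytest.approx(want)


class TestCycleLoss:
    def test_zero_at_perfect_reconstruction(self, rng):
        x = rng.normal(size=(1, 1, 4, 4, 4))
        y = rng.normal(size=(1, 1, 4, 4, 4))
        assert float(obj.cycle_loss(t(x), x, t(y), y).data) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=(1, 1, 4, 4, 4))
        y = rng.normal(size=(1, 1, 4, 4, 4))
        assert float(obj.cycle_loss(t(x + 0.5), x, t(y + 0.5), y).data) == \
            pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        rx, cx = rng.normal(size=(2, 8)), rng.normal(size=(2, 8))
        ry, cy = rng.normal(size=(2, 8)), rng.normal(size=(2, 8))
        want = np.abs(rx - cx).mean() + np.abs(ry - cy).mean()
        assert float(obj.cycle_loss(t(rx), cx, t(ry), cy).data) == \
            pytest.approx(want)


class TestSupervisedSegLoss:
    def make_target(self, rng, shape=(1, 3, 4, 4, 4)):
        tgt = np.zeros(shape)
        tgt[:, 0] = (rng.random(shape[2:]) > 0.5)
        tgt[:, 1] = (rng.random(shape[2:]) > 0.7)
        tgt[:, 2] = rng.uniform(-1, 1, shape[2:])
        return tgt

    def test_perfect_prediction_near_zero(self, rng):
        tgt = self.make_target(rng)
        loss = obj.seg_supervised_loss(t(tgt), tgt)
        assert float(loss.data) < 1e-5

    def test_uniform_half_b_gives_ln2(self, rng):
        tgt = self.make_target(rng)
        pred = tgt.copy()
        pred[:, 0] = 0.5
        loss = obj.seg_supervised_loss(t(pred), tgt)
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-6)

    def test_matches_bruteforce(self, rng):
        tgt = self.make_target(rng)
        pred = tgt.copy()
        pred[:, 0] = rng.uniform(0.01, 0.99, tgt.shape[2:])
        pred[:, 1] = rng.uniform(0.01, 0.99, tgt.shape[2:])
        pred[:, 2] = rng.uniform(-1, 1, tgt.shape[2:])
        want = 0.0
        for ch, kind in ((0, "bce"), (1, "bce"), (2, "mse")):
            p, g = pred[:, ch], tgt[:, ch]
            if kind == "bce":
                want += -np.mean(g * np.log(p) + (1 - g) * np.log(1 - p))
            else:
                want += np.mean((p - g) ** 2)
        assert float(obj.seg_supervised_loss(t(pred), tgt).data) == \
            pytest.approx(want, rel=1e-7)

    def test_non_binary_target_rejected(self, rng):
        tgt = self.make_target(rng)
        tgt[:, 0] = 0.3
        with pytest.raises(UsageError):
            obj.seg_supervised_loss(t(tgt), tgt)


class TestStructuralConsistency:
    def test_identical_stacks_zero(self, rng):
        s = rng.normal(size=(1, 3, 4, 4, 4))
        assert float(obj.structural_consistency_loss(t(s), t(s)).data) == 0.0

    def test_offset_on_single_channel(self, rng):
        a = rng.normal(size=(1, 3, 4, 4, 4))
        b = a.copy()
        b[:, 0] += 0.2
        got = float(obj.structural_consistency_loss(t(a), t(b)).data)
        assert got == pytest.approx(0.2 / 3)

    def test_matches_bruteforce(self, rng):
        a, b = rng.normal(size=(1, 3, 8)), rng.normal(size=(1, 3, 8))
        assert float(obj.structural_consistency_loss(t(a), t(b)).data) == \
            pytest.approx(np.abs(a - b).mean())


class TestTotalObjective:
    def ones_terms(self, names):
        return {n: t(1.0) for n in names}

    def test_all_zero(self):
        terms = {n: t(0.0) for n in obj.GENERATOR_TERMS}
        total, report = obj.total_objective(terms)
        assert float(total.data) == 0.0 and report.total == 0.0

    def test_uniform_weights_sum_to_eight(self):
        total, report = obj.total_objective(
            self.ones_terms(obj.GENERATOR_TERMS))
        assert float(total.data) == 8.0
        assert len(report.terms) == 8

    def test_semisup_ablation_sums_to_five(self):
        total, report = obj.total_objective(
            self.ones_terms(obj.GENERATOR_TERMS), no_semisup=True)
        assert float(total.data) == 5.0
        assert "sc" not in report and "segGAN_G" not in report

    def test_total_equals_sum_of_report(self, rng):
        terms = {n: t(float(rng.uniform(0, 2))) for n in obj.GENERATOR_TERMS}
        total, report = obj.total_objective(terms)
        assert float(total.data) == pytest.approx(
            sum(report.terms[n] for n in obj.GENERATOR_TERMS), abs=1e-6)

    def test_nan_term_raises_with_name(self):
        terms = self.ones_terms(obj.GENERATOR_TERMS)
        terms["cyc"] = t(np.nan)
        with pytest.raises(TrainingError, match="cyc"):
            obj.total_objective(terms)


class TestGradientIsolation:
    def test_seg_losses_do_not_touch_image_heads(self, rng):
        """Supervised segmentation gradients must not reach the translation
        heads of either generator when synthesized inputs are detached."""
        from cysgan.networks import GeneratorConfig, UNetGenerator
        f = UNetGenerator(GeneratorConfig(depth=1, width=4),
                          rng=np.random.default_rng(0))
        g = UNetGenerator(GeneratorConfig(depth=1, width=4),
                          rng=np.random.default_rng(1))
        x = Tensor(rng.uniform(-1, 1, (1, 1, 8, 8, 8)).astype(np.float32))
        tgt = np.zeros((1, 3, 8, 8, 8), dtype=np.float32)
        tgt[:, 0, 2:5] = 1

        out_f = f(x)
        seg_f_loss = obj.seg_supervised_loss(out_f.seg, tgt)
        out_g = g(out_f.image.detach())
        seg_g_loss = obj.seg_supervised_loss(out_g.seg, tgt)
        (seg_f_loss + seg_g_loss).backward()

        for gennet in (f, g):
            for p in gennet.head_image.parameters():
                assert p.grad is None or not p.grad.any()
        # sanity: the seg heads and trunks did receive gradient
        assert any(p.grad is not None and p.grad.any()
                   for p in f.head_seg.parameters())
        assert any(p.grad is not None and p.grad.any()
                   for p in f.stem.parameters())
        # and F's trunk got no gradient from G's supervised loss via the
        # detached synthesized image
        g_trunk_grads = [p.grad for p in g.stem.parameters()]
        assert any(gr is not None and gr.any() for gr in g_trunk_grads)
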