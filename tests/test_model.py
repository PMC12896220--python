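"""Network-level tests: the selective-scan recurrence against an unrolled
closed-form oracle, shape algebra of the U-shaped block chain, determinism,
stability, and a finite-difference check of the full backward pass."""

import numpy as np
import pytest

from glnet.model import (
    GLNetConfig,
    GLNetModel,
    glb_forward,
    glnet_forward,
    init_model,
    load_checkpoint,
    predict_proba,
    predict_proba_batched,
    save_checkpoint,
    softmax,
    ssm_scan,
)
from glnet.nn import SSMScan, softplus


def _ssm_ingredients(params: SSMScan, u: np.ndarray):
    """Discretized per-step quantities from the layer's parameters."""
    p = params.params
    A = -np.exp(p["A_log"])
    dt = softplus(p["w_dt"][0] * u + p["b_dt"][0])
    abar = np.exp(dt[:, None] * A)            # (L, N)
    B = u[:, None] * p["w_B"] + p["b_B"]
    C = u[:, None] * p["w_C"] + p["b_C"]
    bbar = dt[:, None] * B
    return A, abar, bbar, C, p["D_skip"][0]


def unrolled_ssm_oracle(params: SSMScan, u: np.ndarray) -> np.ndarray:
    """Brute-force y_t = sum_{k<=t} C_t (prod_{j=k+1..t} Abar_j) Bbar_k u_k
    + D u_t, computed directly from the closed-form sum."""
    _, abar, bbar, C, D = _ssm_ingredients(params, u)
    L = u.shape[0]
    y = np.empty(L)
    for t in range(L):
        total = np.zeros_like(bbar[0])
        for k in range(t + 1):
            prod = np.ones_like(bbar[0])
            for j in range(k + 1, t + 1):
                prod = prod * abar[j]
            total += prod * bbar[k] * u[k]
        y[t] = C[t] @ total + D * u[t]
    return y


class TestSSMScan:
    def test_zero_input_zero_skip_gives_zero_output(self):
        s = SSMScan(4, np.random.default_rng(0))
        s.params["D_skip"][0] = 0.0
        out = ssm_scan(np.zeros(10), s)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_step_closed_form(self):
        s = SSMScan(3, np.random.default_rng(1))
        u = np.array([0.7])
        _, abar, bbar, C, D = _ssm_ingredients(s, u)
        expected = C[0] @ (bbar[0] * u[0]) + D * u[0]
        assert ssm_scan(u, s)[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_recurrence_matches_unrolled_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = SSMScan(int(rng.integers(2, 8)), rng)
        u = rng.normal(size=int(rng.integers(2, 33)))
        np.testing.assert_allclose(ssm_scan(u, s), unrolled_ssm_oracle(s, u),
                                   atol=1e-5)

    def test_empty_sequence_rejected(self):
        s = SSMScan(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            ssm_scan(np.array([]), s)

    def test_states_bounded_over_long_sequences(self):
        s = SSMScan(8, np.random.default_rng(2))
        u = np.sin(np.arange(10_000) / 7.0) * 3.0
        y = ssm_scan(u, s)
        assert np.isfinite(y).all()
        assert np.abs(y).max() < 1e3


class TestGLBlock:
    def test_up_block_doubles_width(self, tiny_model):
        out = glb_forward(np.zeros(16), tiny_model.blocks[0])
        assert out.shape == (32,)

    def test_down_block_halves_width(self, tiny_model):
        out = glb_forward(np.zeros(64), tiny_model.blocks[2])
        assert out.shape == (32,)

    def test_width_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            glb_forward(np.zeros(17), tiny_model.blocks[0])

    def test_identity_configuration_reduces_to_leaky_relu(self):
        """With the state contribution silenced (C=0), unit skip, identity
        conv kernel, duplicate-identity fc and pristine batch norm, an
        up-block is exactly leaky-ReLU of its input, duplicated."""
        cfg = GLNetConfig(input_dim=8, embed_dim=8, ssm_state_dim=3, seed=0)
        m = init_model(cfg)
        blk = m.blocks[0]
        blk.ssm.params["w_C"][:] = 0.0
        blk.ssm.params["b_C"][:] = 0.0
        blk.ssm.params["D_skip"][0] = 1.0
        blk.conv.params["w"][:] = [0.0, 1.0, 0.0]
        blk.conv.params["b"][:] = 0.0
        blk.fc.params["W"][:] = np.vstack([np.eye(8), np.eye(8)])
        blk.fc.params["b"][:] = 0.0
        blk.bn.eps = 0.0  # pristine running moments (0, 1) act as identity
        x = np.random.default_rng(5).normal(size=(4, 8))
        out = glb_forward(x, blk)  # eval mode: running stats are (0, 1)
        lrelu = np.where(x > 0, x, 0.01 * x)
        np.testing.assert_allclose(out, np.hstack([lrelu, lrelu]), atol=1e-10)

    def test_inference_is_batch_size_invariant(self, tiny_model):
        rng = np.random.default_rng(8)
        batch = rng.normal(size=(6, 16))
        whole = tiny_model.blocks[0].forward(batch, train=False)
        alone = np.vstack([
            tiny_model.blocks[0].forward(batch[i:i + 1], train=False)
            for i in range(6)])
        np.testing.assert_allclose(whole, alone, atol=1e-12)


class TestGLNetModel:
    def test_same_seed_gives_identical_parameters(self):
        cfg = GLNetConfig(input_dim=20, embed_dim=16, ssm_state_dim=4, seed=12)
        a, b = init_model(cfg), init_model(cfg)
        for k, v in a.named_parameters().items():
            np.testing.assert_array_equal(v, b.named_parameters()[k])

    def test_embed_dim_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError):
            GLNetConfig(input_dim=10, embed_dim=126)

    def test_parameter_count_closed_form(self):
        d, N, k, classes, inp = 16, 4, 3, 2, 12
        cfg = GLNetConfig(input_dim=inp, embed_dim=d, ssm_state_dim=N,
                          conv_kernel=k, seed=0)
        m = init_model(cfg)
        ssm = N + 1 + 1 + N + N + N + N + 1      # A_log, w/b_dt, w/b_B, w/b_C, D
        conv = k + 1
        blocks = 0
        for din, dout in ((d, 2 * d), (2 * d, 4 * d), (4 * d, 2 * d), (2 * d, d)):
            blocks += ssm + conv + (din * dout + dout) + 2 * dout  # fc + bn
        expected = (inp * d + d) + blocks + (d * classes + classes)
        assert m.n_parameters() == expected

    def test_forward_shapes_through_u_structure(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(7, 12))
        assert tiny_model.forward(x).shape == (7, 2)

    @pytest.mark.parametrize("embed_dim", [8, 16, 32])
    def test_chain_returns_to_embed_dim_for_any_multiple_of_four(self, embed_dim):
        cfg = GLNetConfig(input_dim=5, embed_dim=embed_dim, ssm_state_dim=3, seed=0)
        m = init_model(cfg)
        z = m.embed.forward(np.zeros((1, 5)), False)
        z1 = m.blocks[0].forward(z, False)
        z2 = m.blocks[1].forward(z1, False)
        z3 = m.blocks[2].forward(z2, False)
        z4 = m.blocks[3].forward(z3 + z1, False)
        assert z4.shape[1] == embed_dim

    def test_eval_forward_is_deterministic(self, tiny_model):
        x = np.random.default_rng(1).normal(size=(3, 12))
        np.testing.assert_array_equal(tiny_model.forward(x), tiny_model.forward(x))

    def test_residual_skip_carries_gradient(self):
        """Finite-difference probe: perturbing the first up-block's output
        along the skip path changes the logits."""
        cfg = GLNetConfig(input_dim=6, embed_dim=8, ssm_state_dim=3, seed=4)
        m = init_model(cfg)
        x = np.random.default_rng(0).normal(size=(1, 6))
        z0 = m.embed.forward(x, False)
        z1 = m.blocks[0].forward(z0, False)

        def head_of(z1_val):
            z2 = m.blocks[1].forward(z1_val, False)
            z3 = m.blocks[2].forward(z2, False)
            return m.head.forward(m.blocks[3].forward(z3 + z1_val, False), False)

        base = head_of(z1)
        eps = 1e-5
        bumped = z1.copy()
        bumped[0, 3] += eps
        fd = (head_of(bumped) - base) / eps
        assert np.abs(fd).max() > 1e-4

    def test_column_permutation_changes_output(self, tiny_model):
        # the scan runs along the feature axis, so column order is meaningful
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 12))
        perm = rng.permutation(12)
        assert not np.allclose(tiny_model.forward(x),
                               tiny_model.forward(x[:, perm]))

    def test_unstandardized_dataset_warns(self, tiny_model):
        from glnet.encoding import EncodedDataset
        ds = EncodedDataset(np.zeros((2, 12)), [f"c{i}" for i in range(12)],
                            np.zeros(2, dtype=int))
        with pytest.warns(UserWarning, match="standardized"):
            glnet_forward(ds, tiny_model)

    def test_full_backward_matches_finite_differences(self):
        from glnet.train import ClassWeights, weighted_cross_entropy_with_grad

        cfg = GLNetConfig(input_dim=6, embed_dim=8, ssm_state_dim=3, seed=1)
        m = init_model(cfg)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 6))
        y = rng.integers(0, 2, 5)
        w = ClassWeights(1.2, 0.9)

        logits = m.forward(x, train=False)
        _, dlogits = weighted_cross_entropy_with_grad(logits, y, w)
        m.zero_grad()
        m.backward(dlogits)
        grads = m.named_grads()

        eps = 1e-6
        check_rng = np.random.default_rng(3)
        for name, p in m.named_parameters().items():
            flat = p.ravel()
            for i in check_rng.choice(flat.size, size=min(2, flat.size),
                                      replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = weighted_cross_entropy_with_grad(m.forward(x), y, w)[0]
                flat[i] = old - eps
                lm = weighted_cross_entropy_with_grad(m.forward(x), y, w)[0]
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = grads[name].ravel()[i]
                assert an == pytest.approx(fd, abs=5e-6), name


class TestPredictProba:
    def test_symmetric_logits_give_half(self):
        np.testing.assert_allclose(softmax(np.array([[0.0, 0.0]]))[:, 1], 0.5)

    def test_saturated_logits(self):
        assert softmax(np.array([[-10.0, 10.0]]))[0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_probabilities_valid_and_batched_path_agrees(self, tiny_model):
        x = np.random.default_rng(4).normal(size=(9, 12))
        p = predict_proba(x, tiny_model)
        assert ((p >= 0) & (p <= 1)).all()
        np.testing.assert_allclose(p, predict_proba_batched(x, tiny_model, chunk=4),
                                   atol=1e-12)


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tiny_model, tmp_path):
        p = tmp_path / "model.bin"
        save_checkpoint(tiny_model, p, extra={"note": "t"})
        loaded, extra = load_checkpoint(p)
        assert extra == {"note": "t"}
        for k, v in tiny_model.named_parameters().items():
            np.testing.assert_array_equal(v, loaded.named_parameters()[k])
        x = np.random.default_rng(0).normal(size=(4, 12))
        np.testing.assert_array_equal(tiny_model.forward(x), loaded.forward(x))

    def test_checkpoint_bytes_deterministic(self, tiny_model, tmp_path):
        a, b = tmp_path / "a.bin", tmp_path / "b.bin"
        save_checkpoint(tiny_model, a)
        save_checkpoint(tiny_model, b)
        assert a.read_bytes() == b.read_bytes()
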