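"""Attention-MIL model: forward pass, losses, pseudo-labels, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2mil.mil_model import (
    MILConfig,
    MILParams,
    forward,
    gated_attention,
    instance_targets,
    loss_and_grads,
    parameter_count_formula,
    smooth_svm_grad,
    smooth_svm_loss,
    softmax,
    total_loss,
)

SMALL = MILConfig(d_in=5, d_proj=6, d_attn=4, n_classes=3, k_sample=2)


@pytest.mark.parametrize(
    "dims",
    [(1024, 1024, 512, 3), (1024, 1024, 512, 2), (32, 64, 32, 2), (16, 8, 4, 3)],
)
def test_parameter_count_formula_matches_tensor_enumeration(dims):
    d_in, d_proj, d_attn, n_classes = dims
    params = MILParams.init(MILConfig(d_in=d_in, d_proj=d_proj, d_attn=d_attn,
                                      n_classes=n_classes), seed=0)
    # oracle: enumerate every trainable tensor and sum element counts
    enumerated = sum(v.size for v in params.tensors().values())
    assert parameter_count_formula(*dims) == enumerated == params.parameter_count()


def test_identical_tiles_get_uniform_attention(rng):
    h = rng.normal(size=4)
    H = np.tile(h, (5, 1))
    a = gated_attention(H, V=rng.normal(size=(3, 4)), b_v=np.zeros(3),
                        U=rng.normal(size=(3, 4)), b_u=np.zeros(3), w=rng.normal(size=3))
    assert np.allclose(a, 0.2)


def test_gated_attention_two_tile_hand_case():
    # h1=(1,0), h2=(0,1), V=I, U=0 (all gates 0.5), w=(1,0):
    # scores (0.5*tanh 1, 0) -> softmax = (0.5941, 0.4059)
    a = gated_attention(
        np.array([[1.0, 0.0], [0.0, 1.0]]), V=np.eye(2), b_v=np.zeros(2),
        U=np.zeros((2, 2)), b_u=np.zeros(2), w=np.array([1.0, 0.0])
    )
    assert np.allclose(a, [0.5941, 0.4059], atol=5e-5)


def test_attention_invariant_to_constant_score_shift(rng):
    H = rng.normal(size=(6, 4))
    V, U = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    w = rng.normal(size=3)
    a0 = gated_attention(H, V, np.zeros(3), U, np.zeros(3), w, b=0.0)
    a1 = gated_attention(H, V, np.zeros(3), U, np.zeros(3), w, b=7.3)
    assert np.allclose(a0, a1)


def test_forward_single_tile_slide_vector_is_the_tile(rng):
    params = MILParams.init(SMALL, seed=0)
    x = rng.normal(size=(1, 5))
    out = forward(x, params)
    h = np.maximum(x @ params.W_proj.T + params.b_proj, 0.0)
    assert np.allclose(out.slide_vectors, np.tile(h, (3, 1)))
    assert np.allclose(out.attention, 1.0)


def test_forward_is_permutation_invariant(rng):
    params = MILParams.init(SMALL, seed=1)
    X = rng.normal(size=(11, 5))
    perm = rng.permutation(11)
    a = forward(X, params)
    b = forward(X[perm], params)
    assert np.allclose(a.probs, b.probs, atol=1e-12)
    assert np.allclose(a.logits, b.logits, atol=1e-12)


def test_outputs_are_probability_vectors(rng):
    params = MILParams.init(SMALL, seed=2)
    out = forward(rng.normal(size=(9, 5)), params)
    assert np.allclose(out.attention.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(out.attention >= 0)
    assert np.allclose(out.probs.sum(), 1.0, atol=1e-6)
    assert np.all((out.instance_probs >= 0) & (out.instance_probs <= 1))


def test_forward_rejects_bad_bags(rng):
    params = MILParams.init(SMALL, seed=0)
    with pytest.raises(ValueError):
        forward(np.empty((0, 5)), params)
    with pytest.raises(ValueError):
        forward(rng.normal(size=(3, 7)), params)


def test_two_tile_two_class_toy_matches_independent_arithmetic():
    """Spreadsheet-style evaluation of the composed formulas with fixed weights."""
    cfg = MILConfig(d_in=2, d_proj=2, d_attn=2, n_classes=2)
    p = MILParams.init(cfg, seed=0)
    p.W_proj[:] = np.eye(2); p.b_proj[:] = 0
    p.V[:] = np.eye(2); p.b_v[:] = 0
    p.U[:] = 0; p.b_u[:] = 0          # gates all 0.5
    p.w_attn[:] = np.array([[1.0, 0.0], [0.0, 1.0]]); p.b_attn[:] = 0
    p.W_bag[:] = np.array([[1.0, 0.0], [0.0, 1.0]]); p.b_bag[:] = 0
    X = np.array([[1.0, 0.0], [0.0, 1.0]])
    out = forward(X, p)
    # by hand: H = X; class 0 scores = 0.5*(tanh h_k)[0] = (0.5*0.76159, 0)
    s = 0.5 * np.tanh(1.0)
    a0 = np.exp([s, 0.0]) / np.exp([s, 0.0]).sum()
    a1 = a0[::-1]  # symmetric for class 1
    np.testing.assert_allclose(out.attention[0], a0, atol=1e-12)
    np.testing.assert_allclose(out.attention[1], a1, atol=1e-12)
    logits = np.array([a0[0], a1[1]])  # M_c = a_c @ X, dotted with unit rows
    np.testing.assert_allclose(out.logits, logits, atol=1e-12)
    np.testing.assert_allclose(out.probs, softmax(logits), atol=1e-12)


def test_smooth_svm_known_values():
    assert smooth_svm_loss([0.0, 0.0], 0) == pytest.approx(np.log(1 + np.e), abs=1e-10)
    assert smooth_svm_loss([0.0, 0.0], 0) == pytest.approx(1.31326, abs=1e-5)
    # tau -> 0 recovers the hard hinge: s=(2,0), y=0, Delta=1 -> hinge 0
    assert smooth_svm_loss([2.0, 0.0], 0, delta=1.0, tau=0.01) < 1e-3


def test_smooth_svm_equals_cross_entropy_at_zero_margin(rng):
    for _ in range(20):
        s = rng.normal(size=4)
        y = int(rng.integers(4))
        ce = -np.log(softmax(s)[y])
        assert smooth_svm_loss(s, y, delta=0.0, tau=1.0) == pytest.approx(ce, abs=1e-10)


def test_smooth_svm_upper_bounds_hinge_and_converges_monotonically(rng):
    for _ in range(20):
        s = rng.normal(size=5)
        y = int(rng.integers(5))
        hinge = max(s[j] + (1.0 if j != y else 0.0) for j in range(5)) - s[y]
        prev = np.inf
        for tau in (2.0, 1.0, 0.5, 0.1, 0.01):
            l = smooth_svm_loss(s, y, delta=1.0, tau=tau)
            assert l >= hinge - 1e-12
            assert l <= prev + 1e-12
            prev = l
        # exact sandwich: hinge <= L_tau <= hinge + tau*log(K)
        assert prev <= hinge + 0.01 * np.log(5) + 1e-12


def test_smooth_svm_gradient_matches_finite_differences(rng):
    s = rng.normal(size=4)
    g = smooth_svm_grad(s, 1, delta=1.0, tau=0.7)
    eps = 1e-6
    for j in range(4):
        sp, sm = s.copy(), s.copy()
        sp[j] += eps; sm[j] -= eps
        num = (smooth_svm_loss(sp, 1, 1.0, 0.7) - smooth_svm_loss(sm, 1, 1.0, 0.7)) / (2 * eps)
        assert g[j] == pytest.approx(num, abs=1e-6)


def test_instance_targets_true_and_out_of_class_branches():
    idx, tgt = instance_targets([0.7, 0.2, 0.1], is_true_class=True, k_sample=1)
    assert dict(zip(idx.tolist(), tgt.tolist())) == {0: 1, 2: 0}
    idx, tgt = instance_targets([0.7, 0.2, 0.1], is_true_class=False, k_sample=1)
    assert dict(zip(idx.tolist(), tgt.tolist())) == {0: 0}


def test_instance_targets_k_clipped_to_half_bag():
    idx, tgt = instance_targets([0.5, 0.3, 0.2], is_true_class=True, k_sample=8)
    assert len(idx) == 2  # k shrinks to floor(3/2) = 1 -> top-1 + bottom-1
    idx, tgt = instance_targets([1.0], is_true_class=True, k_sample=8)
    assert len(idx) == 0


def test_total_loss_convex_combination():
    assert total_loss(1.0, [1.0]) == pytest.approx(1.0)
    assert total_loss(2.0, [0.0]) == pytest.approx(1.4)
    assert total_loss(2.0, []) == pytest.approx(1.4)  # no instance term


def test_admil_variant_has_no_instance_loss(rng):
    cfg = MILConfig(d_in=5, d_proj=6, d_attn=4, n_classes=2, use_instance_loss=False)
    parts, grads = loss_and_grads(rng.normal(size=(8, 5)), 0, MILParams.init(cfg, seed=0))
    assert parts.instance == 0.0
    assert parts.total == pytest.approx(cfg.bag_weight * parts.bag)
    assert np.all(grads["W_inst"] == 0)


@given(seed=st.integers(0, 10), y=st.integers(0, 2), n=st.integers(2, 12))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_analytic_gradients_match_finite_differences(seed, y, n):
    params = MILParams.init(SMALL, seed=seed)
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    _, grads = loss_and_grads(X, y, params)
    eps = 1e-6
    for name, arr in params.tensors().items():
        for _ in range(3):
            idx = tuple(int(rng.integers(s)) for s in arr.shape)
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = loss_and_grads(X, y, params)
            arr[idx] = old - eps
            lm, _ = loss_and_grads(X, y, params)
            arr[idx] = old
            num = (lp.total - lm.total) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, abs=2e-6, rel=1e-4)


def test_single_branch_variant_shares_attention(rng):
    cfg = MILConfig(d_in=5, d_proj=6, d_attn=4, n_classes=3, multi_branch=False)
    params = MILParams.init(cfg, seed=0)
    out = forward(rng.normal(size=(7, 5)), params)
    assert np.allclose(out.attention[0], out.attention[1])
    assert params.w_attn.shape[0] == 1


def test_checkpoint_round_trip(tmp_path, rng):
    params = MILParams.init(SMALL, seed=4)
    path = tmp_path / "ckpt.npz"
    params.save(path)
    back = MILParams.load(path)
    assert back.config == SMALL
    for k, v in params.tensors().items():
        assert np.array_equal(back.tensors()[k], v)
    X = rng.normal(size=(4, 5))
    assert np.allclose(forward(X, params).probs, forward(X, back).probs)
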