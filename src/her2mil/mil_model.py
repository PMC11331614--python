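"""Clustering-constrained attention MIL classifier for bags of tile embeddings.

Architecture (per bag X of n tile embeddings, d_in each):

* shared projection            h_k = relu(W1 x_k + b1), width d_proj
* per-class gated attention    a_{c,k} = softmax_k( w_c · (tanh(V h_k) ⊙ σ(U h_k)) + b_c )
* per-class slide vector       M_c = Σ_k a_{c,k} h_k
* per-class bag classifier     logit_c = w^bag_c · M_c, combined by a softmax
* per-class instance head      2-way linear classifier on h_k (tile in / out of class)

The tanh branch scores a tile while the sigmoid branch gates it, and the
softmax over tiles turns each class's scores into a distribution of
attention. The instance heads are trained on pseudo-labels derived from the
attention ranking (top-k attended tiles of the true class are positives,
bottom-k negatives; top-k tiles of other classes are negatives), which
regularizes the attention space and afterwards acts as a tile-level detector.

Training loss: 0.7 · bag cross-entropy + 0.3 · mean smooth-SVM instance loss.
The smooth (temperature-τ) multiclass SVM loss is
``L = τ·log Σ_j exp((s_j + Δ·1[j≠y] − s_y)/τ)``, which tends to the hard
margin hinge as τ → 0 and equals cross-entropy at Δ = 0, τ = 1.

Everything here is plain NumPy: forward, loss, and analytically derived
gradients (validated against finite differences in the test suite), so the
model trains on a CPU with no deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np


@dataclass(frozen=True)
class MILConfig:
    d_in: int = 1024
    d_proj: int = 1024
    d_attn: int = 512
    n_classes: int = 3
    multi_branch: bool = True  # one attention branch per class (vs a single shared one)
    use_instance_loss: bool = True  # False = plain attention-MIL (ADMIL-style) variant
    k_sample: int = 8
    bag_weight: float = 0.7
    svm_delta: float = 1.0
    svm_tau: float = 1.0

    @property
    def n_branches(self) -> int:
        return self.n_classes if self.multi_branch else 1


def parameter_count_formula(d_in: int, d_proj: int, d_attn: int, n_classes: int) -> int:
    """Closed-form trainable-parameter count of the default multi-branch model."""
    return (
        d_in * d_proj + d_proj
        + 2 * (d_proj * d_attn + d_attn)
        + n_classes * (d_attn + 1)
        + n_classes * (d_proj + 1)
        + n_classes * 2 * (d_proj + 1)
    )


PARAM_NAMES = (
    "W_proj", "b_proj", "V", "b_v", "U", "b_u",
    "w_attn", "b_attn", "W_bag", "b_bag", "W_inst", "b_inst",
)


@dataclass
class MILParams:
    """All trainable tensors plus the configuration that shaped them."""

    config: MILConfig
    W_proj: np.ndarray
    b_proj: np.ndarray
    V: np.ndarray
    b_v: np.ndarray
    U: np.ndarray
    b_u: np.ndarray
    w_attn: np.ndarray  # (n_branches, d_attn)
    b_attn: np.ndarray  # (n_branches,)
    W_bag: np.ndarray  # (n_classes, d_proj)
    b_bag: np.ndarray  # (n_classes,)
    W_inst: np.ndarray  # (n_classes, 2, d_proj)
    b_inst: np.ndarray  # (n_classes, 2)

    @classmethod
    def init(cls, config: MILConfig, seed: int = 0) -> "MILParams":
        rng = np.random.default_rng(seed)

        def glorot(*shape):
            fan = shape[-1] + (shape[-2] if len(shape) > 1 else 1)
            return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

        c = config
        return cls(
            config=c,
            W_proj=glorot(c.d_proj, c.d_in),
            b_proj=np.zeros(c.d_proj),
            V=glorot(c.d_attn, c.d_proj),
            b_v=np.zeros(c.d_attn),
            U=glorot(c.d_attn, c.d_proj),
            b_u=np.zeros(c.d_attn),
            w_attn=glorot(c.n_branches, c.d_attn),
            b_attn=np.zeros(c.n_branches),
            W_bag=glorot(c.n_classes, c.d_proj),
            b_bag=np.zeros(c.n_classes),
            W_inst=glorot(c.n_classes, 2, c.d_proj),
            b_inst=np.zeros((c.n_classes, 2)),
        )

    def tensors(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.tensors().values()))

    def copy(self) -> "MILParams":
        return MILParams(config=self.config, **{k: v.copy() for k, v in self.tensors().items()})

    def zeros_like(self) -> dict:
        return {k: np.zeros_like(v) for k, v in self.tensors().items()}

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.tensors())

    @classmethod
    def load(cls, path) -> "MILParams":
        with np.load(path, allow_pickle=False) as z:
            config = MILConfig(**json.loads(str(z["__config__"])))
            return cls(config=config, **{k: z[k] for k in PARAM_NAMES})


@dataclass
class MILOutput:
    attention: np.ndarray  # (n_classes, n_tiles), rows sum to 1
    slide_vectors: np.ndarray  # (n_classes, d_proj)
    logits: np.ndarray  # (n_classes,)
    probs: np.ndarray  # (n_classes,), sums to 1
    instance_logits: np.ndarray  # (n_classes, n_tiles, 2)
    instance_probs: np.ndarray  # (n_classes, n_tiles), P(tile in class)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def gated_attention(H: np.ndarray, V, b_v, U, b_u, w, b=0.0) -> np.ndarray:
    """Attention distribution over tiles for one branch.

    ``a_k = softmax_k( w · (tanh(V h_k + b_v) ⊙ σ(U h_k + b_u)) + b )``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if H.shape[0] == 0:
        raise ValueError("empty bag")
    gate = np.tanh(H @ np.asarray(V).T + b_v) * _sigmoid(H @ np.asarray(U).T + b_u)
    scores = gate @ np.asarray(w, dtype=np.float64) + b
    return softmax(scores, axis=0)


def _hidden(X, p: MILParams):
    Z1 = X @ p.W_proj.T + p.b_proj
    return Z1, np.maximum(Z1, 0.0)


def forward(X: np.ndarray, params: MILParams) -> MILOutput:
    """Run the full model on one bag; returns all per-class intermediates."""
    c = params.config
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("empty bag")
    if X.shape[1] != c.d_in:
        raise ValueError(f"bag dimension {X.shape[1]} != model d_in {c.d_in}")
    _, H = _hidden(X, params)
    Av = np.tanh(H @ params.V.T + params.b_v)
    Au = _sigmoid(H @ params.U.T + params.b_u)
    G = Av * Au
    scores = G @ params.w_attn.T + params.b_attn  # (n, n_branches)
    A_br = softmax(scores, axis=0)  # columns are distributions over tiles
    branch = np.arange(c.n_classes) if c.multi_branch else np.zeros(c.n_classes, dtype=int)
    attention = A_br[:, branch].T  # (n_classes, n)
    slide_vectors = attention @ H
    logits = np.einsum("cd,cd->c", params.W_bag, slide_vectors) + params.b_bag
    probs = softmax(logits)
    inst_logits = np.stack(
        [H @ params.W_inst[j].T + params.b_inst[j] for j in range(c.n_classes)]
    )  # (n_classes, n, 2)
    inst_probs = softmax(inst_logits, axis=-1)[:, :, 1]
    return MILOutput(
        attention=attention,
        slide_vectors=slide_vectors,
        logits=logits,
        probs=probs,
        instance_logits=inst_logits,
        instance_probs=inst_probs,
    )


def smooth_svm_loss(scores, y: int, delta: float = 1.0, tau: float = 1.0) -> float:
    """Temperature-smoothed multiclass margin loss (→ hinge as τ→0, CE at Δ=0, τ=1)."""
    s = np.asarray(scores, dtype=np.float64)
    z = (s + delta * (np.arange(s.size) != y) - s[y]) / tau
    m = z.max()
    return float(tau * (m + np.log(np.exp(z - m).sum())))


def smooth_svm_grad(scores, y: int, delta: float = 1.0, tau: float = 1.0) -> np.ndarray:
    s = np.asarray(scores, dtype=np.float64)
    p = softmax((s + delta * (np.arange(s.size) != y)) / tau)
    p[y] -= 1.0
    return p


def instance_targets(attention_row, is_true_class: bool, k_sample: int):
    """Pseudo-labels for the instance head from one attention ranking.

    True-class branch: top-k attended tiles → 1, bottom-k → 0.
    Other branches: top-k attended tiles → 0 (out-of-class suppression).
    k shrinks to ⌊n/2⌋ when the bag is small. Ties broken by tile index.
    """
    a = np.asarray(attention_row, dtype=np.float64)
    n = a.size
    k = min(int(k_sample), n // 2)
    if k == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    order = np.argsort(-a, kind="stable")
    top = order[:k]
    if is_true_class:
        bottom = order[-k:]
        return np.concatenate([top, bottom]), np.concatenate(
            [np.ones(k, dtype=int), np.zeros(k, dtype=int)]
        )
    return top, np.zeros(k, dtype=int)


def total_loss(bag_loss: float, instance_losses, bag_weight: float = 0.7) -> float:
    """Convex combination 0.7·bag CE + 0.3·mean instance loss."""
    inst = np.asarray(instance_losses, dtype=np.float64)
    inst_mean = float(inst.mean()) if inst.size else 0.0
    return bag_weight * float(bag_loss) + (1.0 - bag_weight) * inst_mean


@dataclass
class LossParts:
    total: float
    bag: float
    instance: float


def loss_and_grads(X: np.ndarray, y: int, params: MILParams):
    """Loss of one bag and analytic gradients for every trainable tensor.

    Instance pseudo-label selection is treated as non-differentiable (the
    attention ranking is a constant of the backward pass), matching how
    clustering-constrained MIL is trained in practice.
    """
    c = params.config
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty bag")
    if X.shape[1] != c.d_in:
        raise ValueError(f"bag dimension {X.shape[1]} != model d_in {c.d_in}")

    # ---- forward ----
    Z1, H = _hidden(X, params)
    Av = np.tanh(H @ params.V.T + params.b_v)
    Au = _sigmoid(H @ params.U.T + params.b_u)
    G = Av * Au
    scores = G @ params.w_attn.T + params.b_attn  # (n, n_branches)
    A_br = softmax(scores, axis=0)
    branch = np.arange(c.n_classes) if c.multi_branch else np.zeros(c.n_classes, dtype=int)
    attention = A_br[:, branch].T
    M = attention @ H  # (n_classes, d_proj)
    logits = np.einsum("cd,cd->c", params.W_bag, M) + params.b_bag
    zl = logits - logits.max()
    log_probs = zl - np.log(np.exp(zl).sum())
    probs = np.exp(log_probs)
    bag_loss = -float(log_probs[y])

    grads = params.zeros_like()
    dH = np.zeros_like(H)
    dS = np.zeros_like(scores)

    # ---- bag branch backward ----
    dlogits = c.bag_weight * (probs - np.eye(c.n_classes)[y])
    for j in range(c.n_classes):
        dM = dlogits[j] * params.W_bag[j]
        grads["W_bag"][j] = dlogits[j] * M[j]
        grads["b_bag"][j] = dlogits[j]
        a_j = attention[j]
        da = H @ dM
        dH += np.outer(a_j, dM)
        dS[:, branch[j]] += a_j * (da - a_j @ da)

    # ---- instance heads ----
    inst_losses = []
    if c.use_instance_loss:
        per_branch = []
        for j in range(c.n_classes):
            idx, tgt = instance_targets(attention[j], j == y, c.k_sample)
            if idx.size == 0:
                continue
            s_j = H[idx] @ params.W_inst[j].T + params.b_inst[j]  # (m, 2)
            losses = [smooth_svm_loss(s_j[i], tgt[i], c.svm_delta, c.svm_tau) for i in range(idx.size)]
            per_branch.append((j, idx, tgt, s_j, float(np.mean(losses))))
        if per_branch:
            nb = len(per_branch)
            w_inst = (1.0 - c.bag_weight) / nb
            for j, idx, tgt, s_j, mean_l in per_branch:
                inst_losses.append(mean_l)
                gsl = np.stack(
                    [smooth_svm_grad(s_j[i], tgt[i], c.svm_delta, c.svm_tau) for i in range(idx.size)]
                ) * (w_inst / idx.size)  # (m, 2)
                grads["W_inst"][j] += gsl.T @ H[idx]
                grads["b_inst"][j] += gsl.sum(axis=0)
                dH[idx] += gsl @ params.W_inst[j]
    inst_mean = float(np.mean(inst_losses)) if inst_losses else 0.0

    # ---- attention backward ----
    dG = dS @ params.w_attn
    grads["w_attn"] = dS.T @ G
    grads["b_attn"] = dS.sum(axis=0)
    dZv = dG * Au * (1.0 - Av**2)
    dZu = dG * Av * Au * (1.0 - Au)
    grads["V"] = dZv.T @ H
    grads["b_v"] = dZv.sum(axis=0)
    grads["U"] = dZu.T @ H
    grads["b_u"] = dZu.sum(axis=0)
    dH += dZv @ params.V + dZu @ params.U

    # ---- shared projection backward ----
    dZ1 = dH * (Z1 > 0)
    grads["W_proj"] = dZ1.T @ X
    grads["b_proj"] = dZ1.sum(axis=0)

    total = c.bag_weight * bag_loss + (1.0 - c.bag_weight) * inst_mean
    return LossParts(total=total, bag=bag_loss, instance=inst_mean), grads
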