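"""Dual graph-autoencoder Markov network trained by variational EM.

Two networks operate in each entity space (circRNA side, disease side):

* **GNNq** — a variational graph encoder/decoder for feature inference.  Two
  graph-convolution layers map per-node features (association profile
  concatenated with convolutional MF features) to a latent Gaussian
  (mu, sigma); a reparameterised sample z is decoded back to the features and
  a sigmoid head emits a candidate score matrix.  Its loss is reconstruction
  plus KL to the standard normal, and a co-training term couples the two
  spaces' score matrices.
* **GNNp** — a two-layer graph-convolutional label propagator.  It consumes
  soft pseudo-labels (elementwise max of GNNq's scores and the observed
  positives) and outputs propagated label matrices F_c (m x n) and F_d
  (n x m).  Its loss is a positive-cell cross-entropy plus a Laplacian
  smoothness (manifold) penalty over the similarity graph.

Each epoch runs one E-step (Adam step on the GNNq loss
L_q = alpha*L_qc + (1-alpha)*L_qd + beta*L_c, with beta ramped linearly from
1/epochs to 1) and one M-step (Adam step on
L_p = alpha*L_pc + (1-alpha)*L_pd).  The final prediction fuses the two
propagated matrices: F = alpha*F_c + (1-alpha)*F_d^T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .embedding import DeepFeatures
from .io import AssociationMatrix
from .similarity import SimilarityGraph

logger = logging.getLogger("circlink")

_F_FLOOR = 1e-12
_GRAD_CLIP = 5.0


# ---------------------------------------------------------------------------
# Loss terms.  Each works on plain numpy arrays (returning a float) and on
# autodiff Tensors (returning a Tensor), so the training path and the test
# oracles share one definition.
# ---------------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _as_value(x) -> np.ndarray:
    return x.value if _is_tensor(x) else np.asarray(x, dtype=float)


def _scalar(x):
    return x if _is_tensor(x) else float(x)


def loss_reconstruction(x, x_prime):
    """Squared Frobenius reconstruction error, 1/2 * ||x - x'||_F^2."""
    if _as_value(x).shape != _as_value(x_prime).shape:
        raise ValueError("loss_reconstruction: shape mismatch")
    diff = x - x_prime if _is_tensor(x) or _is_tensor(x_prime) else np.asarray(x, float) - np.asarray(x_prime, float)
    if _is_tensor(diff):
        return _scalar(0.5 * diff.square().sum())
    return 0.5 * float((diff**2).sum())


def loss_kl(mu, sigma):
    """KL divergence of elementwise N(mu, sigma^2) from N(0, 1).

    -sum_ij 1/2 (1 + 2 log sigma_ij - mu_ij^2 - sigma_ij^2); zero exactly at
    the standard normal (mu = 0, sigma = 1) and non-negative everywhere else.
    """
    if np.any(_as_value(sigma) <= 0):
        raise ValueError("loss_kl: sigma must be positive")
    if _is_tensor(mu) or _is_tensor(sigma):
        mu = mu if _is_tensor(mu) else Tensor(mu)
        sigma = sigma if _is_tensor(sigma) else Tensor(sigma)
        inner = 1.0 + 2.0 * sigma.log() - mu.square() - sigma.square()
        return _scalar(-0.5 * inner.sum())
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    return float(-0.5 * (1.0 + 2.0 * np.log(sigma) - mu**2 - sigma**2).sum())


def loss_label(Y, F):
    """Positive-cell cross entropy -sum_ij Y_ij log F_ij.

    Y may be binary observed labels or soft pseudo-labels in [0, 1]; only
    cells with Y > 0 contribute.  F values at or below the 1e-12 floor are
    clamped (with a warning) rather than producing -inf.
    """
    Yv, Fv = _as_value(Y), _as_value(F)
    if Yv.shape != Fv.shape:
        raise ValueError("loss_label: shape mismatch")
    if np.any((Fv <= _F_FLOOR) & (Yv > 0)):
        logger.warning("loss_label: clamping near-zero predictions at positive cells")
    if _is_tensor(Y) or _is_tensor(F):
        F = F if _is_tensor(F) else Tensor(F)
        Y = Y if _is_tensor(Y) else Tensor(Y)
        return _scalar(-(Y * F.clip_min(_F_FLOOR).log()).sum())
    return float(-(Yv * np.log(np.clip(Fv, _F_FLOOR, None))).sum())


def loss_manifold(F, graph: SimilarityGraph):
    """Laplacian smoothness tr(F^T L F) / #edges over the similarity graph.

    Zero when all connected rows of F are equal; the per-edge normalisation
    keeps the penalty comparable across graph densities.
    """
    Fv = _as_value(F)
    L = graph.laplacian()
    if Fv.shape[0] != L.shape[0]:
        raise ValueError("loss_manifold: F rows must match graph nodes")
    n_edges = max(graph.n_edges(), 1)
    if _is_tensor(F):
        return _scalar((F * (Tensor(L) @ F)).sum() * (1.0 / n_edges))
    return float(np.einsum("ij,ij->", Fv, L @ Fv)) / n_edges


def loss_cotrain(Sc, Sd):
    """Cross-space consistency: mean squared difference ||Sc - Sd^T||^2 / (m n)."""
    Sc_v, Sd_v = _as_value(Sc), _as_value(Sd)
    if Sc_v.shape != Sd_v.shape[::-1]:
        raise ValueError("loss_cotrain: Sd must be the transpose shape of Sc")
    m, n = Sc_v.shape
    if _is_tensor(Sc) or _is_tensor(Sd):
        Sc = Sc if _is_tensor(Sc) else Tensor(Sc)
        Sd = Sd if _is_tensor(Sd) else Tensor(Sd)
        return _scalar((Sc - Sd.T).square().sum() * (1.0 / (m * n)))
    return float(((Sc_v - Sd_v.T) ** 2).sum()) / (m * n)


def total_loss_q(Lqc, Lqd, Lc, alpha: float, beta: float):
    """Combined inference-network loss alpha*Lqc + (1-alpha)*Lqd + beta*Lc."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return alpha * Lqc + (1.0 - alpha) * Lqd + beta * Lc


def total_loss_p(Lpc, Lpd, alpha: float):
    """Combined propagation-network loss alpha*Lpc + (1-alpha)*Lpd."""
    alpha = min(max(alpha, 1e-9), 1.0 - 1e-9)
    return alpha * Lpc + (1.0 - alpha) * Lpd


def predict_scores(Fc: np.ndarray, Fd: np.ndarray, alpha: float) -> np.ndarray:
    """Fuse the two propagated label matrices: F = alpha*Fc + (1-alpha)*Fd^T."""
    Fc = np.asarray(Fc, float)
    Fd = np.asarray(Fd, float)
    if Fc.shape != Fd.shape[::-1]:
        raise ValueError("predict_scores: Fd must have the transposed shape of Fc")
    return alpha * Fc + (1.0 - alpha) * Fd.T


# ---------------------------------------------------------------------------
# Network building blocks
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of the variational-EM trainer.

    alpha balances the circRNA and disease spaces in every combined loss and
    in the final fusion (0.8 by default); lr is the Adam learning rate
    (0.001); the co-training weight beta is scheduled internally as
    epoch/epochs and is not a free parameter.
    """

    alpha: float = 0.8
    epochs: int = 500
    lr: float = 0.001
    hidden_dim: int = 64
    latent_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)


class _GraphConv:
    """One graph-convolution layer: act(adj @ X @ W + b)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, act: str):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)
        self.act = act

    def __call__(self, adj: Tensor, X: Tensor) -> Tensor:
        h = adj @ (X @ self.W) + self.b
        if self.act == "relu":
            return h.relu()
        if self.act == "sigmoid":
            return h.sigmoid()
        return h

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class _GnnqSpace:
    """Variational encoder/decoder plus score head for one entity space."""

    def __init__(self, rng, n_features: int, n_targets: int, hidden: int, latent: int):
        self.enc = _GraphConv(rng, n_features, hidden, "relu")
        self.mu_layer = _GraphConv(rng, hidden, latent, "linear")
        self.logsig_layer = _GraphConv(rng, hidden, latent, "linear")
        self.W_dec = _glorot(rng, latent, n_features)
        self.b_dec = Tensor(np.zeros((1, n_features)), requires_grad=True)
        self.n_targets = n_targets

    @property
    def params(self) -> list[Tensor]:
        return (
            self.enc.params + self.mu_layer.params + self.logsig_layer.params
            + [self.W_dec, self.b_dec]
        )

    def forward(self, adj: Tensor, x: Tensor, eps: np.ndarray | None):
        """Returns (mu, sigma, z, x_reconstructed, scores).

        eps=None uses the posterior mean z = mu (deterministic pass for
        pseudo-labels and prediction); otherwise z = mu + sigma * eps.  The
        score head is the decoder's association-profile block: the input
        features start with the node's row of A, so the first ``n_targets``
        columns of the reconstruction are the candidate scores, anchored to
        the observed labels through the reconstruction loss.
        """
        h = self.enc(adj, x)
        mu = self.mu_layer(adj, h)
        logsig = self.logsig_layer(adj, h)
        sigma = logsig.exp()
        z = mu if eps is None else mu + sigma * Tensor(eps)
        x_prime = z @ self.W_dec + self.b_dec
        scores = x_prime.cols(0, self.n_targets)
        return mu, sigma, z, x_prime, scores


class _GnnpSpace:
    """Two-layer graph-convolutional label propagator for one entity space."""

    def __init__(self, rng, n_targets: int, hidden: int):
        self.gc1 = _GraphConv(rng, n_targets, hidden, "relu")
        self.gc2 = _GraphConv(rng, hidden, n_targets, "sigmoid")

    @property
    def params(self) -> list[Tensor]:
        return self.gc1.params + self.gc2.params

    def forward(self, adj: Tensor, Y: Tensor) -> Tensor:
        return self.gc2(adj, self.gc1(adj, Y))


@dataclass
class GnnqState:
    """Trained inference networks and their last deterministic pass."""

    circ: _GnnqSpace
    disease: _GnnqSpace
    mu: dict[str, np.ndarray] = field(default_factory=dict)
    sigma: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class GnnpState:
    """Trained propagation networks and the final propagated label matrices."""

    circ: _GnnpSpace
    disease: _GnnpSpace
    Fc: np.ndarray | None = None  # m x n
    Fd: np.ndarray | None = None  # n x m


@dataclass
class TrainResult:
    qstate: GnnqState
    pstate: GnnpState
    scores: np.ndarray  # fused m x n prediction matrix
    loss_trace_q: np.ndarray
    loss_trace_p: np.ndarray


# ---------------------------------------------------------------------------
# Variational EM
# ---------------------------------------------------------------------------

def train_em(
    A_train: AssociationMatrix,
    graphs: tuple[SimilarityGraph, SimilarityGraph],
    feats: DeepFeatures,
    cfg: TrainConfig,
) -> TrainResult:
    """Alternately train GNNq (E-step) and GNNp (M-step) and fuse the scores.

    The similarity graphs must be built from *A_train* only (no held-out
    positives), otherwise evaluation leaks labels.  Raises RuntimeError if
    either loss becomes non-finite.
    """
    g_circ, g_dis = graphs
    A = np.asarray(A_train.values, dtype=float)
    m, n = A.shape
    if g_circ.n_nodes != m or g_dis.n_nodes != n:
        raise ValueError("graph sizes do not match the association matrix")
    rng = np.random.default_rng(cfg.seed)

    x_c = np.concatenate([A, feats.Hc], axis=1)
    x_d = np.concatenate([A.T, feats.Hd], axis=1)
    adj_c = Tensor(g_circ.norm_adj)
    adj_d = Tensor(g_dis.norm_adj)
    xt_c, xt_d = Tensor(x_c), Tensor(x_d)

    q_c = _GnnqSpace(rng, x_c.shape[1], n, cfg.hidden_dim, cfg.latent_dim)
    q_d = _GnnqSpace(rng, x_d.shape[1], m, cfg.hidden_dim, cfg.latent_dim)
    p_c = _GnnpSpace(rng, n, cfg.hidden_dim)
    p_d = _GnnpSpace(rng, m, cfg.hidden_dim)

    opt_q = Adam(q_c.params + q_d.params, lr=cfg.lr)
    opt_p = Adam(p_c.params + p_d.params, lr=cfg.lr)

    trace_q: list[float] = []
    trace_p: list[float] = []
    Yc_np = A
    Yd_np = A.T

    for epoch in range(1, cfg.epochs + 1):
        beta = epoch / cfg.epochs

        # E-step: variational inference networks
        opt_q.zero_grad()
        eps_c = rng.standard_normal((m, cfg.latent_dim))
        eps_d = rng.standard_normal((n, cfg.latent_dim))
        mu_c, sig_c, _, xp_c, sc_c = q_c.forward(adj_c, xt_c, eps_c)
        mu_d, sig_d, _, xp_d, sc_d = q_d.forward(adj_d, xt_d, eps_d)
        Lqc = loss_reconstruction(xt_c, xp_c) + loss_kl(mu_c, sig_c)
        Lqd = loss_reconstruction(xt_d, xp_d) + loss_kl(mu_d, sig_d)
        Lc = loss_cotrain(sc_c, sc_d)
        Lq = total_loss_q(Lqc, Lqd, Lc, cfg.alpha, beta)
        if not np.isfinite(Lq.value):
            raise RuntimeError(
                f"GNNq loss diverged at epoch {epoch}: Lqc={Lqc.value}, "
                f"Lqd={Lqd.value}, Lc={Lc.value}"
            )
        Lq.backward()
        opt_q.clip_grad_norm(_GRAD_CLIP)
        opt_q.step()
        trace_q.append(float(Lq.value))

        # Pseudo-labels: deterministic (mean-latent) GNNq scores, never below
        # the observed positives
        _, _, _, _, sc_c_det = q_c.forward(adj_c, xt_c, None)
        _, _, _, _, sc_d_det = q_d.forward(adj_d, xt_d, None)
        Yc_np = np.maximum(np.clip(sc_c_det.value, 0.0, 1.0), A)
        Yd_np = np.maximum(np.clip(sc_d_det.value, 0.0, 1.0), A.T)

        # M-step: label propagation networks
        opt_p.zero_grad()
        Fc = p_c.forward(adj_c, Tensor(Yc_np))
        Fd = p_d.forward(adj_d, Tensor(Yd_np))
        Lpc = loss_label(Tensor(Yc_np), Fc) + loss_manifold(Fc, g_circ)
        Lpd = loss_label(Tensor(Yd_np), Fd) + loss_manifold(Fd, g_dis)
        Lp = total_loss_p(Lpc, Lpd, cfg.alpha)
        if not np.isfinite(Lp.value):
            raise RuntimeError(
                f"GNNp loss diverged at epoch {epoch}: Lpc={Lpc.value}, Lpd={Lpd.value}"
            )
        Lp.backward()
        opt_p.clip_grad_norm(_GRAD_CLIP)
        opt_p.step()
        trace_p.append(float(Lp.value))

    # Final deterministic pass and fusion
    mu_c, sig_c, _, _, sc_c_det = q_c.forward(adj_c, xt_c, None)
    mu_d, sig_d, _, _, sc_d_det = q_d.forward(adj_d, xt_d, None)
    Fc = p_c.forward(adj_c, Tensor(np.maximum(np.clip(sc_c_det.value, 0.0, 1.0), A))).value
    Fd = p_d.forward(adj_d, Tensor(np.maximum(np.clip(sc_d_det.value, 0.0, 1.0), A.T))).value
    fused = predict_scores(Fc, Fd, cfg.alpha)

    qstate = GnnqState(
        circ=q_c,
        disease=q_d,
        mu={"c": mu_c.value, "d": mu_d.value},
        sigma={"c": sig_c.value, "d": sig_d.value},
        scores={"c": sc_c_det.value, "d": sc_d_det.value},
    )
    pstate = GnnpState(circ=p_c, disease=p_d, Fc=Fc, Fd=Fd)
    return TrainResult(
        qstate=qstate,
        pstate=pstate,
        scores=fused,
        loss_trace_q=np.array(trace_q),
        loss_trace_p=np.array(trace_p),
    )
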