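"""Regularised matrix-factorisation embeddings and the convolutional combiner.

The association matrix A (m x n) is approximated as A ~ C D^T with latent
factor matrices C (m x k) and D (n x k), minimising

    1/2 ||A - C D^T||_F^2 + reg (||C||_F^2 + ||D||_F^2)

by alternating closed-form ridge updates.  A fixed, seeded one-layer 1-D
convolution then maps each entity's latent vector into several feature
channels; those feature maps are the per-entity input features of the
variational encoder downstream (which is where they are refined by training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix


@dataclass(frozen=True)
class EmbeddingPair:
    """Latent factors of the association matrix plus the optimisation trace."""

    C: np.ndarray  # m x k circRNA factors
    D: np.ndarray  # n x k disease factors
    k: int
    reg: float
    objective_trace: np.ndarray  # objective value after each alternating sweep


@dataclass(frozen=True)
class ConvSpec:
    """One-layer 1-D convolution: width, channels, activation, padding."""

    channels: int = 8
    width: int = 3
    activation: str = "relu"  # "relu" | "identity"
    padding: str = "same"  # "same" | "valid"


@dataclass(frozen=True)
class DeepFeatures:
    """Convolutional feature maps of the two embedding matrices."""

    Hc: np.ndarray  # m x k'
    Hd: np.ndarray  # n x k'
    kernel_spec: ConvSpec
    seed: int


def _objective(A: np.ndarray, C: np.ndarray, D: np.ndarray, reg: float) -> float:
    resid = A - C @ D.T
    return 0.5 * float((resid**2).sum()) + reg * (
        float((C**2).sum()) + float((D**2).sum())
    )


def matrix_factorize(
    A: AssociationMatrix | np.ndarray,
    k: int,
    reg: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
) -> EmbeddingPair:
    """Alternating-ridge factorisation of a binary association matrix.

    Each half-step solves its ridge subproblem exactly:

        C <- A D (D^T D + 2 reg I)^-1,    D <- A^T C (C^T C + 2 reg I)^-1

    so the joint objective is non-increasing across sweeps.  Iteration stops
    when the relative objective change drops below *tol* or after *max_iter*
    sweeps.  Initialisation is uniform(0, 1/sqrt(k)) from the given seed.
    """
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("matrix_factorize expects a binary matrix")
    Af = np.asarray(values, dtype=float)
    m, n = Af.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"latent dimension k={k} outside [1, {min(m, n)}]")
    if reg <= 0:
        raise ValueError("regularisation weight must be positive")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(k)
    C = rng.uniform(0.0, scale, size=(m, k))
    D = rng.uniform(0.0, scale, size=(n, k))
    eye2r = 2.0 * reg * np.eye(k)
    trace = [_objective(Af, C, D, reg)]
    for _ in range(max_iter):
        C = np.linalg.solve((D.T @ D + eye2r).T, (Af @ D).T).T
        D = np.linalg.solve((C.T @ C + eye2r).T, (Af.T @ C).T).T
        obj = _objective(Af, C, D, reg)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            break
    return EmbeddingPair(C=C, D=D, k=k, reg=reg, objective_trace=np.array(trace))


def _conv1d_rows(X: np.ndarray, kernels: np.ndarray, bias: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Convolve each row of X with each kernel; returns (rows, channels * out_len)."""
    n_rows, k = X.shape
    n_ch, width = kernels.shape
    if spec.padding == "same":
        left = (width - 1) // 2
        right = width - 1 - left
        Xp = np.pad(X, ((0, 0), (left, right)))
        out_len = k
    else:  # valid
        Xp = X
        out_len = k - width + 1
    # im2col along the latent axis
    cols = np.lib.stride_tricks.sliding_window_view(Xp, width, axis=1)  # rows x out_len x width
    out = np.einsum("row,cw->rco", cols, kernels, optimize=True)
    out = out + bias[None, :, None]
    if spec.activation == "relu":
        out = np.maximum(out, 0.0)
    elif spec.activation != "identity":
        raise ValueError(f"unknown activation {spec.activation!r}")
    return out.reshape(n_rows, n_ch * out_len)


def conv_feature_map(
    emb: EmbeddingPair, kernel_spec: ConvSpec | None = None, seed: int = 0
) -> DeepFeatures:
    """Map MF embeddings through a fixed seeded one-layer 1-D convolution.

    Kernels are drawn once from N(0, 1/width) at the given seed and never
    trained here; determinism is part of the contract (same embedding, spec
    and seed give bit-identical features).
    """
    spec = kernel_spec or ConvSpec()
    if spec.width > emb.k:
        raise ValueError(f"kernel width {spec.width} exceeds latent dimension {emb.k}")
    if spec.channels < 1 or spec.width < 1:
        raise ValueError("channels and width must be positive")
    rng = np.random.default_rng(seed)
    kernels = rng.normal(0.0, 1.0 / np.sqrt(spec.width), size=(spec.channels, spec.width))
    bias = np.zeros(spec.channels)
    Hc = _conv1d_rows(emb.C, kernels, bias, spec)
    Hd = _conv1d_rows(emb.D, kernels, bias, spec)
    return DeepFeatures(Hc=Hc, Hd=Hd, kernel_spec=spec, seed=seed)
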