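"""Cross-validation over known positive cells and threshold-free ranking metrics.

Folds partition the positive cells of the association matrix; in each round
the test positives are zeroed out of the training matrix, every upstream
stage (similarity graphs, MF, training) is rebuilt from that training matrix,
and the model ranks the candidate set = test positives plus all unobserved
cells.  AUROC and AUPR are delegated to scikit-learn (rank formulation with
averaged ties; step-interpolated PR area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .embedding import ConvSpec, conv_feature_map, matrix_factorize
from .gmnn import TrainConfig, train_em
from .io import AssociationMatrix, SideNetwork
from .similarity import build_side_graphs


@dataclass(frozen=True)
class FoldSplit:
    """Partition of the positive cells of A into folds of near-equal size."""

    positive_cells: np.ndarray  # (n_pos, 2) array of (row, col)
    fold_id: np.ndarray  # (n_pos,) in [0, n_folds)
    n_folds: int
    seed: int

    def test_cells(self, fold: int) -> np.ndarray:
        return self.positive_cells[self.fold_id == fold]


@dataclass(frozen=True)
class MetricReport:
    """Per-fold and aggregate AUROC/AUPR."""

    auroc_folds: np.ndarray
    aupr_folds: np.ndarray

    @property
    def auroc(self) -> float:
        return float(self.auroc_folds.mean())

    @property
    def aupr(self) -> float:
        return float(self.aupr_folds.mean())

    @property
    def auroc_sd(self) -> float:
        return float(self.auroc_folds.std(ddof=1)) if len(self.auroc_folds) > 1 else 0.0

    @property
    def aupr_sd(self) -> float:
        return float(self.aupr_folds.std(ddof=1)) if len(self.aupr_folds) > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "auroc_mean": self.auroc,
            "auroc_sd": self.auroc_sd,
            "aupr_mean": self.aupr,
            "aupr_sd": self.aupr_sd,
            "auroc_folds": self.auroc_folds.tolist(),
            "aupr_folds": self.aupr_folds.tolist(),
        }


def make_folds(A: AssociationMatrix, n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Uniform random partition of the positive cells into *n_folds* folds.

    Fold sizes differ by at most one; the same seed reproduces the split.
    """
    cells = np.argwhere(A.values == 1)
    n_pos = len(cells)
    if n_pos < n_folds:
        raise ValueError(f"too few positives ({n_pos}) for {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pos)
    fold_id = np.empty(n_pos, dtype=int)
    fold_id[perm] = np.arange(n_pos) % n_folds
    return FoldSplit(positive_cells=cells, fold_id=fold_id, n_folds=n_folds, seed=seed)


def auroc(scores, labels) -> float:
    """Area under the ROC curve, equal to P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("auroc undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve via step interpolation."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("aupr undefined: no positive labels")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def masked_recovery_metrics(
    scores: np.ndarray, A_full: np.ndarray, A_train: np.ndarray
) -> tuple[float, float]:
    """AUROC/AUPR of held-out positives vs all unobserved cells.

    Candidates are every cell that is not a training positive; the held-out
    (masked) positives are the positive class.
    """
    candidate = A_train == 0
    labels = (A_full[candidate] == 1).astype(int)
    s = scores[candidate]
    return auroc(s, labels), aupr(s, labels)


def train_and_score(
    A_train: AssociationMatrix,
    side_nets: dict[str, SideNetwork],
    cfg: TrainConfig,
    mf_k: int = 64,
    mf_reg: float = 0.01,
    mf_max_iter: int = 200,
    mf_tol: float = 1e-5,
    conv_spec: ConvSpec | None = None,
    fusion_gamma: float = 0.5,
    k_neighbors: int = 10,
):
    """Run the full pipeline on one training matrix; returns the TrainResult.

    The latent dimension is capped at min(m, n) - 1 so factorisation stays
    a genuine low-rank compression.
    """
    m, n = A_train.shape
    k = max(1, min(mf_k, min(m, n) - 1))
    emb = matrix_factorize(
        A_train, k=k, reg=mf_reg, max_iter=mf_max_iter, tol=mf_tol, seed=cfg.seed
    )
    spec = conv_spec or ConvSpec()
    if spec.width > k:
        spec = ConvSpec(channels=spec.channels, width=k, activation=spec.activation,
                        padding=spec.padding)
    feats = conv_feature_map(emb, spec, seed=cfg.seed)
    graphs = build_side_graphs(A_train, side_nets, gamma=fusion_gamma,
                               k_neighbors=k_neighbors)
    return train_em(A_train, graphs, feats, cfg)


def cross_validate(
    A: AssociationMatrix,
    side_nets: dict[str, SideNetwork],
    cfg: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    **pipeline_kwargs,
) -> MetricReport:
    """Five-fold cross-validation over positive cells.

    For each fold the test positives are zeroed in the training matrix before
    any similarity or embedding computation, so the held-out labels cannot
    leak into the model.  Candidates for scoring are the test positives plus
    every unobserved cell.
    """
    split = make_folds(A, n_folds=n_folds, seed=seed)
    A_full = np.asarray(A.values)
    aurocs, auprs = [], []
    for fold in range(n_folds):
        test = split.test_cells(fold)
        train_vals = A_full.copy()
        train_vals[test[:, 0], test[:, 1]] = 0
        A_train = A.with_values(train_vals)
        result = train_and_score(A_train, side_nets, cfg, **pipeline_kwargs)
        roc, pr = masked_recovery_metrics(result.scores, A_full, train_vals)
        aurocs.append(roc)
        auprs.append(pr)
    return MetricReport(auroc_folds=np.array(aurocs), aupr_folds=np.array(auprs))
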