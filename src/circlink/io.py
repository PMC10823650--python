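"""Edge-table I/O and assembly of the binary association and side-network matrices.

The central object is the binary association matrix ``A`` (circRNAs x diseases):
``A[i, j] = 1`` when circRNA *i* has an experimentally supported link to disease
*j*, 0 otherwise.  Side networks (circRNA-miRNA, miRNA-disease, circRNA-gene,
disease-gene) are binary incidence matrices whose primary axis is aligned to one
side of ``A``.

All files are plain UTF-8 TSV edge lists: one pair per line, first two columns
used, extra columns ignored, ``#`` lines treated as comments.  Identifiers are
opaque case-sensitive strings; no name normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("circlink")

SIDE_NETWORK_KINDS = ("circ-mirna", "mirna-disease", "circ-gene", "disease-gene")


class EdgeTableError(ValueError):
    """Raised for malformed edge-table lines (carries the offending line number)."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered bijection between entity names and 0-based matrix positions.

    Order is first appearance in the input, so rebuilding from the same file
    yields the same index.
    """

    names: tuple[str, ...]
    position: dict[str, int] = field(repr=False)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "EntityIndex":
        ordered: list[str] = []
        pos: dict[str, int] = {}
        for name in names:
            if name not in pos:
                pos[name] = len(ordered)
                ordered.append(name)
        return cls(names=tuple(ordered), position=pos)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.position


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary m x n label matrix with row (circRNA) and column (disease) indices."""

    values: np.ndarray
    rows: EntityIndex
    cols: EntityIndex

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"matrix shape {v.shape} does not match indices "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_positives(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Same indices, new values (used to zero held-out cells for training)."""
        return AssociationMatrix(values=values, rows=self.rows, cols=self.cols)


@dataclass(frozen=True)
class SideNetwork:
    """Binary incidence matrix between a primary side of A and an auxiliary type."""

    values: np.ndarray
    rows: EntityIndex
    cols: EntityIndex
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SIDE_NETWORK_KINDS:
            raise ValueError(f"unknown side-network kind {self.kind!r}")
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("side-network shape does not match indices")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("side-network entries must be 0 or 1")


def load_edge_table(path: str | Path, dedupe: bool = True) -> list[tuple[str, str]]:
    """Read an edge list of (entity, entity) pairs from a TSV file.

    Lines starting with ``#`` and blank lines are skipped.  Each remaining line
    must have at least two tab-separated fields; extra columns are ignored.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    EdgeTableError
        naming the 1-based line number of any line with fewer than two fields.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f for f in line.split("\t")]
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeTableError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields"
                )
            pair = (fields[0].strip(), fields[1].strip())
            if dedupe:
                if pair in seen:
                    continue
                seen.add(pair)
            pairs.append(pair)
    return pairs


def build_association_matrix(pairs: Sequence[tuple[str, str]]) -> AssociationMatrix:
    """Assemble the binary association matrix from (circRNA, disease) pairs.

    Entry (i, j) is 1 iff the pair appears; the matrix sum equals the number of
    distinct pairs.  Row/column order is first appearance.
    """
    if not pairs:
        raise ValueError("no associations: pair list is empty")
    rows = EntityIndex.from_names(p[0] for p in pairs)
    cols = EntityIndex.from_names(p[1] for p in pairs)
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for a, b in pairs:
        values[rows.position[a], cols.position[b]] = 1
    return AssociationMatrix(values=values, rows=rows, cols=cols)


def align_side_network(
    pairs: Sequence[tuple[str, str]],
    primary_index: EntityIndex,
    kind: str,
) -> SideNetwork:
    """Build a side network whose rows are aligned to *primary_index*.

    Primaries present in the index but absent from *pairs* get all-zero rows;
    pairs whose primary is unknown to the index are dropped with a warning
    (auxiliary databases routinely cover entities outside the benchmark).
    """
    kept: list[tuple[str, str]] = []
    dropped = 0
    for p, aux in pairs:
        if p in primary_index:
            kept.append((p, aux))
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "align_side_network(%s): dropped %d pairs with primaries absent "
            "from the association matrix",
            kind,
            dropped,
        )
    cols = EntityIndex.from_names(aux for _, aux in kept)
    values = np.zeros((len(primary_index), len(cols)), dtype=np.int8)
    for p, aux in kept:
        values[primary_index.position[p], cols.position[aux]] = 1
    return SideNetwork(values=values, rows=primary_index, cols=cols, kind=kind)


def association_to_pairs(A: AssociationMatrix) -> list[tuple[str, str]]:
    """Invert :func:`build_association_matrix`: list the positive cells as pairs."""
    ii, jj = np.nonzero(A.values)
    return [(A.rows.names[i], A.cols.names[j]) for i, j in zip(ii, jj)]


def write_edge_table(path: str | Path, pairs: Sequence[tuple[str, str]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def write_scores(
    path: str | Path,
    scores: np.ndarray,
    rows: EntityIndex,
    cols: EntityIndex,
    exclude: np.ndarray | None = None,
) -> None:
    """Write a score matrix as long-format TSV (circRNA, disease, score),
    sorted by descending score.  Cells flagged in *exclude* (e.g. known
    training positives) are omitted."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m, n = scores.shape
    mask = np.ones((m, n), dtype=bool) if exclude is None else ~exclude.astype(bool)
    ii, jj = np.nonzero(mask)
    order = np.argsort(-scores[ii, jj], kind="stable")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("circRNA\tdisease\tscore\n")
        for idx in order:
            i, j = ii[idx], jj[idx]
            fh.write(f"{rows.names[i]}\t{cols.names[j]}\t{scores[i, j]:.6g}\n")
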