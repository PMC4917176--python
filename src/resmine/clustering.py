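"""Journal/resource embedding via sparse singular value decomposition.

The underlying object is the sparse resource x journal matrix of
document-level mention counts.  The counts are decomposed raw — no centering
or scaling, since mean-centering a large sparse matrix would densify it —
so the leading singular direction mostly captures scale (total mention
volume); it is dropped by default and components two and three form the 2-D
embedding.  Journals embed via the right singular vectors, resources via the
left; ``transpose=True`` flips which one is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import svds

from .analytics import UsageTable


@dataclass
class SparseCountMatrix:
    resources: list[str]
    journals: list[str]
    matrix: csr_matrix  # shape (len(resources), len(journals))

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def total(self) -> int:
        return int(self.matrix.sum())


def build_count_matrix(u: UsageTable, partition: str,
                       log1p: bool = False) -> SparseCountMatrix:
    """Cell (r, j) = document-level count of resource r in journal j.

    Zero cells are never stored.  ``log1p`` optionally compresses the counts;
    raw counts are the default.
    """
    sub = u.partition_df(partition)
    cells = sub.groupby(["resource", "journal"])["doc_count"].sum().reset_index()
    resources = sorted(cells["resource"].unique())
    journals = sorted(cells["journal"].unique())
    r_idx = {r: i for i, r in enumerate(resources)}
    j_idx = {j: i for i, j in enumerate(journals)}
    data = cells["doc_count"].to_numpy(dtype=float)
    if log1p:
        data = np.log1p(data)
    m = csr_matrix(
        (data,
         (cells["resource"].map(r_idx).to_numpy(),
          cells["journal"].map(j_idx).to_numpy())),
        shape=(len(resources), len(journals)),
    )
    return SparseCountMatrix(resources=resources, journals=journals, matrix=m)


@dataclass
class Projection:
    entities: list[str]
    coords: np.ndarray            # (n_entities, 2): components 2 and 3
    singular_values: np.ndarray   # non-increasing, computed rank
    variance_fractions: np.ndarray
    components: tuple[int, int] = (2, 3)
    degenerate: bool = False

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {e: (float(x), float(y)) for e, (x, y) in zip(self.entities, self.coords)}


def svd_project(m: SparseCountMatrix, k: int = 3, drop_first: bool = True,
                transpose: bool = False, rank: int = 10) -> Projection:
    """Project journals (or resources, with ``transpose``) onto singular axes.

    Computes the top ``rank`` singular triplets of the raw count matrix (so
    variance fractions are meaningful), then embeds on components ``2..k``
    when ``drop_first`` (the scale axis is excluded), else ``1..k-1``.
    """
    n_rows, n_cols = m.shape
    min_dim = min(n_rows, n_cols)
    if k > min_dim:
        raise ValueError(f"k={k} exceeds min(matrix dims)={min_dim}")
    rank = max(k, min(rank, min_dim))

    def _dense():
        du, ds, dvt = np.linalg.svd(m.matrix.toarray(), full_matrices=False)
        return du[:, :rank], ds[:rank], dvt[:rank, :]

    if rank >= min_dim or min_dim <= 20:
        # tiny or full-rank requests: dense decomposition is exact and cheap
        u, s, vt = _dense()
    else:
        try:
            u, s, vt = svds(m.matrix, k=rank, random_state=0)
            order = np.argsort(s)[::-1]
            u, s, vt = u[:, order], s[order], vt[order, :]
        except Exception:
            # ARPACK struggles on (near-)rank-deficient inputs; fall back
            if n_rows * n_cols > 10 ** 7:
                raise
            u, s, vt = _dense()

    variance = s ** 2
    fractions = variance / variance.sum() if variance.sum() > 0 else variance

    lo = 1 if drop_first else 0
    hi = min(lo + 2, len(s))
    if lo >= len(s):
        raise ValueError("no components left after dropping the scale axis")
    # fewer than two usable axes, or a vanishing singular value, flags the
    # embedding as degenerate (e.g. a rank-1 matrix)
    degenerate = (hi - lo < 2) or bool(
        np.any(s[lo:hi] <= 1e-12 * max(s[0], 1.0)))

    if transpose:
        entities, vectors = m.resources, u[:, lo:hi] * s[lo:hi]
    else:
        entities, vectors = m.journals, (vt[lo:hi, :].T) * s[lo:hi]
    return Projection(entities=entities, coords=vectors,
                      singular_values=s.copy(),
                      variance_fractions=fractions,
                      components=(lo + 1, hi), degenerate=degenerate)


def variance_explained(p: Projection) -> np.ndarray:
    """Fraction of total squared singular value per computed component."""
    total = float((p.singular_values ** 2).sum())
    if total == 0:
        raise ValueError("all-zero matrix has no variance to explain")
    return (p.singular_values ** 2) / total
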