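"""Reliable-source scoring from a web-link graph.

The link structure of the crawled pages is encoded as a column-stochastic
*transfer matrix* M: entry (i, j) is 1/outdegree(j) when page j links to
page i, so each nonzero column holds outdegree(j) equal entries summing
to 1, and pages without out-links have an all-zero (dangling) column.

Reliability is the stationary mass of a damped random surfer on M
(PageRank): dangling mass and a uniform teleport at rate ``1 - damping``
are redistributed uniformly.  Pages scoring at or above the uniform
baseline 1/N (or, alternatively, a top fraction) are kept as reliable
sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .corpus import CorpusValidationError, WebPage

__all__ = [
    "TransferMatrix",
    "ReliabilityScores",
    "build_transfer_matrix",
    "score_pages",
    "select_reliable",
]


@dataclass(frozen=True)
class TransferMatrix:
    """Column-stochastic link matrix over the corpus pages.

    ``matrix`` is an N x N scipy CSC matrix; ``page_ids[k]`` maps matrix
    index k back to the page id.
    """

    matrix: sparse.csc_matrix
    page_ids: tuple[int, ...]

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def entry(self, row_page: int, col_page: int) -> float:
        """M[row, col] addressed by page ids."""
        idx = {pid: k for k, pid in enumerate(self.page_ids)}
        return float(self.matrix[idx[row_page], idx[col_page]])

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


@dataclass(frozen=True)
class ReliabilityScores:
    scores: dict[int, float]
    converged: bool
    iterations: int


def build_transfer_matrix(pages: list[WebPage]) -> TransferMatrix:
    """Build M from the link graph.

    Self-links, duplicate links and links to unknown pages are dropped
    (unknown targets with a warning); the column of page j then holds
    outdegree(j) entries of value 1/outdegree(j), or is all zero when j
    has no surviving out-links.
    """
    ids = [p.page_id for p in pages]
    if len(set(ids)) != len(ids):
        raise CorpusValidationError("duplicate page_id in link graph")
    index = {pid: k for k, pid in enumerate(ids)}
    n = len(pages)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for p in pages:
        targets = {t for t in p.out_links if t != p.page_id}
        unknown = {t for t in targets if t not in index}
        if unknown:
            warnings.warn(
                f"page {p.page_id}: dropping {len(unknown)} out-link(s) to "
                f"unknown pages",
                stacklevel=2,
            )
            targets -= unknown
        if not targets:
            continue
        w = 1.0 / len(targets)
        for t in sorted(targets):
            rows.append(index[t])
            cols.append(index[p.page_id])
            vals.append(w)
    m = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return TransferMatrix(m, tuple(ids))


def score_pages(
    M: TransferMatrix,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ReliabilityScores:
    """Damped power iteration on the transfer matrix.

    Iterates ``r <- damping * (M r + dangling_mass/N) + (1-damping)/N``
    from the uniform vector until the L1 change drops below ``tol``.
    Scores sum to 1 at every iteration.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0,1), got {damping}")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    n = M.size
    if n == 0:
        return ReliabilityScores({}, True, 0)
    A = M.matrix
    dangling = np.asarray(A.sum(axis=0)).ravel() < 1e-12
    r = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dang_mass = r[dangling].sum()
        r_new = damping * (A @ r + dang_mass / n) + (1.0 - damping) / n
        delta = np.abs(r_new - r).sum()
        r = r_new
        if delta < tol:
            converged = True
            break
    scores = {pid: float(r[k]) for k, pid in enumerate(M.page_ids)}
    return ReliabilityScores(scores, converged, it)


def select_reliable(
    scores: ReliabilityScores,
    policy: str = "baseline",
    multiplier: float = 1.0,
    top_fraction: float = 0.5,
) -> set[int]:
    """Select reliable pages from reliability scores.

    ``policy="baseline"`` keeps pages scoring at least ``multiplier / N``
    (the uniform baseline times a multiplier); ``policy="top_fraction"``
    keeps the ``top_fraction`` highest-scoring pages (at least one when
    scores are nonempty).
    """
    if not scores.scores:
        return set()
    n = len(scores.scores)
    if policy == "baseline":
        thr = multiplier / n
        # tiny tolerance so exactly-uniform graphs keep every page
        return {pid for pid, s in scores.scores.items() if s >= thr - 1e-12}
    if policy == "top_fraction":
        if not 0.0 < top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0,1]")
        k = max(1, int(round(top_fraction * n)))
        ranked = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return {pid for pid, _ in ranked[:k]}
    raise ValueError(f"unknown policy {policy!r}")
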