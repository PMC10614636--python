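"""Eigencentrality profiling of significant-difference networks.

Each pairwise comparison yields a weighted graph over the significant-region
union: edge weight = |Fisher-z difference| on edges that survived the
permutation mask, 0 elsewhere.  A region's influence in that graph is its
eigenvector centrality — the dominant-eigenvector score of the nonnegative
weight matrix.

Convention for sparse graphs: the dominant eigenvector is computed on the
largest connected component (most edges; ties broken by total edge weight)
and L1-normalized to sum 1 over that component.  Every node outside it —
including isolated nodes — is assigned the uniform baseline ``1/N`` where N
is the full network size.  An empty graph is therefore all ``1/N``
(0.0164 for N = 61), which is exactly the repeated filler value seen in
published 61-region centrality tables and makes "not in the dominant
difference network" visually explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import ConvergenceError, ValidationError
from .network_compare import DifferenceNetwork

__all__ = ["CentralityProfileMatrix", "eigencentrality", "build_profile_matrix", "hits_scores"]


def _check_weights(w: np.ndarray, allow_asymmetric: bool = False) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"weight matrix must be square, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValidationError("weight matrix contains non-finite entries")
    if w.min(initial=0.0) < 0:
        raise ValidationError("weight matrix must be nonnegative")
    if not allow_asymmetric and not np.allclose(w, w.T):
        raise ValidationError("weight matrix must be symmetric")
    return w


def eigencentrality(
    weights: np.ndarray,
    baseline_n: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Dominant-component eigenvector centrality with a uniform 1/N baseline.

    Power iteration on ``W + sI`` (s = max row sum) — the shift leaves the
    eigenvectors unchanged but makes the dominant eigenvalue unique, so the
    iteration also converges on bipartite components (a bare edge, a star)
    where plain power iteration would oscillate between +/- the spectral
    radius.  The returned vector sums to 1 over the dominant component and
    equals ``1/baseline_n`` everywhere else.
    """
    w = _check_weights(weights)
    if np.abs(np.diag(w)).max(initial=0.0) > 0:
        raise ValidationError("weight matrix must have a zero diagonal (no self-edges)")
    n = w.shape[0]
    if baseline_n is None:
        baseline_n = n
    out = np.full(n, 1.0 / baseline_n)
    adj = w > 0
    if not adj.any():
        return out
    n_comp, labels = connected_components(adj, directed=False)
    # dominant component: most edges, then largest total weight, then lowest label
    best, best_key = None, None
    for c in range(n_comp):
        nodes = labels == c
        sub = w[np.ix_(nodes, nodes)]
        key = (int((sub > 0).sum()) // 2, float(sub.sum()) / 2.0)
        if key <= ((0, 0.0)):
            continue
        if best_key is None or key > best_key:
            best, best_key = nodes, key
    sub = w[np.ix_(best, best)]
    shift = sub.sum(axis=1).max()
    x = np.full(sub.shape[0], 1.0 / sub.shape[0])
    for _ in range(max_iter):
        y = sub @ x + shift * x
        y /= y.sum()
        if np.abs(y - x).sum() < tol:
            out[best] = y
            return out
        x = y
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations",
        residual=float(np.abs(y - x).sum()),
    )


@dataclass(frozen=True)
class CentralityProfileMatrix:
    """Regions x comparisons eigencentrality values plus the row-average column."""

    region_names: tuple[str, ...]
    comparisons: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    average: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.region_names), len(self.comparisons)):
            raise ValidationError("profile matrix shape does not match labels")
        if self.values.min(initial=0.0) < 0:
            raise ValidationError("eigencentrality values must be nonnegative")
        if not np.allclose(self.average, self.values.mean(axis=1)):
            raise ValidationError("average column is not the row mean")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.comparisons))
        df.insert(0, "region", list(self.region_names))
        df.insert(1, "average", self.average)
        return df


def build_profile_matrix(
    diffs: Sequence[DifferenceNetwork],
    region_union: Sequence[str],
) -> CentralityProfileMatrix:
    """Assemble the regions x comparisons eigencentrality profile matrix.

    Comparison columns follow the canonical pair-label order of the inputs
    (sorted by label).  The per-column weight matrix is |delta_z| restricted
    to masked edges and to the union regions; the baseline N is the union
    size.
    """
    if not region_union:
        raise ValidationError("no significant regions: region union is empty")
    if not diffs:
        raise ValidationError("no comparisons supplied")
    universe = list(diffs[0].region_names)
    idx = [universe.index(r) for r in region_union]
    diffs = sorted(diffs, key=lambda d: d.pair)
    n = len(region_union)
    cols = np.empty((n, len(diffs)))
    for k, d in enumerate(diffs):
        w = (np.abs(d.delta_z) * d.mask)[np.ix_(idx, idx)]
        cols[:, k] = eigencentrality(w, baseline_n=n)
    return CentralityProfileMatrix(
        region_names=tuple(region_union),
        comparisons=tuple(d.pair for d in diffs),
        values=cols,
        average=cols.mean(axis=1),
    )


def hits_scores(
    weights: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """HITS hub and authority scores of a nonnegative (possibly directed) weight matrix.

    Standard coupled iteration ``a <- W.T h``, ``h <- W a`` with L1
    normalisation each step; for symmetric weights hubs equal authorities.
    Returns ``(hubs, authorities)``.
    """
    w = _check_weights(weights, allow_asymmetric=True)
    n = w.shape[0]
    if n == 0:
        raise ValidationError("empty weight matrix")
    h = np.full(n, 1.0 / n)
    a = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        a_new = w.T @ h
        s = a_new.sum()
        a_new = a_new / s if s > 0 else np.full(n, 1.0 / n)
        h_new = w @ a_new
        s = h_new.sum()
        h_new = h_new / s if s > 0 else np.full(n, 1.0 / n)
        if np.abs(h_new - h).sum() + np.abs(a_new - a).sum() < tol:
            return h_new, a_new
        h, a = h_new, a_new
    raise ConvergenceError(
        f"HITS did not converge in {max_iter} iterations",
        residual=float(np.abs(h_new - h).sum() + np.abs(a_new - a).sum()),
    )
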