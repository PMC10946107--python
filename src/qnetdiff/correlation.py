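"""Between-taxon correlation estimation and network construction.

Relative-abundance data are compositional: because every sample sums to 1,
naive correlations between taxa are biased (typically negatively).  The
default backend therefore infers *basis* correlations — correlations between
the unobserved absolute abundances — from pairwise log-ratio variances, the
scheme introduced by Friedman & Alm (SparCC).  A deterministic Spearman
backend and a precomputed-matrix backend are provided as alternatives.

Correlation matrices are thresholded into weighted networks: an entry becomes
an edge weight iff it is *strictly* greater than ``edge_threshold`` (default
0.4); everything else, including all negative correlations, is dropped.
Taxa isolated in both groups' networks are then pruned jointly, yielding the
list of effective taxa shared by the two networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import WeightedNetwork
from .tables_io import CountTable

__all__ = [
    "CorrelationMatrix",
    "SparccOptions",
    "estimate_correlations",
    "sparcc_correlations",
    "spearman_correlations",
    "read_correlation_tsv",
    "threshold_to_network",
    "prune_jointly_isolated",
    "DEFAULT_EDGE_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.4

_BOUND_TOL = 1e-9


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlation estimates in [-1, 1]."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T, atol=_BOUND_TOL, rtol=0.0):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(v) > 1.0 + _BOUND_TOL):
            raise ValueError("correlation entries must lie in [-1, 1]")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v


@dataclass(frozen=True)
class SparccOptions:
    """Tuning knobs of the basis-correlation inference.

    ``iterations`` resampled (Dirichlet) estimates are aggregated; within
    each, up to ``exclusion_rounds`` strongly correlated pairs (|r| above
    ``exclusion_threshold``) are excluded from the sparsity-based
    basis-variance solve.  ``pseudo_count`` is added to every count before
    resampling so zeros pose no problem for the log-ratios.
    """

    iterations: int = 20
    exclusion_threshold: float = 0.1
    exclusion_rounds: int = 10
    pseudo_count: float = 1.0
    aggregation: str = "median"  # or "mean"


def estimate_correlations(
    ct: CountTable,
    backend: str = "sparcc",
    seed: int = 0,
    options: SparccOptions | None = None,
    precomputed: "CorrelationMatrix | str | Path | None" = None,
) -> CorrelationMatrix:
    """Estimate pairwise between-taxon correlations for one group.

    Parameters
    ----------
    backend
        ``"sparcc"`` (compositional basis correlations, seeded),
        ``"spearman"`` (deterministic rank correlation on counts), or
        ``"precomputed"`` (a user-supplied matrix, see ``precomputed``).
    """
    if backend == "sparcc":
        return sparcc_correlations(ct, seed=seed, options=options)
    if backend == "spearman":
        return spearman_correlations(ct)
    if backend == "precomputed":
        if precomputed is None:
            raise ValueError("backend 'precomputed' requires a matrix or path")
        if isinstance(precomputed, CorrelationMatrix):
            cm = precomputed
        else:
            cm = read_correlation_tsv(precomputed)
        if set(cm.taxa) != set(ct.taxa):
            raise ValueError(
                "precomputed correlation matrix taxa do not match count table"
            )
        if cm.taxa != ct.taxa:  # reorder to the count table's taxon order
            idx = [cm.taxa.index(t) for t in ct.taxa]
            cm = CorrelationMatrix(ct.taxa, cm.values[np.ix_(idx, idx)])
        return cm
    raise ValueError(f"unknown correlation backend {backend!r}")


# ---------------------------------------------------------------------------
# SparCC-style basis correlation inference
# ---------------------------------------------------------------------------


def sparcc_correlations(
    ct: CountTable,
    seed: int = 0,
    options: SparccOptions | None = None,
) -> CorrelationMatrix:
    """Infer basis correlations from compositional counts.

    For each inner iteration, sample fractions are drawn from per-sample
    Dirichlet posteriors (counts + pseudo-count), the matrix of log-ratio
    variances ``T[i, j] = Var(log x_i/x_j)`` is formed, and basis variances
    are solved under the sparsity assumption; the most correlated pairs are
    iteratively excluded from the solve and the correlations recomputed.
    Estimates are aggregated across iterations (median by default) and
    clipped to [-1, 1].
    """
    opts = options or SparccOptions()
    counts = ct.data.to_numpy(dtype=float)
    d, n = counts.shape
    if d < 3:
        raise ValueError(
            "sparcc backend needs at least 3 taxa (the log-ratio system is "
            "degenerate below that); use the spearman backend instead"
        )
    if n < 2:
        raise ValueError("sparcc backend needs at least 2 samples")
    zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
    if zero_rows.size:
        names = [ct.taxa[i] for i in zero_rows]
        raise ValueError(
            f"taxa with zero counts in every sample: {names}; add a "
            "pseudo-count to the table or remove them before running sparcc"
        )

    rng = np.random.default_rng(seed)
    alpha = counts + opts.pseudo_count
    estimates = np.empty((opts.iterations, d, d))
    for it in range(opts.iterations):
        # one Dirichlet draw of fractions per sample column
        logf = np.empty((d, n))
        for k in range(n):
            logf[:, k] = np.log(rng.dirichlet(alpha[:, k]))
        cov = np.cov(logf)
        v = np.diag(cov)
        # T[i,j] = Var(log x_i - log x_j)
        t_mat = v[:, None] + v[None, :] - 2.0 * cov
        np.fill_diagonal(t_mat, 0.0)
        estimates[it] = _basis_correlations(
            t_mat,
            exclusion_threshold=opts.exclusion_threshold,
            exclusion_rounds=opts.exclusion_rounds,
        )
    if opts.aggregation == "median":
        cor = np.median(estimates, axis=0)
    elif opts.aggregation == "mean":
        cor = estimates.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation {opts.aggregation!r}")
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return CorrelationMatrix(ct.taxa, cor)


def _basis_correlations(
    t_mat: np.ndarray,
    exclusion_threshold: float,
    exclusion_rounds: int,
) -> np.ndarray:
    """Solve for basis variances under sparsity and derive correlations.

    The sparsity approximation sets the sum of basis covariances of each
    taxon to zero, giving the linear system ``M @ omega = T @ 1`` with
    ``M = I*(d-2) + J``.  Pairs whose resulting |correlation| exceeds the
    exclusion threshold most strongly are removed from the system one at a
    time and the solve repeated, limiting the damage a few genuinely
    correlated pairs do to the approximation.
    """
    d = t_mat.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_work = t_mat.copy()
    excluded = np.zeros((d, d), dtype=bool)

    cor = np.eye(d)
    for round_ in range(exclusion_rounds + 1):
        omega = np.linalg.solve(m, t_work.sum(axis=1))
        # a non-positive solved variance is a degeneracy of the sparsity
        # approximation; replace it by the smallest positive one
        bad = omega <= 0
        if bad.any():
            floor = float(omega[~bad].min()) if (~bad).any() else 1e-12
            omega[bad] = floor
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        cor = (omega[:, None] + omega[None, :] - t_mat) / denom
        np.fill_diagonal(cor, 1.0)
        if round_ == exclusion_rounds:
            break
        candidate = np.abs(cor)
        np.fill_diagonal(candidate, 0.0)
        candidate[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(candidate), candidate.shape)
        if candidate[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        t_work[i, j] = t_work[j, i] = 0.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    return cor


# ---------------------------------------------------------------------------
# Alternative backends
# ---------------------------------------------------------------------------


def spearman_correlations(ct: CountTable) -> CorrelationMatrix:
    """Deterministic Spearman rank correlation between taxon count rows."""
    values = ct.data.to_numpy(dtype=float)
    d = values.shape[0]
    if d == 2:
        rho = stats.spearmanr(values[0], values[1]).statistic
        cor = np.array([[1.0, rho], [rho, 1.0]])
    else:
        cor = stats.spearmanr(values, axis=1).statistic
    cor = np.asarray(cor, dtype=float)
    cor = np.nan_to_num(cor, nan=0.0)  # constant rows have undefined rho
    np.fill_diagonal(cor, 1.0)
    return CorrelationMatrix(ct.taxa, np.clip(cor, -1.0, 1.0))


def read_correlation_tsv(path: str | Path) -> CorrelationMatrix:
    """Load a square correlation TSV with matching row/column taxon labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"correlation matrix {path}: row labels must equal column labels"
        )
    return CorrelationMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Thresholding and joint-isolate pruning
# ---------------------------------------------------------------------------


def threshold_to_network(
    cm: CorrelationMatrix, edge_threshold: float = DEFAULT_EDGE_THRESHOLD
) -> WeightedNetwork:
    """Keep entries strictly greater than the threshold as edge weights.

    Entries equal to the threshold are dropped; negative correlations can
    never pass a non-negative threshold and never become edges.
    """
    if not (-1.0 <= edge_threshold < 1.0):
        raise ValueError(
            f"edge_threshold must lie in [-1, 1), got {edge_threshold}"
        )
    w = np.where(cm.values > edge_threshold, cm.values, 0.0)
    np.fill_diagonal(w, 0.0)
    w = np.maximum(w, 0.0)
    return WeightedNetwork(cm.taxa, w)


def prune_jointly_isolated(
    net_x: WeightedNetwork, net_y: WeightedNetwork
) -> tuple[WeightedNetwork, WeightedNetwork, list[str]]:
    """Remove taxa that are isolated in *both* networks.

    Returns the two pruned networks (over the identical retained node list)
    and the ordered list of effective taxa.  A taxon with at least one edge
    in either network is retained in both.
    """
    if net_x.taxa != net_y.taxa:
        raise ValueError("networks must share an identical ordered node list")
    keep = (net_x.degrees() > 0) | (net_y.degrees() > 0)
    effective = [t for t, k in zip(net_x.taxa, keep) if k]
    n_removed = len(net_x.taxa) - len(effective)
    if n_removed:
        logger.info("pruned %d jointly isolated taxa", n_removed)
    idx = np.flatnonzero(keep)
    sub_x = WeightedNetwork(effective, net_x.weights[np.ix_(idx, idx)])
    sub_y = WeightedNetwork(effective, net_y.weights[np.ix_(idx, idx)])
    return sub_x, sub_y, effective
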