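"""Discriminant genes between drug clusters by sparse LDA.

Two-class linear discriminant analysis is recast as an l1-penalized least
squares problem: with n1 and n2 drugs in clusters v1 and v2 (n = n1 + n2),
labels are coded y_j = -n/n1 for v1 and y_j = +n/n2 for v2, and

    (b, b0) = argmin { n^-1 sum_j (y_j - b0 - x_j' b)^2 + lambda ||b||_1 }

is solved by cyclic coordinate descent along a geometric lambda grid from
lambda_max (the smallest penalty with an all-zero solution) down to
``ratio * lambda_max``.  Genes are standardized internally and the
coefficients reported on the original scale.  Because the cohorts are far
too small for reliable cross-validation, the discriminant gene set is read
off at the smallest grid lambda.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class LassoPath:
    """Solutions of the penalized problem along a descending lambda grid.

    ``coefs`` holds original-scale coefficient vectors (n_lambda x p);
    standardized-scale solutions and the standardization constants are
    retained so optimality can be verified on the problem actually solved.
    """

    lambdas: np.ndarray
    coefs: np.ndarray
    intercepts: np.ndarray
    genes: list
    coefs_std: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    dropped_genes: list = field(default_factory=list)


@dataclass
class DiscriminantResult:
    pair: tuple
    lambda_used: float
    path: LassoPath
    beta: pd.Series
    intercept: float
    nonzero_genes: list


def encode_labels(n1: int, n2: int) -> np.ndarray:
    """Discriminant coding -n/n1 (first cluster) and +n/n2 (second)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one drug")
    n = n1 + n2
    return np.concatenate([np.full(n1, -n / n1), np.full(n2, n / n2)])


def _soft_threshold(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _cd_solve(X, y, lam, beta, w=None, max_sweeps=10_000, tol=1e-7):
    """Cyclic coordinate descent for n^-1 ||y - b0 - X b||^2 + lam ||b||_1.

    ``w`` holds the column mean squares ||x_g||^2 / n (all 1 for
    standardized columns); each coordinate update is an exact
    soft-thresholding step.
    """
    n, p = X.shape
    if w is None:
        w = np.ones(p)
    b0 = float(np.mean(y - X @ beta))
    r = y - b0 - X @ beta

    def sweep(indices):
        max_delta = 0.0
        nonlocal r, b0
        for g in indices:
            c = w[g] * beta[g] + X[:, g] @ r / n
            new = _soft_threshold(c, lam / 2.0) / w[g]
            if new != beta[g]:
                r -= X[:, g] * (new - beta[g])
                max_delta = max(max_delta, abs(new - beta[g]))
                beta[g] = new
        shift = float(np.mean(r))
        if shift != 0.0:
            r -= shift
            b0 += shift
            max_delta = max(max_delta, abs(shift))
        return max_delta

    # glmnet-style: converge on the active set, then one full sweep to admit
    # KKT violators; done when a full sweep changes nothing appreciably
    sweeps = 0
    while sweeps < max_sweeps:
        delta = sweep(range(p))
        sweeps += 1
        if delta < tol:
            break
        active = np.flatnonzero(beta)
        while sweeps < max_sweeps:
            delta = sweep(active)
            sweeps += 1
            if delta < tol:
                break
    return beta, b0


def lasso_path(X: pd.DataFrame, y: np.ndarray, n_lambda: int = 100,
               ratio: float = 0.01, standardize: bool = True) -> LassoPath:
    """Coordinate-descent solution path over a geometric lambda grid.

    ``X`` is a gene x drug matrix; samples are drugs.  Constant gene rows
    are dropped with a warning (their coefficient is reported as 0).
    """
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least three drugs")
    if len(y) != n:
        raise ValueError("label vector length must match the drug count")

    genes = list(X.index)
    A = X.to_numpy(dtype=float).T  # drugs x genes
    sds_all = A.std(axis=0)
    keep = sds_all > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant gene(s)")
    A = A[:, keep]
    means = A.mean(axis=0)
    if standardize:
        sds = A.std(axis=0)
    else:
        sds = np.ones(A.shape[1])
    Astd = (A - means) / sds

    ybar = y.mean()
    # smallest penalty with an all-zero solution: |2/n <x_g, y - ybar>| <= lam
    lam_max = 2.0 * np.max(np.abs(Astd.T @ (y - ybar))) / n
    lambdas = lam_max * np.power(ratio, np.linspace(0, 1, n_lambda))

    p_kept = Astd.shape[1]
    coefs_std = np.zeros((n_lambda, p_kept))
    intercepts = np.zeros(n_lambda)
    beta = np.zeros(p_kept)
    colw = np.mean(Astd ** 2, axis=0)
    for i, lam in enumerate(lambdas):
        beta, b0 = _cd_solve(Astd, y, lam, beta.copy(), w=colw)
        coefs_std[i] = beta
        intercepts[i] = b0

    coefs = np.zeros((n_lambda, len(genes)))
    coefs[:, keep] = coefs_std / sds
    intercepts_orig = intercepts - coefs_std @ (means / sds)
    return LassoPath(lambdas=lambdas, coefs=coefs,
                     intercepts=intercepts_orig, genes=genes,
                     coefs_std=coefs_std, gene_means=means, gene_sds=sds,
                     dropped_genes=dropped)


def select_discriminant_genes(path: LassoPath,
                              pair: tuple = (1, 2)) -> DiscriminantResult:
    """Nonzero gene set at the smallest grid lambda."""
    if path.lambdas.size == 0:
        raise ValueError("empty lambda path")
    i = int(np.argmin(path.lambdas))
    beta = pd.Series(path.coefs[i], index=path.genes)
    nonzero = [g for g in path.genes if beta[g] != 0.0]
    return DiscriminantResult(pair=pair, lambda_used=float(path.lambdas[i]),
                              path=path, beta=beta,
                              intercept=float(path.intercepts[i]),
                              nonzero_genes=nonzero)


def pairwise_discriminant_sets(profile: pd.DataFrame,
                               clusters: ClusterAssignment,
                               merge_control: bool = False,
                               control_clusters: tuple = (3, 4),
                               n_lambda: int = 100,
                               ratio: float = 0.01) -> list:
    """Discriminant gene sets for cluster contrasts.

    With ``merge_control`` the contrasts are each non-control cluster
    versus the merged control (by default clusters 3 and 4, whose AE
    burden is comparatively mild); otherwise every unordered cluster pair
    is contrasted.  Drugs without expression data are dropped with a log
    message; a group left with fewer than two expressed drugs causes its
    contrast to be skipped with a warning.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) \
        else pd.Series(clusters, dtype=int)
    expressed = [d for d in labels.index if d in profile.columns]
    missing = sorted(set(labels.index) - set(expressed))
    if missing:
        logger.info("dropped %d drug(s) without expression data: %s",
                    len(missing), missing[:5])
    labels = labels[expressed]

    groups: list[tuple[tuple, list, list]] = []
    if merge_control:
        control = [d for d in labels.index
                   if labels[d] in set(control_clusters)]
        for c in sorted(set(labels.unique()) - set(control_clusters)):
            members = [d for d in labels.index if labels[d] == c]
            groups.append(((c, "control"), members, control))
    else:
        for a, b in itertools.combinations(sorted(labels.unique()), 2):
            groups.append(((a, b),
                           [d for d in labels.index if labels[d] == a],
                           [d for d in labels.index if labels[d] == b]))

    results = []
    for pair, g1, g2 in groups:
        if len(g1) < 2 or len(g2) < 2:
            warnings.warn(f"contrast {pair} skipped: a group has fewer than "
                          "two expressed drugs")
            continue
        y = encode_labels(len(g1), len(g2))
        sub = profile[g1 + g2]
        path = lasso_path(sub, y, n_lambda=n_lambda, ratio=ratio)
        results.append(select_discriminant_genes(path, pair=pair))
    return results


def heatmap_table(profile: pd.DataFrame, clusters: ClusterAssignment,
                  results: list) -> pd.DataFrame:
    """Long-format (gene, drug, logFC, cluster) table over the union of
    selected genes, for heatmap export."""
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) \
        else pd.Series(clusters, dtype=int)
    genes = sorted(set(g for res in results for g in res.nonzero_genes))
    drugs = [d for d in labels.sort_values().index if d in profile.columns]
    rows = []
    for g in genes:
        for d in drugs:
            rows.append({"gene": g, "drug": d,
                         "logFC": float(profile.at[g, d]),
                         "cluster": int(labels[d])})
    return pd.DataFrame(rows)
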