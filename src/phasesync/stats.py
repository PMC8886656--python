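"""Confound residualization, group tests, FDR control, and connectome PCA.

All group-level inference in the pipeline runs on *residualized* metrics:
nuisance covariates (age, gender, handedness, education, mean framewise
displacement, total intracranial volume, ...) are regressed out by ordinary
least squares before correlation or t-testing.  Multiple comparisons are
controlled with the Benjamini–Hochberg step-up procedure.  Subject-by-edge
streamline-count matrices are normalized per subject (division by the
subject's mean fiber count) and summarized by their first principal
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ResidualizedVector",
    "ConnectivityTable",
    "PCResult",
    "residualize",
    "partial_correlation",
    "group_ttest",
    "fdr_bh",
    "normalize_fibers",
    "pc1",
]


@dataclass
class ResidualizedVector:
    """OLS residuals of a vector on an intercept plus covariates."""

    values: np.ndarray
    covariate_names: tuple[str, ...]
    intercept_included: bool = True


@dataclass
class ConnectivityTable:
    """Subject-by-edge matrix of streamline (fiber) counts.

    ``edge_labels`` are (seed-region, target-region) pairs.  ``normalized``
    records whether each subject's row has been divided by its own mean.
    ``latent_scores`` is populated only by the synthetic generator and holds
    the ground-truth first factor for recovery tests.
    """

    matrix: np.ndarray
    edge_labels: tuple[tuple[str, str], ...] = ()
    subject_ids: tuple[str, ...] = ()
    normalized: bool = False
    latent_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("connectivity matrix must be 2-D (subjects x edges)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("connectivity matrix contains non-finite values")
        if (self.matrix < 0).any():
            raise ValueError("fiber counts must be non-negative")
        n_sub, n_edge = self.matrix.shape
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub-{i:03d}" for i in range(n_sub))
        if not self.edge_labels:
            self.edge_labels = tuple(("seed", f"edge{j:04d}") for j in range(n_edge))
        if len(self.subject_ids) != n_sub or len(self.edge_labels) != n_edge:
            raise ValueError("label lengths do not match matrix shape")


@dataclass
class PCResult:
    """First principal component of a connectivity table."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: float


def _design(covariates, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Build an [intercept | covariates] design matrix from array or DataFrame."""
    if covariates is None:
        return np.ones((n, 1)), ()
    if isinstance(covariates, pd.DataFrame):
        names = tuple(map(str, covariates.columns))
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = tuple(f"cov{j}" for j in range(cov.shape[1]))
    if cov.shape[0] != n:
        raise ValueError(f"covariate rows ({cov.shape[0]}) != observations ({n})")
    if not np.isfinite(cov).all():
        raise ValueError("covariates contain non-finite values")
    X = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        labels = ["intercept", *names]
        culprit = ", ".join(labels[i] for i in bad) or "unknown"
        raise ValueError(f"rank-deficient covariate design; collinear column(s): {culprit}")
    return X, names


def residualize(y, covariates=None) -> ResidualizedVector:
    """OLS residuals of ``y`` on an intercept plus the covariate columns."""
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    X, names = _design(covariates, y.size)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ResidualizedVector(values=y - X @ beta, covariate_names=names)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of two covariate-residualized vectors.

    Returns ``(r, p)`` with the ordinary two-sided p-value of the Pearson
    coefficient computed on the residuals.
    """
    rx = residualize(x, covariates).values
    ry = residualize(y, covariates).values
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance residuals; correlation undefined")
    res = sps.pearsonr(rx, ry)
    return float(res.statistic), float(res.pvalue)


def group_ttest(
    values,
    group_labels,
    covariates=None,
    paired: bool = False,
    pair_ids: Sequence | None = None,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-group t-test on covariate-residualized values.

    Values are residualized on the covariates across the *pooled* sample,
    then compared with a Welch two-sample t-test (``equal_var=False``, the
    default) or, for ``paired=True``, a paired t-test on within-pair
    differences matched by ``pair_ids``.  Returns ``(t, p, df)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    group_labels = np.asarray(group_labels)
    if values.size != group_labels.size:
        raise ValueError("values and group_labels differ in length")
    groups = np.unique(group_labels)
    if groups.size != 2:
        raise ValueError(f"need exactly 2 groups, got {groups.size}")
    resid = residualize(values, covariates).values
    a = resid[group_labels == groups[0]]
    b = resid[group_labels == groups[1]]

    if not paired:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return float(res.statistic), float(res.pvalue), float(res.df)

    if pair_ids is None:
        raise ValueError("paired test requires pair_ids")
    pair_ids = np.asarray(pair_ids)
    ids_a = pair_ids[group_labels == groups[0]]
    ids_b = pair_ids[group_labels == groups[1]]
    missing = sorted(set(ids_a).symmetric_difference(ids_b))
    if missing:
        raise ValueError(f"unmatched pair id(s): {', '.join(map(str, missing))}")
    order_a = np.argsort(ids_a)
    order_b = np.argsort(ids_b)
    diffs = a[order_a] - b[order_b]
    if diffs.std(ddof=1) == 0:
        raise ValueError("zero-variance within-pair differences; t undefined")
    res = sps.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue), float(diffs.size - 1)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` where ``reject`` is the boolean
    rejection mask at level ``q`` and ``p_adjusted`` the monotone
    BH-adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def normalize_fibers(table: ConnectivityTable) -> ConnectivityTable:
    """Divide each subject's row by its own mean fiber count."""
    means = table.matrix.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        names = ", ".join(table.subject_ids[i] for i in bad[:10])
        raise ValueError(f"non-positive mean fiber count for subject(s): {names}")
    return ConnectivityTable(
        matrix=table.matrix / means[:, None],
        edge_labels=table.edge_labels,
        subject_ids=table.subject_ids,
        normalized=True,
        latent_scores=table.latent_scores,
    )


def pc1(table: ConnectivityTable, center: bool = True, scale: bool = False) -> PCResult:
    """First principal component of the subject-by-edge matrix.

    Edges are centered (and optionally scaled to unit variance) before the
    decomposition.  The sign is fixed so that the sum of the loadings is
    positive, removing the eigenvector sign ambiguity so that PC1-metric
    correlations are reproducible run to run.
    """
    X = table.matrix
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 edges")
    if np.allclose(X, X[0], atol=0):
        raise ValueError("constant connectivity matrix; PCA undefined")
    work = X.copy()
    if scale:
        sd = work.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        work = work / sd
    if center:
        pca = PCA(n_components=1, svd_solver="full")
        scores = pca.fit_transform(work).ravel()
        loadings = pca.components_[0]
        var_explained = float(pca.explained_variance_ratio_[0])
    else:
        # uncentered PCA: plain SVD of the data matrix
        U, S, Vt = np.linalg.svd(work, full_matrices=False)
        loadings = Vt[0]
        scores = U[:, 0] * S[0]
        var_explained = float(S[0] ** 2 / np.sum(S**2))
    if loadings.sum() < 0:
        loadings = -loadings
        scores = -scores
    return PCResult(scores=scores, loadings=loadings, variance_explained=var_explained)
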