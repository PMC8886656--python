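"""Three-variable mediation analysis with bias-corrected bootstrap inference.

The standard single-mediator path model:

* path ``a`` — effect of the independent variable x on the mediator m,
  from the OLS fit of m on [x, covariates];
* paths ``b`` and ``c'`` — effects of the mediator and of x on the outcome
  y, from the fit of y on [x, m, covariates];
* path ``c`` — total effect of x on y, from the fit of y on [x, covariates];
* ``a*b`` — the indirect (mediated) effect.

For OLS fits sharing the same covariates the decomposition ``c = c' + a*b``
holds exactly for the point estimates.  Confidence intervals and p-values
come from a nonparametric bootstrap that resamples whole subject rows
(x, m, y, covariates jointly) and applies the bias-corrected (BC)
percentile construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["MediationResult", "fit_paths", "bootstrap_mediation"]

PATHS = ("a", "b", "c", "c_prime", "ab")


@dataclass
class MediationResult:
    """Path estimates with optional bootstrap intervals.

    ``estimates`` maps each path name in ``('a', 'b', 'c', 'c_prime', 'ab')``
    to its point estimate.  After ``bootstrap_mediation``, ``ci`` holds the
    bias-corrected (lower, upper) bounds and ``p_values`` the two-sided
    bootstrap p-values; ``degenerate`` lists paths whose bootstrap
    distribution collapsed to a single value (their CI equals the point
    estimate and p is reported as 0).
    """

    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    level: float = 0.95
    n_boot: int = 0
    seed: int | None = None
    n_redraws: int = 0
    covariate_names: tuple[str, ...] = ()
    degenerate: tuple[str, ...] = ()

    def __getitem__(self, path: str) -> float:
        return self.estimates[path]


def _validate(x, m, y, covariates):
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if m.size != n or y.size != n:
        raise ValueError("x, m, y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
        names: tuple[str, ...] = ()
    else:
        if hasattr(covariates, "columns"):  # DataFrame
            names = tuple(map(str, covariates.columns))
            cov = np.asarray(covariates, dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            names = tuple(f"cov{j}" for j in range(cov.shape[1]))
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match sample size")
    for name, arr in (("x", x), ("m", m), ("y", y), ("covariates", cov)):
        if not np.isfinite(arr).all():
            raise ValueError(f"{name} contains non-finite values")
    if n < cov.shape[1] + 3:
        raise ValueError(
            f"need at least n_covariates + 3 = {cov.shape[1] + 3} observations, got {n}"
        )
    return x, m, y, cov, names


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        culprit = ", ".join(labels[i] for i in bad) or "unknown"
        raise ValueError(f"rank-deficient design; collinear column(s): {culprit}")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _path_estimates(x, m, y, cov) -> dict[str, float]:
    n = x.size
    ones = np.ones(n)
    Xm = np.column_stack([ones, x, cov])  # m ~ 1 + x + cov
    Xy = np.column_stack([ones, x, m, cov])  # y ~ 1 + x + m + cov
    Xc = np.column_stack([ones, x, cov])  # y ~ 1 + x + cov
    a = _ols(Xm, m)[1]
    by = _ols(Xy, y)
    c_prime, b = by[1], by[2]
    c = _ols(Xc, y)[1]
    return {
        "a": float(a),
        "b": float(b),
        "c": float(c),
        "c_prime": float(c_prime),
        "ab": float(a * b),
    }


def fit_paths(x, m, y, covariates=None) -> MediationResult:
    """Point estimates of all five mediation paths by ordinary least squares."""
    x, m, y, cov, names = _validate(x, m, y, covariates)
    labels = ["intercept", "x", "m", *names]
    _check_rank(np.column_stack([np.ones(x.size), x, m, cov]), labels)
    return MediationResult(estimates=_path_estimates(x, m, y, cov), covariate_names=names)


def _bc_interval(boot: np.ndarray, est: float, level: float):
    """Bias-corrected percentile interval and two-sided p-value.

    The bias-correction constant z0 is the normal quantile of the fraction
    of bootstrap replicates below the point estimate; the interval endpoints
    are the bootstrap quantiles at Phi(2*z0 + z_alpha) and
    Phi(2*z0 + z_{1-alpha}).  The p-value inverts the same mapping at zero.
    """
    B = boot.size
    if np.ptp(boot) == 0:
        return (float(boot[0]), float(boot[0])), 0.0, True
    eps = 1.0 / (B + 1)
    prop_below = np.clip((boot < est).mean() + 0.5 * (boot == est).mean(), eps, 1 - eps)
    z0 = norm.ppf(prop_below)
    alpha = (1.0 - level) / 2.0
    lo_q = norm.cdf(2 * z0 + norm.ppf(alpha))
    hi_q = norm.cdf(2 * z0 + norm.ppf(1 - alpha))
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    # position of zero in the bootstrap distribution, bias-corrected
    frac_below_zero = np.clip((boot < 0).mean() + 0.5 * (boot == 0).mean(), eps, 1 - eps)
    p_one = norm.cdf(norm.ppf(frac_below_zero) - 2 * z0)
    p = float(np.clip(2 * min(p_one, 1 - p_one), 0.0, 1.0))
    return (float(lo), float(hi)), p, False


def _batched_paths(x, m, y, cov, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Path estimates for a batch of bootstrap index sets.

    Returns ``(paths, ok)`` where ``paths`` has one row per replicate with
    columns (a, b, c, c_prime, ab) and ``ok`` flags replicates whose designs
    were numerically full rank.  Solves the normal equations batch-wise.
    """
    n = x.size
    ones = np.ones(n)
    Xy_full = np.column_stack([ones, x, m, cov])  # widest design
    B = idx.shape[0]
    Xb = Xy_full[idx]  # (B, n, p_full)
    mb = m[idx]
    yb = y[idx]

    cols_m = [0, 1] + list(range(3, Xy_full.shape[1]))  # drop the m column
    Xm = Xb[:, :, cols_m]
    p_m = len(cols_m)
    p_y = Xy_full.shape[1]

    out = np.empty((B, 5))
    ok = np.ones(B, dtype=bool)

    def batch_solve(Xmat, target, p):
        G = np.einsum("bij,bik->bjk", Xmat, Xmat)
        rhs = np.einsum("bij,bi->bj", Xmat, target)
        # scale-invariant singularity test: eigenvalues of the gram matrix
        # normalized to unit diagonal (columns of very different units must
        # not register as collinear)
        d = np.sqrt(np.einsum("bjj->bj", G))
        nonzero = (d > 0).all(axis=1)
        d = np.where(d > 0, d, 1.0)
        Gs = G / (d[:, :, None] * d[:, None, :])
        eig = np.linalg.eigvalsh(Gs)
        good = nonzero & (eig[:, 0] > 1e-10 * eig[:, -1])
        beta = np.full((Xmat.shape[0], p), np.nan)
        if good.any():
            beta[good] = np.linalg.solve(G[good], rhs[good][..., None])[..., 0]
        return beta, good

    beta_m, ok_m = batch_solve(Xm, mb, p_m)  # m ~ 1 + x + cov
    beta_y, ok_y = batch_solve(Xb, yb, p_y)  # y ~ 1 + x + m + cov
    beta_c, ok_c = batch_solve(Xm, yb, p_m)  # y ~ 1 + x + cov
    ok = ok_m & ok_y & ok_c

    out[:, 0] = beta_m[:, 1]  # a
    out[:, 1] = beta_y[:, 2]  # b
    out[:, 2] = beta_c[:, 1]  # c
    out[:, 3] = beta_y[:, 1]  # c_prime
    out[:, 4] = out[:, 0] * out[:, 1]  # ab
    return out, ok


def bootstrap_mediation(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
    chunk_size: int = 2000,
) -> MediationResult:
    """Mediation paths with bias-corrected bootstrap CIs and p-values.

    Whole subject rows are resampled with replacement ``n_boot`` times.
    Replicates with a rank-deficient design (e.g. a resample containing a
    single group) are redrawn; if redraws exceed 10% of ``n_boot`` the data
    are deemed too fragile to bootstrap and an error is raised.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    x, m, y, cov, names = _validate(x, m, y, covariates)
    labels = ["intercept", "x", "m", *names]
    _check_rank(np.column_stack([np.ones(x.size), x, m, cov]), labels)
    estimates = _path_estimates(x, m, y, cov)

    rng = np.random.default_rng(seed)
    n = x.size
    max_redraws = int(0.10 * n_boot)
    collected: list[np.ndarray] = []
    n_done = 0
    n_redraws = 0
    while n_done < n_boot:
        want = min(chunk_size, n_boot - n_done)
        idx = rng.integers(0, n, size=(want, n))
        paths, ok = _batched_paths(x, m, y, cov, idx)
        n_bad = int((~ok).sum())
        if n_bad:
            n_redraws += n_bad
            if n_redraws > max_redraws:
                raise ValueError(
                    f"too many rank-deficient bootstrap replicates "
                    f"({n_redraws} > {max_redraws}); data not bootstrappable"
                )
        collected.append(paths[ok])
        n_done += int(ok.sum())
    boot = np.vstack(collected)[:n_boot]

    ci: dict[str, tuple[float, float]] = {}
    p_values: dict[str, float] = {}
    degenerate: list[str] = []
    for j, path in enumerate(PATHS):
        interval, p, degen = _bc_interval(boot[:, j], estimates[path], level)
        ci[path] = interval
        p_values[path] = p
        if degen:
            degenerate.append(path)

    return MediationResult(
        estimates=estimates,
        ci=ci,
        p_values=p_values,
        level=level,
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
        covariate_names=names,
        degenerate=tuple(degenerate),
    )
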