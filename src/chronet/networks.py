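"""Functional-network construction via Tikhonov partial correlation.

Each subject's standardized ROI time series yields a sample covariance
matrix C; the Tikhonov (ridge-regularized) precision matrix is
P = (C + lambda * I)^-1, and the network edge weights are the partial
correlations rho_ij = -P_ij / sqrt(P_ii * P_jj). The regularization
parameter lambda is chosen cohort-wide by minimizing the dispersion of
individual precision matrices around the cohort mean precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import FunctionalNetwork, NetworkCohort, RoiTimeSeriesSet


@dataclass
class TikhonovConfig:
    """Regularization settings for partial-correlation network construction."""

    lambda_reg: float = 0.0259
    lambda_grid: np.ndarray = field(default_factory=lambda: default_lambda_grid())

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size and (np.any(np.diff(grid) <= 0) or np.any(grid < 0)):
            raise ValueError("lambda_grid must be strictly increasing and nonnegative")
        self.lambda_grid = grid


def default_lambda_grid(n: int = 200, lo: float = 1e-4, hi: float = 10.0) -> np.ndarray:
    """Coarse search grid: ``n`` log-spaced values in [lo, hi]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def standardize(series: np.ndarray) -> np.ndarray:
    """Column-wise standardization to mean 0 and sample sd 1 (divisor T-1).

    Raises ValueError naming the offending ROI if any column has zero
    sample standard deviation.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"series must be 2-D, got shape {x.shape}")
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance ROI column(s) at 1-based index {[int(k) + 1 for k in zero]}: "
            "cannot standardize a constant time series"
        )
    return (x - x.mean(axis=0)) / sd


def covariance(series_std: np.ndarray) -> np.ndarray:
    """Sample covariance with divisor T-1.

    For standardized input this equals the sample correlation matrix
    (unit diagonal).
    """
    x = np.asarray(series_std, dtype=float)
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    c = xc.T @ xc / (t - 1)
    return (c + c.T) / 2.0


def tikhonov_precision(cov: np.ndarray, lam: float) -> np.ndarray:
    """Ridge-regularized precision matrix (cov + lambda*I)^-1."""
    c = np.asarray(cov, dtype=float)
    n = c.shape[0]
    reg = c + lam * np.eye(n)
    try:
        p = scipy.linalg.inv(reg)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance + {lam}*I is singular; increase the regularization "
            "parameter lambda"
        ) from exc
    if not np.isfinite(p).all():
        raise np.linalg.LinAlgError(
            f"covariance + {lam}*I is numerically singular; increase the "
            "regularization parameter lambda"
        )
    return (p + p.T) / 2.0


def partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    rho_ij = -P_ij / sqrt(P_ii * P_jj) for i != j; the diagonal is set to
    NaN (self-links are undefined under partial correlation).
    """
    p = np.asarray(precision, dtype=float)
    d = np.diag(p)
    if np.any(d <= 0):
        bad = np.flatnonzero(d <= 0)
        raise ValueError(
            f"precision matrix has non-positive diagonal at 1-based index {list(bad + 1)}"
        )
    scale = np.sqrt(np.outer(d, d))
    rho = -p / scale
    # Regularized precision matrices are SPD, so |rho| <= 1 up to roundoff;
    # clip the roundoff, not genuine violations.
    np.clip(rho, -1.0 - 1e-10, 1.0 + 1e-10, out=rho)
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, np.nan)
    return rho


def build_network(
    series: np.ndarray, lam: float, subject_id: str = "", label: str = "UNKNOWN"
) -> FunctionalNetwork:
    """Full chain: standardize -> covariance -> Tikhonov precision -> partial correlation."""
    prec = tikhonov_precision(covariance(standardize(series)), lam)
    return FunctionalNetwork(partial_correlation(prec), subject_id=subject_id, label=label)


def build_cohort_networks(cohort: RoiTimeSeriesSet, lam: float) -> NetworkCohort:
    """Construct one functional network per subject at a shared lambda."""
    return NetworkCohort(
        [build_network(s.series, lam, s.subject_id, s.label) for s in cohort]
    )


def _subject_covariances(cohort: RoiTimeSeriesSet) -> list[np.ndarray]:
    return [covariance(standardize(s.series)) for s in cohort]


def lambda_objective(covs: list[np.ndarray], lam: float) -> float:
    """Dispersion of individual Tikhonov precisions around the cohort mean.

    F(lambda) = sqrt( sum_{i<j} sum_m ( Pbar_ij - P^m_ij )^2 ), where P^m is
    subject m's precision at this lambda and Pbar the cohort mean precision.
    The sum runs over the strict upper triangle (the diagonal reflects
    scale, not connectivity).
    """
    precisions = np.stack([tikhonov_precision(c, lam) for c in covs])
    mean_p = precisions.mean(axis=0)
    dev = mean_p[None, :, :] - precisions
    iu = np.triu_indices(mean_p.shape[0], k=1)
    return float(np.sqrt((dev[:, iu[0], iu[1]] ** 2).sum()))


def optimize_lambda(
    cohort: RoiTimeSeriesSet | list[RoiTimeSeriesSet],
    grid: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Grid-search the cohort-dispersion objective for the optimal lambda.

    Multiple cohorts (e.g. scanning sessions) may be passed together; a
    single global lambda is fitted on the pooled set of subjects. Returns
    (lambda*, curve) where curve is a (len(grid), 2) array of (lambda, F)
    pairs; grid values for which any subject's regularized covariance is
    singular carry F = NaN and are excluded from the minimization. Ties
    resolve to the smallest lambda.

    Note that the raw dispersion F typically decreases monotonically with
    lambda (heavier regularization shrinks every subject's precision toward
    (1/lambda) * I, collapsing between-subject spread), so on real data the
    minimizer tends to sit at the top of the grid: the grid bounds are part
    of the protocol, not a mere search range. For routine network
    construction prefer a conventionally chosen lambda (the
    ``TikhonovConfig`` default).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    cohorts = cohort if isinstance(cohort, list) else [cohort]
    covs: list[np.ndarray] = []
    for c in cohorts:
        covs.extend(_subject_covariances(c))
    if len(covs) < 2:
        raise ValueError("lambda optimization needs at least 2 subjects")
    values = np.empty(grid.size)
    for k, lam in enumerate(grid):
        try:
            values[k] = lambda_objective(covs, lam)
        except np.linalg.LinAlgError:
            values[k] = np.nan
    if np.isnan(values).all():
        raise np.linalg.LinAlgError("every grid lambda left a singular regularized covariance")
    # ties (within numerical noise of the minimum) resolve to the smallest
    # lambda; exact equality would miss e.g. the all-identical-subjects case,
    # where the mean-of-identical-matrices roundoff perturbs F by ~1e-16
    finite = np.where(np.isnan(values), np.inf, values)
    fmin = finite.min()
    tol = 1e-9 * max(1.0, abs(fmin))
    best = int(np.flatnonzero(finite <= fmin + tol)[0])
    return float(grid[best]), np.column_stack([grid, values])


def optimize_lambda_refined(
    cohort: RoiTimeSeriesSet | list[RoiTimeSeriesSet],
    grid: np.ndarray | None = None,
    n_refine: int = 100,
) -> tuple[float, np.ndarray]:
    """Two-stage lambda search: coarse log grid, then a linear refinement.

    The refinement spans the coarse grid's neighbors of the minimizer with
    ``n_refine`` linearly spaced points. Returns (lambda*, combined curve).
    """
    coarse_grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    lam0, curve0 = optimize_lambda(cohort, coarse_grid)
    idx = int(np.argmin(np.abs(coarse_grid - lam0)))
    lo = coarse_grid[max(idx - 1, 0)]
    hi = coarse_grid[min(idx + 1, coarse_grid.size - 1)]
    if lo == hi:
        return lam0, curve0
    fine_grid = np.linspace(lo, hi, n_refine)
    _, curve1 = optimize_lambda(cohort, fine_grid)
    curve = np.vstack([curve0, curve1])
    curve = curve[np.argsort(curve[:, 0], kind="stable")]
    finite = np.where(np.isnan(curve[:, 1]), np.inf, curve[:, 1])
    return float(curve[int(np.argmin(finite)), 0]), curve
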