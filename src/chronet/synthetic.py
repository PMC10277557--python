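"""Seeded synthetic cohorts with planted group differences.

The generator emulates the statistical structure the pipeline assumes: two
chronotype groups (16 ECP vs 22 LCP by default), 70 ROIs, 450 timepoints
per scan, and a planted subnetwork whose partial correlations are more
positive in the ECP group. Time series are drawn from zero-mean
multivariate Gaussians defined by per-subject precision matrices: a shared
base precision, minus the effect size on planted off-diagonal entries for
ECP subjects (a more negative precision entry is a more positive partial
correlation), plus an optional per-subject symmetric perturbation.
Positive definiteness is restored by diagonal loading when perturbations or
strong effects require it.

An edge-level fast path samples subject weight matrices directly, skipping
time series, for cheap classifier tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ECP,
    LCP,
    FunctionalNetwork,
    NetworkCohort,
    RoiTimeSeriesSet,
    SubjectSeries,
)
from .networks import partial_correlation

#: minimum eigenvalue required of every generating precision matrix
_PD_FLOOR = 1e-6
#: diagonal-loading increment and retry cap
_LOAD_STEP = 0.05
_LOAD_MAX_TRIES = 100


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``effect_size`` is the shift subtracted from planted off-diagonal
    precision entries for ECP subjects, making the planted partial
    correlations more positive for ECPs (detecting contrast ECP > LCP).
    ``base_partial`` sets the planted partial correlation shared by both
    groups before the shift. For the edge-level fast path,
    ``base_weight`` is the mean edge weight everywhere and ``subject_sd``
    doubles as the edge-noise scale.
    """

    n_ecp: int = 16
    n_lcp: int = 22
    n_rois: int = 70
    n_timepoints: int = 450
    planted_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    effect_size: float = 0.0
    base_partial: float = 0.05
    base_weight: float = 0.1
    subject_sd: float = 0.0
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ecp < 2 or self.n_lcp < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_rois < 2 or self.n_timepoints < 2:
            raise ValueError("need at least 2 ROIs and 2 timepoints")
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("ar1 coefficient must lie in (-1, 1)")
        edges = set()
        for e in self.planted_edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is a self-link")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"planted edge ({i}, {j}) outside 0..{self.n_rois - 1}")
            edges.add((min(i, j), max(i, j)))
        self.planted_edges = frozenset(edges)

    @property
    def n_subjects(self) -> int:
        return self.n_ecp + self.n_lcp

    @property
    def labels(self) -> list[str]:
        return [ECP] * self.n_ecp + [LCP] * self.n_lcp


def random_planted_edges(
    n_rois: int, n_edges: int, seed: int = 0
) -> frozenset[tuple[int, int]]:
    """A seeded random set of distinct off-diagonal ROI pairs."""
    iu, ju = np.triu_indices(n_rois, k=1)
    if n_edges > iu.size:
        raise ValueError(f"requested {n_edges} edges but only {iu.size} pairs exist")
    rng = np.random.default_rng(seed)
    pick = rng.choice(iu.size, size=n_edges, replace=False)
    return frozenset((int(iu[k]), int(ju[k])) for k in pick)


def _ensure_positive_definite(omega: np.ndarray, context: str) -> tuple[np.ndarray, float]:
    """Diagonal-load in fixed increments until the minimum eigenvalue clears the floor.

    Returns (loaded matrix, total loading applied). Raises after the retry
    cap — a pathologically indefinite generating matrix should fail loudly.
    """
    loading = 0.0
    out = omega
    for _ in range(_LOAD_MAX_TRIES + 1):
        min_eig = float(np.linalg.eigvalsh(out)[0])
        if min_eig > _PD_FLOOR:
            return out, loading
        loading += _LOAD_STEP
        out = omega + loading * np.eye(omega.shape[0])
    raise ValueError(
        f"could not restore positive definiteness of {context} after "
        f"{_LOAD_MAX_TRIES} loading increments (total loading {loading:.2f})"
    )


def base_precision(spec: CohortSpec) -> np.ndarray:
    """Shared base precision: identity with planted entries at -base_partial."""
    omega = np.eye(spec.n_rois)
    for i, j in spec.planted_edges:
        omega[i, j] = omega[j, i] = -spec.base_partial
    return omega


def subject_precision(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One subject's generating precision matrix (loaded to PD if needed).

    ECP subjects get ``effect_size`` subtracted on planted entries; a
    symmetric Gaussian perturbation of scale ``subject_sd`` models
    between-subject heterogeneity.
    """
    omega = base_precision(spec)
    if group == ECP and spec.effect_size != 0.0:
        for i, j in spec.planted_edges:
            omega[i, j] -= spec.effect_size
            omega[j, i] = omega[i, j]
    if spec.subject_sd > 0:
        pert = rng.normal(scale=spec.subject_sd, size=omega.shape)
        pert = (pert + pert.T) / 2.0
        np.fill_diagonal(pert, 0.0)
        omega = omega + pert
    return _ensure_positive_definite(omega, f"{group} subject precision")


def planted_partial_correlations(spec: CohortSpec, group: str) -> np.ndarray:
    """Population partial correlations on the planted edges for one group.

    Computed from the (loaded) group-level precision with no subject
    perturbation — the ground truth against which sample estimates are
    checked.
    """
    rng = np.random.default_rng(0)  # unused when subject_sd is ignored
    spec0 = CohortSpec(**{**spec.__dict__, "subject_sd": 0.0})
    omega, _ = subject_precision(spec0, group, rng)
    rho = partial_correlation(omega)
    return np.array([rho[i, j] for i, j in sorted(spec.planted_edges)])


def _sample_series(
    omega: np.ndarray, t: int, rng: np.random.Generator, ar1: float
) -> np.ndarray:
    """Draw T samples from N(0, omega^-1); optional AR(1) innovation mixing."""
    n = omega.shape[0]
    chol = np.linalg.cholesky(omega)
    z = rng.standard_normal((t, n))
    # x = L^-T z has covariance (L L^T)^-1 = omega^-1
    x = np.linalg.solve(chol.T, z.T).T
    if ar1 != 0.0:
        y = np.empty_like(x)
        y[0] = x[0]
        scale = np.sqrt(1.0 - ar1**2)
        for k in range(1, t):
            y[k] = ar1 * y[k - 1] + scale * x[k]
        x = y
    return x


def generate_cohort(spec: CohortSpec) -> RoiTimeSeriesSet:
    """Generate a seeded synthetic cohort of ROI time series.

    Subjects are ordered ECP first, then LCP; ids are e01..e{n_ecp} and
    l01..l{n_lcp}. Identical spec and seed give bit-identical output.
    """
    root = np.random.SeedSequence(entropy=(int(spec.seed), spec.n_subjects))
    child_seeds = root.spawn(spec.n_subjects)
    subjects = []
    for s, (group, seed) in enumerate(zip(spec.labels, child_seeds)):
        rng = np.random.default_rng(seed)
        omega, _ = subject_precision(spec, group, rng)
        series = _sample_series(omega, spec.n_timepoints, rng, spec.ar1)
        prefix, rank = ("e", s) if group == ECP else ("l", s - spec.n_ecp)
        subjects.append(
            SubjectSeries(subject_id=f"{prefix}{rank + 1:02d}", label=group, series=series)
        )
    return RoiTimeSeriesSet(subjects)


def generate_edge_level_cohort(spec: CohortSpec) -> NetworkCohort:
    """Directly sample subject weight matrices (fast path, no time series).

    Every off-diagonal weight is ``base_weight``, plus ``effect_size`` on
    planted edges for ECP subjects, plus symmetric Gaussian noise of scale
    ``subject_sd``, clipped to [-1, 1]; the diagonal is NaN.
    """
    root = np.random.SeedSequence(entropy=(int(spec.seed), spec.n_subjects, 1))
    child_seeds = root.spawn(spec.n_subjects)
    n = spec.n_rois
    mean_lcp = np.full((n, n), spec.base_weight)
    mean_ecp = mean_lcp.copy()
    for i, j in spec.planted_edges:
        mean_ecp[i, j] += spec.effect_size
        mean_ecp[j, i] = mean_ecp[i, j]
    networks = []
    for s, (group, seed) in enumerate(zip(spec.labels, child_seeds)):
        rng = np.random.default_rng(seed)
        w = (mean_ecp if group == ECP else mean_lcp).copy()
        if spec.subject_sd > 0:
            iu, ju = np.triu_indices(n, k=1)
            noise = rng.normal(scale=spec.subject_sd, size=iu.size)
            w[iu, ju] += noise
            w[ju, iu] = w[iu, ju]
        np.clip(w, -1.0, 1.0, out=w)
        np.fill_diagonal(w, np.nan)
        prefix, rank = ("e", s) if group == ECP else ("l", s - spec.n_ecp)
        networks.append(
            FunctionalNetwork(w, subject_id=f"{prefix}{rank + 1:02d}", label=group)
        )
    return NetworkCohort(networks)
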