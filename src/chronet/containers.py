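"""Core in-memory containers shared across the pipeline.

A cohort is an ordered sequence of subjects; each subject carries either a
raw ROI time-series matrix (timepoints x ROIs) or a functional network (a
symmetric partial-correlation adjacency matrix with an undefined diagonal).
Group labels are the chronotype phenotypes: ECP (early circadian phenotype,
"lark") and LCP (late circadian phenotype, "owl").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ECP = "ECP"
LCP = "LCP"
UNCLEAR = "UNCLEAR"
UNKNOWN = "UNKNOWN"

GROUP_LABELS = (ECP, LCP)

#: Tolerance for symmetry checks on adjacency matrices.
SYMMETRY_TOL = 1e-10


@dataclass
class SubjectSeries:
    """One subject's ROI time series (rows = timepoints, columns = ROIs)."""

    subject_id: str
    label: str
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id}: series must be 2-D "
                f"(timepoints x ROIs), got shape {self.series.shape}"
            )
        if not np.isfinite(self.series).all():
            raise ValueError(f"subject {self.subject_id}: series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass
class RoiTimeSeriesSet:
    """An ordered cohort of subjects with raw ROI time series."""

    subjects: list[SubjectSeries]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        n_set = {s.n_rois for s in self.subjects}
        if len(n_set) != 1:
            raise ValueError(f"all subjects must share the same ROI count, got {sorted(n_set)}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, idx: int) -> SubjectSeries:
        return self.subjects[idx]

    @property
    def n_rois(self) -> int:
        return self.subjects[0].n_rois

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subjects]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


@dataclass
class FunctionalNetwork:
    """Symmetric weighted functional network for one subject.

    ``weights`` is N x N with off-diagonal entries in [-1, 1] and the
    leading diagonal set to NaN: self-links are not interpretable under
    partial correlation.
    """

    weights: np.ndarray
    subject_id: str = ""
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=SYMMETRY_TOL, equal_nan=True):
            raise ValueError(f"subject {self.subject_id}: weight matrix is not symmetric")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if np.nanmax(np.abs(off), initial=0.0) > 1.0 + SYMMETRY_TOL:
            raise ValueError(
                f"subject {self.subject_id}: off-diagonal weights exceed [-1, 1]"
            )
        np.fill_diagonal(w, np.nan)
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkCohort:
    """An ordered cohort of functional networks (one per subject)."""

    networks: list[FunctionalNetwork]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("cohort must contain at least one network")
        n_set = {n.n_rois for n in self.networks}
        if len(n_set) != 1:
            raise ValueError(f"all networks must share the same ROI count, got {sorted(n_set)}")
        ids = [n.subject_id for n in self.networks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __getitem__(self, idx: int) -> FunctionalNetwork:
        return self.networks[idx]

    @property
    def n_rois(self) -> int:
        return self.networks[0].n_rois

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.networks]

    @property
    def subject_ids(self) -> list[str]:
        return [n.subject_id for n in self.networks]

    def stack(self) -> np.ndarray:
        """Stack all weight matrices into an (n_subjects, N, N) array."""
        return np.stack([n.weights for n in self.networks])

    def without(self, idx: int) -> "NetworkCohort":
        """Copy of the cohort with subject ``idx`` removed."""
        return NetworkCohort([n for i, n in enumerate(self.networks) if i != idx])


@dataclass
class RoiMetadata:
    """Per-ROI metadata: 1-based index, name, MNI coordinates, network label."""

    indices: np.ndarray  # 1-based, contiguous
    names: list[str]
    coords: np.ndarray  # (N, 3) MNI mm
    networks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.indices)
        if not np.array_equal(self.indices, np.arange(1, n + 1)):
            raise ValueError("ROI indices must be contiguous 1..N")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("ROI coordinates must be finite")
        if len(self.names) != n:
            raise ValueError("names length must match indices")
        if self.networks and len(self.networks) != n:
            raise ValueError("networks length must match indices")

    @property
    def n_rois(self) -> int:
        return len(self.indices)


def validate_group_sizes(labels: Sequence[str], minimum: int = 2) -> tuple[int, int]:
    """Count ECP/LCP labels and enforce a per-group minimum.

    Returns (n_ecp, n_lcp). Raises ValueError if either group is smaller
    than ``minimum`` (two-sample t-tests need at least two per group).
    """
    n_ecp = sum(1 for l in labels if l == ECP)
    n_lcp = sum(1 for l in labels if l == LCP)
    unknown = sorted({l for l in labels if l not in GROUP_LABELS})
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    if n_ecp < minimum or n_lcp < minimum:
        raise ValueError(
            f"need at least {minimum} subjects per group, got {n_ecp} ECP / {n_lcp} LCP"
        )
    return n_ecp, n_lcp
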