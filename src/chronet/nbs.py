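"""Network-based statistic (NBS) with percolation-threshold component selection.

The group contrast is evaluated edge by edge with a one-sided two-sample
t-test, giving a symmetric t-statistic matrix. Thresholding that matrix and
keeping connected components of suprathreshold edges yields "dysconnected
networks" — candidate subnetworks separating the groups. Familywise error
is controlled by permutation: the intensity (sum of edge t-values) of an
observed component is compared against the null distribution of the maximum
component intensity under random relabelings of the subjects.

The percolation threshold is the highest t-threshold at which the
suprathreshold graph still connects every ROI; the component there is the
minimum connected component (MCC). It is computed as the bottleneck (minimum
edge weight) of a maximum spanning tree of the complete t-weighted graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components as _cc

from .containers import ECP, LCP, NetworkCohort, validate_group_sizes

#: Sentinel threshold request: use the percolation threshold.
PERCOLATION = "percolation"

#: t-value sentinel for degenerate (zero pooled variance) edges; can never
#: be suprathreshold.
DEGENERATE_T = -np.inf


class Contrast(Enum):
    """Direction of the one-sided group comparison."""

    ECP_GT_LCP = "ecp-gt-lcp"
    ECP_LT_LCP = "ecp-lt-lcp"

    @property
    def favored(self) -> str:
        """Group whose mean enters the t numerator with a positive sign."""
        return ECP if self is Contrast.ECP_GT_LCP else LCP

    def flipped(self) -> "Contrast":
        return Contrast.ECP_LT_LCP if self is Contrast.ECP_GT_LCP else Contrast.ECP_GT_LCP


@dataclass
class TStatMatrix:
    """Symmetric matrix of one-sided two-sample t-statistics.

    The diagonal is NaN; degenerate edges (zero pooled variance) carry
    -inf so they can never exceed a finite threshold.
    """

    values: np.ndarray
    n_a: int
    n_b: int
    contrast: Contrast

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"t-matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("t-matrix must be symmetric")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class PermutationConfig:
    """Permutation-test settings for familywise-error p-values."""

    n_perm: int = 5000
    seed: int = 0
    #: count ties and add-one correction ((#{null >= obs} + 1)/(n+1)) if True;
    #: default is the plain strictly-greater fraction.
    conservative: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class DysconnectedNetwork:
    """A connected suprathreshold component from a thresholded t-matrix.

    ``edges`` maps unordered ROI index pairs (i < j, 0-based) to their
    t-values. Intensity is the sum of edge t-values — the component
    statistic compared against the permutation null.
    """

    edges: dict[tuple[int, int], float]
    threshold: float
    p_value: float | None = None
    label_context: str | None = None
    subject_context: str | None = None

    def __post_init__(self) -> None:
        for (i, j), t in self.edges.items():
            if i >= j:
                raise ValueError(f"edge ({i}, {j}) must have i < j")
            if not (t >= self.threshold):
                raise ValueError(
                    f"edge ({i}, {j}) has t={t} below threshold {self.threshold}"
                )

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(itertools.chain.from_iterable(self.edges))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def intensity(self) -> float:
        return float(sum(self.edges.values()))

    def min_node(self) -> int:
        return min(self.nodes)


def _as_stack_and_labels(
    cohort: NetworkCohort | np.ndarray, labels: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(cohort, NetworkCohort):
        stack = cohort.stack()
        lab = list(labels) if labels is not None else cohort.labels
    else:
        stack = np.asarray(cohort, dtype=float)
        if labels is None:
            raise ValueError("labels are required when passing a raw weight stack")
        lab = list(labels)
    if stack.shape[0] != len(lab):
        raise ValueError(f"{stack.shape[0]} networks but {len(lab)} labels")
    return stack, lab


def _edge_matrix(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a (M, N, N) stack to (M, E) over the strict upper triangle."""
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return stack[:, iu, ju], iu, ju


def _pooled_t(
    w: np.ndarray, first: np.ndarray, equal_var: bool = True
) -> np.ndarray:
    """Vectorized pooled-variance two-sample t over edge columns.

    ``w`` is (M, E); ``first`` is a boolean membership mask (P, M) or (M,)
    for the group whose mean enters with positive sign. Returns (P, E) or
    (E,). Zero-pooled-variance edges get -inf.
    """
    one_d = first.ndim == 1
    a = np.atleast_2d(first).astype(float)
    m = w.shape[0]
    n_a = a.sum(axis=1)
    n_b = m - n_a
    s1a = a @ w
    s2a = a @ (w * w)
    s1 = w.sum(axis=0)
    s2 = (w * w).sum(axis=0)
    s1b = s1[None, :] - s1a
    s2b = s2[None, :] - s2a
    mean_a = s1a / n_a[:, None]
    mean_b = s1b / n_b[:, None]
    ssa = s2a - n_a[:, None] * mean_a**2
    ssb = s2b - n_b[:, None] * mean_b**2
    dof = (n_a + n_b - 2)[:, None]
    if equal_var:
        sp2 = (ssa + ssb) / dof
        se = np.sqrt(sp2 * (1.0 / n_a[:, None] + 1.0 / n_b[:, None]))
    else:
        va = ssa / (n_a[:, None] - 1)
        vb = ssb / (n_b[:, None] - 1)
        se = np.sqrt(va / n_a[:, None] + vb / n_b[:, None])
    # roundoff can push sums-of-squares fractionally negative
    se = np.where(se > 0, se, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    t = np.where(se == 0, DEGENERATE_T, t)
    return t[0] if one_d else t


def edge_t_statistics(
    cohort: NetworkCohort | np.ndarray,
    labels: Sequence[str] | None = None,
    contrast: Contrast = Contrast.ECP_GT_LCP,
    equal_var: bool = True,
) -> TStatMatrix:
    """Edgewise one-sided two-sample t-statistics under a group contrast.

    The numerator is (mean of the contrast's favored group) minus (mean of
    the other group); pooled-variance Student t with n_A + n_B - 2 degrees
    of freedom by default (``equal_var=False`` switches to Welch). Edges
    with zero pooled variance carry -inf and are logged as degenerate.
    """
    stack, lab = _as_stack_and_labels(cohort, labels)
    n_ecp, n_lcp = validate_group_sizes(lab)
    w, iu, ju = _edge_matrix(stack)
    first = np.array([l == contrast.favored for l in lab])
    t_edges = _pooled_t(w, first, equal_var=equal_var)
    n = stack.shape[1]
    values = np.full((n, n), np.nan)
    values[iu, ju] = t_edges
    values[ju, iu] = t_edges
    n_a = n_ecp if contrast.favored == ECP else n_lcp
    n_b = n_ecp + n_lcp - n_a
    return TStatMatrix(values=values, n_a=n_a, n_b=n_b, contrast=contrast)


def _components_from_mask(
    iu: np.ndarray, ju: np.ndarray, mask: np.ndarray, n: int
) -> tuple[np.ndarray, int, np.ndarray]:
    """Connected-component labels for the suprathreshold edge graph.

    Returns (edge component ids, number of components, node labels).
    """
    ei = iu[mask]
    ej = ju[mask]
    data = np.ones(ei.size)
    g = scipy.sparse.coo_matrix((data, (ei, ej)), shape=(n, n))
    n_comp, node_labels = _cc(g, directed=False)
    return node_labels[ei], n_comp, node_labels


def suprathreshold_components(
    tmat: TStatMatrix, tau: float
) -> list[DysconnectedNetwork]:
    """All connected components of edges with t >= tau (inclusive rule).

    Each component with at least one edge becomes a candidate dysconnected
    network with its p-value unset. Returns an empty list when no edge
    survives.
    """
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    n = tmat.n_rois
    iu, ju = np.triu_indices(n, k=1)
    t_edges = tmat.values[iu, ju]
    mask = t_edges >= tau
    if not mask.any():
        return []
    edge_comp, _, _ = _components_from_mask(iu, ju, mask, n)
    out = []
    for comp_id in np.unique(edge_comp):
        sel = mask.copy()
        sel[mask] = edge_comp == comp_id
        edges = {
            (int(i), int(j)): float(t)
            for i, j, t in zip(iu[sel], ju[sel], t_edges[sel])
        }
        out.append(DysconnectedNetwork(edges=edges, threshold=tau))
    out.sort(key=lambda d: d.min_node())
    return out


def percolation_threshold(
    tmat: TStatMatrix,
) -> tuple[float, DysconnectedNetwork]:
    """Percolation threshold and minimum connected component (MCC).

    The percolation threshold tau* is the largest t-value such that the
    graph of edges with t >= tau* connects all N ROIs: the bottleneck
    (minimum) edge weight of a maximum spanning tree of the complete
    t-weighted graph. The MCC is the single suprathreshold component at
    tau*, spanning every ROI; any strictly larger threshold isolates at
    least one ROI.
    """
    n = tmat.n_rois
    if n < 2:
        raise ValueError("need at least 2 ROIs")
    iu, ju = np.triu_indices(n, k=1)
    t_edges = tmat.values[iu, ju]
    finite = np.isfinite(t_edges)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(
        zip(iu[finite].tolist(), ju[finite].tolist(), t_edges[finite].tolist())
    )
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len)
        isolated = sorted(comps[0])
        raise ValueError(
            "graph of finite-t edges is disconnected (degenerate edges "
            f"isolate ROIs {isolated}); percolation threshold is undefined"
        )
    mst = nx.maximum_spanning_tree(g, weight="weight")
    tau = min(d["weight"] for _, _, d in mst.edges(data=True))
    comps = suprathreshold_components(tmat, tau)
    assert len(comps) == 1 and comps[0].n_nodes == n, "MCC must span all ROIs"
    mcc = comps[0]
    return float(tau), mcc


def verify_percolation(tmat: TStatMatrix, tau: float) -> bool:
    """True if the next distinct t-value above tau disconnects the graph."""
    iu, ju = np.triu_indices(tmat.n_rois, k=1)
    t_edges = tmat.values[iu, ju]
    above = t_edges[np.isfinite(t_edges) & (t_edges > tau)]
    if above.size == 0:
        return True  # no stricter threshold exists
    nxt = above.min()
    mask = t_edges >= nxt
    _, _, node_labels = _components_from_mask(iu, ju, mask, tmat.n_rois)
    return len(np.unique(node_labels)) > 1


def _iter_first_masks(
    labels: Sequence[str], favored: str, cfg: PermutationConfig
) -> tuple[np.ndarray, int]:
    """Boolean membership masks (P, M) for the favored group under permutation.

    Permutes the full label vector with group sizes preserved. Enumerates
    all distinct assignments exhaustively when their number does not exceed
    n_perm; otherwise draws n_perm uniform random permutations (with
    replacement over assignments), seeded.
    """
    lab = np.asarray(labels)
    m = lab.size
    k = int((lab == favored).sum())
    n_distinct = math.comb(m, k)
    if n_distinct <= cfg.n_perm:
        masks = np.zeros((n_distinct, m), dtype=bool)
        for r, combo in enumerate(itertools.combinations(range(m), k)):
            masks[r, list(combo)] = True
        return masks, n_distinct
    rng = np.random.default_rng(cfg.seed)
    masks = np.zeros((cfg.n_perm, m), dtype=bool)
    base = lab == favored
    for r in range(cfg.n_perm):
        masks[r] = base[rng.permutation(m)]
    return masks, cfg.n_perm


def max_component_intensity(
    t_row: np.ndarray, iu: np.ndarray, ju: np.ndarray, n: int, tau: float
) -> float:
    """Maximum component intensity of one thresholded edge-statistic vector.

    Returns 0.0 when no edge is suprathreshold (the null contributes a
    zero-intensity outcome).
    """
    mask = t_row >= tau
    if not mask.any():
        return 0.0
    edge_comp, n_comp, _ = _components_from_mask(iu, ju, mask, n)
    sums = np.bincount(edge_comp, weights=t_row[mask], minlength=n_comp)
    present = np.unique(edge_comp)
    return float(sums[present].max())


def null_max_intensities(
    cohort: NetworkCohort | np.ndarray,
    labels: Sequence[str] | None,
    contrast: Contrast,
    tau: float,
    cfg: PermutationConfig,
    equal_var: bool = True,
) -> np.ndarray:
    """Null distribution of the maximum component intensity at threshold tau.

    Each permutation relabels the full cohort (group sizes preserved),
    recomputes the edgewise t-statistics under the same contrast, thresholds
    at the same tau, and records the largest component intensity (0 when no
    edge survives).
    """
    stack, lab = _as_stack_and_labels(cohort, labels)
    w, iu, ju = _edge_matrix(stack)
    n = stack.shape[1]
    masks, n_used = _iter_first_masks(lab, contrast.favored, cfg)
    out = np.empty(n_used)
    # chunk the vectorized t computation to bound memory
    chunk = max(1, int(2_000_000 // max(w.shape[1], 1)))
    for lo in range(0, n_used, chunk):
        t_block = _pooled_t(w, masks[lo : lo + chunk], equal_var=equal_var)
        for r, t_row in enumerate(t_block):
            out[lo + r] = max_component_intensity(t_row, iu, ju, n, tau)
    return out


def pvalue_from_null(
    observed_intensity: float, null: np.ndarray, conservative: bool = False
) -> float:
    """FWE p-value: fraction of null maxima exceeding the observed intensity."""
    if conservative:
        return float(((null >= observed_intensity).sum() + 1) / (null.size + 1))
    return float((null > observed_intensity).sum() / null.size)


def permutation_pvalue(
    cohort: NetworkCohort | np.ndarray,
    labels: Sequence[str] | None,
    contrast: Contrast,
    tau: float,
    observed: DysconnectedNetwork,
    cfg: PermutationConfig,
    equal_var: bool = True,
) -> float:
    """FWE-corrected p-value of an observed dysconnected network."""
    null = null_max_intensities(cohort, labels, contrast, tau, cfg, equal_var=equal_var)
    return pvalue_from_null(observed.intensity, null, cfg.conservative)


def select_component(
    candidates: Sequence[DysconnectedNetwork],
) -> DysconnectedNetwork | None:
    """Pick one dysconnected network from candidates with p-values set.

    Smallest FWE p-value wins; ties resolve to the most edges, then
    deterministically to the component containing the lowest ROI index.
    Returns None for an empty candidate list (no component).
    """
    if not candidates:
        return None
    for c in candidates:
        if c.p_value is None:
            raise ValueError("all candidates must carry a p-value")
    return min(candidates, key=lambda c: (c.p_value, -c.n_edges, c.min_node()))


def run_nbs(
    cohort: NetworkCohort | np.ndarray,
    labels: Sequence[str] | None = None,
    contrast: Contrast = Contrast.ECP_GT_LCP,
    threshold: float | str = PERCOLATION,
    cfg: PermutationConfig | None = None,
    equal_var: bool = True,
    label_context: str | None = None,
    subject_context: str | None = None,
) -> DysconnectedNetwork | None:
    """Full NBS pass: t-matrix, components, permutation p-values, selection.

    With ``threshold=PERCOLATION`` the single MCC at the percolation
    threshold is returned with its p-value. With a fixed numeric threshold
    all suprathreshold components are tested against one shared null
    distribution of the maximum component intensity, and the selection rule
    (smallest p, then most edges) picks the winner; returns None when no
    edge survives.
    """
    cfg = cfg or PermutationConfig()
    stack, lab = _as_stack_and_labels(cohort, labels)
    tmat = edge_t_statistics(stack, lab, contrast, equal_var=equal_var)
    if threshold == PERCOLATION:
        tau, mcc = percolation_threshold(tmat)
        candidates = [mcc]
    else:
        tau = float(threshold)
        candidates = suprathreshold_components(tmat, tau)
        if not candidates:
            return None
    null = null_max_intensities(stack, lab, contrast, tau, cfg, equal_var=equal_var)
    for c in candidates:
        c.p_value = pvalue_from_null(c.intensity, null, cfg.conservative)
        c.label_context = label_context
        c.subject_context = subject_context
    return select_component(candidates)
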