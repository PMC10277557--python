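"""Leave-one-out evaluation, threshold/significance sweeps, and stability.

Outcome metrics follow the abstention-aware conventions: accuracy is the
fraction of all subjects given their true label, misclassification the
fraction given a wrong definite label, and unclear the abstention fraction
— the three always sum to one. Sensitivity is the fraction of true ECPs
assigned ECP, specificity the fraction of true LCPs assigned LCP, and
balanced accuracy their mean, so the 16-vs-22 group imbalance cannot bias
the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierConfig,
    build_quad,
    classify_subject,
    decide_from_quad,
)
from .containers import ECP, LCP, UNCLEAR, NetworkCohort, validate_group_sizes
from .nbs import (
    DysconnectedNetwork,
    edge_t_statistics,
    percolation_threshold,
)

NA = "NA"
DEFINITE = (ECP, LCP)


@dataclass
class EvaluationSummary:
    """Outcome fractions and per-subject detail for one LOO evaluation."""

    accuracy: float
    misclassification: float
    unclear: float
    sensitivity: float
    specificity: float
    per_subject: pd.DataFrame
    step_counts: pd.DataFrame

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def summarize_outcomes(
    true_labels: Sequence[str],
    assigned_labels: Sequence[str],
    deciding_steps: Sequence[int | None] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> EvaluationSummary:
    """Compute the outcome metrics from per-subject true/assigned labels.

    Entries whose assigned label is NA are excluded entirely (e.g. a
    subject absent from one scanning session).
    """
    true = list(true_labels)
    assigned = list(assigned_labels)
    if len(true) != len(assigned):
        raise ValueError("label sequences must have equal length")
    steps = list(deciding_steps) if deciding_steps is not None else [None] * len(true)
    ids = list(subject_ids) if subject_ids is not None else [str(i + 1) for i in range(len(true))]
    keep = [i for i, a in enumerate(assigned) if a != NA]
    if not keep:
        raise ValueError("no valid (non-NA) entries to summarize")
    true = [true[i] for i in keep]
    assigned = [assigned[i] for i in keep]
    steps = [steps[i] for i in keep]
    ids = [ids[i] for i in keep]
    n = len(true)
    n_correct = sum(1 for t, a in zip(true, assigned) if a == t)
    n_wrong = sum(1 for t, a in zip(true, assigned) if a in DEFINITE and a != t)
    n_unclear = sum(1 for a in assigned if a not in DEFINITE)
    n_ecp = sum(1 for t in true if t == ECP)
    n_lcp = sum(1 for t in true if t == LCP)
    sens = (
        sum(1 for t, a in zip(true, assigned) if t == ECP and a == ECP) / n_ecp
        if n_ecp else np.nan
    )
    spec = (
        sum(1 for t, a in zip(true, assigned) if t == LCP and a == LCP) / n_lcp
        if n_lcp else np.nan
    )
    per_subject = pd.DataFrame(
        {
            "subject_id": ids,
            "true_label": true,
            "assigned_label": assigned,
            "deciding_step": steps,
        }
    )
    counts = (
        per_subject[per_subject.deciding_step.notna()]
        .groupby(["deciding_step", "true_label"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[ECP, LCP], fill_value=0)
    )
    counts.index.name = "step"
    return EvaluationSummary(
        accuracy=n_correct / n,
        misclassification=n_wrong / n,
        unclear=n_unclear / n,
        sensitivity=float(sens),
        specificity=float(spec),
        per_subject=per_subject,
        step_counts=counts,
    )


def evaluate_loo(cohort: NetworkCohort, cfg: ClassifierConfig) -> EvaluationSummary:
    """Leave-one-out evaluation: classify every subject against the rest."""
    validate_group_sizes(cohort.labels, minimum=3)
    results = [classify_subject(cohort, m, cfg) for m in range(len(cohort))]
    return summarize_outcomes(
        cohort.labels,
        [r.assigned_label for r in results],
        [r.deciding_step for r in results],
        cohort.subject_ids,
    )


@dataclass
class SweepResult:
    """Per-grid-value evaluation summaries for a parameter sweep."""

    parameter: str  # "threshold" or "alpha"
    grid: np.ndarray
    summaries: list[EvaluationSummary]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        if len(self.summaries) != self.grid.size:
            raise ValueError("one summary per grid value required")

    def table(self) -> pd.DataFrame:
        """Stacked outcome fractions per grid value."""
        return pd.DataFrame(
            {
                self.parameter: self.grid,
                "accuracy": [s.accuracy for s in self.summaries],
                "misclassification": [s.misclassification for s in self.summaries],
                "unclear": [s.unclear for s in self.summaries],
                "balanced_accuracy": [s.balanced_accuracy for s in self.summaries],
            }
        )


def default_threshold_grid() -> np.ndarray:
    """t-threshold grid 0 to 4.5 in steps of 0.01."""
    return np.round(np.arange(0.0, 4.5 + 1e-9, 0.01), 10)


def default_alpha_grid() -> np.ndarray:
    """Significance-threshold grid 0 to 1 in steps of 0.01."""
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)


def sweep_threshold(
    cohort: NetworkCohort,
    cfg: ClassifierConfig,
    grid: np.ndarray | None = None,
) -> SweepResult:
    """Reduced-classifier LOO evaluation at every fixed t-threshold.

    One shared threshold is applied to both labelings of each held-out
    subject. The observed and permuted t-matrices depend on the labeling
    but not on the threshold, so they are computed once per subject and
    re-thresholded across the grid; results at each grid value match
    ``classify_subject`` run at that fixed threshold with the same seed.
    Also records the correct-labeling percolation threshold (the value the
    adaptive classifier would have used).
    """
    from .classifier import LabeledNetworkQuad, subject_seed
    from .nbs import (
        _edge_matrix,
        _iter_first_masks,
        _pooled_t,
        PermutationConfig,
        max_component_intensity,
        pvalue_from_null,
        select_component,
        suprathreshold_components,
    )

    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    validate_group_sizes(cohort.labels, minimum=3)
    stack = cohort.stack()
    w, iu, ju = _edge_matrix(stack)
    n = stack.shape[1]
    per_tau: list[list[tuple[str, int | None]]] = [[] for _ in grid]
    for m in range(len(cohort)):
        seeds = [
            int(c.generate_state(1)[0] % (2**31))
            for c in subject_seed(cfg.seed, m).spawn(4)
        ]
        nets_by_labeling = []
        for hyp, seed in ((ECP, seeds[0]), (LCP, seeds[1])):
            labels = list(cohort.labels)
            labels[m] = hyp
            tmat = edge_t_statistics(stack, labels, cfg.contrast,
                                     equal_var=cfg.equal_var)
            pcfg = PermutationConfig(n_perm=cfg.n_perm, seed=seed,
                                     conservative=cfg.conservative_p)
            masks, _ = _iter_first_masks(labels, cfg.contrast.favored, pcfg)
            t_null = _pooled_t(w, masks, equal_var=cfg.equal_var)
            per_tau_net = []
            for tau in grid:
                cands = suprathreshold_components(tmat, float(tau))
                if not cands:
                    per_tau_net.append(None)
                    continue
                null = np.array([
                    max_component_intensity(row, iu, ju, n, float(tau))
                    for row in t_null
                ])
                for c in cands:
                    c.p_value = pvalue_from_null(c.intensity, null,
                                                 cfg.conservative_p)
                per_tau_net.append(select_component(cands))
            nets_by_labeling.append(per_tau_net)
        for k, tau in enumerate(grid):
            net_e, net_l = nets_by_labeling[0][k], nets_by_labeling[1][k]
            quad = LabeledNetworkQuad(
                t_E=float(tau), t_L=float(tau),
                net_E_tE=net_e, net_L_tL=net_l,
                net_E_tL=net_e, net_L_tE=net_l,
            )
            quad._cross_done = True
            label, step = decide_from_quad(quad, cfg.alpha, reduced=True)
            per_tau[k].append((label, step))
    summaries = [
        summarize_outcomes(
            cohort.labels,
            [a for a, _ in res],
            [s for _, s in res],
            cohort.subject_ids,
        )
        for res in per_tau
    ]
    tmat = edge_t_statistics(stack, cohort.labels, cfg.contrast,
                             equal_var=cfg.equal_var)
    tau_star, _ = percolation_threshold(tmat)
    return SweepResult(
        parameter="threshold", grid=grid, summaries=summaries,
        extra={"correct_labeling_percolation_threshold": tau_star},
    )


def materialized_quads(
    cohort: NetworkCohort, cfg: ClassifierConfig
) -> list:
    """Fully materialized four-network quads for every subject.

    Permutation p-values do not depend on alpha, so one materialization
    serves an entire significance-threshold sweep.
    """
    quads = []
    for m in range(len(cohort)):
        q = build_quad(cohort, m, cfg)
        q.ensure_cross()
        quads.append(q)
    return quads


def sweep_alpha(
    cohort: NetworkCohort,
    cfg: ClassifierConfig,
    grid: np.ndarray | None = None,
    quads: list | None = None,
) -> SweepResult:
    """LOO evaluation across significance thresholds with cached p-values.

    At alpha = 0 no network is significant, so every subject is UNCLEAR;
    above the largest of all subjects' four p-values the outcome fractions
    are constant.
    """
    grid = default_alpha_grid() if grid is None else np.asarray(grid, dtype=float)
    if quads is None:
        quads = materialized_quads(cohort, cfg)
    reduced = not cfg.percolation_mode
    summaries = []
    for alpha in grid:
        assigned, steps = [], []
        for q in quads:
            label, step = decide_from_quad(q, float(alpha), reduced=reduced)
            assigned.append(label)
            steps.append(step)
        summaries.append(
            summarize_outcomes(cohort.labels, assigned, steps, cohort.subject_ids)
        )
    return SweepResult(parameter="alpha", grid=grid, summaries=summaries)


@dataclass
class StabilityTable:
    """Per-removed-subject LOO summaries over the remaining N-1 subjects."""

    rows: pd.DataFrame  # indexed by removed subject_id
    summaries: dict[str, EvaluationSummary]

    def column_means(self) -> pd.Series:
        return self.rows[
            ["accuracy", "unclear", "misclassification", "balanced_accuracy"]
        ].mean()


def stability_analysis(cohort: NetworkCohort, cfg: ClassifierConfig) -> StabilityTable:
    """Leave-one-subject-out stability: drop each subject, re-run LOO.

    Each removed subject yields a partial dataset of N-1 subjects whose
    full LOO evaluation forms one table row; large deviations of a row from
    the column means flag influential subjects.
    """
    validate_group_sizes(cohort.labels, minimum=4)
    records, summaries = [], {}
    for r in range(len(cohort)):
        sid = cohort.subject_ids[r]
        summary = evaluate_loo(cohort.without(r), cfg)
        summaries[sid] = summary
        records.append(
            {
                "removed_subject": sid,
                "accuracy": summary.accuracy,
                "unclear": summary.unclear,
                "misclassification": summary.misclassification,
                "balanced_accuracy": summary.balanced_accuracy,
            }
        )
    rows = pd.DataFrame.from_records(records).set_index("removed_subject")
    return StabilityTable(rows=rows, summaries=summaries)


def percent_definite(labels_column: Sequence[str]) -> float:
    """Percentage of non-NA entries assigned a definite (ECP/LCP) label.

    Accepts the abbreviated UNC token as well as UNCLEAR. Rounded to one
    decimal place, matching reporting convention.
    """
    vals = [str(v) for v in labels_column]
    valid = [v for v in vals if v != NA]
    if not valid:
        raise ValueError("all entries are NA")
    allowed = {ECP, LCP, UNCLEAR, "UNC"}
    unknown = sorted(set(valid) - allowed)
    if unknown:
        raise ValueError(f"unknown label tokens: {unknown}")
    definite = sum(1 for v in valid if v in DEFINITE)
    return round(100.0 * definite / len(valid), 1)


@dataclass
class DegreeSummary:
    """Node-degree summary of a dysconnected network over a full parcellation."""

    mean_degree: float
    sd_degree: float
    max_degree: int
    argmax_nodes: list[int]  # 0-based node indices attaining the maximum


def network_degree_summary(net: DysconnectedNetwork, n_total: int) -> DegreeSummary:
    """Degree statistics over ALL ``n_total`` parcellation nodes.

    Nodes untouched by the network have degree zero, so the mean degree is
    2 * n_edges / n_total. The standard deviation uses the population
    (divide-by-N) convention.
    """
    if n_total < net.n_nodes:
        raise ValueError("n_total smaller than the number of nodes touched")
    degrees = np.zeros(n_total, dtype=int)
    for i, j in net.edges:
        degrees[i] += 1
        degrees[j] += 1
    max_d = int(degrees.max())
    return DegreeSummary(
        mean_degree=float(degrees.mean()),
        sd_degree=float(degrees.std()),
        max_degree=max_d,
        argmax_nodes=[int(i) for i in np.flatnonzero(degrees == max_d)],
    )
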