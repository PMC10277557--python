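"""Three-step four-network chronotype classifier for a held-out subject.

The held-out subject m is provisionally labeled ECP and the NBS pipeline is
run on the full cohort, giving the percolation threshold t_E and the MCC
E_tE; likewise labeling m LCP gives t_L and L_tL. Two cross networks —
E_tL (m labeled ECP, thresholded at t_L) and L_tE (m labeled LCP,
thresholded at t_E) — complete the quad. The decision proceeds in three
steps: (1) significance of E_tE vs L_tL; (2) significance of the cross
networks; (3) edge-count comparisons at matched thresholds. A subject that
no step can decide is labeled UNCLEAR.

With a single preselected threshold tau (t_E = t_L = tau) the classifier
reduces to a significance check on the two labelings followed by an
edge-count comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .containers import ECP, LCP, UNCLEAR, NetworkCohort, validate_group_sizes
from .nbs import (
    PERCOLATION,
    Contrast,
    DysconnectedNetwork,
    PermutationConfig,
    TStatMatrix,
    edge_t_statistics,
    null_max_intensities,
    percolation_threshold,
    pvalue_from_null,
    select_component,
    suprathreshold_components,
)

CONTINUE = "CONTINUE"


@dataclass
class ClassifierConfig:
    """Settings for the held-out-subject classifier.

    ``threshold`` is either the PERCOLATION sentinel (the full three-step
    classifier with per-labeling percolation thresholds) or a fixed numeric
    t-threshold (the reduced classifier).
    """

    contrast: Contrast = Contrast.ECP_GT_LCP
    alpha: float = 0.05
    threshold: float | str = PERCOLATION
    n_perm: int = 5000
    seed: int = 0
    conservative_p: bool = False
    equal_var: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.threshold != PERCOLATION:
            self.threshold = float(self.threshold)

    @property
    def percolation_mode(self) -> bool:
        return self.threshold == PERCOLATION


def subject_seed(base_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Deterministic per-subject seed so LOO results are order-independent."""
    return np.random.SeedSequence(entropy=(int(base_seed), int(subject_index)))


@dataclass
class LabeledNetworkQuad:
    """The four dysconnected networks from two labelings x two thresholds.

    ``net_E_tE``/``net_L_tL`` are the MCCs at each labeling's own
    percolation threshold; the cross networks ``net_E_tL``/``net_L_tE`` are
    materialized lazily (permutation testing dominates runtime and step one
    often decides). A network may be None (no suprathreshold component),
    which counts as non-significant with zero edges. In fixed-threshold
    mode net_E_tE and net_E_tL alias one object, as do net_L_tL and
    net_L_tE.
    """

    t_E: float
    t_L: float
    net_E_tE: DysconnectedNetwork | None
    net_L_tL: DysconnectedNetwork | None
    net_E_tL: DysconnectedNetwork | None = None
    net_L_tE: DysconnectedNetwork | None = None
    _cross_builder: Callable[[], tuple] | None = None
    _cross_done: bool = False

    def ensure_cross(self) -> None:
        """Materialize the cross networks (idempotent)."""
        if self._cross_done:
            return
        if self._cross_builder is not None:
            self.net_E_tL, self.net_L_tE = self._cross_builder()
        self._cross_done = True


def _significant(net: DysconnectedNetwork | None, alpha: float) -> bool:
    """A missing component is never significant; otherwise p < alpha."""
    return net is not None and net.p_value is not None and net.p_value < alpha


def _n_edges(net: DysconnectedNetwork | None) -> int:
    return 0 if net is None else net.n_edges


def classify_step1(
    net_E_tE: DysconnectedNetwork | None,
    net_L_tL: DysconnectedNetwork | None,
    alpha: float,
) -> str:
    """Significance of the two own-threshold MCCs.

    Exactly one significant -> that label; neither -> UNCLEAR; both ->
    CONTINUE to step two.
    """
    sig_e = _significant(net_E_tE, alpha)
    sig_l = _significant(net_L_tL, alpha)
    if sig_e and sig_l:
        return CONTINUE
    if sig_e:
        return ECP
    if sig_l:
        return LCP
    return UNCLEAR


def classify_step2(
    net_E_tL: DysconnectedNetwork | None,
    net_L_tE: DysconnectedNetwork | None,
    alpha: float,
) -> str:
    """Same decision table as step one, over the cross networks."""
    return classify_step1(net_E_tL, net_L_tE, alpha)


def classify_step3(quad: LabeledNetworkQuad) -> str:
    """Edge-count comparisons at matched thresholds.

    Comparison A: |E_tE| vs |L_tE| (both at t_E); comparison B: |E_tL| vs
    |L_tL| (both at t_L). Both favoring the same label decides it; any
    conflict or exact tie is UNCLEAR.
    """
    a = np.sign(_n_edges(quad.net_E_tE) - _n_edges(quad.net_L_tE))
    b = np.sign(_n_edges(quad.net_E_tL) - _n_edges(quad.net_L_tL))
    if a > 0 and b > 0:
        return ECP
    if a < 0 and b < 0:
        return LCP
    return UNCLEAR


@dataclass
class ClassifierResult:
    """Outcome of classifying one held-out subject."""

    subject_id: str
    assigned_label: str
    deciding_step: int | None
    quad: LabeledNetworkQuad
    alpha: float
    contrast: Contrast


def _hypothetical_labels(cohort: NetworkCohort, m: int, as_label: str) -> list[str]:
    labels = list(cohort.labels)
    labels[m] = as_label
    return labels


def build_quad(
    cohort: NetworkCohort,
    m: int,
    cfg: ClassifierConfig,
) -> LabeledNetworkQuad:
    """Construct the four-network quad for held-out subject ``m``.

    In percolation mode the two own-threshold MCCs are computed eagerly
    with their permutation p-values; the cross networks are attached as a
    lazy builder. In fixed-threshold mode both labelings are thresholded at
    the same tau and the pairs alias each other. The held-out subject's
    hypothesized label joins the permutation vector like any other subject.
    """
    labels_e = _hypothetical_labels(cohort, m, ECP)
    labels_l = _hypothetical_labels(cohort, m, LCP)
    for lab in (labels_e, labels_l):
        validate_group_sizes(lab)
    stack = cohort.stack()
    sid = cohort.subject_ids[m]
    ss = subject_seed(cfg.seed, m)
    # fixed spawn order keeps determinism independent of lazy evaluation
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    pcfg = lambda s: PermutationConfig(  # noqa: E731
        n_perm=cfg.n_perm, seed=s, conservative=cfg.conservative_p
    )

    tmat_e = edge_t_statistics(stack, labels_e, cfg.contrast, equal_var=cfg.equal_var)
    tmat_l = edge_t_statistics(stack, labels_l, cfg.contrast, equal_var=cfg.equal_var)

    def nbs_at(
        tmat: TStatMatrix, labels: list[str], tau: float, seed: int, ctx: str
    ) -> DysconnectedNetwork | None:
        cands = suprathreshold_components(tmat, tau)
        if not cands:
            return None
        null = null_max_intensities(
            stack, labels, cfg.contrast, tau, pcfg(seed), equal_var=cfg.equal_var
        )
        for c in cands:
            c.p_value = pvalue_from_null(c.intensity, null, cfg.conservative_p)
            c.label_context = ctx
            c.subject_context = sid
        return select_component(cands)

    if cfg.percolation_mode:
        t_e, _ = percolation_threshold(tmat_e)
        t_l, _ = percolation_threshold(tmat_l)
        net_e_te = nbs_at(tmat_e, labels_e, t_e, seeds[0], "E")
        net_l_tl = nbs_at(tmat_l, labels_l, t_l, seeds[1], "L")

        def cross() -> tuple:
            return (
                nbs_at(tmat_e, labels_e, t_l, seeds[2], "E"),
                nbs_at(tmat_l, labels_l, t_e, seeds[3], "L"),
            )

        return LabeledNetworkQuad(
            t_E=t_e, t_L=t_l, net_E_tE=net_e_te, net_L_tL=net_l_tl,
            _cross_builder=cross,
        )

    tau = float(cfg.threshold)
    net_e = nbs_at(tmat_e, labels_e, tau, seeds[0], "E")
    net_l = nbs_at(tmat_l, labels_l, tau, seeds[1], "L")
    quad = LabeledNetworkQuad(
        t_E=tau, t_L=tau,
        net_E_tE=net_e, net_L_tL=net_l,
        net_E_tL=net_e, net_L_tE=net_l,
    )
    quad._cross_done = True
    return quad


def decide_from_quad(
    quad: LabeledNetworkQuad, alpha: float, reduced: bool = False
) -> tuple[str, int | None]:
    """Apply the decision rules to a quad; returns (label, deciding step).

    The reduced (shared-threshold) form skips step two: significance of the
    two aliased networks (recorded as step 1), then the edge-count
    comparison (step 3). UNCLEAR from a "neither significant" branch
    records that step; UNCLEAR from a step-3 conflict or tie records no
    step (exhaustion).
    """
    if reduced:
        outcome = classify_step1(quad.net_E_tE, quad.net_L_tL, alpha)
        if outcome != CONTINUE:
            return outcome, 1
        label = classify_step3(quad)
        return label, (3 if label != UNCLEAR else None)

    outcome = classify_step1(quad.net_E_tE, quad.net_L_tL, alpha)
    if outcome != CONTINUE:
        return outcome, 1
    quad.ensure_cross()
    outcome = classify_step2(quad.net_E_tL, quad.net_L_tE, alpha)
    if outcome != CONTINUE:
        return outcome, 2
    label = classify_step3(quad)
    return label, (3 if label != UNCLEAR else None)


def classify_subject(
    cohort: NetworkCohort, m: int, cfg: ClassifierConfig
) -> ClassifierResult:
    """Classify held-out subject ``m`` against the rest of the cohort."""
    quad = build_quad(cohort, m, cfg)
    label, step = decide_from_quad(quad, cfg.alpha, reduced=not cfg.percolation_mode)
    return ClassifierResult(
        subject_id=cohort.subject_ids[m],
        assigned_label=label,
        deciding_step=step,
        quad=quad,
        alpha=cfg.alpha,
        contrast=cfg.contrast,
    )
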