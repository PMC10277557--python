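"""Reference tables from the 38-subject chronotype rs-fMRI study design.

The raw imaging data behind the study is not publicly deposited, but its
reported per-subject classification outcomes and dysconnected-network
topology counts are reproduced here as plain tables. They pin down the
arithmetic conventions of the evaluation module (abstention-aware accuracy,
percent-classified, divide-by-70 mean node degree) and serve as inputs to
the convention checks — they are never used as expected outputs of any
computation on synthetic data.

Cohort composition: subjects 1-16 are early chronotypes (ECP), 17-38 late
chronotypes (LCP); three scanning sessions (morning, afternoon, evening)
were each analyzed under both one-sided contrasts. Subject 11's afternoon
scan was excluded upstream (excess head motion), hence the NA entries.
"""

from __future__ import annotations

from .containers import ECP, LCP
from .nbs import DysconnectedNetwork

#: True chronotype labels for the 38-subject cohort (1-16 ECP, 17-38 LCP).
TRUE_LABELS: list[str] = [ECP] * 16 + [LCP] * 22

#: Reported per-subject classifier outcomes, one column per
#: (session, contrast) configuration. UNC = unclear, NA = scan excluded.
SESSION_LABELS: dict[str, list[str]] = {
    "afternoon_ecp_lt_lcp": [
        "UNC", "UNC", "UNC", "UNC", "LCP", "LCP", "LCP", "UNC", "UNC", "LCP",
        "NA", "UNC", "UNC", "UNC", "UNC", "LCP", "UNC", "UNC", "UNC", "UNC",
        "UNC", "UNC", "ECP", "UNC", "UNC", "ECP", "UNC", "UNC", "UNC", "UNC",
        "ECP", "UNC", "UNC", "UNC", "UNC", "ECP", "ECP", "ECP",
    ],
    "afternoon_ecp_gt_lcp": [
        "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC",
        "NA", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC",
        "UNC", "ECP", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC",
        "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC",
    ],
    "evening_ecp_lt_lcp": ["UNC"] * 38,
    "evening_ecp_gt_lcp": [
        "ECP", "ECP", "ECP", "ECP", "ECP", "ECP", "ECP", "ECP", "ECP", "ECP",
        "ECP", "ECP", "ECP", "ECP", "ECP", "ECP", "LCP", "LCP", "LCP", "LCP",
        "LCP", "LCP", "LCP", "LCP", "LCP", "LCP", "LCP", "LCP", "LCP", "LCP",
        "LCP", "LCP", "LCP", "LCP", "LCP", "ECP", "LCP", "LCP",
    ],
    "morning_ecp_lt_lcp": [
        "UNC", "LCP", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "UNC", "LCP",
        "UNC", "UNC", "LCP", "UNC", "UNC", "UNC", "UNC", "UNC", "ECP", "ECP",
        "UNC", "UNC", "UNC", "UNC", "UNC", "ECP", "ECP", "UNC", "UNC", "UNC",
        "UNC", "UNC", "UNC", "UNC", "UNC", "ECP", "ECP", "UNC",
    ],
    "morning_ecp_gt_lcp": ["UNC"] * 38,
}

#: Reported dysconnected-network topologies at the thresholds where the
#: threshold sweep showed non-zero accuracy: (session, contrast,
#: t-threshold, number of edges, number of nodes touched), over the
#: 70-ROI parcellation.
NETWORK_TOPOLOGIES: list[dict] = [
    {"session": "afternoon", "contrast": "ecp-lt-lcp", "threshold": 2.19,
     "n_edges": 55, "n_nodes": 53},
    {"session": "evening", "contrast": "ecp-gt-lcp", "threshold": 1.69,
     "n_edges": 146, "n_nodes": 70},
    {"session": "morning", "contrast": "ecp-lt-lcp", "threshold": 2.19,
     "n_edges": 53, "n_nodes": 48},
    {"session": "morning", "contrast": "ecp-lt-lcp", "threshold": 2.79,
     "n_edges": 6, "n_nodes": 7},
]

N_PARCELLATION = 70


def synthetic_component(
    n_edges: int, n_nodes: int, threshold: float = 0.0, t_value: float = 1.0
) -> DysconnectedNetwork:
    """A synthetic connected component with prescribed edge and node counts.

    Builds a path spanning ``n_nodes`` nodes, then adds chords until
    ``n_edges`` is reached; every edge carries the same t-value. Stands in
    for real dysconnected networks whose edge lists are unavailable —
    degree-summary conventions that depend only on counts (mean degree)
    are exact on it; topology-dependent quantities (max degree) are not.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (n_nodes - 1 <= n_edges <= n_nodes * (n_nodes - 1) // 2):
        raise ValueError(
            f"no connected simple graph has {n_edges} edges on {n_nodes} nodes"
        )
    edges: dict[tuple[int, int], float] = {}
    for i in range(n_nodes - 1):
        edges[(i, i + 1)] = t_value
    gap = 2
    while len(edges) < n_edges:
        for i in range(n_nodes - gap):
            if len(edges) == n_edges:
                break
            edges[(i, i + gap)] = t_value
        gap += 1
    return DysconnectedNetwork(edges=edges, threshold=threshold)
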