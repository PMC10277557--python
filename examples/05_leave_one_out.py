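"""Leave-one-out evaluation with abstention-aware metrics.

Every subject is classified with the remaining 37 as training set.
Accuracy, misclassification and unclear fractions sum to one; balanced
accuracy (mean of ECP and LCP recovery rates) is immune to the 16-vs-22
group imbalance.
"""

from chronet import (
    ClassifierConfig, CohortSpec, Contrast, build_cohort_networks,
    evaluate_loo, generate_cohort, random_planted_edges,
)

spec = CohortSpec(n_ecp=16, n_lcp=22, n_rois=15, n_timepoints=450,
                  planted_edges=random_planted_edges(15, 30, seed=7),
                  effect_size=0.30, seed=11)
nets = build_cohort_networks(generate_cohort(spec), 0.05)

cfg = ClassifierConfig(contrast=Contrast.ECP_GT_LCP, n_perm=200, seed=5)
s = evaluate_loo(nets, cfg)
print(f"accuracy          {100 * s.accuracy:.2f}%")
print(f"misclassification {100 * s.misclassification:.2f}%")
print(f"unclear           {100 * s.unclear:.2f}%")
print(f"sensitivity {100 * s.sensitivity:.1f}%  "
      f"specificity {100 * s.specificity:.1f}%  "
      f"balanced {100 * s.balanced_accuracy:.1f}%")
print("subjects decided per step (columns = true group):")
print(s.step_counts)
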