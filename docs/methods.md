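# Methods

`chronet` implements a pipeline for asking whether resting-state functional
brain networks carry enough information to separate two phenotype groups —
here early (ECP) versus late (LCP) circadian phenotypes — and for
classifying a single held-out subject by that information. This note
records the model, the conventions, and the design choices the code makes
where more than one reasonable reading existed.

## Functional networks: Tikhonov partial correlation

Each subject contributes a T × N matrix of ROI time series (T timepoints,
N regions). Columns are standardized to mean 0 and sample standard
deviation 1 (divisor T − 1; the same divisor is used for the covariance,
so the two stages are mutually consistent — any other consistent choice
only rescales the covariance, which the regularization parameter absorbs).
The sample covariance C of the standardized series equals the correlation
matrix. The ridge-regularized ("Tikhonov") precision matrix is

    P(λ) = (C + λ I)⁻¹,   λ ≥ 0,

and the network's edge weights are the partial correlations

    ρ_ij = − P_ij / √(P_ii P_jj),   i ≠ j,

which lie in [−1, 1] for a positive-definite P. The diagonal is set to NaN
throughout: self-links are not interpretable under partial correlation,
and every downstream stage treats the diagonal as undefined. Partial
rather than marginal correlation suppresses indirect (two-step)
connections; the ridge term keeps the inversion stable even when T < N.

**Choosing λ.** The package ships the cohort-dispersion objective

    F(λ) = √( Σ_{i<j} Σ_m ( P̄_ij(λ) − P^m_ij(λ) )² ),

where P^m is subject m's regularized precision and P̄ the cohort mean,
summed over the strict upper triangle (the diagonal reflects scale, not
connectivity). One global λ is fitted when several cohorts or sessions are
passed together. Two facts matter in practice:

1. An alternative reading of this objective — sum the deviations over
   subjects *before* squaring — is identically zero (the deviations from
   the mean cancel), so the square-then-sum form is the only
   non-degenerate one and is what `optimize_lambda` computes.
2. F(λ) decreases monotonically in λ on every dataset we have generated:
   heavier regularization shrinks all subjects toward the same matrix
   (P → (1/λ)I), collapsing between-subject dispersion like λ⁻⁴. The grid
   minimizer therefore sits at the grid's upper bound. The grid bounds are
   part of the protocol, not a neutral search range, and the optimizer is
   retained for that bounded protocol (coarse 200-point log grid on
   [10⁻⁴, 10], one 100-point linear refinement; ties resolve to the
   smallest λ). For routine network construction the package defaults to
   the conventional λ = 0.0259 used in the chronotype study this pipeline
   targets; that value cannot be derived from F on synthetic data.

## The network-based statistic with percolation thresholding

Given one network per subject and a one-sided contrast (ECP > LCP or
ECP < LCP), every edge receives a pooled-variance two-sample t-statistic
with n_A + n_B − 2 degrees of freedom; the numerator is (mean of the
contrast's favored group) − (mean of the other group), so large positive t
always means "evidence in the contrast's direction". Welch's form is
available behind a flag but the pooled Student form is the default,
matching standard NBS practice. Edges with zero pooled variance get a −∞
sentinel: they can never exceed a finite threshold, and if they ever
isolate a node the percolation search fails loudly rather than silently.

Thresholding the t-matrix at τ (inclusive, t ≥ τ) and keeping connected
components of surviving edges yields candidate *dysconnected networks* —
subnetworks whose edges most separate the groups. Familywise error over
the whole edge set is controlled by permutation: each of n_perm
relabelings of the full subject vector (group sizes preserved) recomputes
the t-matrix, thresholds at the *same* τ, and records the maximum
component intensity, where intensity is the plain sum of edge t-values
(not the exceedance sum Σ(t − τ); the exceedance variant is available
behind a flag). The FWE p-value is the fraction of permutations whose
maximum intensity strictly exceeds the observed component's intensity,
with no add-one correction (a conservative ≥/(n+1) mode exists behind a
flag). When the number of distinct assignments C(n, n_A) does not exceed
n_perm the sampler switches to exhaustive enumeration automatically, making
small-cohort p-values exact. The held-out subject's hypothesized label is
permuted like any other label — nothing exempts it from the null.

**Percolation threshold.** The adaptive threshold τ* is the largest value
at which the suprathreshold graph still connects all N ROIs — equivalently
the minimum edge weight along a maximum spanning tree of the complete
t-weighted graph (the maximum-bottleneck property). The component at τ*
is the *minimum connected component* (MCC): the sparsest suprathreshold
network touching every ROI. With finitely many t-values the supremum is
attained only under the inclusive t ≥ τ rule, which is why τ* is reported
as the bottleneck edge's exact value; the implementation asserts on every
call that the MCC spans all nodes and that the next distinct t-value
disconnects the graph. An exhaustive threshold-scan oracle backs the
spanning-tree implementation in the test suite.

At thresholds above τ* several components can coexist. The selection rule
is: smallest FWE p-value; ties broken by most edges; remaining ties broken
deterministically by the lowest ROI index contained (the original
formulation calls such candidates indistinguishable and picks arbitrarily —
we pick reproducibly).

## The three-step four-network classifier

To classify held-out subject m, the cohort is analyzed twice: with m
provisionally labeled ECP (percolation threshold t_E, MCC E_tE) and with m
labeled LCP (t_L, L_tL). Thresholding the ECP-labeling t-matrix at t_L
gives the cross network E_tL, and the LCP-labeling matrix at t_E gives
L_tE. All four networks carry permutation p-values. The decision is:

1. **Step 1** — significance of E_tE and L_tL at level α (p < α strictly).
   Exactly one significant → that label. Neither → UNCLEAR. Both →
   continue.
2. **Step 2** — the same table over the cross networks E_tL and L_tE.
3. **Step 3** — edge counts at matched thresholds: compare |E_tE| with
   |L_tE| (both at t_E) and |E_tL| with |L_tL| (both at t_L). Both
   comparisons favoring the same label decide it; any conflict or exact
   tie is UNCLEAR. The rationale: labeling m correctly increases group
   separation, so more edges survive any fixed threshold under the correct
   labeling. The full branch table of the original figure is not available
   in text; resolving conflicts and ties to UNCLEAR is the conservative,
   symmetric choice and is consistent with the reduced variant below.

A missing network (no edge survives) counts as non-significant with zero
edges. Cross networks and their permutation p-values are materialized
lazily — only when step 1 fails to decide — because permutation testing
dominates runtime; a fixed spawn order of per-network seeds keeps lazy and
eager evaluation bit-identical. Every subject gets a deterministic seed
derived from (base seed, subject index), so leave-one-out results are
reproducible and order-independent.

**Reduced classifier.** With a single preselected threshold (t_E = t_L =
τ) the four networks collapse to two aliased pairs; step 2 is redundant
and step 3 reduces to one comparison |E_τ| vs |L_τ|. The implementation
records the significance check as step 1 and the edge comparison as step
3, mirroring the full classifier's semantics (step 2 never fires in
reduced mode). A structural test confirms the reduced path equals the full
path whenever the thresholds coincide. `deciding_step` is None only for
UNCLEAR by step-3 conflict/tie (exhaustion); UNCLEAR from a
"neither significant" branch records that step.

## Evaluation conventions

Because the classifier can abstain, three outcome fractions are tracked —
accuracy (correct definite labels / all subjects), misclassification
(wrong definite labels / all subjects) and unclear — which sum to one by
construction. Sensitivity is the fraction of true ECPs assigned ECP,
specificity the fraction of true LCPs assigned LCP, and balanced accuracy
their mean; an abstention helps none of them. Published summary rows for
this design contain an internal inconsistency (an evening-session accuracy
printed as 97.7 with balanced accuracy 100% against a text value of 97.37
and a group accuracy of 95.5); the package implements the definitions
above and recomputes all reported quantities from per-subject label
columns, not from summary rows.

Percent-classified is 100 × (definite labels) / (non-missing entries),
reported to one decimal. Node-degree summaries of a dysconnected network
are computed over the *full* parcellation (N_total = 70 by default):
untouched ROIs count with degree zero, so the mean degree is
2E / N_total — the only convention that reproduces all four published
mean-degree values from their edge counts. The degree standard deviation
uses the population (divide-by-N) convention; the sample convention
differs negligibly and the source does not specify, so the ± values are
recorded but not asserted against.

Sweeps: the t-threshold sweep (default grid 0 to 4.5 in steps of 0.01)
runs the reduced classifier at every grid value, reusing each labeling's
observed and permuted t-matrices across the grid (they do not depend on
τ), so each grid point reproduces exactly what a standalone fixed-τ run
with the same seed would give. The significance sweep (default grid 0 to 1
in steps of 0.01) materializes each subject's four p-values once and
reapplies the decision tables, because p-values do not depend on α; at
α = 0 nothing is significant and every outcome is UNCLEAR, and above the
largest of all subjects' p-values the outcome fractions are constant.
No multiple-comparison correction is applied across grid points — sweeps
are exploratory descriptions of where information lives, not selection
procedures, and outputs label them as such.

Stability: each subject is removed in turn and the full leave-one-out
evaluation re-runs on the remaining N − 1; one row per removed subject
plus column means. Rows are individually reproducible bit-for-bit from the
same base seed.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
at the study's dimensions by default: 16 ECP vs 22 LCP subjects, 70 ROIs,
450 timepoints. Time series are T i.i.d. draws from a zero-mean
multivariate Gaussian with per-subject precision matrix

    Ω_m = Ω_base − δ · 1[m ∈ ECP] · (planted pattern) + per-subject noise,

where Ω_base is the identity with planted off-diagonal entries at
−base_partial (default 0.05, a weak baseline partial correlation) and δ
(`effect_size`) is subtracted on planted entries for ECP subjects only —
a more negative precision entry is a more positive partial correlation, so
the detecting contrast is always ECP > LCP. Positive definiteness is
restored by diagonal loading in increments of 0.05 until the minimum
eigenvalue exceeds 10⁻⁶ (abort after 100 increments). Loading attenuates
the realized planted partial correlation: with 30 planted edges among 15
ROIs and δ = 0.30 the nominal 0.35 becomes ≈ 0.22 against an LCP baseline
of 0.05 (`planted_partial_correlations` reports the realized values);
attenuation is the price of a dense planted subnetwork on a small
parcellation and leaves the group gap large.

Temporal autocorrelation is off by default (an AR(1) coefficient is
accepted): the pipeline consumes only covariance, and autocorrelation
affects the effective sample size — a realism knob, not a correctness
requirement. The generator does not model hemodynamics, motion,
physiological noise or scanner drift, so passing tests demonstrate that
the *statistical machinery* behaves as specified under its own
assumptions, not that the pipeline is robust to fMRI artifacts; real-data
preprocessing is upstream and out of scope. An edge-level fast path
samples subject weight matrices directly (mean + planted shift + Gaussian
edge noise, clipped to [−1, 1]) for cheap classifier-level tests.

Exchangeability at δ = 0 is the generator's key testable property: both
groups are then draws from one distribution, so edgewise tests reject at
the nominal rate and the MCC's FWE p-value is calibrated (verified by
simulation in the acceptance suite).

## Problem sizes in the shipped checks

The convention fixtures are instantaneous. The calibration check uses 200
null replicates (15 ROIs, 450 timepoints, 16/22 subjects, 200
permutations) and the recovery check one strong planted-effect cohort at
the same dimensions with leave-one-out evaluation under both contrasts —
sizes chosen so the whole suite completes in well under a minute per
check while keeping the Monte-Carlo intervals informative. The permutation
default of n_perm = 5000 matches the study; tests and the acceptance
script use 200 to keep the binomial resolution of a p < 0.05 call
adequate (±0.015) at simulation scale.

## Known limitations

- The λ objective degeneracy above: `optimize_lambda` is protocol-faithful
  but cannot recover an interior optimum on data generated here.
- Step 3's branch table is reconstructed from its description; other
  resolutions of conflicts/ties are conceivable.
- Permutation p-values at n_perm = 200 have granularity 0.005; classifier
  decisions near α are correspondingly seed-sensitive on null data.
- The synthetic generator's planted effects are homogeneous across planted
  edges; real group differences are heterogeneous and signed.
- F-test/ANOVA designs, exchange-block permutation, FDR-edgewise
  alternatives and feature-selection classifiers are out of scope.
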