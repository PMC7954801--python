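# Methods

This note documents the models and procedures implemented in `coregrn`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Identity-TF scoring

For a TF with expression vector x over the query sample plus N background
samples, the empirical distribution p = x / Σx is compared with the ideal
point mass e on the query using the base-2 Jensen–Shannon divergence, and

    specificity = 1 − √JSD(p, e).

A TF expressed exclusively in the query has JSD = 0 and specificity 1; a TF
with no query expression has disjoint support, JSD = 1 and specificity 0.
We rank by *descending specificity*. Because all off-query mass contributes
identically to the divergence against a point mass, the per-sample score is
a strictly monotone function of the TF's normalized mass on that sample —
a property the synthetic fixtures exploit to make planted ranks exact.

Before scoring, background samples with Pearson r > `correlation_cutoff`
(default **0.75**) to the query are removed, so closely related cell types
do not absorb probability mass that distinguishes identity TFs.
Correlations are computed on log₂(x+1) values over shared genes; the log
transform stabilizes heavy-tailed TPM-like abundances. The cutoff can be
re-calibrated with `calibrate_correlation_cutoff`, which maximizes the F1
score of centroid-correlation classification over a 0.01-step grid on
[0, 1], ties resolved toward the larger cutoff.

## Activity calls and activation probabilities

A gene is called active when the empirical one-sided p-value against its
own background distribution,

    p = (1 + #{background ≥ x}) / (1 + N),

falls below `activity_alpha` (default **0.1**). The +1 correction keeps
p > 0 for any finite background. This empirical surrogate replaces an
external bootstrap-threshold procedure; externally computed p-values can be
supplied per gene via `pvalue_override`, preserving the p < 0.1 decision
rule. The state prior uses the empirical CDF P(active) = #{background <
x}/N. Activity and marginals are computed against the *full* compendium;
specificity and co-factor ranks use the correlation-filtered one, since the
filter exists to sharpen specificity, not to redefine a gene's background.

## Co-factor rank z-scores

Each candidate TF's specificity rank in the query is standardized against
the distribution of its ranks when each filtered background sample is
treated as the query in turn: z = (rank_query − mean)/sd, eligible when
z ≤ **−1.5**. Degenerate sd = 0 yields z = 0 (never eligible) unless the
query rank strictly beats the constant background rank (z = −∞, eligible).
Ranks are dense, ties broken lexicographically on gene id; genes with
undefined specificity (all-zero expression in a block) rank last.

## Regulatory regions and binding events

Promoter windows span 1500 bp upstream to 500 bp downstream of the TSS
(defaults `promoter_upstream`/`promoter_downstream`), oriented by strand
and clipped at coordinate 0; the window is kept whole when active (≥ 1 bp
H3K4me3 overlap). Enhancers are truncated to their H3K27ac support: every
maximal segment of enhancer ∩ (union of overlapping peaks) becomes one
active region, so disjoint peaks in one enhancer yield multiple regions
rather than a bounding span. Peaks within one assay are *not* merged before
intersection. A binding event requires a ≥ 1 bp triple overlap of TF peak,
region and a DNase peak, with the accessible base inside the peak∩region
intersection — the strictest reading of "within accessible chromatin"; the
DNase filter applies only to binding events, never to region activity.
All coordinates are 0-based half-open; chromosome names match verbatim.

Each region carries a unique `region_id` plus an `element_id` naming the
annotated element it derives from; segments of one truncated enhancer share
an `element_id`, which is how regions are matched across cell types.

## Cooperativity and Boolean rules

Two TFs bound in one region are cooperative iff their reciprocal peak
overlap min(ov/|a|, ov/|b|) is ≥ `overlap_threshold` (default **0.6243**)
*and* the pair has a PPI record — the conjunction is the strict reading of
the two conditions. A TF with several peaks in a region contributes its
maximal pairwise overlap. Connected components of the cooperative graph are
AND-clusters; clusters combine by OR within a region. The rule of a target
is promoter_clause ∧ (OR over enhancer clauses); all literals positive.
Conventions for degenerate cases: an active region with no bound TFs is a
vacuously true clause; enhancer clauses are built only for regions with at
least one binding event; a target with no regulators at all self-maintains
(next state = current state); targets without an active promoter are
dropped from the core network, since they cannot be induced under these
semantics. The calibrator for the overlap threshold maximizes balanced
accuracy over a 10⁻⁴-step sweep (the objective behind the shipped constant
is not recoverable, so the constant is the default and calibration is
optional).

## Conversion scoring

Dynamics are synchronous and deterministic; stochasticity enters only
through the product prior over initial states. Over-expressed TFs are
clamped active for the entire simulation (sustained cassette expression,
not a one-off flip) and their prior marginals are forced to 1. Because the
transition system is deterministic, revisiting a state proves the all-active
target unreachable, so exact scoring enumerates all 2ⁿ states with
path-memoized distances (capped at n = 22, ≈4M states); beyond that a
seeded Monte-Carlo estimator draws initial states from the prior. Two
transcriptional-score variants are shipped because "average distance
weighted by the prior" and "probability of activating the whole network"
are both defensible readings: `reachability` (default) is the prior mass of
converging states; `distance_weighted` scales each converging state by
1 − d(s)/(d_max+1). The epigenetic fraction uses the *target-side*
denominator (it measures remodeling still required to reach the target) and
includes the promoter among regulatory elements by default
(`include_promoter=False` restricts to enhancers). Region identity across
cell types = same `element_id` plus ≥ 1 bp overlap of active segments.
Ranking ties break lexicographically on sorted TF names; exhaustive
enumeration is limited to C(n,k) ≤ 10⁶, beyond which an explicit candidate
list is required.

The concordance test compares rank vectors by Euclidean distance; p =
#{permutations with distance ≤ D}/k!, exhaustive for k ≤ 8 and seeded
Monte-Carlo (10⁵ draws) beyond. The ≤ convention keeps p ∈ (0, 1] and makes
a perfectly concordant ranking score p = 1/k!.

## Synthetic fixtures

The generator builds a single toy chromosome (genes spaced 20 kb apart,
promoter windows disjoint, 1–4 geometric enhancers per gene), a planted
core network (identity TFs, co-factors satisfying the in/out-degree
constraints, AND-pairs with reciprocal overlap 0.8 and a PPI record,
competitive co-occupants disjoint), peak sets realizing exactly the planted
binding events, and an expression compendium (30 background samples over 5
phenotypes by default) in which identity TFs are query-exclusive,
co-factors are high in the query with one strong related-sample bump in the
background, and outsider TFs are query-silent with broad background
expression. The bump design pins each co-factor's background specificity
ranks near the bottom (deterministically, via the monotone mass property
above) while keeping rank variance positive, so the planted z ≤ −1.5
guarantee holds analytically at noise 0 for the shipped identity/outsider
proportions (identity ≈ n/4 of the TFs). Cooperative overlaps are planted
at 0.8 and competitive ones at 0, comfortably either side of the 0.6243
threshold, so small threshold perturbations cannot flip labels.

The conversion scenario plants a regulatory cascade TF01 → TF02 → …: TF01
has no regulators and is silent in the source cell type (activation
marginal 0), making it essential — no perturbation omitting it can reach
the all-active state. The planted optimal triple comprises the only genes
whose regions are inactive in the source epigenome, so it uniquely attains
T = E = 1. `noise_level` > 0 drops/adds peaks and jitters expression at the
given rate; the exactness guarantees hold at noise 0 only.

What passing these fixtures does *not* show: robustness to peak-caller
noise, to enhancer–gene mis-assignment, to compendium batch effects, or to
the scale of real compendia (thousands of samples, hundreds of TFs); the
fixtures verify the logic of every rule, not the biology of real data.
Problem sizes were chosen for exhaustive verifiability: networks of 8–16
TFs, where every Boolean claim can be checked against full state-space
enumeration.

## Numerical choices and limitations

- JSD is computed via `scipy.spatial.distance.jensenshannon` (which returns
  √JSD) with base 2, bounding scores in [0, 1].
- Self-loops are retained in the scaffold; autoregulation is pervasive in
  core identity circuits and the logic layer handles it naturally.
- Identity TFs missing from the scaffold are dropped with warnings rather
  than aborting the run.
- Both promoter- and enhancer-mediated edges satisfy the co-factor
  regulates/regulated-by conditions.
- No repressor logic: the model has no negative literals, so every compiled
  rule is monotone.
- Exact scoring uses Python-int bitmask states; networks beyond 60 TFs are
  rejected, and exact enumeration beyond n = 22 instructs Monte-Carlo use.
- All stochastic paths (Monte-Carlo scoring, large-k concordance, fixture
  generation) require an explicit seed and record it in their outputs.
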