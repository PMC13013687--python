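# Methods

## Statistical model

### Edge-wise GLM

Every backbone edge (and, for nodal maps, every region's strength) is
modelled by ordinary least squares against one shared design: intercept,
the effect under test, and nuisance covariates. Categorical covariates are
treatment-coded against their first sorted level; HC is the reference
group, so the printed contrasts (MDD vs HC, MDD+ANX vs HC) are single
coefficients. Continuous covariates are mean-centered; `age2` denotes the
centered square of centered age, available for non-linear age control.
Edge weights are analyzed on the raw streamline-count scale — the quantity
the edge definition actually measures — with a `log1p` transform exposed as
a config option. σ̂² uses the unbiased df = n − p. Edges with (numerically)
zero residual variance get statistic 0 and a flag rather than NaN.

### Permutation inference

Two schemes are implemented. `freedman_lane` (default) fits the reduced
model (nuisance only), permutes its residuals, adds them back to the
reduced fit and recomputes the full-model statistics; this respects
exchangeability when nuisance covariates carry real signal, which is the
normal situation in cohort data. `label` permutes the rows of the effect
columns only, covariates fixed; it is simpler, matches common toolbox
behaviour, and is used where exact enumeration is wanted in tests. Within
one realization the same subject permutation applies to every edge, which
is what preserves the spatial dependence the NBS exploits. The identity
permutation reproduces the observed statistics exactly under both schemes.

Permutation r draws its own child generator from a counter-derived
substream of the master seed, so results do not depend on evaluation
order. p_FWE uses the (1 + b)/(1 + K) estimator, which is valid (never
anti-conservative) at any K and makes 1/(K + 1) the smallest attainable
value; a `proportion` flag reports b/K for comparability with toolboxes
that print raw proportions. With `exhaustive=True` all n! permutations are
enumerated (identity included) and the exact proportion is reported.

### Component inference

Supra-threshold edges (F > τ_F, or signed t beyond τ_t in the stated
direction) are grouped by union-find into connected components, sorted by
extent with ties broken by smallest contained node index. The component
statistic is extent (edge count), the NBS default and the unit in which
subnetwork sizes are reported; an intensity option (sum of threshold
exceedances) is exposed. The primary thresholds are user choices with the
usual NBS caveat that they shape sensitivity; defaults are F = 4.0 and
t = 1.962 (the two-sided 5% normal quantile), with a slightly laxer
t = 1.9 for the MDD+ANX vs MDD post-hoc contrast.

### Ordered-pattern (conjunction) test

The directed three-group pattern test keeps an edge iff
t(MDD−HC) < −τ AND t(MDD+ANX−HC) > +τ, then proceeds exactly as above,
with the conjunction rule re-applied inside every permutation. A
conjunction of two one-sided contrasts at a common threshold is the most
direct reading of "each edge shows the ordered pattern"; a single
composite statistic (e.g. min of the two margins) would be an alternative
— the two t-fields are retained in the result for audit, so users can
apply their own rule post hoc. The three post-hoc tests each get their own
permutation null (reusing the omnibus null would misstate their reference
distribution); FDR (Benjamini–Hochberg) is applied across their component
p-values, and likewise across the two anxiety scores in the
transdiagnostic analysis.

### Effect sizes

A component is scored per subject by the mean weight over its edges. The
score is residualized on the nuisance columns (group structure is not
regressed out), then Cohen's d = (mean_a − mean_b)/pooled SD for a group
pair, and partial η² = Fq/(Fq + df₂) from the omnibus F on the score.

### Topology characterization

Hubs are the nodes with the highest within-component degree (ties to the
smaller index). Lobe-pair composition compares the component's 15
unordered lobe-pair counts with expected = extent × backbone proportions
via a goodness-of-fit chi-square (categories with expected < 1 pooled into
"other"; counts are never dropped) plus per-category one-vs-rest 2×2
chi-squares. The fiber-length test compares the component's mean total
fiber length (mean over subjects of the per-subject sum across component
edges; absent edges contribute 0) against R random subnetworks of
identical size drawn from the backbone. "Identical size" is read as same
edge count with `uniform_edges` the default null — the simplest null
consistent with a size-matched comparison; `degree_matched` additionally
preserves the component's degree sequence exactly via double-edge swaps
constrained to backbone membership (≥ 10× size successful swaps per draw,
falling back to uniform with a warning when too few legal swaps exist).
Random subnetworks are not constrained to be connected. Ties count against
the observed network ((1 + b)/(1 + R), one-sided `greater` by default).

### Backbone and nodal strength

The analyzable connectome is the set of edges with weight > 0 in at least
⌈prevalence × n⌉ subjects (default 5%; "present" means any nonzero count,
since no minimum streamline count is defensible a priori). The backbone is
applied both to the edge-wise analyses and as the composition background;
this is configurable. Nodal strength divides by the node's backbone degree
— a fixed support shared by all subjects, so between-subject comparisons
are not distorted by subject-specific denominators — with an "all N−1
partners" option. Matrices are symmetrized by element-wise max on read,
warning when relative asymmetry exceeds 1e−6; indices are 0-based
internally with a flag for 1-based edge-list files.

## The synthetic cohort generator

What it emulates: three groups of configurable (default 906/532/249)
subjects; ages truncated-normal 18–65 (mean 35, SD 13); sex and site
Bernoulli with group-specific female fractions; a 114-node atlas with
random coordinates in a 140 mm box, lobes by spatial octant; a shared
backbone drawn with probability ∝ exp(−λd) at 20% density; expected edge
weight w₀ = A·exp(−λd) (A = 400, λ = 0.012/mm, giving realistic two- to
three-digit streamline counts); per-subject weights
round(w₀·exp(covariates + group shift·1[planted] + latent + noise)) with
2% edge dropout; fiber lengths = distance × (1 + 3% noise). The planted
component (default 109 edges, the scale of reported subnetworks) is grown
by randomized breadth-first edge accretion, so it is connected by
construction; an optional length bias plants it on long-range edges. A
second, disjoint component carries the anxiety coupling so the two
calibrations do not interact.

Two calibrations make "configured truth" exact rather than nominal:

- the group log-shift s is solved in closed form from the lognormal
  moments so the *count-scale* per-edge standardized difference equals the
  configured δ (first order: s = δ·sqrt(e^{σ²} − 1));
- planted edges split their total log-noise variance σ² into a shared
  per-subject latent (fraction `latent_share`, default 0.5) and an
  independent remainder. Without the shared part, averaging over edges
  would shrink the component score's noise by √m and inflate component d
  far above δ; with it, the expected component-level d follows in closed
  form from the planted w₀, noise split and dropout
  (`GroundTruth.expected_component_d`), and matches measurement to ~0.01
  at moderate n. Defaults δ = −0.33/+0.54 put the component d near
  −0.47/+0.76 at full cohort scale.

STAI scores are group base + 4·latent + residual noise with group bases
and SDs at published cohort values, so group means are ordered
HC < MDD < MDD+ANX and scores are coupled to connectivity through the same
latent that drives the anxiety component.

What it does **not** emulate: spatial autocorrelation of tractography
errors, scanner-specific noise spectra, head-motion artifacts correlated
with diagnosis, hemispheric asymmetries, hub-concentrated topology of real
cortex, or heavy-tailed inter-individual variability. Passing calibration
and recovery tests therefore demonstrates the *inferential machinery* is
correct and calibrated under the assumed model, not that real acquisitions
satisfy that model.

## Numerical choices

- OLS via `lstsq`/QR; permutation statistics via cached orthonormal bases
  (residual sums of squares as norm differences), clipped at 0 against
  round-off; zero-variance edges flagged at rss ≤ 1e−12 × total SS.
- Design rank is checked up front; collinear columns are named in the
  error.
- Component extraction is exact integer union-find; determinism is fixed
  by lexicographic edge order and the smallest-node tie-break.
- All randomness flows from numpy Generators seeded by explicit integers;
  derived seeds stay below 2³¹.

## Validation problem sizes

The test suite and acceptance script validate at deliberately scaled-down
sizes chosen to give stable Monte-Carlo estimates quickly: FWE calibration
on 500 null cohorts (30 nodes, 20/group, 200 permutations; binomial SE
≈ 0.01 at α = 0.05); pattern recovery over 50 seeds (40 nodes, 150/group,
δ = ±0.8, the regime where per-edge t ≈ 7 makes recovery a correctness
check rather than a power study); effect-size recovery over 20 seeds at
300/group (mean-of-seeds SE ≈ 0.02 on d); fiber-length null over 200
uniform components at R = 500. Exhaustive-permutation equivalence is
checked at n = 6 and 7 subjects where all n! orders are enumerable.

## Known limitations

- The conjunction rule for the ordered-pattern test is one reasonable
  formalization of a directed three-group pattern; composite-statistic
  variants would weight borderline edges differently.
- The chi-square composition test is asymptotic; with small components and
  many lobe-pair categories it can be conservative despite pooling.
- Freedman–Lane is approximate (exact only asymptotically or under
  i.i.d. errors); its type-I error is verified empirically, not proven.
- The generator's dropout is independent across edges and subjects;
  structured missingness (e.g. whole-lobe dropouts) is not modelled.
- QC beyond a per-subject mean-connectivity z-score exclusion hook is out
  of scope, as is any MRI preprocessing: the pipeline starts at matrices.
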