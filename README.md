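# nbsconn

Network-based statistic (NBS) analysis of weighted structural connectomes,
with a synthetic cohort generator for validating every inferential step.

## The problem

Structural connectomes represent each subject's white matter as an
undirected weighted graph: nodes are parcellated cortical regions, edge
weights are streamline counts from diffusion tractography. Comparing such
graphs between diagnostic groups (here: healthy controls **HC**, depressed
subjects without comorbid anxiety **MDD**, and depressed subjects with
comorbid anxiety **MDD+ANX**) edge by edge faces a massive
multiple-comparisons problem. The NBS sidesteps it by testing *connected
components*: an edge-wise general linear model (with age, sex and scanner
site as nuisance covariates) is thresholded at a primary cutoff, connected
components of the supra-threshold graph are extracted, and each component's
extent (edge count) is referred to the permutation distribution of the
*maximal* null component extent — giving family-wise-error-corrected
p-values at the network level.

For an edge with weights y over n subjects and design X (intercept, group
indicators with HC as reference, covariates), the package computes

    F = [(RSS0 − RSS1)/q] / [RSS1/(n − p)]      (omnibus, q group columns)
    t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)              (post-hoc contrasts)

and, per permutation (Freedman–Lane residual permutation by default, plain
label permutation optionally), re-forms the supra-threshold graph and
records its maximal component extent;
p_FWE = (1 + #{null ≥ observed}) / (1 + K).

Beyond the standard omnibus and one-sided tests, the package provides:

- an **ordered-pattern test**: an edge-wise conjunction keeping edges where
  t(MDD−HC) < −τ *and* t(MDD+ANX−HC) > +τ simultaneously, i.e. a connected
  subnetwork on which the three groups are ordered MDD < HC < MDD+ANX;
- **topology characterization** of an identified component: hub nodes,
  lobe-pair composition against the connectome backbone (chi-square), and a
  permutation test of mean total fiber length against size-matched random
  subnetworks (uniform or degree-preserving);
- **nodal meta-analysis**: covariate-adjusted t-maps of nodal strength, the
  hypo/hyper sign split across regions (chi-square), and paired t-tests
  between contrast maps;
- a two-stage **continuous (transdiagnostic) analysis** associating edge
  weights with dimensional anxiety scores (STAI state/trait);
- summary-statistic utilities (chi-square, Welch t, one-way ANOVA from
  printed group means/SDs) for demographic tables.

Because subject-level connectome data from clinical cohorts are typically
available only on request, the package ships a **synthetic cohort
generator** (`nbsconn.simulate`) that emulates the statistical structure
such studies assume — three unequal groups, covariate effects, a
distance-dependent sparse backbone with per-subject edge dropout, a
connected planted subnetwork carrying opposite group shifts, and anxiety
scores coupled to connectivity through a subject latent — together with the
ground truth needed for recovery and calibration testing.

## Worked example

```bash
nbsconn simulate --out-dir demo --n-per-group 100 --n-nodes 40 \
    --planted-size 30 --delta-hypo -0.5 --delta-hyper 0.6 --seed 42
nbsconn analyze --data-dir demo --out-dir run --n-perm 500 --seed 1
```

prints

```
wrote 300 subjects to demo
{"omnibus_p": [0.001996007984031936], "pattern_extent": [26], "pattern_p": [0.001996007984031936]}
```

The omnibus NBS (F > 4.0, 500 permutations) finds a 32-edge component at
the smallest attainable p = 1/501 ≈ 0.002; the ordered-pattern conjunction
(τ = 1.962) recovers a 26-edge subnetwork of the 30 planted edges at the
same p. `run/report.json` holds the full bundle, e.g. post-hoc component
Cohen's d of −0.84 (MDD vs HC), +0.77 (MDD+ANX vs HC) and +1.55
(MDD+ANX vs MDD) — the planted down/up pattern — and the nodal
meta-analysis (sign split 32:8 vs 8:32 hypo:hyper regions, χ² = 28.8;
paired t = −6.78), while `run/components/*.tsv` list each component's edges
with region names and statistics. The same dataset directory can be fed to
`nbsconn transdiagnostic` for the anxiety-score association and
`nbsconn calibrate` for type-I/power tables.

All functionality is a library first (`nbsconn.nbs_test`,
`nbsconn.ordered_pattern_test`, `nbsconn.continuous_nbs`, ...); the CLI is
a thin wrapper.

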