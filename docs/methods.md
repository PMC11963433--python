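# Methods

This note documents the models and numerical choices behind each module,
what the synthetic generators do and do not emulate, and the known limits of
the approach. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature preparation

Raw feature abundances (samples × features) pass through a fixed, tag-checked
pipeline: prevalence filter → total-sum scaling (TSS) → log transform.

- The prevalence filter keeps features non-zero in **at least** the given
  fraction of samples. The comparison is made on exact rationals
  (`Fraction(count, n) >= Fraction(threshold)`, with the float threshold
  snapped to its nearest small rational) so that 1/10 of samples passes a
  0.10 threshold exactly. Filtering uses the zero pattern only, so it
  commutes with TSS; we filter before TSS.
- The sparse-abundance transform is `log10(x + 0.01) + 2`: zero maps to
  exactly zero, the transform is strictly increasing, and non-zero relative
  abundances are shifted only minimally. Strictly positive abundance types
  (ecological-relationship frequencies) use a plain `log10`, and a zero
  there is a contract violation, not data.
- Each table carries a `scale` tag (`raw → relative → transformed`); every
  operation validates the tag, so the pipeline cannot be run out of order.
  The companion 16S workflow's stricter "20% of samples" filter is the same
  operation with a different threshold argument.

## Mixed-model aging screen

Each transformed feature is fitted with

```
y = b0 + b_age·age + b_trt·1[yMB] + b_int·age·1[yMB] + u_mouse + e,
u_mouse ~ N(0, σ²_u),  e ~ N(0, σ²_e)
```

with iMB as the reference level, so `b_age` is the iMB age slope and
`b_age + b_int` the yMB slope, both in transformed units per week (age in
weeks, uncentered).

**Estimation.** Restricted maximum likelihood. Because the only random term
is a per-mouse intercept, the REML criterion profiles down to a scalar
search over the variance ratio `λ = σ²_u/σ²_e`: for fixed λ the fixed
effects are GLS with the per-mouse Woodbury inverse
`V_i⁻¹ = I − λ/(1+λ·m_i)·J`, and λ is found by bounded minimization over
`log λ ∈ [−25, 25]` with the λ = 0 boundary checked explicitly. This
specialized fitter is exact for the model family, runs in ~1 ms per
feature, and is validated in the test suite against a general mixed-model
implementation (coefficients to 1e-7) and against closed-form OLS in the
balanced noise-free case. The interaction is tested with the Wald z
statistic (`p = 2·Φ(−|b_int/se|)`), matching lmer-style conventions. In the
noise-free limit (`σ̂² = 0`) a non-zero coefficient gets p = 0, and the
fitted slopes reproduce planted slopes to 1e-6.

**Screen.** Benjamini–Hochberg across all converged features; non-converged
or singular fits are reported as `fit_failed` and excluded from the FDR
family (smaller m). Features at FDR ≤ α are classified by their slope signs:
opposite strict signs → `inverted`; both positive/negative → concordant
up/down; an exact-zero slope → `indeterminate` (a measure-zero event kept
visible rather than silently binned). The interaction alone gates
significance; no main-effect filter is applied.

**Pathways.** One-sided hypergeometric upper-tail test per pathway against
the annotated universe; only pathways of size 3–500 within the universe are
tested; BH across tested pathways (m = tested-pathway count); rows reported
at raw p ≤ 0.05 with overlap ≥ 3. Pathway fold change is the per-feature
`log2(mean relative abundance at 120 w / mean at 72 w)` within each
treatment, averaged arithmetically over member features; a group mean of
exactly zero is replaced by half the smallest non-zero relative abundance in
the table and the output flagged.

## Flux-balance analysis and ecological relationships

Models are small stoichiometric systems (cytosolic/extracellular
metabolites, bounded reactions, one biomass objective; exchange reactions
are single-metabolite `{met: −1}` reactions on extracellular metabolites,
negative flux = uptake). Growth is the optimum of the LP
`max v_biomass s.t. S·v = 0, lb ≤ v ≤ ub`, solved with HiGHS; infeasible
problems report growth 0 with a flag, an unbounded objective raises (model
defect). Solutions satisfy steady state within 1e-9 of the bound scale, and
growth is scale-covariant (doubling all bounds doubles growth).

**Co-growth.** Two models merge into a community: internal metabolites and
reactions are namespaced per member, the extracellular pool is shared, and
each environmental resource keeps a single community exchange whose medium
bound applies once — shared substrates are contested, and one member's
secretions feed the other. Because the joint optimum is typically degenerate
(any split of a shared substrate maximizes the total), the default protocol
maximizes summed biomass and reports each member's **flux-variability
midpoint** at that optimum (re-solving min/max of each biomass with the
total pinned to within `1e-9·max(1,|total|)`). This is deterministic under
degeneracy; the allocation rule used by published co-growth pipelines is not
printed anywhere we could adopt it from, so the protocol is explicit
configuration, not a claim of equivalence.

**Classification.** Effects `g_pair − g_alone` are thresholded into
−/0/+ with a neutral band `max(tol_abs, tol_rel·g_alone)`, defaults
`tol_rel = 1e-6`, `tol_abs = 1e-9` — wide enough to absorb LP noise on toy
scales (observed ~1e-8), far below real effects (≥ 0.9 growth units in the
fixtures). The unordered sign pair maps onto the six classical
relationships; "antagonistic" defaults to {competition, amensalism,
exploitation} (any pattern with a harmed member) and is configurable.
Community profiles tally pairs among members above a detection threshold
(default: relative abundance > 0); frequencies are counts over pairs.

## Community drift

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric, seeded) to the minimum shared depth by default. Bray–Curtis
is computed on relative abundances of rarefied counts. The drift statistic
is each sample's distance to its **own mouse's** week-8 baseline sample,
falling back to the baseline centroid (mean relative abundance) for mice
without one; a centroid-only mode exists because figure-level conventions
differ. Arms are compared per timepoint with Mann–Whitney. PCoA is classical
metric scaling (double-centered squared distances, `eigh`); axes are
returned for positive eigenvalues only, negative eigenvalues are reported
so the user can judge non-Euclideanity. The constrained ordination used for
presentation in comparable studies is a published composite method and is
deliberately replaced by unconstrained PCoA plus group labels.

## Single-cell scores and differential expression

QC keeps cells with total counts in [200, 5000] ("more than 5000" and
"fewer than 200" are removed, so both stated bounds are kept),
mitochondrial fraction ≤ 0.25 and housekeeping fraction ≥ 0.10; criteria
are conjunctive, hence order-independent. "Reads mapping to genome" is
interpreted as total counts per cell. Mitochondrial genes are flagged by
the `mt-` prefix and housekeeping genes by a per-dataset flag column, since
no canonical lists are universal.

Normalization is counts/total·10⁴ then `ln(1+x)`. The module score of a
gene signature is the mean normalized expression of the signature genes
minus that of control genes drawn per signature gene (seeded, n_ctrl = 100)
from its average-expression bin (24 equal-size rank bins over all genes).
This is the common additive-control scheme; the exact scoring formula of
Seurat-era workflows is not printed in the sources this design follows, so
the score is an *emulation* with the same intent — expression-matched
background correction — not a byte-level reproduction. Passing the
signature itself as the control pool yields an identically zero score,
which the tests use as an identity oracle.

DE per cell type is a two-sided Wilcoxon rank-sum on normalized expression
with log fold = difference of group means on the natural-log scale
(Seurat-era convention; the 0.1 threshold applies on that scale) and
Bonferroni correction with m = all genes in the dataset. Cell proportions
are computed per mouse (rows sum to 1) and compared per cell type with
Mann–Whitney across mice.

## Phenotype statistics

AUC is the trapezoidal integral over a stated window; window edges that fall
between observations are linearly interpolated, since the measurement grid
of a real cohort rarely hits the window bounds exactly. AUC is additive over
adjacent windows. Mann–Whitney is two-sided throughout; the exact p
(enumeration of the U distribution) is used when both n ≤ 8 and the pooled
data are tie-free, otherwise the normal approximation with tie and
continuity corrections — the n ≤ 8 cutoff keeps the exact path cheap. The
log-rank test is the classical Mantel–Cox form (per-event-time
hypergeometric expectation and variance, 1-df chi-square); censored subjects
join risk sets but never event counts, so a subject censored at time zero
leaves the statistic unchanged.

## Synthetic-data generators

One user seed fans out to fixed per-generator child streams
(`SeedSequence(seed, spawn_key=(component,))`), so adding a generator never
perturbs existing outputs; identical seed and configuration give identical
outputs.

- **KO tables** are generated directly on the transformed scale under the
  screen's own model — Gaussian noise, per-(mouse, feature) random
  intercepts drawn once and reused across timepoints — so the additive model
  holds exactly in expectation and noise-free recovery is exact. Defaults:
  10 mice/group, weeks {8, 40, 72, 120}, 200 null + 50 inverted features,
  slope 0.005 transformed-units/week, mouse SD 0.1, residual SD 0.2. The
  slope and noise defaults are chosen for test power: over the 112-week age
  span the planted slope moves a feature by ~0.56 transformed units, about
  3 residual SDs. Concordant features get the same-sign iMB slope attenuated
  by 0.4 so they still carry a true interaction. Real KO tables are counts
  with compositional, heteroscedastic noise; these tables are not, by
  design, so passing recovery tests certifies the inference machinery, not
  robustness to count noise.
- **Model pairs** are deterministic constructions (the seed argument is
  kept for API uniformity); the table in `synthio/models.py` documents how
  each sign pattern is forced (e.g. amensalism via an obligatory 0.1-unit
  co-consumption of the partner's substrate by an otherwise A-limited
  organism).
- **ASV tables** are Dirichlet-multinomial: per-mouse baseline and "aged"
  compositions, linear mixing toward the aged attractor at a per-week,
  per-treatment rate (defaults 0.002 yMB vs 0.006 iMB), concentration 300
  for the realized sample, depths uniform in [8000, 12000]. This produces
  the overdispersion rarefaction must absorb, but no taxonomic structure or
  realistic mouse-gut composition.
- **Cell matrices** are negative-binomial (fixed dispersion 0.4, log-normal
  gene means, log-normal per-cell depth factors); signature and DE effects
  are multiplicative natural-log shifts of gene means in yMB cells.
- **Phenotypes**: saturating weight growth with a late-life yMB ramp whose
  planted weeks-80–120 AUC difference equals `auc_offset` in expectation;
  ipGTT curves peaking near 15–30 min with a null group effect by default;
  survival exponential beyond a shared 60-week minimum lifespan with the
  iMB hazard scaled by the hazard ratio, censored administratively at week
  122.

## Problem sizes and calibration

The Monte-Carlo calibration (`false_discovery_calibration`) uses 50
replicates of the default 250-feature design; with the profiled-REML fitter
this takes well under a minute on one CPU. A flagged feature counts as a
false discovery when its true per-treatment slopes are equal. Recovery of
planted inversions is reported alongside. Test-suite Monte-Carlo loops use
20 seeds (drift ordering, score shifts, DE recovery) or 200–500 replicates
(p-value uniformity), sized to keep the default run in tens of seconds.

## Known limitations

- The screen's Wald p-values are asymptotic; with very few mice per group a
  Satterthwaite or Kenward-Roger correction would be less anti-conservative.
  The calibration runs quantify the actual FDP at the default design.
- The co-growth allocation protocol and neutral bands are configuration;
  different choices can move borderline pairs between classes.
- The synthetic generators share none of the compositionality, sparsity
  structure, taxonomic correlation or batch effects of real sequencing
  data; green tests demonstrate correctness of the computations and
  calibration under the stated models, not performance on real data.
- Survival simulation uses a single exponential phase after a hard minimum
  lifespan — adequate for testing the log-rank machinery, not a demographic
  model of mouse aging.
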