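# Methods

## The model

RT-qPCR reports, per well, a quantification cycle Cq; wells that never cross
the fluorescence threshold before the instrument's limit of detection (LOD)
are exported as "undetermined". `censorq` treats an undetermined well as a
*right-censored* observation: the latent cycle `C*` satisfies
`C = min(C*, LOD)`, and all we know is `C* >= LOD`. The latent process is a
linear model over targets i = 1..I, samples j = 1..J in groups k = 1..K:

    C*_ijk = mu + alpha_i + beta_j + (alpha gamma)_ik + eps_ij,
    eps_ij ~ N(0, sigma_i^2)

`alpha_i` is the target's overall level, `beta_j` a per-sample normalization
factor, and the target-by-group interaction carries differential expression.
Because one Cq cycle is one PCR doubling, a group contrast of the latent
mean is directly a log2 fold change `delta_i`. A reference-gene variant adds
per-sample effects `zeta_j` acting only on flagged reference genes,

    C*_ijk = mu + alpha_i + beta_j + R_i zeta_j + (1 - R_i)(alpha gamma)_ik + eps_ij,

so `mu + beta_j + zeta_j` is the reference-gene normalization factor.

All parameters are estimated jointly by maximum likelihood: observed wells
contribute normal log densities, censored wells normal log survival terms
(`log(1 - Phi((LOD - m)/sigma_i))`, evaluated through the log survival
function, numerically stable for standardized residuals out to +/- 40).
Normalization and testing therefore happen in one step, and the uncertainty
of the normalization propagates into the tests — the point on which the
sequential pipelines fail.

## Identifiability and the definition of delta

The model as written is over-parameterized. The fixed full-rank coding is:
`alpha` sums to zero over targets; `beta` sums to zero *within each group*
(so sample effects are purely technical and group-level location sits in the
interactions); interactions of the first group are pinned at zero; `zeta`
sums to zero over all samples. The mean design has full column rank by
construction (verified by rank checks in the tests).

`delta_i` is defined, for the global variant, as the interaction contrast of
target i **minus its average over the anchor targets**. The reason is
identifiability of the scientific quantity, not convenience: with a free
per-sample effect in the model, a shift of *every* target in one group
cannot be distinguished from a technical group-level sample effect. Exactly
as in global-mean normalization, differential expression is measured
relative to the panel average, and the estimator on complete data reduces
algebraically to the MOD-normalized group-mean difference (the tests verify
agreement to 1e-6). The anchor set consists of the targets with at least one
uncensored well in each compared group; a target with a fully censored group
has a barely identified interaction whose variance would otherwise leak into
every contrast through the shared centering term. With no censoring the
anchor is the full panel. Under the reference-gene variant, `delta_i`
subtracts the `zeta` group-mean contrast instead: differential expression
relative to the reference genes.

The sign convention is `delta_i = (latent mean, reference group) - (latent
mean, comparison group)`; since lower Cq means more transcript, positive
`delta` is up-regulation in the comparison group. A `flip` flag negates it.

## Optimization

The likelihood is maximized with L-BFGS-B using the analytic gradient
(hazard-weighted score terms for censored wells), starting from a
deterministic initialization: least squares on the design with censored
wells held at their bound, and per-target log residual SDs floored at
ln 0.05. The per-target-variance likelihood is *unbounded*: the per-sample
effects have enough degrees of freedom to interpolate any single target
exactly, sending that `sigma_i` to zero with infinite likelihood gain (the
classic degenerate basin of heteroskedastic and mixture likelihoods). Two
safeguards keep the iterate at the interior (scientifically meaningful)
optimum: first, optimization proceeds blockwise — mean parameters given
noise scales (a concave subproblem with a unique optimum), then noise scales
given means (which cannot collapse at interior means) — for two rounds
before the joint quasi-Newton polish; second, if a `sigma_i` still reaches
the floor (1e-3 cycles) while its target has more uncensored wells than
groups, the fit is restarted once with that scale bounded below by half its
initial residual SD, and a warning is attached. `sigma` floors and all
bound hits are reported in `FitResult.warnings`.

Convergence requires a gradient infinity-norm at most 1e-6 (up to a factor
10 on the free coordinates) or the optimizer's own tight relative-objective
criterion; `converged` is never silently true. Standard errors come from
the observed information: a central-difference Hessian of the negative log
likelihood built from the analytic gradient (step `1e-5 * (1 + |theta|)`),
pseudo-inverted for the covariance. Wald tests use the standard normal
reference (maximum-likelihood asymptotics); BH controls the FDR across
targets; fold-change intervals for the selected targets are widened to the
false coverage rate level `1 - Rq/m` before the `2^x` transform.

A caveat the test suite documents honestly: the ML variance carries no
effective-degrees-of-freedom correction, so at small panels the Wald
statistics run systematically above the sequential pooled-t statistics by
about `df_eff / (2 n_i)` with `df_eff ≈ K + (J - K)/I` — roughly 8% at
I = 10, J = 40. The corresponding equivalence test asserts the 5% band that
plain asymptotics would suggest and fails by this structural margin; the
null calibration test measures the same effect as a rejection rate slightly
above nominal at 20 samples per group.

## Normalization

`mod_normalize` implements the modified global mean: center each target
over the samples where it is expressed (uncensored), then center each
sample over its expressed targets; the second-pass means are the factors,
optionally restricted to targets expressed in every sample
(`common_only`). "Expressed" always means uncensored; imputed values can be
supplied explicitly. `lmn_factors` (latent mean normalization) returns the
fitted `beta_j` — the model-based factors that keep using censored wells
through their likelihood terms, which is why they stay stable as censoring
grows while MOD factors drift (the tests assert the widening gap at
10/30/50% censoring).

## Sequential baselines

Three imputation strategies feed per-target two-sample tests (pooled t by
default, Welch and tie-corrected Wilcoxon rank-sum available):

* **LOD**: censored wells take the LOD on the raw scale; MOD normalization
  is applied to the completed matrix.
* **MNV+1**: on the expressed-only normalized matrix, a target's censored
  wells become its maximum normalized value plus one cycle (deliberately
  tied, preserving "worst observed" status).
* **KNN**: a censored well takes the mean expressed value, at that sample,
  of the k = 10 nearest targets under a Euclidean distance over
  pairwise-complete samples rescaled by `sqrt(J / shared)`; ties and
  unexpressed neighbors fall back with warnings.

Normalization precedes MNV+1/KNN imputation and follows LOD imputation,
matching the order in which each strategy is used in practice. Each
pipeline can normalize either by the modified global mean or by per-sample
reference-gene means (classical delta-Cq), for panels with designated
reference genes.

## Synthetic data and the censoring sweep

`generate_synthetic` draws complete panels from the latent model with known
truth. The defaults emulate a two-group neuroblastoma-style miRNA panel:
I = 50 targets, 22 + 39 samples, 20 DE targets at |delta| = 2 (fold change
4) split evenly up and down so the panel-wide average shift is zero,
`alpha_i ~ N(0, 2^2)` (between-target Cq spread), `beta_j ~ N(0, 1)`
(sample-to-sample technical shifts), intercept 28 cycles, and per-target
noise `sigma_i ~ U(1.0, 2.5)` cycles — typical between-tumor biological
variability, chosen so the injected effects give two-sample statistics of
roughly 3–7, the regime where the handling of undetermined wells actually
decides significance. What the generator does *not* emulate: correlated
co-expression between targets, skewed or heavy-tailed noise,
amplification-efficiency differences, and technically missing wells; tests
passing on this generator therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to
model misspecification.

`censoring_sweep` censors the largest remaining Cq one step at a time (ties
at the maximum are censored together; the LOD stays a strict upper bound),
re-bounds every censored well at the prevailing LOD, and re-runs the
unified model and the sequential pipelines on a stride (defaults: every 25
steps for the unified model, every 8 for baselines) — full per-step refits
are exact but needlessly slow at desk scale. Per step it records estimates,
p-values, per-target censored fractions and removal events (targets at or
above the removal threshold, default 80% censored, are dropped from the
fit). `robustness_proportion` reports the censored fraction a truly DE
target reaches at the last evaluated step before its raw p-value first
exceeds 0.05; the sweep-level comparison restricts to DE targets that
actually experience substantial censoring (the measure is undefined in
practice for targets the sweep barely touches) and uses a 0.9 removal
threshold so tests can fail before removal truncates them.

## LOD selection

`select_lod` scores each candidate threshold L by a held-out predictive log
likelihood: a random fraction (default 20%) of the wells below the smallest
candidate — wells uncensored under every candidate, in targets retained
under every candidate — is held out; the model is refitted to the remaining
wells censored at L; and the candidate is scored by the mean log density
the fit assigns to the held-out wells, averaged over 5 holdout splits
shared by all candidates (a paired comparison, keeping split noise out of
the candidate differences). Two failure modes shape this design. Scoring a
candidate on its *own* uncensored wells is monotone in L — discarding the
upper tail always raises the average density — and cannot locate a
boundary. Scoring a fixed *in-sample* evaluation set is biased the other
way: candidates that censor everything except the evaluation set let the
fit specialize to exactly those wells (in-sample optimism), again favoring
the smallest candidate. Holding the evaluation wells out of every fit
removes both. Junk above the true instrument boundary corrupts fits for
candidates above it; candidates below merely discard a little signal — so
the criterion peaks at or near the boundary (tests: within one cycle of a
hard boundary at cycle 39 in most synthetic replicates). Ties resolve to
the smallest candidate; the criterion function is pluggable.

## Numerical choices and degenerate inputs

* Censored log survival terms via `scipy.stats.norm.logsf`; hazards as
  `exp(logpdf - logsf)` — stable to |z| = 40.
* Observations exactly at the LOD are censored (the censoring relation ties
  them to the boundary).
* Explicitly missing wells (token `missing`) are excluded from the
  likelihood and from normalization, never imputed: censoring semantics
  apply only to undetermined reactions.
* A target with one group fully censored stays in the fit (censored terms
  still carry information) with a warning; removal happens only through the
  censoring-fraction threshold.
* With a single target the per-sample effects are dropped (they would
  saturate the mean structure); the design degenerates to a two-group
  location model.
* Duplicate (sample, target) wells, unknown groups and non-numeric cells
  are hard validation errors naming the offending entry.

## Problem sizes used in the checks

The shipped test suite and the acceptance script run entirely on synthetic
panels: 200-replicate Monte-Carlo studies at I = 50 with 61 or 40 samples
for the recovery and calibration checks, two seeded sweeps of ~1500 steps
with strided refits for the robustness ordering, and small panels elsewhere.
These sizes were chosen as the smallest at which the Monte-Carlo noise is
clearly below the effect sizes being asserted.
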