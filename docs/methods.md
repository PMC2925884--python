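# Methods

## Problem and model

The package infers associations between biological pathways and adverse
drug reactions (ADRs) from three observable layers: predicted drug–protein
binding (virtual-docking scores), curated protein→pathway membership, and
per-drug ADR reports. The underlying assumption is that drugs capable of
modulating the same pathway — often through promiscuous off-target binding
— tend to induce similar ADRs. Both binding evidence and *non*-binding
evidence matter: a drug that shares an ADR but is predicted not to touch a
pathway argues against that pathway being necessary for the ADR, and the
regression framework uses both.

Formally, for each ADR group *a* with binary occurrence vector
*y<sub>a</sub>* over drugs, and the drug×pathway score matrix **X** (sum of
retained normalized docking scores over each pathway's member proteins),
the model is a logistic regression

  logit P(y<sub>a,d</sub> = 1) = β₀ + Σ<sub>p</sub> β<sub>p</sub> X<sub>d,p</sub>

estimated in two phases: an L1-penalized screen followed by an unpenalized
stepwise refit with AIC pruning and pooled Benjamini–Hochberg (BH) control.

## Pipeline stages and their conventions

**Ligand eligibility.** Molecular weight within [100, 800] Da (closed
interval) and strictly fewer than 10 rotatable bonds. Drugs missing either
property are dropped with a logged reason rather than guessed.

**Target eligibility.** X-ray (resolution strictly better than 3 Å) or NMR
structure; strictly more than 50 residues; human; EC-numbered; pathway
annotated. Redundancy removal links structures with identity > 90% and
coverage > 90% (both strict, single linkage over a supplied pairwise
similarity table; an absent pair counts as below threshold) and keeps, per
cluster, the structure with the best (lowest) resolution, ties broken by
longer sequence, then lexicographic id. NMR structures carry no resolution
and sort after any resolved X-ray structure. The similarity computation
itself is upstream of the package: any aligner's identity/coverage table
works.

**ADR harmonization.** Phrases are lowercased and suffix-stemmed per token
with a deliberately light rule list iterated to a fixed point (so stemming
is idempotent); a WordNet-style lemmatizer can be plugged in via the same
interface. Stemmed phrases at Levenshtein distance ≤ 1 are merged by
transitive closure; the group representative is the lexicographically
smallest member, which makes group ids deterministic. Whether grouping is
applied to raw or stemmed phrases is switchable (`group_on_stemmed`);
stemmed is the default. Retention rules: post-marketing-only instances are
dropped; instances with known frequency are dropped when frequency minus
placebo frequency (0 when unknown) is below 1%; instances with unknown
frequency pass — the least destructive reading of "if available". Columns
must be supported by ≥ 3 drugs and by no more than floor(0.05·n) drugs;
"more than 5%" is read as exclusive, so a column exactly at the cap
(36 of 730) is kept.

**Docking post-processing.** The per-pair score is the better of the two
pocket attempts; which direction is "better" is a mandatory configuration
key (`better_direction`), never inferred from signs, because score
orientation is engine-specific. Scores are then negated if lower-is-better
so larger always means stronger binding, and z-normalized per receptor —
the scale heterogeneity the normalization addresses lives between
receptors, though a per-drug axis is available since the choice is
genuinely open. Standard deviations are population (n-denominator)
throughout; zero-variance groups (including singleton receptors) carry no
ranking information and map to z = 0 with a warning. Interaction calling
is per drug: retain targets with z strictly greater than that drug's
mean + 1 sd. Features are the *continuous* sums of retained z per pathway,
not binary hit counts; a protein in k pathways credits all k columns.

## Inference details

**λ_max.** For standardized features, the all-zero solution (with intercept
at logit ȳ) is stationary iff λ ≥ (1/n)·max_j |X_jᵀ(y − ȳ)|; that bound is
λ_max, and phase I fits at λ = `rel_lambda`·λ_max per ADR. `rel_lambda`
defaults to 0.1 and is deliberately explicit and swept in tests: it is a
screening knob, not a significance threshold, and the FDR control
downstream is what bounds false discoveries.

**L1 solver.** The penalized objective (mean log-loss + λ‖β‖₁, intercept
unpenalized) is minimized by scikit-learn's saga solver (C = 1/(nλ),
deterministic seed). Two numerical touches are applied after the solve:
coefficients below 1e-10 in magnitude are snapped to exactly zero (the
proximal path produces exact zeros except for round-off at the λ_max
boundary), and the intercept is polished by one-dimensional Newton steps,
because saga's stopping rule can leave it slack when all slopes are zero.
Every returned fit carries an independently computed KKT subgradient
residual; `converged` means that residual is within `tol` (default 1e-6).
Fits that fail the certificate are returned anyway, flagged, and logged.

**Stepwise AIC.** Phase II starts from the full phase-I candidate model
for the ADR and repeatedly takes the single-feature removal or re-addition
that most decreases AIC (= 2k − 2·log L, k counting the intercept),
stopping when no move strictly improves. Starting from the full model
makes the search backward-first with forward re-entry; the classical
forward–backward stepper converges to the same single-step-stable models.
Candidate columns are standardized; coefficients and Wald p-values are
reported on that scale. Perfect separation (detected via the fitter's
warning, non-convergence, or coefficients beyond 1e3 on standardized
features) is handled by exclusion: the coefficient is flagged, its p-value
set to 1, and it can never reach significance — penalized rescue fits were
deliberately avoided to keep silent coefficient inflation out of the
results.

**Multiple testing.** Wald p-values of stepwise survivors are pooled
across *all* ADRs into one BH correction at FDR 0.02 (one family for the
final association list, not per-ADR families). The output table reports
every phase-I candidate; candidates dropped by the stepwise search carry
NA phase-II fields and are never significant. The whole procedure is
deterministic: identical inputs and configuration give byte-identical
outputs.

**Permutation null.** Shuffling which drug owns which docking-profile row
(equivalently, shuffling the drug→ADR pairing) preserves every marginal
statistic of X and Y individually and destroys only their pairing. The
null distribution of significant-association counts is summarized by its
mean/sd, a normal-approximation tail p, and an add-one empirical p,
(1 + #{trials ≥ observed})/(n_trials + 1), which is honest at small trial
counts. The default is 100 trials, configurable.

**Literature filter.** An offline (pathway term, ADR term) → hit-count
table gates associations at ≥ 5 hits by default; absent pairs count 0.
No network access happens anywhere in the pipeline.

## Synthetic data

The generator produces the full input bundle with known ground truth.
Proteins get 1–3 pathway memberships (Binomial(3, 0.25) clipped to ≥ 1,
after seeding every pathway with one member) so multi-membership summation
is exercised. Each drug independently modulates each pathway with
probability 0.15. Docking scores are Gaussian noise (sd 1.0, two pockets,
higher = better) plus a +3 sd shift on proteins of modulated pathways —
large enough that per-drug interaction calling is informative but far from
noiseless. ADR labels are drawn from a logistic model on the *true*
modulation indicators (baseline log-odds −1.1, ≈ 25% prevalence; planted
(pathway, ADR) pairs add their effect size), not from the noisy scores, so
docking noise and label noise are independently controllable. Drug
properties are drawn inside the eligibility ranges, and ADR phrase ids are
constructed pairwise edit-distance ≥ 2 apart so harmonization leaves them
as singleton groups.

What the generator does *not* emulate: correlated docking error (real
engines fail systematically on receptor classes, not i.i.d.), frequency
structure and post-marketing reporting bias in ADR tables, phrase-level
synonymy beyond small edits, and population structure among drugs
(chemical series). Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under the stated model,
not that real docking campaigns carry equivalent signal.

## Standard problem sizes

The calibration and recovery checks run at 200 drugs × 120 proteins × 20
pathways × 12 ADRs with 4 planted effects of 2.0 log-odds — small enough
for quick iteration, large enough that the planted effects are comfortably
detectable and zero-effect runs are almost always empty at FDR 2%.
Permutation controls use 49 shuffles for an empirical-p resolution of
0.02; unit fixtures are smaller (120 drugs, 2 planted effects) and are
only asserted against what that power supports.

## Known limitations

- Association is not causation; cohort-structure effects (a pathway
  characterizing a patient group prone to the ADR) are expected and
  flagged only by downstream reading, not by the statistics.
- Phase-II p-values are post-selection (the same data chose the model);
  the pooled BH control and the permutation null are the honest guards,
  and the null calibration shows near-zero false positives at the default
  settings and desk scale. At much larger candidate spaces the selection
  optimism grows, which is consistent with permutation nulls on real-scale
  data producing substantial association counts.
- Wald p-values are the default; a likelihood-ratio alternative would
  behave better at quasi-separation but costs one fit per coefficient.
- The stepwise search is greedy; it can stop at single-step-stable models
  whose AIC exceeds the exhaustive optimum (the tests bound, and on small
  instances verify, this gap).
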