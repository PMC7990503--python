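# Methods

## Task and payoff structure

The stimulus grid crosses reported payoffs {56, 64, 72, 80, 88, 96} (CNY)
with offer proportions {10%, …, 90%}. The offer is the nearest integer
(ties to even) of proportion × payoff; a pair survives only if the
proposer stays strictly better off than under the alternative option
(reported − offer > 100 − reported). This leaves exactly 36 offers
(2/4/6/7/8/9 per payoff level). Each subject sees every offer once per
condition (SC, SB, DC, DB: Solo/Dyad × Control/Bribe; 144 trials), split
into two runs of 72 such that each offer appears exactly twice per run:
the offers are randomly halved, one half paired with a random pair of
conditions in run 1 and the complementary pair in run 2, and vice versa
for the other half. Only the reported payoff and the conduct are stored;
the computer-indicated option is derived (Control: identical to the
reported one; Bribe: its complement), which fixes the third party's
payoff after a rejection.

Accept: p_PH = offer, p_P = reported − offer, p_T = 100 − reported (Dyad).
Reject: p_P = p_PH = 0; p_T = indicated-option payoff (100 − reported in
DC, reported in DB). The decision covariates exported for neural analyses
are the expected gains (offer; reported − offer) and the third party's
expected loss, 2·reported − 100 on DB trials and 0 elsewhere.

## Choice models

Seven utility functions assign subjective values to accept/reject; all are
linear in their parameters given the trial, so each model is carried as a
per-trial design vector with `SV = offset + x·u` (offset 0 for Models 1–5;
p_PH for the Fehr–Schmidt Models 6–7). Utilities are bounded in [−20, 20],
the inverse temperature τ in [0, 10]; the choice rule is a softmax in
τ·ΔSV, evaluated in log-sum-exp form so τ·SV in the thousands neither
overflows nor underflows. The rejection branch is evaluated with the same
formula on the reject payoffs for every model (no special-casing), which
for Model 5 leaves the ω·q·p_T term — the utility of the third party's
preserved earnings — as the only nonzero rejection term in DB.

Model 7's printed parameter labels cover one condition per agent
(α_P:DC, β_P:DC for the proposer; α_T:DB, β_T:DB for the third party);
the proposer-inequity terms use the former and the third-party terms the
latter in both Dyad conditions, the literal reading of the labels. No
payoff normalizer is applied before the softmax.

## Hierarchical estimation

Each subject's raw parameter vector (utilities + τ) is drawn from
independent group-level normals and mapped to its bounded support by a
probit squashing, `param = lower + (upper − lower)·Φ(z)`. Priors:
group means ~ Normal(0, 1), group sds ~ half-Normal(1), both on the raw
scale. These choices are declared defaults (the convention of common
hierarchical-Bayesian packages for bounded decision parameters), not
asserted as identical to any particular implementation.

The joint posterior is sampled by Hamiltonian Monte Carlo on the
non-centered parameterization (subject standard effects z̃, group means μ,
group log-sds log σ), with:

* analytic gradients (the Bernoulli-logit likelihood of a linear-in-
  parameters SV reduces every gradient to segment sums over trials);
* a diagonal mass matrix adapted from the warmup sample variances
  (restarted once chains reach the typical set) and per-chain step sizes
  adapted to an 85% Metropolis acceptance;
* trajectory lengths jittered uniformly between 16 and 64 leapfrog steps;
* a short gradient-descent initialization per chain, because random
  starting points can sit in saturated-logit regions whose gradients defeat
  step-size adaptation;
* one exact "scale-ridge" Metropolis move per iteration for models whose
  ΔSV offset is zero: the likelihood there constrains only τ·u, and the
  move u → u/c, τ → τ·c (all subjects and the group locations together)
  leaves every logit unchanged, so only priors and the transform Jacobian
  enter the acceptance ratio. This decorrelates the otherwise slowly
  mixing overall-scale direction.

Chains are vectorized in one process. Presets: `paper` (4 chains, 2000
warmup + 1000 kept), `test` (2 chains, 1000 + 500), `acceptance` (4
chains, 1000 + 500). The reduced presets keep 1000 warmup iterations
because mass/step-size adaptation needs them. Convergence is summarized
by split R-hat over all group and individual parameters (arviz); the
default study fits reach max R-hat ≈ 1.02–1.06 at the reduced presets.

Model comparison uses LOOIC = −2·elpd from PSIS-LOO (arviz) on the
per-trial pointwise log-likelihood; differences ≥ 10 are flagged decisive.
For trials whose log-likelihood is numerically constant across draws
(choices every plausible parameter predicts with probability ≈ 1), PSIS
importance weights have zero variance and return NaN; the leave-one-out
density for such trials equals the ordinary log predictive density, which
is substituted.

## Synthetic-data generator

The generator emulates the study conditions: 39 subjects, choices from
Model 5 with individual parameters drawn independently from normals at
the reported group statistics (β_P −0.88 ± 2.48, β_PH 16.02 ± 2.47,
θ 5.94 ± 4.28, ω 0.97 ± 0.82, γ −2.35 ± 2.23), truncated (clipped) to the
bounds for determinism. Parameters are drawn independently; the reported
θ–ω correlation (r = 0.258, n.s.) supports near-independence for the two
that matter downstream. τ is not reported anywhere; the default is a
fixed τ = 0.01, which with the group-mean utilities reproduces grand-mean
condition-wise acceptance rates inside the observed 60–85% band (and, as
it happens, per-condition means and between-subject SDs close to the
reported 61.6 ± 22.6 / 82.8 ± 13.2 / 67.0 ± 20.7 / 83.3 ± 14.8). A
calibration test asserts the band.

Synthetic neural patterns are pure stand-ins for extracted ROI contrast
values — no hemodynamics, no spatial smoothness: per subject, a shared
component (cross-condition correlation), ± half a population-level
condition-effect direction, a behavior-coupling component embedding the
z-scored (θ, ω) into two fixed voxel directions (planted into the
Bribe-minus-Control difference), and iid Gaussian noise. Passing tests on
these patterns show the similarity/decoding statistics detect planted
structure and stay calibrated under nulls; they say nothing about real
BOLD data.

## Validation procedures

Parameter recovery simulates one dataset from the individual-level
posterior means, refits with the same settings, and correlates generating
vs recovered posterior means per parameter. PPC: within-sample predictions
average the analytic softmax acceptance probability over 200 posterior
draws per trial (the draw-wise Bernoulli path is available and agrees in
expectation; the analytic path has strictly lower variance);
out-of-sample fits run 1 only and simulates run 2 once from the
individual posterior means. Predicted and observed per-subject
per-condition acceptance proportions are correlated across subjects
within each condition.

## Similarity analyses

Parameter RDM: Euclidean distance in the (θ, ω) plane, z-scored per
parameter by default (θ's spread is ~5× ω's; the flag is recorded and
switchable). Neural RDM: 1 − Pearson r between subjects' voxel vectors.
IS-RSA: Spearman rho of the strictly-lower triangles; Mantel permutation
(joint row/column permutation of one RDM), one-tailed for positive
association, p = (b + 1)/(n_perm + 1). Pattern similarity: per-subject
Pearson r between condition maps, Fisher z (|r| = 1 clipped and flagged),
two-sided sign-flip test of the group mean. LOSO decoding: linear SVM
with C = 1 (labels +1/−1); the held-out subject is correct iff the
decision value of their first-condition map exceeds the second's
(two-choice forced alternative); ROC/AUC from pooled cross-validated
decision values; permutation null from within-subject label flips. The
forced-choice accuracy is discrete (multiples of 1/n) with heavy ties, so
its permutation p is conservative rather than exactly uniform under the
null; calibration tests therefore check size control and range coverage
for decoding, and strict decile uniformity for the continuous IS-RSA
statistic.

## Problem sizes and numerical choices

Test and acceptance runs use the full 39 × 144 study for fitting,
recovery and PPC; model recovery (Models 1–5) runs on a 15-subject study;
null-calibration properties use 200 seeds at 8–10 subjects with 39–99
permutations; power checks use 39 subjects at 199 permutations. Offer
rounding is banker's rounding; permutation p-values always carry the +1
correction; all randomness flows from explicit integer seeds
(`numpy.random.SeedSequence` spawning per stage).

## Known limitations

* Individual-level ω is only weakly identified in fully synthetic data at
  the calibrated τ: an unregularized per-subject ML fit with τ fixed at
  its generating value recovers ω at r ≈ 0.25, and the hierarchical
  posterior concentrates at σ_ω ≈ 0.02–0.1 (verified by initializing
  chains at σ_ω = 0.8 — they return), so individual ω posterior means
  shrink toward the group mean and the recovery correlation for ω lands
  well below the other four parameters (β_P/β_PH/θ/γ recover at
  ≈ 0.8–0.96). Real subjects evidently carry stronger ω signal (their
  reported across-subject spread of ω posterior means is 0.82); a
  generative model matched only to group-level statistics does not
  reproduce it.
* The likelihood identifies τ·SV, not τ and the utilities separately;
  reported group means are one point on that ridge selected by the priors,
  so they can sit 10–20% away from generating values while predictions
  match.
* The true deposited 36-offer list is reconstructed from the stated grid
  and constraint; the reconstruction reproduces the documented exemplar
  (38 of 96) but is a default, not ground truth, and can be overridden by
  a trial-table file.
* The exact permutation schemes and the z-scoring convention of the
  original similarity analyses are not documented beyond the permutation
  count; the choices above are declared defaults, switchable where
  reasonable.
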