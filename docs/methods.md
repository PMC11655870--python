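# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order the pipeline uses them.

## Task and value scales

A sequence presents N ∈ {10, 12, 14} option values, one at a time; each may
be taken (ending the search) or sampled past, and the final option is taken
by default.  All models operate on a common 1–100 scale in which larger is
better.  Objective prices (GBP) are mapped by reflecting about their mean and
rescaling affinely so the highest (worst) price is 1 and the lowest (best) is
100; subjective values are the mean of two attractiveness ratings already on
that scale.  Relative rank h counts strictly greater earlier values plus one,
so the first option always has h = 1 and ties share the better rank (ties are
rare because sequences are drawn without replacement).  The number of samples
before decision is the take position; a forced final take counts as N.  The
take at the final position carries no likelihood term anywhere, because only
one action exists there.

## Belief model

Option values are modelled as Gaussian draws with a normal-inverse-χ²
conjugate prior.  The prior mean and variance come from the generating values
the agent has been exposed to (the rescaled market for objective runs, the
participant's own averaged ratings for subjective runs); the variance uses
the sample divisor (n − 1).  The one-observation update is

- κ_{n+1} = κ_n + 1, ν_{n+1} = ν_n + 1,
- μ_{n+1} = (κ_n μ_n + x) / (κ_n + 1),
- ν_{n+1} σ²_{n+1} = ν_n σ²_n + κ_n/(κ_n+1) · (x − μ_n)².

The posterior predictive is Student-t with location μ_n, scale
√(σ²_n (1 + 1/κ_n)) and ν_n degrees of freedom, discretised as CDF
differences over 100 equal-width bins spanning [1, 100] (configurable);
out-of-scale mass is folded back in by renormalisation, since options only
exist on the rating scale.  "Exceeds" is always strict.

**Prior confidence defaults: κ₀ = ν₀ = 10.**  The task design exposes the
searcher to the full 90-price generating distribution (each price rated
twice) before any stopping decision, so substantial confidence in the prior
moments is the realistic setting.  It is also required for the Biased Prior
model to behave as intended: with weak confidence (κ₀, ν₀ of order 1) a
shifted prior mean is violently corrected by the first observations — the
(x − μ)² surprise term inflates the posterior variance, which *raises* the
continuation value — so mean sampling is no longer monotone in the shift δ
and the parameter loses identifiability at its pessimistic end.  With
κ₀ = ν₀ = 10 mean greedy sampling is monotone across the full fitted ranges
of δ, C and c.  Both values are exposed in every configuration surface.

## Backward induction and the lookahead abstraction

Exact dynamic programming over future *posteriors* is exponential, so the
solver freezes the posterior at the current decision time t: the same
predictive supplies the transition probabilities for all future positions,
and is refreshed (with the induction recomputed) each time an option is
actually observed.

Taking now is evaluated exactly given the frozen predictive: the final rank
of the current option (relative rank h among t seen) is h + K with
K ~ Binomial(N − t, p_exceed(x_t)), and the expected scheme reward over that
distribution — or, for the continuous scheme, the current value rescaled to
[0, 1].  Payoffs are normalised to [0, 1] in all schemes so the fitted cost
C shares a scale with them.

For the lookahead, a hypothetical future option of value v at position t′ is
ranked against the options actually observed so far, r₀(v) = 1 +
#{observed > v}; draws arriving after t′ enter through the
Binomial(N − t′, p_exceed(v)) term of its take-reward, and the intermediate
lookahead positions contribute through the recursion itself, as opportunities
to stop.  The future self is assumed to observe its rank before acting, so
the max over take/sample sits inside the state-value computation:

u_{t′}(v) = max( E[R(r₀(v) + K_{t′})], C + Σ_j p(j) u_{t′+1}(j) ),  u_N(v) = E[R(r₀(v) + 0)].

Two tempting alternatives were evaluated and rejected.  Treating *all* t′−1
earlier positions as random binomial competitors (and averaging rank rewards
before the action max) systematically undervalues continuation under
rank-based schemes — badly enough to invert the known ordering in which
rank-based payoffs induce more optimal sampling than the continuous payoff
(an exact DP with the full best-so-far state gives mean samples 7.16 vs 5.34
at N = 12 on a known distribution).  Counting the unobserved intermediate
lookahead draws as additional rank competitors has the same deflating defect
in weaker form: under optimal play a high intermediate draw would have been
taken, so its unconditional exceedance probability overstates the
competition.  The chosen abstraction keeps the solver O(N²·G) per sequence
and reproduces the payoff-scheme and sequence-length orderings; it is
validated against a brute-force enumeration oracle (N = 3, 5-point grids,
all schemes, |Δ| < 1e−9) that shares the same frozen-posterior policy but
enumerates every exceedance pattern and future-value combination explicitly.

Tie-break: q_take ≥ q_sample ⇒ take (deterministic; ties are measure-zero on
continuous grids).

## Bias models

- **Cut Off** uses only relative ranks, never the prior.  Its action values
  are 0/1 indicators (sample during the learning period t ≤ c; take the
  first h = 1 option after it), so softmax choice probabilities depend on β
  alone.
- **Cost to Sample** is the Ideal Observer with the recursion's C freed on
  [−1, 1] (payoff units).
- **Biased Prior** is the Ideal Observer with μ₀ shifted by δ ∈ [−100, 100]
  before any updating.

Both reductions are exact identities at C = 0 and δ = 0 — they share the
solver code path — and the suite asserts this on random contexts.

## Fitting

P(take) = 1/(1 + e^{−β ΔQ}) with ΔQ = Q_take − Q_sample; the per-participant
negative log-likelihood sums over all free decisions (choice probabilities
floored at 1e−12; log-sigmoid evaluated overflow-safely).  Optimisation is a
bounded derivative-free simplex: Nelder-Mead in sin-transformed coordinates
x = lo + (hi − lo)(sin z + 1)/2, tolerance 1e−6, cap 2000 evaluations.
Starting values follow the study protocol: β = 1; C = δ = 0 (their optimal
values); cut-off at 37% of the sequence length rounded to the nearest
integer, the asymptotic 1/e secretary optimum.  Because rounding a
continuous c makes the likelihood piecewise-constant (a simplex started
inside a plateau never moves), the cut-off is fitted by exhaustive
enumeration of the integer positions 2..N−1 with a one-dimensional bounded
simplex on β inside each — same contract, robust for a discrete parameter.
Multi-start (jittered within bounds) is available and off by default, since
single protocol starts already pass the recovery gates; saturated regimes
(e.g. strongly negative C, where every sequence stops at position 1) are a
known local-optimum risk for the two continuous models.

BIC = 2·NLL + k·ln n with k = 2 and n = the number of free decisions (forced
final takes excluded — likelihood terms define the sample size).  Best-fit
ties split counts equally with a warning.

## Statistics

The JZS (default) Bayes factor for one-sample/paired designs is computed by
quadrature of the Rouder-style marginal ratio over the variance-ratio
parameter g ~ inverse-gamma(1/2, r²/2), with Cauchy scale r defaulting to
0.71 = √2/2 and the 0.5 / 0.71 / 1 sensitivity ladder reported alongside.
The implementation is cross-checked in the tests against pingouin and a
10⁶-sample Monte-Carlo integration (2% agreement).  Frequentist paired and
independent t-tests report Bonferroni-adjusted p-values, confidence
intervals at the corrected α, and Cohen's d (sd of differences for paired
designs, pooled sd otherwise).  Cohort bias classification: BF01 > 3 at the
default scale reads "equivalent"; BF10 > 3 reads under- or oversampling by
the sign of the mean difference; anything else is inconclusive;
zero-variance differences are flagged degenerate rather than tested.
Participant-versus-Ideal-Observer comparisons are paired (same participants
and sequences); between-cohort comparisons are independent.

## Synthetic data

The published 90-price list is not reproduced; the default market is
normal(900, 150) GBP truncated below 300 — a plausible stand-in for 2-year
flagship contracts — with the family configurable.  Ratings are the scaled
values plus i.i.d. Gaussian noise clipped to [1, 100], with noise variance
σ²_e = Var(values)(1 − r)/r so the expected two-pass correlation matches the
target test–retest r (default 0.85, the empirical 0.81–0.88 range).  The
attenuation formula ignores clipping bias; the realised correlation is
checked empirically rather than corrected analytically.  Sequences draw N
prices without replacement, fresh per sequence; a fixed-sequence mode
reproduces designs where option values were fixed in advance and only the
sequence order randomised.  Cohorts assign each simulated participant a
model and parameters from a configured mix and generate softmax choices;
every artefact is a pure function of the master seed, with per-stage streams
derived by counter so adding a stage never perturbs earlier ones.

What the generator does *not* emulate: response times, slider dynamics,
within-session learning, individual differences in rating reliability, or
the true (unknown) shape of the price distribution.  Passing tests therefore
certify the machinery and its qualitative behaviour under the assumed
generative model, not claims about any particular human dataset.

## Validation scales

Parameter recovery uses β = 10 and 30 sequences per simulant over declared
grids (c: 2..11; C: −1..1 step 0.25; δ: −40..40 step 10), gating Pearson
r ≥ 0.7 for configured-vs-recovered parameters and for the sampling rates
they imply.  Model recovery uses 20 simulants per generating model (c
uniform integer, C ~ U(−0.5, 0.5), δ ~ U(−40, 40)) and requires each row of
the BIC-confusion matrix to peak on its own diagonal.  Directional contrasts
and monotonicity sweeps use 500 matched 12-option sequences; the
undersampling cohort uses 40 participants × 6 sequences under the top-3
monetary scheme.  These sizes keep the full validation suite within a few
minutes on one CPU while leaving the gated effects far from their
thresholds.

## Data interchange

Choices round-trip through a flat CSV (one row per viewed option) carrying
an `n_options` column for the horizon, since a participant who stops early
never reveals the remaining values; when absent, the horizon falls back to
the largest observed position.  For objective-value datasets loaded from
CSV, the prior-generating pool is the set of distinct option values observed
across the dataset (no separate market file exists in the interchange
format); subjective runs use each participant's averaged ratings.

## Known limitations

- The frozen-posterior lookahead is an approximation; it ignores the value
  of information future observations carry for later beliefs, and its rank
  abstraction ignores the policy-path correlation between intermediate draws
  and continued search.
- δ near the pessimistic bound can saturate behaviour (every sequence stops
  immediately), where only β separates candidate parameter values.
- The Biased Values and Biased Rewards strategies are not implemented; the
  former's published description is not operational (censoring vs truncation
  ambiguity) and both failed identifiability screening in the source
  literature.
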