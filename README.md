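# optstop

Computational modelling of **economic optimal stopping** ("full information")
decisions: a Bayes-optimal ideal observer, three parameterised bias models of
human sampling, softmax likelihood fitting, BIC / Bayes-factor model
comparison, and parameter/model recovery — with a synthetic cohort generator
standing in for human data.

The package is aimed at decision scientists who study sequential
take-or-sample choices: a searcher views a fixed-length sequence of option
values (here: smartphone-contract prices rescaled to a 1–100 attractiveness
scale, 100 = best) one at a time and must either *take* the current option,
ending the search, or irreversibly *sample* the next one.  If the last option
is reached it is chosen by default.  The recurring empirical puzzle is that
people often **undersample** — they commit earlier than the optimal policy —
and the models here formalise competing explanations.

## The models

**Ideal Observer.**  A finite-horizon Markov decision process solved by
backward induction.  Option values are treated as draws from a Gaussian with
a normal-inverse-χ² prior (μ₀, κ₀, σ²₀, ν₀), initialised from the mean and
variance of the generating values and updated after every observed option.
The utility of a state is

u_t(s_t) = max_{a} { r_t(s_t, a) + Σ_j p_t(j | s_t, a) · u_{t+1}(j) },

with u_N(s_N) = r(s_N) at the forced final position.  Taking pays through a
customisable payoff scheme R over the option's **final rank** — continuous
(the option's own value rescaled to [0, 1]), top-3 monetary (12p / 8p / 4p /
0) or top-3 stars (5 / 3 / 1 / 0) — where the final rank of an option of
relative rank *h* among those seen is h + K with K ~ Binomial(N − t,
p_exceed) future exceedances under the Student-t posterior predictive.
Sampling pays the cost to sample *C* (fixed to 0 for the Ideal Observer)
plus the expected utility of the next position.

**Bias models** (each with one key parameter θ plus a softmax inverse
temperature β ∈ [0, 100]):

| model | θ | strategy |
|---|---|---|
| Cut Off | c ∈ [2, N−1] | sample to position c, then take the next best-so-far (secretary heuristic; ranks only, no prior) |
| Cost to Sample | C ∈ [−1, 1] | Ideal Observer, but sampling feels costly (C < 0) or rewarding (C > 0) |
| Biased Prior | δ ∈ [−100, 100] | Ideal Observer with δ added to the prior mean; δ < 0 encodes pessimism about future options |

Choices enter a softmax likelihood P(take) = 1 / (1 + e^{−β(Q_take −
Q_sample)}); per-participant (θ, β) are fitted by bounded simplex search and
compared via BIC = 2·NLL + k·ln n, pairwise JZS Bayes-factor t-tests (Cauchy
scales 0.5, 0.71 = √2/2, 1) and best-fit counts.

## Worked example

```bash
python examples/ideal_observer_sampling.py
```

```
Ideal Observer, N=12, 300 matched sequences
  continuous   mean samples = 6.15
  top3_money   mean samples = 7.05
  top3_stars   mean samples = 7.13

Ideal Observer, continuous payoff, sequence-length effect
  N=10  mean samples = 5.54
  N=14  mean samples = 6.78
```

Mean samples-to-decision is the study's main dependent variable.  The two
contrasts shown are the qualitative signatures the models are built around:
rank-based payoff schemes make the optimal policy sample more than the
continuous scheme (rank certainty arrives late in a sequence), and longer
sequences induce more sampling.  The other examples fit the bias models to a
simulated cohort (`fit_bias_models.py`), classify a pessimistic-prior cohort
as undersampling versus the Ideal Observer benchmark
(`undersampling_bias_report.py`, BF10 ≈ 10⁶, mean difference −2.4 samples)
and run small-scale recovery checks (`recovery_checks.py`).

A thin CLI wraps the pipeline for shell use:

```bash
optstop --seed 3 --out run/ compare          # simulate -> fit -> compare
optstop --seed 3 ideal --scheme top3_money --length 10
optstop --seed 3 --out rec/ recover --kind model
```

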