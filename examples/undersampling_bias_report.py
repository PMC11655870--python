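"""Classify a cohort's sampling bias against the Ideal Observer benchmark.

Simulates a cohort of Biased Prior agents with pessimistic prior shifts
(delta between -40 and -10) under the top-3 monetary payoff, runs the Ideal
Observer over the same sequences, and applies the default-Bayes-factor
classification: BF01 > 3 reads "equivalent", BF10 > 3 with a negative mean
difference reads "undersampling".
"""

import numpy as np

from optstop import cohort_bias_report, ideal_stop_position, init_prior
from optstop.payoffs import PayoffScheme
from optstop.synthetic import CohortDesign, simulate_cohort

scheme = PayoffScheme.top3_money()
design = CohortDesign(
    n_participants=30,
    n_sequences=6,
    scheme=scheme,
    model_mix=(("biased_prior", lambda rng: rng.uniform(-40.0, -10.0), 10.0),),
    master_seed=7,
)
participants, _ = simulate_cohort(design)

cohort_means, ideal_means = [], []
for p in participants:
    prior = init_prior(p.prior_values)
    ideal_stops = [ideal_stop_position(seq, scheme, prior)[0] for seq in p.sequences]
    cohort_means.append(p.mean_samples)
    ideal_means.append(np.mean(ideal_stops))

report = cohort_bias_report(cohort_means, ideal_means)
print(f"cohort mean samples : {report.mean_participant_samples:.2f}")
print(f"ideal  mean samples : {report.mean_ideal_samples:.2f}")
print(f"mean difference     : {report.mean_difference:+.2f}")
for scale, bf10 in report.bf10.items():
    print(f"BF10 (Cauchy r={scale}) : {bf10:.3g}")
print(f"classification      : {report.classification}")
print(
    "\nA negative difference with BF10 > 3 at the default scale is the"
    "\nundersampling signature: agents commit before the optimal point"
    "\nbecause their prior tells them future options will be poor."
)
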