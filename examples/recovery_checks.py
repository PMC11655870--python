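"""Can the fitted parameters and models be trusted?  Recovery at small scale.

Parameter recovery: simulate one agent per grid value of the key parameter,
refit the generating model, and correlate configured with recovered values.
Model recovery: simulate from each model, fit all three, count BIC wins.
(Reduced sizes for a quick demonstration; the test suite runs the full-scale
versions.)
"""

from optstop.recovery import model_recovery, parameter_recovery
from optstop.synthetic import CohortDesign

design = CohortDesign(n_sequences=15, master_seed=0)

print("parameter recovery (beta=10, 15 sequences/simulant)")
for model, grid in (
    ("cutoff", [2, 4, 6, 8, 10]),
    ("biased_prior", [-40, -20, 0, 20, 40]),
):
    res = parameter_recovery(model, theta_grid=grid, beta=10.0, design=design, seed=1)
    print(f"  {model:13s} r(theta) = {res.parameter_r:.2f}   "
          f"r(sampling rate) = {res.sampling_rate_r:.2f}")

print("\nmodel recovery confusion matrix (rows = generating model,")
print("columns = best-fitting model by BIC, 6 simulants/model):")
confusion = model_recovery(design=design, n_simulants=6, beta=10.0, seed=3)
print(confusion.round(2).to_string())
print(
    "\nCorrelations near 1 mean the key parameters are identifiable from"
    "\nchoice data; a diagonally dominant matrix means data simulated by one"
    "\nmodel are rarely explained better by another."
)
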