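"""A small in-silico clinical trial of nab-paclitaxel monotherapy.

Generates virtual patients by Latin-hypercube sampling, grows each tumor
to its sampled pre-treatment size (patients that never reach it are
eliminated), treats for 400 days, and reports ORR and duration of
response with bootstrap confidence intervals.  A population of hundreds
behaves like the shipped defaults; n=30 keeps this example fast.
"""

from tnbcqsp import trial as T

population = T.generate_population(T.default_distributions(), 30, seed=5)
for record in population:
    T.initialize_patient(record, horizon=1500.0)
    T.apply_plausibility_filter(record)
evaluable = [r for r in population if r.status == "initialized"]
print(f"{len(evaluable)}/{len(population)} virtual patients reached their "
      "pre-treatment size")

result = T.run_trial(evaluable, "nab-paclitaxel-mono", seed=1)
print(f"ORR {result.orr:.0f}% "
      f"(95% bootstrap CI {result.orr_ci.ci_low:.0f}-{result.orr_ci.ci_high:.0f}%)")
print(f"median duration of response: {result.dor_median:.1f} months")
print(result.patients.best_overall.value_counts().to_string())
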