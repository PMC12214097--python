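"""Kaplan-Meier / log-rank comparison of two synthetic injection arms.

Simulates a dual-target responder cohort from the published recurrence
summaries and a historical standard-injection arm with a higher recurrence
fraction and shorter times, labels both with the 365-day rule, and compares
time to pain recurrence. The restricted mean survival times (area under each
KM curve up to the last observed day) and the log-rank test are printed.
"""
import numpy as np

from subacrodyn import km_logrank, label_cohort, simulate_cohort, table_defaults

dual_params = table_defaults("table3")
dual_params.seed = 11
dual = label_cohort(simulate_cohort(dual_params))

std_params = table_defaults("table3")
std_params.groups["positive"].n = 35   # standard arm recurs more often
std_params.groups["negative"].n = 35
std_params.recurrence_time_mean_days = 150.0  # ... and sooner
std_params.seed = 12
standard = label_cohort(simulate_cohort(std_params))

times = np.concatenate([dual["time_days"], standard["time_days"]]).clip(min=1)
events = np.concatenate([dual["event"], standard["event"]])
arms = np.array(["dual_target"] * len(dual) + ["standard"] * len(standard))

curves, lr = km_logrank(times, events, arms)
for name, c in curves.items():
    print(f"{name:12s} n={c.n:3d} events={c.n_events:3d} "
          f"mean time to recurrence {c.mean_time:6.1f} days "
          f"(95% CI {c.mean_ci_low:.1f} to {c.mean_ci_high:.1f})")
print(f"log-rank chi-square {lr.chi_square:.2f}, p = {lr.p_value:.4f}")
print("\nA longer restricted mean in the dual-target arm indicates a more")
print("durable treatment effect; p < 0.05 marks the separation significant.")
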