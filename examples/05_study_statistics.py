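"""Run a full simulated study and the repeated-measures statistics.

Simulates subjects x tasks x environments with environment-linked scale
errors and speed-linked drift/noise, evaluates every cell, then asks
the inferential questions of a tracker-validation study: does speed
error depend on the environment, and does relative translation error
depend on locomotion speed?
"""

import headtrack as ht
from headtrack.stats_summary import boxplot_summary, kde
from headtrack.synthetic import generate_study

pairs = generate_study(subjects=6, duration=45.0, seed=21)
results, reports = ht.run_evaluation(pairs)
print(f"evaluated {len(reports)} cells ({sum(r.failed for r in results)} failed)")

df = ht.metric_table(reports)
spe = df[(df.metric == "SpE") & (df.environment != "tracking_space")]
print("\nmedian SpE by environment (%):")
print(spe.groupby("environment").value.median().round(2).to_string())

anova = ht.pooled_statistics(
    [r for r in reports if r.environment != "tracking_space"],
    "SpE", factor="environment", second_factor="task",
)
for name, res in anova.items():
    print(f"two-way RM-ANOVA {name}: F({res.df[0]},{res.df[1]}) = {res.F:.2f}, p = {res.p:.4f}")

rte = ht.pooled_statistics(
    [r for r in reports if r.environment == "tracking_space"], "RTE", factor="task",
)
print(f"one-way RM-ANOVA RTE ~ task: F{rte.df} = {rte.F:.2f}, p = {rte.p:.4f}")
for c in rte.posthoc:
    print(f"  {c.pair[0]:>9s} vs {c.pair[1]:<9s} t = {c.t:+.2f}, "
          f"p_corr = {c.p_corrected:.4f}, {c.direction}")

speeds = df[(df.metric == "SpE") & (df.task == "walk")].value.to_numpy()
box = boxplot_summary(speeds)
print(f"\nwalking SpE: median {box.median:.2f}%, IQR [{box.q1:.2f}, {box.q3:.2f}]%")
print()
print("Speed under-estimation deepens with environment size (the simulated")
print("scale error grows with scene distance), and RTE rises with task speed")
print("(drift and noise grow with locomotion speed) - the sign structure a")
print("real tracker evaluation reports.")
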