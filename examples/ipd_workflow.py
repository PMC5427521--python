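"""Full IPD analysis: five relative-effect CIs plus survival analysis.

Simulates a trial with a known 25% multiplicative reduction in cold
duration (lognormal baseline, 50 patients per arm), then runs every
confidence-interval construction and the recovery-time survival analysis.
"""

import relscale as rs
from relscale.survival import cox_binary

sim = rs.simulate_trial(
    rs.TrialConfig(seed=4, ratio=0.75, n_treated=50, n_control=50)
)
ipd = sim.ipd
trial = rs.summarize_ipd(ipd, treated_arm="treated")
print(f"treated mean {trial.treated.mean:.2f} d, "
      f"control mean {trial.control.mean:.2f} d (true ratio 0.75)")

for method in ("normalized-t", "log-t", "taylor", "fieller", "bootstrap"):
    kwargs = {"reps": 9999, "seed": 4} if method == "bootstrap" else {}
    e = rs.effect_relative(trial, method=method, ipd=ipd, **kwargs)
    print(f"  {e.method:>28}: {e.point:6.1f}% "
          f"(95% CI {e.ci_low:6.1f} to {e.ci_high:6.1f})")

perm = rs.permutation_test(ipd, seed=4)
lr = rs.logrank(ipd)
cox = cox_binary(ipd)
print(f"\npermutation test P = {perm.p_value:.4f} ({perm.method})")
print(f"logrank test     P = {lr.p_value:.4f}")
print(f"Cox rate ratio for recovery: {cox.rr:.2f} "
      f"(95% CI {cox.ci_low:.2f} to {cox.ci_high:.2f})")

print(
    "\nAll five intervals should bracket the true -25% effect; a rate ratio\n"
    "above 1 means the treated arm recovers faster."
)
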