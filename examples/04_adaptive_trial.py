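"""One full adaptive predictive-enrichment run.

Replays a synthetic candidate pool through the group-sequential design:
at each interim the enrolled data are split, phenomapped, a benefit model
is trained, and — if the held-out half shows treatment-effect
heterogeneity and the revised power calculation allows it — the next
period's enrollment is conditioned on predicted benefit.
"""

from phenoadapt import generate_trial, run_adaptive_trial
from phenoadapt.scenarios import desk_design, planted_hte_config

ds = generate_trial(planted_hte_config(seed=1))
spec = desk_design()

result = run_adaptive_trial(ds, spec, seed=2, n_grid=6)
print("look  time(d)  boundary z  interaction p  gate  q     revised N")
for d in result.decisions:
    p = "--" if d.interaction_p is None else f"{d.interaction_p:.3f}"
    q = "--" if d.q_chosen is None else f"{d.q_chosen:.2f}"
    n = "--" if d.n_revised is None else str(d.n_revised)
    print(f"{d.look_index:4d}  {d.calendar_time:7.0f}  {d.boundary_z:10.3f}  "
          f"{p:>13s}  {str(d.gate_passed):>5s}  {q:>4s}  {n:>9s}")

print(f"\nfinal N {result.final_n} of {ds.n} candidates "
      f"({100 * (result.final_n - ds.n) / ds.n:+.1f}%)")
print(f"final HR {result.final_hr:.3f} (p={result.final_p:.4f}); "
      f"arm-balance chi-square p {result.arm_balance_p:.2f}")
print(f"cumulative events at looks: {result.event_counts}")
if result.win_ratios:
    wr = result.win_ratios[-1]
    print(f"final safety win ratio {wr.wr:.2f} [{wr.ci_low:.2f}, {wr.ci_high:.2f}] "
          "(values near 1 = no safety penalty from enrichment)")
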