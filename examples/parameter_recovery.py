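"""Small parameter-recovery experiment: simulate -> fit -> aggregate.

Each replicate simulates a trial from known parameters, refits the joint
model, and the summary reports per-parameter bias, empirical SE and 95%
CI coverage.  Five fast replicates here; scale n_reps up for real use.
"""

from fvcjoint import JointModelSpec, SimulationConfig, recovery_experiment

config = SimulationConfig(
    n_subjects=150, period="whole",
    hazard_ata_neg=(0.3,), hazard_ata_pos=(0.3,),
)
spec = JointModelSpec(n_internal_knots=2, gh_nodes=5, min_events=10, period="whole")
summary, reps = recovery_experiment(config, n_reps=5, spec=spec)

cols = ["parameter", "truth", "mean_estimate", "bias", "empirical_se", "ci_coverage"]
print(summary[cols].round(3).to_string(index=False))
# 'alpha' is the association coefficient (truth -ln(1.13) = -0.1222);
# 'arm_x_time_years' the treatment slope difference.  With only 5
# replicates the coverage column is coarse (multiples of 0.2).
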