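"""Fit the slope-association joint model and print the hazard-ratio table.

A shared-parameter joint model links a linear mixed model of FVC%
predicted to a piecewise-exponential hazard for first hospitalisation or
death; the association coefficient alpha converts a 1-point-per-year
faster FVC decline into a hazard ratio exp(-alpha).
"""

from fvcjoint import (
    JointModelSpec,
    SimulationConfig,
    fit_joint,
    hazard_ratio_report,
    publication_table,
    simulate_dataset,
)

dataset, truth = simulate_dataset(SimulationConfig(n_subjects=300), seed=7)
fit = fit_joint(dataset, JointModelSpec(association="slope"))
report = hazard_ratio_report(fit)

print(f"n={fit.n}, events={fit.n_events}, loglik={fit.loglik:.1f}")
print(f"alpha = {fit.alpha:.4f} (SE {fit.alpha_se:.4f}), "
      f"Wald p = {report.p_value:.4f}")
print(report.table.round(3).to_string(index=False))
print()
print(publication_table(fit, report).round(3).to_string(index=False))
# Rows are hazard ratios for 1/3/5-point declines in the annual FVC%
# slope: values above 1 mean faster decline carries a higher risk of
# hospitalisation or death.  The simulation truth is HR(1) = 1.13.
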