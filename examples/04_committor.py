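"""Validate a candidate transition state by committor shooting.

On a symmetric 5 kcal/mol double well, trajectories launched from the
barrier top with thermal velocities should commit to the product basin
half the time; launched from inside the reactant well, almost never.
"""

from fieldpmf.committor import (
    LangevinParams,
    committor_probability,
    double_well,
    validate_ts_ensemble,
)

well = double_well(barrier_height=5.0, half_separation=1.0)
dyn = LangevinParams(temperature=343.15, friction=10.0, timestep=0.001, mass=12.0)

top = committor_probability(well, start=0.0, n_shots=400, dynamics=dyn, seed=2024)
print(f"barrier top : p_product = {top.p_product:.3f} "
      f"(95% CI {top.ci95[0]:.3f}-{top.ci95[1]:.3f}) — a true TS sits near 0.5")

basin = committor_probability(well, start=-0.9, n_shots=200, dynamics=dyn, seed=7)
print(f"reactant well: p_product = {basin.p_product:.3f} — committed reactant geometry")

verdict = validate_ts_ensemble(well, [-0.02, -0.01, 0.0, 0.01, 0.02],
                               n_shots=120, dynamics=dyn, seed=3)
print(f"ensemble median p = {verdict.median_p:.3f}; "
      f"verdict: {'PASS' if verdict.passed else 'FAIL'} "
      "(pass = median committor in [0.4, 0.6])")
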