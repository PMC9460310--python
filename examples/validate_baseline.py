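"""First-cycle expenditure validation.

The model's first annual cycle under the base case represents 2019, so its
undiscounted outpatient and inpatient spending must reproduce the reference
expenditure table (computed here by an independent closed-form ledger).  A
1% perturbation of any cell must be caught.
"""

import saltsim as ss

params = ss.generate_parameters(ss.SyntheticConfig(seed=42))
trajectory = ss.run_cohort(params, ss.make_scenario(params, "base"))
reference = ss.generate_reference_expenditures(params)

print("reference 2019 expenditures (JPY, billions):")
print((reference / 1e9).round(1))

failures = ss.validate_first_cycle(trajectory, reference)
print(f"\nvalidation failures: {failures!r}")
print("an empty list means the engine reproduces baseline spending exactly")

perturbed = reference.copy()
perturbed.loc[("ihd", "male"), "inpatient"] *= 1.01
failures = ss.validate_first_cycle(trajectory, perturbed)
print(f"\nafter inflating one cell by 1%: {len(failures)} failing cell")
f = failures[0]
print(f"  {f.disease}/{f.sex}/{f.care_type}: "
      f"modeled {f.modeled / 1e9:.2f}B vs reference {f.reference / 1e9:.2f}B JPY")
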