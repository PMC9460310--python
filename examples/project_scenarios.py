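"""Project cardiovascular events, deaths, and costs under salt targets.

Runs the status-quo base case and the three salt-reduction scenarios
(8, 6, 5 g/day over 10 years) and prints what each target would avert.
"""

import saltsim as ss

params = ss.generate_parameters(ss.SyntheticConfig(seed=42))

base = ss.summarize(
    ss.run_cohort(params, ss.make_scenario(params, "base")), params.costs
)
pooled = base.pooled()
print("base case (salt held at 2019 levels, 10 years):")
print(f"  incident cases: {pooled['incidence_ihd']:,.0f} IHD, "
      f"{pooled['incidence_stroke']:,.0f} stroke")
print(f"  deaths:         {pooled['deaths_ihd']:,.0f} IHD, "
      f"{pooled['deaths_stroke']:,.0f} stroke")
print(f"  discounted expenditures: USD {base.total_cost_usd() / 1e9:.1f} billion")

comparisons = []
for name in ("8g", "6g", "5g"):
    scenario = ss.make_scenario(params, name)
    summary = ss.summarize(ss.run_cohort(params, scenario), params.costs)
    comparisons.append(ss.compare(base, summary))
    print(f"\ntarget {scenario.target_salt:.0f} g/day "
          f"(annual reduction rate {100 * scenario.annual_reduction_rate:.1f}%):")
    c = comparisons[-1]
    print(f"  averted events: {c.averted_events():,.0f} ({c.percent('events'):.1f}%)")
    print(f"  averted deaths: {c.averted_deaths():,.0f} ({c.percent('deaths'):.1f}%)")
    print(f"  saved:          USD {c.saved_cost_usd() / 1e9:.2f} billion "
          f"({c.percent('cost'):.1f}%)")

print("\nsummary table (counts rounded, percentages of the base case):")
print(ss.comparison_table(comparisons).to_string(index=False))
print("\ndeeper targets always avert more: the pathway is monotone in salt.")
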