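"""Generate and fit a full synthetic aging cohort.

25 subjects (ages 25-80), two regions, three metabolites, stick-model
ground truth at region-typical diffusivities, study-matched noise. Prints
cohort-mean estimates against the generating values.
"""

from metabdiff.fitting import default_specs, fit_cohort
from metabdiff.synthetic import (DEFAULT_GROUND_TRUTH, CohortConfig,
                                 generate_cohort)

records = generate_cohort(CohortConfig(seed=42))
table = fit_cohort(records, default_specs(), seed=42)

sticks = table[table["model"] == "astrosticks"]
print("cohort-mean stick diffusivity (truth in parentheses):")
for (region, metab), cell in sticks.groupby(["region", "metabolite"]):
    truth = DEFAULT_GROUND_TRUTH[(region, metab)].Dintra
    print(f"  {region:10s} {metab:5s} Dintra = {cell['estimate'].mean():.3f}"
          f" +/- {cell['estimate'].std():.3f}  ({truth:.3f})")

at_bound = table[table["at_lower_bound"]]
print(f"\nestimates at the fitting lower bound: {len(at_bound)} "
      f"of {len(table)} rows")
print(at_bound.groupby(['model', 'parameter']).size().to_string())
print("\nKintra collapses to its bound for many subjects because the "
      "generating model has no intra-stick kurtosis — exactly the rows "
      "the trajectory analysis excludes as unreliable.")
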