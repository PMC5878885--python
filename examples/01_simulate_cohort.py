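"""Generate a synthetic ED cohort with a known informative complaint set.

The generator emulates the structure the search assumes: a two-level
complaint hierarchy with long-tailed complaint frequencies, the standard
triage predictor blocks, and a rare critical-care outcome driven by
category-level effects plus complaint-specific shifts for a planted set S.
"""
from levelopt import SyntheticConfig, generate_cohort, save_cohort

config = SyntheticConfig(
    n_patients=10_000,
    n_categories=4,
    complaints_per_category=(5, 5),
    informative_complaint_count=6,
    specific_effect=0.8,
    target_prevalence=0.03,
    seed=42,
)
cohort, truth = generate_cohort(config)

print(f"visits:              {cohort.n_records}")
print(f"specific complaints: {cohort.hierarchy.n} in {len(cohort.hierarchy.categories)} categories")
print(f"realized prevalence: {cohort.outcome.mean():.4f} (target {config.target_prevalence})")
print("planted informative complaints (signed log-odds shifts):")
for complaint, delta in truth.informative.items():
    print(f"  {complaint} ({truth.hierarchy.parent[complaint]}): {delta:+.1f}")

save_cohort(cohort, "/tmp/cohort.csv", "/tmp/hierarchy.csv")
print("wrote /tmp/cohort.csv and /tmp/hierarchy.csv")
# The prevalence should land within sampling noise of the target; the
# planted set is what a successful search should rediscover from outcomes.
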