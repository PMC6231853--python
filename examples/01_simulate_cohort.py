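"""Generate a synthetic remote-study cohort and inspect its funnel.

The generator emulates a fully app-based observational study: downloads
thin to consents and enrollments, participants are randomized 1:1 into
arms A/B, and each week a per-arm hazard drops some participants.
"""

from siteless import CohortConfig, funnel_summary, generate_cohort

config = CohortConfig(seed=7)
records, funnel = generate_cohort(config)

print(funnel_summary(funnel).to_string(index=False))
print()
n_a = sum(1 for r in records if r.group == "A")
print(f"arm A: {n_a}, arm B: {len(records) - n_a} "
      "(unstratified 1:1 randomization)")
week12 = sum(1 for r in records if r.active_at(12))
print(f"still active at week 12: {week12} of {len(records)} enrolled")
# The pct_of_downloads column shows how the enrollment funnel thins:
# every stage is a count plus its share of all app downloads.
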