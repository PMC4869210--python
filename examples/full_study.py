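"""Run the complete simulated validation study end to end.

Simulates a cohort under the default over-reporting conditions, reduces
the device data (wear-time imputation, blocking, valid days, weekly
5/2 scores), scores the questionnaires, applies the exclusion rules and
prints the agreement battery.
"""

from metbout import CohortConfig, StudyConfig, run_study, verify_fixtures

report = run_study(StudyConfig(cohort=CohortConfig(n_participants=52, seed=7)))

print(f"participants: {report['n_participants']}")
print(f"excluded (insufficient valid days): {report['exclusions']['insufficient_days'] or 'none'}")
print(f"excluded from test-retest (exercised more): "
      f"{report['exclusions']['test_retest_exercised_more'] or 'none'}")

for name in (
    "ipaq_followup_vs_device_blocked",
    "maas_followup_vs_device_blocked",
    "maas_vs_ipaq_followup",
    "maas_baseline_vs_followup",
):
    c = report["comparisons"][name]
    ba = c["bland_altman"]
    line = (f"{name:34s} r={c['pearson_r']:+.2f}  "
            f"BA mean={ba['mean_difference']:+.2f} "
            f"LoA=({ba['loa_lower']:+.2f}, {ba['loa_upper']:+.2f})")
    if "categorical" in c:
        line += f"  kappa={c['categorical']['kappa']:.2f}"
    print(line)

print("\nfixture verification (published tables):")
for name, r in verify_fixtures().items():
    print(f"  {'PASS' if r['passed'] else 'FAIL'} {name}: {r['value']}")
# Positive Bland-Altman means for questionnaire-vs-device comparisons
# show the simulated recall bias (self-report > monitor); the fixture
# section re-derives the published agreement statistics exactly.
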