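"""End-to-end dyad pipeline on a small synthetic cohort.

Generates a cohort of synthetic client-caregiver recordings (wearable-like
native rates, planted coupling directions, two deliberately short
recordings), runs windowing, quality control and the per-variable
inter-system recurrence analysis, and prints the direction-frequency table
plus one incident's multiplex network.
"""

from irnet import (
    AnalysisConfig,
    analyze_incident,
    extract_window,
    generate_fixture,
    qc_filter,
    summarize_directions,
)

cohort = generate_fixture(
    n_incidents=6,
    coupling_spec={"EDA": "client", "ACC": "caregiver"},
    seed=7,
    n_short=2,
)
windows = [extract_window(rec) for rec in cohort]
retained, excluded = qc_filter(windows)
print(f"{len(cohort)} incidents generated, {len(excluded)} excluded by QC:")
for entry in excluded:
    print(f"  {entry['incident_id']}: {entry['reason']}")

cfg = AnalysisConfig()  # 35-min window, 1 Hz, lag 100, dim 5, RR .05/.04
per_incident = []
for win in retained:
    summaries, multiplex = analyze_incident(win, cfg)
    per_incident.append(summaries)

print("\nDirection frequencies (%) across retained incidents:")
print(summarize_directions(per_incident).round(1).to_string(index=False))

print("\nMultiplex network of the first retained incident "
      "(edge weight = |dC|):")
for a, b, attrs in multiplex.edges(data=True):
    print(f"  {a:4s} - {b:4s}  weight {attrs['weight']:.3f}  {attrs['direction']}")
strengths = dict(multiplex.nodes(data="strength"))
top = max(strengths, key=strengths.get)
print(f"strongest vertex: {top} (strength {strengths[top]:.3f})")
print("\nPlanted truth: the client drives EDA, the caregiver drives ACC;"
      "\nwith only a handful of incidents the table is a noisy estimate of"
      "\nthose planted odds, which is the point of the planted-direction"
      "\nrecovery checks in the test suite.")
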