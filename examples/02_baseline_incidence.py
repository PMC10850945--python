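"""Baseline mutation incidence in the 79-patient fixture cohort.

Runs germline filtering and pathogenicity classification, then tabulates
per-gene and per-ESR1-variant incidence at the printed precision.
"""

from ctdnatrack import fixture_baseline_cohort, summarize_cohort

summary = summarize_cohort(fixture_baseline_cohort())
print(f"patients: {summary.n_patients}\n")
print("per-gene incidence (percent of all patients with >=1 pathogenic call):")
print(summary.gene_incidence.to_string(index=False))
print()
print("ESR1 variant spectrum (one patient may carry several variants):")
print(summary.esr1_variants.to_string(index=False))
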