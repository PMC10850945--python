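"""Acquired mutations and ESR1 clonality dynamics on fulvestrant.

Compares baseline and progression call sets patient by patient in the
69-patient paired fixture: a pathogenic variant key present at progression
but absent at baseline is acquired; clonality tracks the count of distinct
activating ESR1 variants (monoclonal = 1, polyclonal >= 2).
"""

from ctdnatrack import annotate_cohort, call_acquired, fixture_paired_cohort, summarize_cohort

cohort = fixture_paired_cohort()
summary = summarize_cohort(cohort)

print("acquisition at progression (percent of 69 paired-timepoint patients):")
print(summary.acquisition.to_string(index=False))
print()
print("ESR1 clonality transitions:")
print(summary.clonality.to_string(index=False))
print()

classified = annotate_cohort(cohort)
base, prog = classified["PP07"]
res = call_acquired("PP07", base, prog)
print("patient PP07 (carries five separate F404 base changes):")
print("  acquired protein keys:",
      sorted(cc.call.protein_change.render() for cc in res.acquired))
print("  maintained:", sorted(cc.call.protein_change.render() for cc in res.maintained))
print("F404V is carried by this one patient only, so the recurrence clause")
print("(>= 2 patients) does not mark it pathogenic; F404L and F404I recur.")
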