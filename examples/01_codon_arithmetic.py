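"""Translate ESR1 cDNA substitutions to protein consequences.

Maps published coding-sequence changes through codon arithmetic on the
packaged ESR1 CDS and checks which substitutions destroy the aromatic ring
at residue F404 (the ring forms a pi-stacking bond with estradiol and
fulvestrant; losing it is the proposed resistance mechanism).
"""

from ctdnatrack import infer_protein_change, is_aromatic, load_reference_cds, parse_hgvs_c

cds = load_reference_cds()
print("cDNA change -> protein consequence (NM_000125.4 coordinates):")
for cdna in ("1210T>C", "1210T>A", "1210T>G", "1212T>A", "1613A>G", "1138G>C"):
    prot = infer_protein_change(parse_hgvs_c(cdna), cds)
    note = ""
    if prot.codon_index == 404:
        note = "  (aromatic ring lost)" if not is_aromatic(prot.alt_aa) else ""
    print(f"  {cdna:>8} -> {prot.render()}{note}")
print()
print("Five distinct base changes of codon TTT yield F404L/I/V; every one")
print("replaces phenylalanine with a residue lacking an aromatic ring.")
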