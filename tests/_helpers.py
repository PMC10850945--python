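"""Shared test utilities: independent oracles and call builders."""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from ctdnatrack.classify import classify_pathogenic
from ctdnatrack.core import (
    AnnotationRecord,
    Consequence,
    TargetabilityLevel,
    Timepoint,
    VariantCall,
    parse_hgvs_c,
    parse_protein_change,
)


def fisher_two_sided_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Independent oracle: two-sided Fisher p by full hypergeometric enumeration.

    With margins fixed, enumerate every achievable top-left cell k and sum the
    probabilities of all tables no more likely than the observed one.
    """
    row1 = n11 + n10
    col1 = n11 + n01
    n = n11 + n10 + n01 + n00
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, col1, row1)
    p_obs = hypergeom.pmf(n11, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def mk_call(
    gene: str = "ESR1",
    protein: str | None = "D538G",
    cdna: str | None = None,
    vaf: float = 5.0,
    pop_af: float = 0.0,
    germline_flagged: bool = False,
    consequence: Consequence = Consequence.MISSENSE,
    timepoint: Timepoint = Timepoint.BASELINE,
) -> VariantCall:
    return VariantCall(
        gene=gene,
        cds_change=parse_hgvs_c(cdna) if cdna else None,
        protein_change=parse_protein_change(protein) if protein else None,
        consequence=consequence,
        vaf=vaf,
        pop_af=pop_af,
        germline_flagged=germline_flagged,
        timepoint=timepoint,
    )


def mk_classified(
    gene: str = "ESR1",
    protein: str = "D538G",
    hotspot: bool = True,
    oncogenic: bool = True,
    level: str = "none",
    recurrence: int = 0,
    timepoint: Timepoint = Timepoint.BASELINE,
    cdna: str | None = None,
    vaf: float = 5.0,
):
    call = mk_call(gene=gene, protein=protein, cdna=cdna, vaf=vaf, timepoint=timepoint)
    ann = AnnotationRecord(hotspot, oncogenic, TargetabilityLevel(level), recurrence)
    return classify_pathogenic(call, ann)
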