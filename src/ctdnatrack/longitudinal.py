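"""Paired baseline/progression comparison and cohort summarization.

Acquisition is keyed at the protein level by default — two base changes
producing one amino-acid change count once for patient-level incidence —
while nucleotide-level keys remain available for base-change tallies.
Percentages are rounded half-up to the printed precision (integer percents
for gene-level incidence and acquisition, one decimal for ESR1-variant and
clonality figures).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd

from .classify import ClassifiedCall, annotate_cohort
from .core import PatientTimeline, cds_to_codon, Consequence, variant_key

__all__ = [
    "AcquisitionResult",
    "ClonalityState",
    "ClonalityTransition",
    "CohortSummary",
    "EsrClonality",
    "call_acquired",
    "clonality_transition",
    "esr1_clonality",
    "is_activating_esr1",
    "round_half_up",
    "summarize_cohort",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (printed style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AcquisitionResult:
    """Pathogenic-call dynamics between two timepoints of one patient.

    ``assessable`` is False when progression plasma was never sequenced;
    the three call sets are then empty and must not enter denominators.
    """

    patient_id: str
    assessable: bool
    acquired: tuple[ClassifiedCall, ...] = ()
    maintained: tuple[ClassifiedCall, ...] = ()
    lost: tuple[ClassifiedCall, ...] = ()
    acquired_targetable: tuple[ClassifiedCall, ...] = ()


def _pathogenic_by_key(
    calls: Iterable[ClassifiedCall], key_level: str
) -> dict[tuple, ClassifiedCall]:
    """First pathogenic call per key, in deterministic input order."""
    out: dict[tuple, ClassifiedCall] = {}
    for cc in calls:
        if not cc.pathogenic:
            continue
        key = variant_key(cc.call, key_level)
        out.setdefault(key, cc)
    return out


def call_acquired(
    patient_id: str,
    baseline: Iterable[ClassifiedCall],
    progression: Optional[Iterable[ClassifiedCall]],
    key_level: str = "protein",
) -> AcquisitionResult:
    """Partition pathogenic keys into acquired / maintained / lost.

    ``progression is None`` (plasma not sequenced) yields an explicitly
    not-assessable result rather than a silently empty acquisition set.
    """
    if progression is None:
        return AcquisitionResult(patient_id, assessable=False)
    base = _pathogenic_by_key(baseline, key_level)
    prog = _pathogenic_by_key(progression, key_level)
    acquired = tuple(cc for k, cc in prog.items() if k not in base)
    maintained = tuple(cc for k, cc in base.items() if k in prog)
    lost = tuple(cc for k, cc in base.items() if k not in prog)
    targetable = tuple(cc for cc in acquired if cc.targetable)
    return AcquisitionResult(patient_id, True, acquired, maintained, lost, targetable)


#: Explicitly activating ESR1 changes outside the L536/Y537 codon families.
_ACTIVATING_EXPLICIT = frozenset({"E380Q", "S463P", "D538G"})
_ACTIVATING_CODONS = frozenset({536, 537})


def is_activating_esr1(gene: str, protein_render: str, codon_index: int,
                       consequence: Consequence = Consequence.MISSENSE) -> bool:
    """Default activating-ESR1 catalog: named hotspots plus the L536/Y537
    families; F404 (LBD-altering but non-activating) and H356Y excluded."""
    if gene != "ESR1" or consequence is not Consequence.MISSENSE:
        return False
    return protein_render in _ACTIVATING_EXPLICIT or codon_index in _ACTIVATING_CODONS


class EsrClonality(str, Enum):
    NO_ESR1 = "no_esr1"
    MONOCLONAL = "monoclonal"
    POLYCLONAL = "polyclonal"


@dataclass(frozen=True)
class ClonalityState:
    state: EsrClonality
    activating_variants: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.activating_variants)
        expected = (
            EsrClonality.NO_ESR1 if n == 0
            else EsrClonality.MONOCLONAL if n == 1
            else EsrClonality.POLYCLONAL
        )
        if self.state is not expected:
            raise ValueError(f"state {self.state} inconsistent with {n} activating variants")


def esr1_clonality(
    calls: Iterable[ClassifiedCall],
    activating: Optional[frozenset[str]] = None,
) -> ClonalityState:
    """Count distinct activating ESR1 protein changes among retained calls.

    ``activating`` overrides the default catalog with an explicit set of
    protein-change renders.
    """
    variants: set[str] = set()
    for cc in calls:
        if cc.germline_excluded or cc.call.protein_change is None:
            continue
        render = cc.call.protein_change.render()
        if activating is not None:
            if cc.call.gene == "ESR1" and render in activating:
                variants.add(render)
        elif is_activating_esr1(
            cc.call.gene, render, cc.call.protein_change.codon_index, cc.call.consequence
        ):
            variants.add(render)
    n = len(variants)
    state = (
        EsrClonality.NO_ESR1 if n == 0
        else EsrClonality.MONOCLONAL if n == 1
        else EsrClonality.POLYCLONAL
    )
    return ClonalityState(state, frozenset(variants))


class ClonalityTransition(str, Enum):
    MAINTAINED = "maintained"
    ACQUIRED_POLYCLONAL = "acquired_polyclonal"
    REDUCED = "reduced"
    GAINED_ESR1 = "gained_esr1"


def clonality_transition(baseline: ClonalityState, progression: ClonalityState) -> ClonalityTransition:
    b, p = baseline.state, progression.state
    if b is p:
        return ClonalityTransition.MAINTAINED
    if p is EsrClonality.POLYCLONAL:
        return ClonalityTransition.ACQUIRED_POLYCLONAL
    if b is EsrClonality.NO_ESR1 and p is EsrClonality.MONOCLONAL:
        return ClonalityTransition.GAINED_ESR1
    return ClonalityTransition.REDUCED


def _is_f404(cc: ClassifiedCall) -> bool:
    if cc.call.gene != "ESR1":
        return False
    if cc.call.cds_change is not None:
        return cds_to_codon(cc.call.cds_change.cds_pos)[0] == 404
    return cc.call.protein_change is not None and cc.call.protein_change.codon_index == 404


@dataclass(frozen=True)
class CohortSummary:
    """Printed-precision incidence, acquisition and clonality tables."""

    n_patients: int
    n_paired: int
    gene_incidence: pd.DataFrame  # gene, count, denominator, percent (int)
    esr1_variants: pd.DataFrame   # variant, count, denominator, percent (0.1)
    acquisition: pd.DataFrame     # measure, count, denominator, percent (int)
    clonality: pd.DataFrame       # transition, count, denominator, percent (0.1)


def summarize_cohort(
    timelines: Iterable[PatientTimeline],
    catalog: Optional[Mapping] = None,
    recurrence_threshold: int = 2,
    key_level: str = "protein",
) -> CohortSummary:
    """Classify a cohort and tabulate every headline statistic.

    Gene incidence counts patients with >= 1 pathogenic baseline call per
    gene (integer percent of all patients); ESR1-variant incidence is per
    distinct protein change (one-decimal percent); acquisition measures are
    integer percents of paired-timepoint patients; clonality transitions are
    one-decimal percents of paired-timepoint patients.
    """
    timelines = list(timelines)
    if not timelines:
        raise ValueError("cannot summarize an empty cohort")
    classified = annotate_cohort(timelines, catalog, recurrence_threshold)
    n = len(timelines)

    gene_carriers: dict[str, set[str]] = {}
    variant_carriers: dict[str, set[str]] = {}
    for tl in timelines:
        base, _ = classified[tl.patient_id]
        for cc in base:
            if not cc.pathogenic:
                continue
            gene_carriers.setdefault(cc.call.gene, set()).add(tl.patient_id)
            if cc.call.gene == "ESR1" and cc.call.protein_change is not None:
                variant_carriers.setdefault(
                    cc.call.protein_change.render(), set()
                ).add(tl.patient_id)

    gene_rows = [
        {"gene": g, "count": len(p), "denominator": n,
         "percent": round_half_up(100.0 * len(p) / n)}
        for g, p in sorted(gene_carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    variant_rows = [
        {"variant": v, "count": len(p), "denominator": n,
         "percent": round_half_up(100.0 * len(p) / n, 1)}
        for v, p in sorted(variant_carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]

    paired = [tl for tl in timelines if tl.has_progression]
    n_paired = len(paired)
    acq_patients = {
        "acquired_pathogenic": set(), "acquired_targetable": set(),
        "acquired_esr1": set(), "acquired_l536": set(), "acquired_f404": set(),
    }
    transitions: dict[ClonalityTransition, int] = {t: 0 for t in ClonalityTransition}
    for tl in paired:
        base, prog = classified[tl.patient_id]
        res = call_acquired(tl.patient_id, base, prog, key_level)
        if res.acquired:
            acq_patients["acquired_pathogenic"].add(tl.patient_id)
        if res.acquired_targetable:
            acq_patients["acquired_targetable"].add(tl.patient_id)
        for cc in res.acquired:
            if cc.call.gene == "ESR1":
                acq_patients["acquired_esr1"].add(tl.patient_id)
                if cc.call.protein_change is not None and cc.call.protein_change.codon_index == 536:
                    acq_patients["acquired_l536"].add(tl.patient_id)
                if _is_f404(cc):
                    acq_patients["acquired_f404"].add(tl.patient_id)
        t = clonality_transition(esr1_clonality(base), esr1_clonality(prog or ()))
        transitions[t] += 1

    acq_rows = [
        {"measure": m, "count": len(p), "denominator": n_paired,
         "percent": round_half_up(100.0 * len(p) / n_paired) if n_paired else float("nan")}
        for m, p in acq_patients.items()
    ]
    clon_rows = [
        {"transition": t.value, "count": c, "denominator": n_paired,
         "percent": round_half_up(100.0 * c / n_paired, 1) if n_paired else float("nan")}
        for t, c in transitions.items()
    ]

    return CohortSummary(
        n_patients=n,
        n_paired=n_paired,
        gene_incidence=pd.DataFrame(gene_rows, columns=["gene", "count", "denominator", "percent"]),
        esr1_variants=pd.DataFrame(variant_rows, columns=["variant", "count", "denominator", "percent"]),
        acquisition=pd.DataFrame(acq_rows, columns=["measure", "count", "denominator", "percent"]),
        clonality=pd.DataFrame(clon_rows, columns=["transition", "count", "denominator", "percent"]),
    )
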