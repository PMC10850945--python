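"""Germline exclusion, pathogenicity classification and targetability.

The germline rule mirrors targeted-panel practice: a call is putatively
germline when the upstream caller flagged it, or when its VAF sits in the
50% +/- 2% band (inclusive) AND its population allele frequency exceeds
0.001% (strict). Calls excluded as germline never reach pathogenicity
classification.

Pathogenicity fires on the first satisfied clause, in order: hotspot-catalog
membership, oncogenicity, recurrence (>= threshold distinct patients) in a
key breast-cancer gene, or a splicing consequence. Hotspot/oncogenicity
knowledge ships as an editable TSV mini-catalog rather than live database
queries, keeping the pipeline hermetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .core import (
    AnnotationRecord,
    Consequence,
    PatientTimeline,
    TargetabilityLevel,
    VariantCall,
    variant_key,
)

__all__ = [
    "KEY_BREAST_GENES",
    "ClassifiedCall",
    "PathogenicReason",
    "annotate_cohort",
    "assign_targetability",
    "classify_pathogenic",
    "classify_timeline",
    "is_putative_germline",
    "load_catalog",
]

#: Key breast-cancer genes for the recurrence clause (HER2 == ERBB2).
KEY_BREAST_GENES = frozenset({"ESR1", "ERBB2", "HER2", "PIK3CA", "EGFR", "RB1", "FGFR2"})

#: Germline-rule constants: VAF band inclusive, population AF strict.
GERMLINE_VAF_LOW = 48.0
GERMLINE_VAF_HIGH = 52.0
GERMLINE_POP_AF = 1e-5  # 0.001%

DEFAULT_RECURRENCE_THRESHOLD = 2


class PathogenicReason(str, Enum):
    HOTSPOT = "hotspot"
    ONCOGENIC = "oncogenic"
    RECURRENT_KEY_GENE = "recurrent_key_gene"
    SPLICING = "splicing"
    NONE = "none"


@dataclass(frozen=True)
class ClassifiedCall:
    call: VariantCall
    annotation: AnnotationRecord
    germline_excluded: bool
    pathogenic: bool
    pathogenic_reason: PathogenicReason
    targetable: bool

    def __post_init__(self) -> None:
        if self.pathogenic and self.pathogenic_reason is PathogenicReason.NONE:
            raise ValueError("pathogenic call must carry a reason")
        if self.germline_excluded and self.pathogenic:
            raise ValueError("germline-excluded call cannot be pathogenic")


def is_putative_germline(vaf: float, pop_af: float, germline_flagged: bool) -> bool:
    """Apply the germline exclusion rule to one call.

    True iff the upstream caller flagged the call, or VAF lies in [48, 52]
    percent (inclusive) and population AF is strictly greater than 1e-5.
    """
    if not 0.0 <= vaf <= 100.0:
        raise ValueError(f"vaf must be in [0, 100], got {vaf}")
    if not 0.0 <= pop_af <= 1.0:
        raise ValueError(f"pop_af must be in [0, 1], got {pop_af}")
    if germline_flagged:
        return True
    return GERMLINE_VAF_LOW <= vaf <= GERMLINE_VAF_HIGH and pop_af > GERMLINE_POP_AF


CatalogEntry = tuple[bool, bool, TargetabilityLevel]
Catalog = Mapping[tuple[str, str], CatalogEntry]


def load_catalog(path: Optional[str] = None) -> dict[tuple[str, str], CatalogEntry]:
    """Load the (gene, protein change) -> annotation catalog from TSV."""
    if path is None:
        ref = resources.files("ctdnatrack.data") / "variant_catalog.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    catalog: dict[tuple[str, str], CatalogEntry] = {}
    for row in df.itertuples(index=False):
        level = TargetabilityLevel(row.targetability_level)
        catalog[(row.gene, row.protein_change)] = (
            bool(int(row.is_hotspot)),
            bool(int(row.is_oncogenic)),
            level,
        )
    return catalog


def assign_targetability(annotation: AnnotationRecord) -> TargetabilityLevel:
    """Pass through the evidence level; ``NONE`` means not targetable."""
    level = annotation.targetability_level
    if not isinstance(level, TargetabilityLevel):
        raise ValueError(f"unknown targetability level {level!r}")
    return level


def classify_pathogenic(
    call: VariantCall,
    annotation: AnnotationRecord,
    recurrence_threshold: int = DEFAULT_RECURRENCE_THRESHOLD,
) -> ClassifiedCall:
    """Classify one non-germline call; reason records the first firing clause."""
    germline = is_putative_germline(call.vaf, call.pop_af, call.germline_flagged)
    if germline:
        return ClassifiedCall(
            call, annotation, True, False, PathogenicReason.NONE, False
        )
    reason = PathogenicReason.NONE
    if annotation.is_hotspot:
        reason = PathogenicReason.HOTSPOT
    elif annotation.is_oncogenic:
        reason = PathogenicReason.ONCOGENIC
    elif (
        annotation.cohort_recurrence >= recurrence_threshold
        and call.gene in KEY_BREAST_GENES
    ):
        reason = PathogenicReason.RECURRENT_KEY_GENE
    elif call.consequence is Consequence.SPLICING:
        reason = PathogenicReason.SPLICING
    pathogenic = reason is not PathogenicReason.NONE
    level = assign_targetability(annotation)
    targetable = pathogenic and level is not TargetabilityLevel.NONE
    return ClassifiedCall(call, annotation, False, pathogenic, reason, targetable)


def _cohort_recurrence(timelines: Iterable[PatientTimeline]) -> dict[tuple, int]:
    """Distinct patients carrying each protein-level key, both timepoints."""
    carriers: dict[tuple, set[str]] = {}
    for tl in timelines:
        for call in tuple(tl.baseline_calls) + tuple(tl.progression_calls or ()):
            if call.protein_change is None:
                continue
            key = variant_key(call, "protein")
            carriers.setdefault(key, set()).add(tl.patient_id)
    return {k: len(v) for k, v in carriers.items()}


def _annotate(call: VariantCall, catalog: Catalog, recurrence: Mapping[tuple, int]) -> AnnotationRecord:
    hot, onc, level = False, False, TargetabilityLevel.NONE
    rec = 0
    if call.protein_change is not None:
        key = (call.gene, call.protein_change.render())
        if key in catalog:
            hot, onc, level = catalog[key]
        rec = recurrence.get(variant_key(call, "protein"), 0)
    return AnnotationRecord(hot, onc, level, rec)


def classify_timeline(
    timeline: PatientTimeline,
    catalog: Catalog,
    recurrence: Mapping[tuple, int],
    recurrence_threshold: int = DEFAULT_RECURRENCE_THRESHOLD,
) -> tuple[tuple[ClassifiedCall, ...], Optional[tuple[ClassifiedCall, ...]]]:
    """Classify every baseline and progression call of one patient."""
    def run(calls: tuple[VariantCall, ...]) -> tuple[ClassifiedCall, ...]:
        return tuple(
            classify_pathogenic(c, _annotate(c, catalog, recurrence), recurrence_threshold)
            for c in calls
        )

    baseline = run(timeline.baseline_calls)
    progression = run(timeline.progression_calls) if timeline.has_progression else None
    return baseline, progression


def annotate_cohort(
    timelines: Iterable[PatientTimeline],
    catalog: Optional[Catalog] = None,
    recurrence_threshold: int = DEFAULT_RECURRENCE_THRESHOLD,
) -> dict[str, tuple[tuple[ClassifiedCall, ...], Optional[tuple[ClassifiedCall, ...]]]]:
    """Classify a whole cohort, computing cohort recurrence internally.

    Returns patient_id -> (classified baseline calls, classified progression
    calls or None when progression was not sequenced).
    """
    timelines = list(timelines)
    if catalog is None:
        catalog = load_catalog()
    recurrence = _cohort_recurrence(timelines)
    return {
        tl.patient_id: classify_timeline(tl, catalog, recurrence, recurrence_threshold)
        for tl in timelines
    }
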