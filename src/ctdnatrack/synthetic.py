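"""Synthetic cohorts, molecule-level phasing evidence, and deterministic fixtures.

The study this package emulates could not release patient-level data, so two
kinds of stand-ins drive everything downstream:

* stochastic generators (:func:`simulate_cohort`, :func:`simulate_fragments`)
  with the structure a Guardant360-style paired ctDNA call set has — per-gene
  baseline mutation probabilities, an ESR1 hotspot spectrum, germline
  contamination centred at 50% VAF, and fulvestrant-conditional acquisition
  of F404 mutations in cis with a preexisting activating ESR1 mutation;

* deterministic fixtures (:func:`fixture_baseline_cohort`,
  :func:`fixture_paired_cohort`, :func:`fixture_phasing_patients`) whose
  marginal counts equal the published cohort statistics exactly. Per-patient
  co-mutation structure was never published, so the joint assignment is an
  arbitrary-but-deterministic cyclic fill consistent with the marginals;
  every downstream summary statistic depends only on the marginals.

One global seed expands into per-stage substreams via ``SeedSequence`` so
each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    CdsChange,
    Consequence,
    PatientTimeline,
    Timepoint,
    VariantCall,
    parse_hgvs_c,
    parse_protein_change,
)
from .phasing import Allele, MoleculeObservation, PhasingTask

__all__ = [
    "CohortConfig",
    "ESR1_CDNA",
    "FragmentSimConfig",
    "fixture_baseline_cohort",
    "fixture_paired_cohort",
    "fixture_phasing_patients",
    "simulate_cohort",
    "simulate_fragments",
    "simulate_two_group_survival",
]

#: Canonical cDNA substitution for each named ESR1 protein change
#: (coordinates on NM_000125.4; F404L additionally arises from the
#: third-position changes 1212T>A and 1212T>G).
ESR1_CDNA = {
    "E380Q": "1138G>C",
    "S463P": "1387T>C",
    "L536R": "1607T>G",
    "L536P": "1607T>C",
    "Y537N": "1609T>A",
    "Y537S": "1610A>C",
    "Y537C": "1610A>G",
    "D538G": "1613A>G",
    "H356Y": "1066C>T",
    "F404L": "1210T>C",
    "F404I": "1210T>A",
    "F404V": "1210T>G",
}

#: The five codon-TTT substitutions yielding F404 I/V/L, as (cdna, protein).
F404_BASE_CHANGES = (
    ("1210T>C", "F404L"),
    ("1210T>A", "F404I"),
    ("1210T>G", "F404V"),
    ("1212T>A", "F404L"),
    ("1212T>G", "F404L"),
)

_E380Q_POS = 1138


def _call(
    gene: str,
    protein: str,
    timepoint: Timepoint,
    vaf: float,
    cdna: Optional[str] = None,
    consequence: Consequence = Consequence.MISSENSE,
    pop_af: float = 0.0,
    germline_flagged: bool = False,
    phase_partner: Optional[str] = None,
) -> VariantCall:
    return VariantCall(
        gene=gene,
        cds_change=parse_hgvs_c(cdna) if cdna else None,
        protein_change=parse_protein_change(protein),
        consequence=consequence,
        vaf=vaf,
        pop_af=pop_af,
        germline_flagged=germline_flagged,
        timepoint=timepoint,
        phase_partner=phase_partner,
    )


def _esr1(protein: str, timepoint: Timepoint, vaf: float, partner: Optional[str] = None) -> VariantCall:
    return _call("ESR1", protein, timepoint, vaf, cdna=ESR1_CDNA[protein], phase_partner=partner)


# ---------------------------------------------------------------------------
# stochastic cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the stochastic cohort generator.

    Gene and variant probabilities default to the observed baseline cohort
    frequencies; ESR1 variant probabilities are conditional on the patient
    being ESR1-mutant. The F404 acquisition probability applies only to
    patients with fulvestrant exposure AND >= 1 activating ESR1 mutation at
    baseline, and is exactly zero otherwise. Germline VAF is drawn from a
    tight beta centred at 50% (sd 1%), deliberately exercising the
    50% +/- 2% exclusion band at its boundary; somatic VAF from beta(2, 18).
    """

    n_patients: int = 79
    gene_probs: dict = field(
        default_factory=lambda: {"ESR1": 0.96, "PIK3CA": 0.43, "TP53": 0.30}
    )
    esr1_variant_probs: dict = field(
        default_factory=lambda: {
            "D538G": 44 / 76, "Y537S": 34 / 76, "E380Q": 22 / 76,
            "Y537N": 22 / 76, "Y537C": 11 / 76, "L536R": 7 / 76, "S463P": 4 / 76,
        }
    )
    germline_mean_calls: float = 1.0
    germline_flag_prob: float = 0.5
    somatic_vaf_beta: tuple[float, float] = (2.0, 18.0)
    germline_vaf_beta: tuple[float, float] = (1249.5, 1249.5)
    p_prior_fulvestrant: float = 1.0
    simulate_progression: bool = True
    p_acquire_esr1: float = 0.20
    p_acquire_pathogenic: float = 0.39
    p_acquire_f404: float = 0.045
    baseline_median_pfs: float = 2.2
    hazard_multipliers: dict = field(
        default_factory=lambda: {"Y537S": 1.9, "Y537C": 0.36}
    )
    censor_time: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            *self.gene_probs.values(), *self.esr1_variant_probs.values(),
            self.germline_flag_prob, self.p_prior_fulvestrant,
            self.p_acquire_esr1, self.p_acquire_pathogenic, self.p_acquire_f404,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


_ACTIVATING_MENU = ("D538G", "Y537S", "E380Q", "Y537N", "Y537C", "L536R", "L536P", "S463P")
_OTHER_GENE_MENU = {
    "PIK3CA": ("H1047R", "E545K", "E542K"),
    "TP53": ("R175H", "R273H", "R248Q"),
}
_ACQUIRED_MENU = (
    ("PIK3CA", "H1047R"), ("PIK3CA", "E545K"), ("PTEN", "R130G"),
    ("BRCA1", "Q1756*"), ("ERBB2", "L755S"), ("AKT1", "E17K"),
    ("TP53", "R175H"), ("BRAF", "V600E"),
)
_GERMLINE_GENES = ("ATM", "CHEK2", "MUTYH", "APC")


def _somatic_vaf(rng: np.random.Generator, cfg: CohortConfig) -> float:
    a, b = cfg.somatic_vaf_beta
    return float(np.clip(rng.beta(a, b) * 100.0, 0.05, 100.0))


def simulate_cohort(config: CohortConfig) -> list[PatientTimeline]:
    """Draw a reproducible synthetic cohort under ``config``.

    Acquired F404 calls appear only in patients with fulvestrant exposure and
    at least one activating ESR1 baseline mutation, and carry a
    ``phase_partner`` tag naming the activating mutation they ride in cis
    with.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    timelines: list[PatientTimeline] = []
    for i in range(config.n_patients):
        pid = f"S{i + 1:04d}"
        prior_fulv = bool(rng.random() < config.p_prior_fulvestrant)
        baseline: list[VariantCall] = []
        activating: list[str] = []

        for gene, p_gene in config.gene_probs.items():
            if rng.random() >= p_gene:
                continue
            if gene == "ESR1":
                chosen = [
                    v for v, pv in config.esr1_variant_probs.items()
                    if rng.random() < pv
                ]
                if not chosen:  # carrier guaranteed by the gene-level draw
                    chosen = ["D538G"]
                for v in chosen:
                    baseline.append(_esr1(v, Timepoint.BASELINE, _somatic_vaf(rng, config)))
                    activating.append(v)
            else:
                menu = _OTHER_GENE_MENU.get(gene, ("E17K",))
                v = menu[int(rng.integers(len(menu)))]
                baseline.append(_call(gene, v, Timepoint.BASELINE, _somatic_vaf(rng, config)))

        n_germline = int(rng.poisson(config.germline_mean_calls))
        germline: list[VariantCall] = []
        for g in range(n_germline):
            gene = _GERMLINE_GENES[int(rng.integers(len(_GERMLINE_GENES)))]
            codon = int(rng.integers(50, 900))
            ga, gb = config.germline_vaf_beta
            germline.append(
                VariantCall(
                    gene=gene,
                    protein_change=parse_protein_change(f"P{codon}L"),
                    consequence=Consequence.MISSENSE,
                    vaf=float(rng.beta(ga, gb) * 100.0),
                    pop_af=float(10 ** rng.uniform(-4.0, -0.5)),
                    germline_flagged=bool(rng.random() < config.germline_flag_prob),
                    timepoint=Timepoint.BASELINE,
                )
            )
        baseline.extend(germline)

        progression: Optional[tuple[VariantCall, ...]] = None
        acquired_names: list[str] = []
        if config.simulate_progression:
            prog = [replace(c, timepoint=Timepoint.PROGRESSION) for c in baseline]
            if rng.random() < config.p_acquire_esr1:
                candidates = [v for v in _ACTIVATING_MENU if v not in activating]
                if candidates:
                    v = candidates[int(rng.integers(len(candidates)))]
                    prog.append(_esr1(v, Timepoint.PROGRESSION, _somatic_vaf(rng, config)))
                    acquired_names.append(v)
            if rng.random() < config.p_acquire_pathogenic:
                gene, v = _ACQUIRED_MENU[int(rng.integers(len(_ACQUIRED_MENU)))]
                cons = Consequence.NONSENSE if v.endswith("*") else Consequence.MISSENSE
                prog.append(_call(gene, v, Timepoint.PROGRESSION, _somatic_vaf(rng, config), consequence=cons))
                acquired_names.append(f"{gene}:{v}")
            if prior_fulv and activating and rng.random() < config.p_acquire_f404:
                cdna, prot = F404_BASE_CHANGES[int(rng.integers(len(F404_BASE_CHANGES)))]
                partner = sorted(activating)[0]
                prog.append(
                    _call("ESR1", prot, Timepoint.PROGRESSION,
                          _somatic_vaf(rng, config), cdna=cdna, phase_partner=partner)
                )
                acquired_names.append(prot)
            progression = tuple(prog)

        hazard = np.log(2.0) / config.baseline_median_pfs
        for v in activating:
            hazard *= config.hazard_multipliers.get(v, 1.0)
        t = float(rng.exponential(1.0 / hazard))
        event = t <= config.censor_time
        pfs = min(t, config.censor_time)

        timelines.append(
            PatientTimeline(
                patient_id=pid,
                baseline_calls=tuple(baseline),
                progression_calls=progression,
                pfs_months=pfs,
                event=event,
                prior_fulvestrant=prior_fulv,
            )
        )
    return timelines


def simulate_two_group_survival(
    n: int,
    hazard_ratio: float,
    baseline_median: float = 3.0,
    censor_time: float = 24.0,
    p_group: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential PFS with a configured true hazard ratio.

    Group 1 ("detected") hazard = group 0 hazard * ``hazard_ratio``;
    administrative censoring at ``censor_time`` months. Returns a DataFrame
    with columns time, event, group.
    """
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < p_group).astype(int)
    lam0 = np.log(2.0) / baseline_median
    lam = lam0 * np.where(group == 1, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / lam)
    event = t <= censor_time
    return pd.DataFrame(
        {"time": np.minimum(t, censor_time), "event": event, "group": group}
    )


# ---------------------------------------------------------------------------
# fragment-level phasing evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSimConfig:
    """Geometry and noise model for molecule-level phasing evidence.

    cfDNA fragment lengths follow a truncated normal (mode ~167 bp, the
    nucleosomal peak); each simulated molecule covers locus A, locus B or
    both according to where it falls, and observed alleles flip with
    ``error_rate`` per base. ``tumor_fraction`` is the fraction of molecules
    drawn from the mutant haplotype(s): under cis truth one haplotype carries
    both alt alleles; under trans truth two haplotypes each carry one.
    """

    truth: str  # "cis" | "trans"
    n_molecules: int = 200
    fragment_mean: float = 167.0
    fragment_sd: float = 20.0
    fragment_max: int = 350
    inter_locus_distance: int = 72
    error_rate: float = 0.01
    tumor_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth not in ("cis", "trans"):
            raise ValueError(f"truth must be 'cis' or 'trans', got {self.truth!r}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.inter_locus_distance < 0:
            raise ValueError("inter-locus distance must be >= 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")


def simulate_fragments(config: FragmentSimConfig) -> tuple[MoleculeObservation, ...]:
    """Simulate molecules covering two loci ``inter_locus_distance`` apart.

    Every emitted molecule covers at least one locus. When the distance
    exceeds the maximum fragment length no molecule can cover both, so the
    output holds only single-locus observations and the pair is unphasable
    on geometry alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    d = config.inter_locus_distance
    out: list[MoleculeObservation] = []
    for i in range(config.n_molecules):
        length = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                             20, config.fragment_max))
        # sample a start uniformly over positions covering >= 1 locus
        if d < length:
            start = int(rng.integers(-length + 1, d + 1))
        else:
            k = int(rng.integers(0, 2 * length))
            start = (-length + 1 + k) if k < length else (d - length + 1 + (k - length))
        covers_a = start <= 0 <= start + length - 1
        covers_b = start <= d <= start + length - 1

        u = rng.random()
        if config.truth == "cis":
            hap = ("alt", "alt") if u < config.tumor_fraction else ("ref", "ref")
        else:
            if u < config.tumor_fraction / 2.0:
                hap = ("alt", "ref")
            elif u < config.tumor_fraction:
                hap = ("ref", "alt")
            else:
                hap = ("ref", "ref")

        def observe(true_allele: str, covered: bool) -> Allele:
            if not covered:
                return Allele.MISSING
            if rng.random() < config.error_rate:
                true_allele = "ref" if true_allele == "alt" else "alt"
            return Allele.ALT if true_allele == "alt" else Allele.REF

        out.append(
            MoleculeObservation(
                molecule_id=f"M{i:05d}",
                allele_a=observe(hap[0], covers_a),
                allele_b=observe(hap[1], covers_b),
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# deterministic fixtures reproducing the printed cohort statistics
# ---------------------------------------------------------------------------

_BASELINE_N = 79
_BASELINE_ESR1_CARRIERS = 76
_BASELINE_ESR1_VARIANTS = (
    ("D538G", 44), ("Y537S", 34), ("E380Q", 22), ("Y537N", 22),
    ("Y537C", 11), ("L536R", 7), ("S463P", 4),
)
_BASELINE_OTHER_GENES = (
    ("PIK3CA", 34, ("H1047R", "E545K")),
    ("TP53", 24, ("R175H", "R273H", "R248Q")),
)


def _fixture_vaf(i: int, j: int) -> float:
    """Deterministic somatic VAF in (0.5, 35.5); never in the germline band."""
    return 0.5 + ((3 * i + 7 * j) % 350) / 10.0


def fixture_baseline_cohort() -> list[PatientTimeline]:
    """The 79-patient baseline cohort with published per-gene/per-variant counts.

    ESR1 carriers: 76/79; variant counts D538G 44, Y537S 34, E380Q 22,
    Y537N 22, Y537C 11, L536R 7, S463P 4, assigned to carriers by a cyclic
    fill so that every carrier holds at least one variant. PIK3CA 34 and
    TP53 24 carriers overlap the low patient indices. Progression plasma is
    unsequenced (``progression_calls is None``).
    """
    per_patient: list[list[VariantCall]] = [[] for _ in range(_BASELINE_N)]

    cursor = 0
    for j, (variant, count) in enumerate(_BASELINE_ESR1_VARIANTS):
        for k in range(count):
            idx = (cursor + k) % _BASELINE_ESR1_CARRIERS
            per_patient[idx].append(
                _esr1(variant, Timepoint.BASELINE, _fixture_vaf(idx, j))
            )
        cursor = (cursor + count) % _BASELINE_ESR1_CARRIERS

    for gene, count, menu in _BASELINE_OTHER_GENES:
        for idx in range(count):
            per_patient[idx].append(
                _call(gene, menu[idx % len(menu)], Timepoint.BASELINE, _fixture_vaf(idx, 9))
            )

    # a sprinkling of germline contamination, excluded downstream
    for idx in (5, 21, 47, 77):
        per_patient[idx].append(
            VariantCall(
                gene="ATM",
                protein_change=parse_protein_change("F858L"),
                consequence=Consequence.MISSENSE,
                vaf=50.4,
                pop_af=0.004,
                germline_flagged=(idx == 21),
                timepoint=Timepoint.BASELINE,
            )
        )

    return [
        PatientTimeline(
            patient_id=f"B{idx + 1:03d}",
            baseline_calls=tuple(calls),
            progression_calls=None,
            pfs_months=0.5 + (idx % 24) * 0.5,
            event=(idx % 5) != 0,
            prior_fulvestrant=False,
        )
        for idx, calls in enumerate(per_patient)
    ]


#: (patient_id, F404 cDNA change, configured truth) for the phasing fixture;
#: the trans pair belongs to the patient carrying additional D538G/S463P/Y537N.
PHASING_FIXTURE_PAIRS = (
    ("PP07", "1210T>C", "cis"),
    ("PP07", "1210T>A", "cis"),
    ("PP07", "1210T>G", "cis"),
    ("PP07", "1212T>A", "cis"),
    ("PP07", "1212T>G", "cis"),
    ("PP08", "1210T>C", "trans"),
    ("PP09", "1210T>A", "cis"),
)

_PHASING_FIXTURE_SEED = 20


def fixture_paired_cohort() -> list[PatientTimeline]:
    """The 69-patient paired baseline/progression cohort.

    Encodes the published acquisition marginals exactly: 35 patients acquire
    >= 1 pathogenic alteration, 17 a targetable one, 14 an ESR1 mutation
    (6 at L536, 3 at F404), 50 keep their ESR1 clonality class and 4 become
    polyclonal. One patient (PP07) carries five separate F404 base changes;
    7 F404 base changes across three patients mirror the phasing fixture.
    """
    timelines: list[PatientTimeline] = []

    def mk(i: int, baseline: list[VariantCall], acquired: list[VariantCall],
           lost_protein: Optional[str] = None, pfs: Optional[float] = None) -> PatientTimeline:
        prog = [
            replace(c, timepoint=Timepoint.PROGRESSION)
            for c in baseline
            if lost_protein is None or c.protein_change is None
            or c.protein_change.render() != lost_protein
        ] + acquired
        return PatientTimeline(
            patient_id=f"PP{i:02d}",
            baseline_calls=tuple(baseline),
            progression_calls=tuple(prog),
            pfs_months=pfs if pfs is not None else 1.0 + (i % 20) * 0.35,
            event=(i % 7) != 0,
            prior_fulvestrant=True,
        )

    B, P = Timepoint.BASELINE, Timepoint.PROGRESSION
    for i in range(1, 70):
        if 1 <= i <= 6:  # acquired L536R on a polyclonal background
            base = [_esr1("D538G", B, _fixture_vaf(i, 0)), _esr1("E380Q", B, _fixture_vaf(i, 1))]
            acq = [_esr1("L536R", P, _fixture_vaf(i, 2))]
            timelines.append(mk(i, base, acq))
        elif i == 7:  # five separate F404 base changes, all in cis with E380Q
            base = [_esr1("E380Q", B, 22.0), _esr1("D538G", B, 18.0)]
            acq = [
                _call("ESR1", prot, P, 2.0 + 0.3 * k, cdna=cdna, phase_partner="E380Q")
                for k, (cdna, prot) in enumerate(F404_BASE_CHANGES)
            ]
            timelines.append(mk(i, base, acq, pfs=5.5))
        elif i == 8:  # F404L in trans with E380Q; extra D538G/S463P/Y537N
            base = [
                _esr1("E380Q", B, 35.0), _esr1("D538G", B, 12.0),
                _esr1("S463P", B, 8.0), _esr1("Y537N", B, 6.0),
            ]
            acq = [_call("ESR1", "F404L", P, 3.1, cdna="1210T>C")]
            timelines.append(mk(i, base, acq, pfs=6.2))
        elif i == 9:  # F404I in cis with the lone activating E380Q
            base = [_esr1("E380Q", B, 27.0)]
            acq = [_call("ESR1", "F404I", P, 2.4, cdna="1210T>A", phase_partner="E380Q")]
            timelines.append(mk(i, base, acq, pfs=4.8))
        elif i == 10:  # acquired Y537N on a polyclonal background
            base = [_esr1("D538G", B, _fixture_vaf(i, 0)), _esr1("Y537S", B, _fixture_vaf(i, 1))]
            acq = [_esr1("Y537N", P, _fixture_vaf(i, 2))]
            timelines.append(mk(i, base, acq))
        elif 11 <= i <= 14:  # monoclonal -> polyclonal through acquired Y537S
            base = [_esr1("D538G", B, _fixture_vaf(i, 0))]
            acq = [_esr1("Y537S", P, _fixture_vaf(i, 2))]
            timelines.append(mk(i, base, acq))
        elif 15 <= i <= 31:  # acquired targetable, ESR1 state untouched
            menu = [
                ("PIK3CA", "H1047R", Consequence.MISSENSE),
                ("PIK3CA", "E545K", Consequence.MISSENSE),
                ("PTEN", "R130G", Consequence.MISSENSE),
                ("BRCA1", "Q1756*", Consequence.NONSENSE),
                ("BRCA2", "W31*", Consequence.NONSENSE),
                ("ERBB2", "L755S", Consequence.MISSENSE),
                ("AKT1", "E17K", Consequence.MISSENSE),
            ]
            gene, prot, cons = menu[(i - 15) % len(menu)]
            base = [_esr1("D538G", B, _fixture_vaf(i, 0))]
            acq = [_call(gene, prot, P, _fixture_vaf(i, 3), consequence=cons)]
            timelines.append(mk(i, base, acq))
        elif 32 <= i <= 35:  # acquired pathogenic but not targetable
            base = [_esr1("D538G", B, _fixture_vaf(i, 0))]
            acq = [_call("TP53", "R175H", P, _fixture_vaf(i, 3))]
            timelines.append(mk(i, base, acq))
        elif 36 <= i <= 54:  # stable monoclonal, nothing acquired
            base = [_esr1("Y537S", B, _fixture_vaf(i, 0))]
            timelines.append(mk(i, base, []))
        else:  # 55..69: polyclonal reduced to monoclonal (Y537S lost)
            base = [_esr1("D538G", B, _fixture_vaf(i, 0)), _esr1("Y537S", B, _fixture_vaf(i, 1))]
            timelines.append(mk(i, base, [], lost_protein="Y537S"))

    # germline contamination on a few patients, both timepoints
    out: list[PatientTimeline] = []
    for tl in timelines:
        if tl.patient_id in ("PP03", "PP20", "PP40", "PP60"):
            g_base = VariantCall(
                gene="CHEK2", protein_change=parse_protein_change("I157T"),
                consequence=Consequence.MISSENSE, vaf=49.6, pop_af=0.005,
                germline_flagged=(tl.patient_id == "PP40"), timepoint=B,
            )
            g_prog = replace(g_base, timepoint=P)
            tl = replace(
                tl,
                baseline_calls=tl.baseline_calls + (g_base,),
                progression_calls=(tl.progression_calls or ()) + (g_prog,),
            )
        out.append(tl)
    return out


def fixture_phasing_patients(seed: int = _PHASING_FIXTURE_SEED) -> dict[tuple[str, str], PhasingTask]:
    """Molecule tables for the 7 assessable F404-vs-E380Q pairs.

    Three patients, 7 F404 base changes, 6 configured cis and 1 trans
    (the trans pair on the patient with additional D538G/S463P/Y537N),
    each simulated with ~200 molecules (>= 30 double-covering), 1% error
    and the default fixture seed; deterministic for a given seed.
    """
    children = np.random.SeedSequence(seed).spawn(len(PHASING_FIXTURE_PAIRS))
    tasks: dict[tuple[str, str], PhasingTask] = {}
    for (patient, cdna, truth), child in zip(PHASING_FIXTURE_PAIRS, children):
        pos = CdsChange(
            parse_hgvs_c(cdna).cds_pos, parse_hgvs_c(cdna).ref_base, parse_hgvs_c(cdna).alt_base
        ).cds_pos
        distance = abs(pos - _E380Q_POS)
        cfg = FragmentSimConfig(
            truth=truth,
            n_molecules=200,
            inter_locus_distance=distance,
            error_rate=0.01,
            tumor_fraction=0.5,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        tasks[(patient, cdna)] = PhasingTask(
            patient_id=patient,
            variant_a=f"ESR1:{cdna}",
            variant_b="ESR1:1138G>C",
            observations=simulate_fragments(cfg),
            inter_locus_distance=distance,
            max_fragment_length=cfg.fragment_max,
        )
    return tasks
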