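"""File formats, pipeline configuration, and report assembly.

Tab-separated values are the canonical interchange format. Dialect notes:

* **call TSV** — one row per call; columns ``gene, cds_change,
  protein_change, consequence, vaf, pop_af, germline_flagged, timepoint,
  phase_partner``. Empty string means absent. ``vaf`` is percent, ``pop_af``
  a fraction.
* **cohort TSV** — call TSV plus per-patient columns ``patient_id,
  pfs_months, event, prior_fulvestrant, has_progression``; a patient with no
  calls keeps one sentinel row with ``gene = "."``. ``has_progression``
  False means progression plasma was never sequenced.
* **minimal VCF 4.2** — convenience dialect; CHROM is the gene symbol, POS
  the CDS coordinate (1 when only a protein change is known; REF/ALT are
  placeholders then). All call fields live in INFO keys ``GENE, HGVSC,
  HGVSP, CSQ, VAF, POPAF, GERMLINE, TP``; VAF/POPAF are String-typed so the
  round trip is lossless. Read through pysam; unknown INFO keys warn.
* **molecule TSV** — ``molecule_id, allele_a, allele_b`` with alleles coded
  ``R`` (ref), ``A`` (alt), ``.`` (locus not covered).
* **survival TSV** — ``patient_id, time_months, event, group``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .classify import DEFAULT_RECURRENCE_THRESHOLD, load_catalog
from .core import (
    Consequence,
    PatientTimeline,
    Timepoint,
    VariantCall,
    parse_hgvs_c,
    parse_protein_change,
)
from .longitudinal import CohortSummary, summarize_cohort
from .phasing import (
    Allele,
    MoleculeObservation,
    PhasingTask,
    build_phase_table,
    phase_pair_for_patient,
)
from .survival import ConvergenceError, cox_two_group, km_estimate, logrank_test
from .synthetic import fixture_paired_cohort, fixture_phasing_patients

__all__ = [
    "PipelineConfig",
    "read_calls",
    "read_cohort_tsv",
    "read_molecule_tsv",
    "read_survival_tsv",
    "run_pipeline",
    "write_calls",
    "write_cohort_tsv",
    "write_molecule_tsv",
]

_CALL_COLUMNS = [
    "gene", "cds_change", "protein_change", "consequence", "vaf", "pop_af",
    "germline_flagged", "timepoint", "phase_partner",
]
_COHORT_COLUMNS = [
    "patient_id", "pfs_months", "event", "prior_fulvestrant", "has_progression",
] + _CALL_COLUMNS

_BOOL = {"true": True, "false": False, "1": True, "0": False}


class CallTableError(ValueError):
    """Malformed call-table row, reported with its 1-based file line."""


def _parse_bool(text: str, line: int, column: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise CallTableError(f"line {line}: {column} must be true/false, got {text!r}") from None


def _call_from_fields(fields: dict[str, str], line: int) -> VariantCall:
    try:
        cds = parse_hgvs_c(fields["cds_change"]) if fields.get("cds_change") else None
        prot = parse_protein_change(fields["protein_change"]) if fields.get("protein_change") else None
        vaf = float(fields["vaf"])
        pop_af = float(fields["pop_af"]) if fields.get("pop_af") else 0.0
        return VariantCall(
            gene=fields["gene"],
            cds_change=cds,
            protein_change=prot,
            consequence=Consequence(fields.get("consequence") or "missense"),
            vaf=vaf,
            pop_af=pop_af,
            germline_flagged=_parse_bool(fields.get("germline_flagged") or "false", line, "germline_flagged"),
            timepoint=Timepoint(fields.get("timepoint") or "baseline"),
            phase_partner=fields.get("phase_partner") or None,
        )
    except CallTableError:
        raise
    except (ValueError, KeyError) as exc:
        raise CallTableError(f"line {line}: {exc}") from exc


def _call_to_fields(call: VariantCall) -> dict[str, str]:
    return {
        "gene": call.gene,
        "cds_change": call.cds_change.render() if call.cds_change else "",
        "protein_change": call.protein_change.render() if call.protein_change else "",
        "consequence": call.consequence.value,
        "vaf": repr(call.vaf),
        "pop_af": repr(call.pop_af),
        "germline_flagged": str(call.germline_flagged).lower(),
        "timepoint": call.timepoint.value,
        "phase_partner": call.phase_partner or "",
    }


def _read_tsv_rows(path: str, required: Sequence[str]) -> list[tuple[int, dict[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CallTableError(f"{path}: missing columns {missing}")
    return [(i + 2, row) for i, row in enumerate(df.to_dict(orient="records"))]


def read_calls(path: str, dialect: str = "tsv") -> list[VariantCall]:
    """Read a flat call table in the TSV or minimal-VCF dialect."""
    if dialect == "tsv":
        return [_call_from_fields(row, line) for line, row in _read_tsv_rows(path, ["gene", "vaf"])]
    if dialect == "vcf":
        return _read_calls_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_calls(calls: Iterable[VariantCall], path: str, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        rows = [_call_to_fields(c) for c in calls]
        pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if dialect == "vcf":
        _write_calls_vcf(calls, path)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


_VCF_INFO_KEYS = {"GENE", "HGVSC", "HGVSP", "CSQ", "VAF", "POPAF", "GERMLINE", "TP", "PARTNER"}


def _write_calls_vcf(calls: Iterable[VariantCall], path: str) -> None:
    calls = list(calls)
    genes = sorted({c.gene for c in calls})
    lines = ["##fileformat=VCFv4.2", "##source=ctdnatrack"]
    lines += [f"##contig=<ID={g},length=100000>" for g in genes]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="CDS substitution">',
        '##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein substitution">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=VAF,Number=1,Type=String,Description="Variant allele fraction, percent">',
        '##INFO=<ID=POPAF,Number=1,Type=String,Description="Population allele fraction">',
        '##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Upstream germline flag">',
        '##INFO=<ID=TP,Number=1,Type=String,Description="Timepoint">',
        '##INFO=<ID=PARTNER,Number=1,Type=String,Description="Known cis partner">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        pos = c.cds_change.cds_pos if c.cds_change else 1
        ref = c.cds_change.ref_base if c.cds_change else "N"
        alt = c.cds_change.alt_base if c.cds_change else "A"
        info = [f"GENE={c.gene}"]
        if c.cds_change:
            info.append(f"HGVSC={c.cds_change.render()}")
        if c.protein_change:
            info.append(f"HGVSP={c.protein_change.render()}")
        info += [f"CSQ={c.consequence.value}", f"VAF={c.vaf!r}", f"POPAF={c.pop_af!r}"]
        if c.germline_flagged:
            info.append("GERMLINE")
        info.append(f"TP={c.timepoint.value}")
        if c.phase_partner:
            info.append(f"PARTNER={c.phase_partner}")
        lines.append(f"{c.gene}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t" + ";".join(info))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_calls_vcf(path: str) -> list[VariantCall]:
    out: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        for key in vcf.header.info.keys():
            if key not in _VCF_INFO_KEYS:
                warnings.warn(f"unknown INFO key {key!r} ignored", stacklevel=2)
        for rec in vcf:
            info = rec.info
            out.append(
                VariantCall(
                    gene=str(info["GENE"]),
                    cds_change=parse_hgvs_c(str(info["HGVSC"])) if "HGVSC" in info else None,
                    protein_change=parse_protein_change(str(info["HGVSP"])) if "HGVSP" in info else None,
                    consequence=Consequence(str(info.get("CSQ", "missense"))),
                    vaf=float(str(info["VAF"])),
                    pop_af=float(str(info.get("POPAF", "0.0"))),
                    germline_flagged=bool(info.get("GERMLINE", False)),
                    timepoint=Timepoint(str(info.get("TP", "baseline"))),
                    phase_partner=str(info["PARTNER"]) if "PARTNER" in info else None,
                )
            )
    return out


def write_cohort_tsv(timelines: Iterable[PatientTimeline], path: str) -> None:
    rows = []
    for tl in timelines:
        meta = {
            "patient_id": tl.patient_id,
            "pfs_months": repr(tl.pfs_months),
            "event": str(tl.event).lower(),
            "prior_fulvestrant": str(tl.prior_fulvestrant).lower(),
            "has_progression": str(tl.has_progression).lower(),
        }
        calls = tuple(tl.baseline_calls) + tuple(tl.progression_calls or ())
        if not calls:
            rows.append({**meta, **{c: "" for c in _CALL_COLUMNS}, "gene": "."})
            continue
        for c in calls:
            rows.append({**meta, **_call_to_fields(c)})
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str) -> list[PatientTimeline]:
    grouped: dict[str, dict] = {}
    for line, row in _read_tsv_rows(path, _COHORT_COLUMNS):
        pid = row["patient_id"]
        entry = grouped.setdefault(
            pid,
            {
                "pfs_months": float(row["pfs_months"]),
                "event": _parse_bool(row["event"], line, "event"),
                "prior_fulvestrant": _parse_bool(row["prior_fulvestrant"], line, "prior_fulvestrant"),
                "has_progression": _parse_bool(row["has_progression"], line, "has_progression"),
                "baseline": [],
                "progression": [],
            },
        )
        if row["gene"] == ".":
            continue
        call = _call_from_fields(row, line)
        if call.timepoint is Timepoint.PROGRESSION:
            entry["progression"].append(call)
        else:
            entry["baseline"].append(call)
    return [
        PatientTimeline(
            patient_id=pid,
            baseline_calls=tuple(e["baseline"]),
            progression_calls=tuple(e["progression"]) if e["has_progression"] else None,
            pfs_months=e["pfs_months"],
            event=e["event"],
            prior_fulvestrant=e["prior_fulvestrant"],
        )
        for pid, e in grouped.items()
    ]


_ALLELE_CODE = {Allele.REF: "R", Allele.ALT: "A", Allele.MISSING: "."}
_CODE_ALLELE = {v: k for k, v in _ALLELE_CODE.items()}


def write_molecule_tsv(observations: Iterable[MoleculeObservation], path: str) -> None:
    rows = [
        {"molecule_id": o.molecule_id,
         "allele_a": _ALLELE_CODE[o.allele_a],
         "allele_b": _ALLELE_CODE[o.allele_b]}
        for o in observations
    ]
    pd.DataFrame(rows, columns=["molecule_id", "allele_a", "allele_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_molecule_tsv(path: str) -> list[MoleculeObservation]:
    out = []
    for line, row in _read_tsv_rows(path, ["molecule_id", "allele_a", "allele_b"]):
        try:
            out.append(
                MoleculeObservation(
                    row["molecule_id"], _CODE_ALLELE[row["allele_a"]], _CODE_ALLELE[row["allele_b"]]
                )
            )
        except KeyError:
            raise CallTableError(f"line {line}: alleles must be R/A/., got "
                                 f"{row['allele_a']!r}/{row['allele_b']!r}") from None
    return out


def read_survival_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_months", "event", "group"):
        if col not in df.columns:
            raise CallTableError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration; every absent key echoes its default."""

    cohort_tsv: Optional[str] = None      # default: packaged paired fixture
    catalog_tsv: Optional[str] = None     # default: packaged mini-catalog
    recurrence_threshold: int = DEFAULT_RECURRENCE_THRESHOLD
    phase_error_rate: float = 0.01
    phase_min_support: int = 3
    phase_cis_fraction: float = 0.8
    phase_alpha: float = 0.05
    survival_strata: tuple[str, ...] = ("Y537S", "D538G")
    cox_ties: str = "breslow"
    seed: int = 0
    out_dir: str = "ctdnatrack_out"

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["survival_strata"] = list(d["survival_strata"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "survival_strata" in d:
            d["survival_strata"] = tuple(d["survival_strata"])
        return cls(**d)


def _survival_report(timelines, summary_classified, config) -> pd.DataFrame:
    """Stratify PFS by baseline carriage of each configured variant."""
    rows = []
    for variant in config.survival_strata:
        carrier = {}
        for tl in timelines:
            base, _ = summary_classified[tl.patient_id]
            carrier[tl.patient_id] = any(
                cc.pathogenic
                and cc.call.gene == "ESR1"
                and cc.call.protein_change is not None
                and cc.call.protein_change.render() == variant
                for cc in base
            )
        t = np.array([tl.pfs_months for tl in timelines])
        e = np.array([tl.event for tl in timelines])
        x = np.array([int(carrier[tl.patient_id]) for tl in timelines])
        row = {"variant": variant, "n_detected": int(x.sum()), "n_not_detected": int((1 - x).sum())}
        if x.sum() == 0 or (1 - x).sum() == 0:
            row.update(note="one group empty; not assessable")
            rows.append(row)
            continue
        km1 = km_estimate(t[x == 1], e[x == 1])
        km0 = km_estimate(t[x == 0], e[x == 0])
        chi2, p = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
        row.update(
            median_detected=km1.median, median_not_detected=km0.median,
            logrank_chi2=round(chi2, 6), logrank_p=round(p, 6),
        )
        try:
            cox = cox_two_group(t, e, x, ties=config.cox_ties)
            row.update(
                hazard_ratio=round(cox.hazard_ratio, 4),
                ci_low=round(cox.ci_low, 4), ci_high=round(cox.ci_high, 4),
                orientation=cox.orientation,
            )
        except (ConvergenceError, ValueError) as exc:
            row.update(note=f"Cox not estimable: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> tuple[CohortSummary, dict[str, Path]]:
    """Run germline filter -> classification -> acquisition -> clonality ->
    phasing -> survival, writing deterministic TSV reports plus a run log.

    Returns the in-memory :class:`CohortSummary` and the written paths.
    """
    from .classify import annotate_cohort  # local import to avoid cycle noise

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_tsv is not None:
        timelines = read_cohort_tsv(config.cohort_tsv)
        phase_tasks: dict[tuple[str, str], PhasingTask] = {}
    else:
        timelines = fixture_paired_cohort()
        phase_tasks = fixture_phasing_patients(seed=config.seed)

    catalog = load_catalog(config.catalog_tsv)
    summary = summarize_cohort(timelines, catalog, config.recurrence_threshold)
    classified = annotate_cohort(timelines, catalog, config.recurrence_threshold)

    paths = {
        "gene_incidence": out / "gene_incidence.tsv",
        "esr1_variants": out / "esr1_variants.tsv",
        "acquisition": out / "acquisition.tsv",
        "clonality": out / "clonality.tsv",
        "phase_report": out / "phase_report.tsv",
        "survival": out / "survival.tsv",
        "report": out / "report.md",
        "run_log": out / "run_log.txt",
    }
    summary.gene_incidence.to_csv(paths["gene_incidence"], sep="\t", index=False)
    summary.esr1_variants.to_csv(paths["esr1_variants"], sep="\t", index=False)
    summary.acquisition.to_csv(paths["acquisition"], sep="\t", index=False)
    summary.clonality.to_csv(paths["clonality"], sep="\t", index=False)

    phase_rows = []
    for (patient, cdna), task in sorted(phase_tasks.items()):
        call = phase_pair_for_patient(
            task, config.phase_error_rate, config.phase_min_support,
            config.phase_cis_fraction, config.phase_alpha,
        )
        phase_rows.append({
            "patient_id": patient, "variant_a": task.variant_a, "variant_b": task.variant_b,
            "n11": call.table.n11, "n10": call.table.n10,
            "n01": call.table.n01, "n00": call.table.n00,
            "p_association": f"{call.p_association:.3e}",
            "verdict": call.verdict.value, "reason": call.reason,
        })
    pd.DataFrame(
        phase_rows,
        columns=["patient_id", "variant_a", "variant_b", "n11", "n10", "n01",
                 "n00", "p_association", "verdict", "reason"],
    ).to_csv(paths["phase_report"], sep="\t", index=False)

    surv = _survival_report(timelines, classified, config)
    surv.to_csv(paths["survival"], sep="\t", index=False)

    report = [
        "# ctDNA mutation-dynamics report", "",
        f"Patients: {summary.n_patients} (paired timepoints: {summary.n_paired})", "",
        "## Baseline gene incidence", summary.gene_incidence.to_markdown(index=False), "",
        "## Baseline ESR1 variants", summary.esr1_variants.to_markdown(index=False), "",
        "## Acquisition at progression", summary.acquisition.to_markdown(index=False), "",
        "## ESR1 clonality transitions", summary.clonality.to_markdown(index=False), "",
    ]
    if phase_rows:
        report += ["## Cis/trans phasing",
                   pd.DataFrame(phase_rows).to_markdown(index=False), ""]
    report += ["## Mutation-stratified PFS", surv.to_markdown(index=False), ""]
    paths["report"].write_text("\n".join(report))

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["survival_strata"] = list(cfg_dict["survival_strata"])
    paths["run_log"].write_text(
        "effective configuration (every threshold used by this run):\n"
        + yaml.safe_dump(cfg_dict, sort_keys=True)
    )
    return summary, paths
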