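"""Domain types and coding-sequence arithmetic shared by every pipeline stage.

Coordinates are 1-based CDS positions counted from the A of the initiator ATG
of ESR1 transcript NM_000125.4; the packaged CDS record is the single source
of truth for reference bases. Only single-nucleotide substitutions receive
automatic protein inference — indel/fusion annotations pass through verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

from Bio import SeqIO

__all__ = [
    "AROMATIC_RESIDUES",
    "AnnotationRecord",
    "CdsChange",
    "Consequence",
    "HgvsParseError",
    "PatientTimeline",
    "ProteinChange",
    "ReferenceMismatchError",
    "TargetabilityLevel",
    "Timepoint",
    "VariantCall",
    "apply_snv_to_codon",
    "cds_to_codon",
    "infer_protein_change",
    "is_aromatic",
    "load_reference_cds",
    "parse_hgvs_c",
    "parse_protein_change",
    "translate_codon",
    "variant_key",
]

_BASES = frozenset("ACGT")

#: Standard genetic code, DNA codons; "*" marks stop.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Amino acids whose side chain carries an aromatic ring.
AROMATIC_RESIDUES = frozenset("FWYH")

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY*")


class HgvsParseError(ValueError):
    """Raised when a cDNA/protein substitution string cannot be parsed."""


class ReferenceMismatchError(ValueError):
    """Reference base disagrees with the packaged CDS (wrong transcript build)."""


class Consequence(str, Enum):
    MISSENSE = "missense"
    SPLICING = "splicing"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


class Timepoint(str, Enum):
    SCREENING = "screening"
    BASELINE = "baseline"
    PROGRESSION = "progression"


class TargetabilityLevel(str, Enum):
    """OncoKB-style evidence tiers; 2B is the strongest present, 4 the weakest."""

    LEVEL_2B = "2B"
    LEVEL_3A = "3A"
    LEVEL_3B = "3B"
    LEVEL_4 = "4"
    NONE = "none"

    @property
    def rank(self) -> int:
        """1 = strongest evidence (2B) ... 5 = not targetable."""
        return _LEVEL_RANK[self]


_LEVEL_RANK = {
    TargetabilityLevel.LEVEL_2B: 1,
    TargetabilityLevel.LEVEL_3A: 2,
    TargetabilityLevel.LEVEL_3B: 3,
    TargetabilityLevel.LEVEL_4: 4,
    TargetabilityLevel.NONE: 5,
}


@dataclass(frozen=True)
class CdsChange:
    """A single-nucleotide substitution in CDS coordinates, e.g. 1210T>C."""

    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ValueError(f"cds_pos must be >= 1, got {self.cds_pos}")
        for name in ("ref_base", "alt_base"):
            b = getattr(self, name)
            if b not in _BASES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt are both {self.ref_base!r}")

    def render(self) -> str:
        return f"{self.cds_pos}{self.ref_base}>{self.alt_base}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_HGVS_C_RE = re.compile(r"^(?:c\.)?(\d+)([ACGT])>([ACGT])$")


def parse_hgvs_c(text: str) -> CdsChange:
    """Parse a cDNA substitution like ``"1210T>C"`` (optional ``c.`` prefix).

    Raises :class:`HgvsParseError` naming the offending token for malformed
    input, non-ACGT bases, or identical ref/alt.
    """
    m = _HGVS_C_RE.match(text.strip())
    if m is None:
        # distinguish the common failure modes for a useful message
        bad = re.search(r"[^c.\dACGT>]", text)
        token = bad.group(0) if bad else text
        raise HgvsParseError(
            f"cannot parse cDNA substitution {text!r} (offending token {token!r}); "
            "expected '<pos><ref>><alt>', e.g. '1210T>C'"
        )
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    if ref == alt:
        raise HgvsParseError(f"identical ref/alt base {ref!r} in {text!r}")
    return CdsChange(pos, ref, alt)


@dataclass(frozen=True)
class ProteinChange:
    """An amino-acid substitution rendered canonically, e.g. F404L."""

    ref_aa: str
    codon_index: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise ValueError(f"codon_index must be >= 1, got {self.codon_index}")
        for name in ("ref_aa", "alt_aa"):
            aa = getattr(self, name)
            if aa not in _AA_LETTERS:
                raise ValueError(f"{name} must be a one-letter amino acid, got {aa!r}")
        if self.ref_aa == "*":
            raise ValueError("reference residue cannot be a stop")

    def render(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_HGVS_P_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


def parse_protein_change(text: str) -> ProteinChange:
    """Parse a one-letter protein substitution like ``"F404L"``."""
    m = _HGVS_P_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(f"cannot parse protein substitution {text!r}")
    return ProteinChange(m.group(1), int(m.group(2)), m.group(3))


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon_index, offset_in_codon in 1..3)."""
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise ValueError(f"invalid codon {codon!r}")
    return CODON_TABLE[codon]


def apply_snv_to_codon(codon: str, offset: int, alt_base: str) -> tuple[str, str, str]:
    """Substitute ``alt_base`` at ``offset`` (1..3) and translate both codons.

    Returns (new_codon, ref_aa, alt_aa) under the standard genetic code.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if offset not in (1, 2, 3):
        raise ValueError(f"offset must be 1, 2 or 3, got {offset}")
    if alt_base not in _BASES:
        raise ValueError(f"alt_base must be one of A/C/G/T, got {alt_base!r}")
    new = codon[: offset - 1] + alt_base + codon[offset:]
    return new, CODON_TABLE[codon], CODON_TABLE[new]


def load_reference_cds(path: Optional[str] = None) -> str:
    """Return the packaged ESR1 CDS (or a caller-supplied single-record FASTA).

    The packaged record is a synthetic stand-in whose anchor codons match the
    published ESR1 variant annotations (see the FASTA header).
    """
    if path is not None:
        record = next(SeqIO.parse(path, "fasta"))
        return str(record.seq).upper()
    ref = resources.files("ctdnatrack.data") / "esr1_cds_synthetic.fasta"
    with resources.as_file(ref) as p:
        record = next(SeqIO.parse(str(p), "fasta"))
    return str(record.seq).upper()


def infer_protein_change(cds_change: CdsChange, cds_sequence: str) -> ProteinChange:
    """Derive the protein consequence of a CDS substitution.

    Raises :class:`ReferenceMismatchError` if the stated reference base does
    not match the sequence — the tell-tale of a wrong transcript build.
    """
    if cds_change.cds_pos > len(cds_sequence):
        raise ValueError(
            f"cds_pos {cds_change.cds_pos} beyond CDS of length {len(cds_sequence)}"
        )
    found = cds_sequence[cds_change.cds_pos - 1]
    if found != cds_change.ref_base:
        raise ReferenceMismatchError(
            f"reference base at CDS position {cds_change.cds_pos} is {found!r}, "
            f"not {cds_change.ref_base!r}: wrong transcript build?"
        )
    codon_index, offset = cds_to_codon(cds_change.cds_pos)
    codon = cds_sequence[(codon_index - 1) * 3 : codon_index * 3]
    _, ref_aa, alt_aa = apply_snv_to_codon(codon, offset, cds_change.alt_base)
    return ProteinChange(ref_aa, codon_index, alt_aa)


def is_aromatic(aa: str) -> bool:
    """True exactly for the ring-bearing residues F, W, Y and H."""
    if aa not in _AA_LETTERS or aa == "*":
        raise ValueError(f"unknown amino acid {aa!r}")
    return aa in AROMATIC_RESIDUES


@dataclass(frozen=True)
class VariantCall:
    """One somatic/germline call at one timepoint.

    ``vaf`` is a percentage in [0, 100]; ``pop_af`` a gnomAD-style population
    allele fraction in [0, 1]. ``phase_partner`` optionally names the
    activating partner a call is known to sit in cis with (simulation truth
    tag; excluded from identity).
    """

    gene: str
    cds_change: Optional[CdsChange] = None
    protein_change: Optional[ProteinChange] = None
    consequence: Consequence = Consequence.MISSENSE
    vaf: float = 0.0
    pop_af: float = 0.0
    germline_flagged: bool = False
    timepoint: Timepoint = Timepoint.BASELINE
    phase_partner: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cds_change is None and self.protein_change is None:
            raise ValueError("a call needs a cDNA change, a protein change, or both")
        if not 0.0 <= self.vaf <= 100.0:
            raise ValueError(f"vaf must be in [0, 100] percent, got {self.vaf}")
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af must be in [0, 1], got {self.pop_af}")


def variant_key(call: VariantCall, level: str = "protein") -> tuple:
    """Identity key for counting: (gene, protein change) or (gene, base change).

    Patient-level incidence uses the protein level (distinct base changes that
    produce one amino-acid change collapse); base-change tallies — e.g. one
    patient carrying five separate F404 substitutions — use nucleotide level.
    """
    if level == "protein":
        if call.protein_change is None:
            raise ValueError(f"call {call.gene} has no protein change for protein-level key")
        return (call.gene, call.protein_change.render())
    if level == "nucleotide":
        if call.cds_change is None:
            raise ValueError(f"call {call.gene} has no cDNA change for nucleotide-level key")
        return (call.gene, call.cds_change.render())
    raise ValueError(f"unknown key level {level!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Knowledge-base annotation attached to one call."""

    is_hotspot: bool = False
    is_oncogenic: bool = False
    targetability_level: TargetabilityLevel = TargetabilityLevel.NONE
    cohort_recurrence: int = 0

    def __post_init__(self) -> None:
        if self.cohort_recurrence < 0:
            raise ValueError("cohort_recurrence must be >= 0")


@dataclass(frozen=True)
class PatientTimeline:
    """Paired baseline/progression call sets plus the survival record.

    ``progression_calls is None`` means progression plasma was never
    sequenced (not assessable for acquisition), distinct from an empty
    progression call set.
    """

    patient_id: str
    baseline_calls: tuple[VariantCall, ...] = ()
    progression_calls: Optional[tuple[VariantCall, ...]] = None
    pfs_months: float = 0.0
    event: bool = False
    prior_fulvestrant: bool = False

    def __post_init__(self) -> None:
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be >= 0")
        for c in self.baseline_calls:
            if c.timepoint is not Timepoint.BASELINE:
                raise ValueError(f"baseline set of {self.patient_id} holds a {c.timepoint.value} call")
        for c in self.progression_calls or ():
            if c.timepoint is not Timepoint.PROGRESSION:
                raise ValueError(f"progression set of {self.patient_id} holds a {c.timepoint.value} call")

    @property
    def has_progression(self) -> bool:
        return self.progression_calls is not None
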