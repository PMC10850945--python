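# Methods

## Scope and model

`ctdnatrack` analyzes paired-timepoint ctDNA variant call sets from a
targeted panel (73–74 cancer genes, Guardant360-style output). The unit of
observation is a `VariantCall` (gene, cDNA and/or protein substitution,
consequence class, VAF in percent, population allele frequency, upstream
germline flag, timepoint); a `PatientTimeline` pairs baseline and
progression call sets with a PFS record and a fulvestrant-exposure flag.
`progression_calls = None` encodes "progression plasma never sequenced" and
is deliberately distinct from an empty progression call set: acquisition on
such patients is reported not-assessable, never silently empty.

## Coding-sequence arithmetic

CDS coordinates are 1-based from the A of the initiator ATG of ESR1
transcript NM_000125.4. Codon arithmetic is exact integer arithmetic
(`codon = floor((pos-1)/3)+1`, `offset = (pos-1) mod 3 + 1`) and
translation uses the standard genetic code, cross-checked in tests against
Biopython's standard-table translation on all 64 codons. Only
single-nucleotide substitutions get automatic protein inference;
indel/fusion descriptions pass through as opaque annotations, because every
variant this pipeline reasons about in depth is an SNV.

The packaged reference CDS is a clearly labelled **synthetic stand-in**
(`esr1_cds_synthetic.fasta`): full sequence databases are not bundled, so
the file has the correct length (1788 nt = 595 codons + stop) and carries
the true codons at every position the analysis touches (F404 = TTT,
E380 = GAG, D538 = GAT, Y537 = TAT, L536 = CTC, S463 = TCT, H356 = CAT),
consistent with the standard HGVS descriptions of the ESR1 hotspots
(c.1613A>G → D538G, c.1610A>C → Y537S, c.1138G>C → E380Q, c.1210T>C →
F404L, …). Filler codons are an arbitrary deterministic non-stop cycle. A
reference-base mismatch during inference raises a dedicated error, the
tell-tale of a wrong transcript build. Aromaticity is the fixed chemical
set {F, W, Y, H}; all F404 substitutions reachable by one base change of
TTT (I, V, L) fall outside it.

## Germline exclusion and pathogenicity

The germline rule is `flagged OR (48 ≤ VAF ≤ 52 AND popAF > 1e-5)` with the
VAF band inclusive and the population threshold strict, following the
printed inequality ("around 50% ± 2%", "> 0.001%") literally. The band is
applied uniformly to all consequence classes. Pathogenicity fires on the
first satisfied clause in a fixed order (hotspot, oncogenic, recurrent key
gene, splicing) so the recorded reason is deterministic. "Recurrent" is
taken as ≥ 2 distinct patients carrying the protein-level key anywhere in
the analyzed cohort — the minimal reading of recurrence — and is
configurable. Annotation knowledge ships as an editable TSV mini-catalog
covering the variants the analysis names, rather than live database
queries, so runs are hermetic and versioned with the code.

A consequence worth knowing: a novel key-gene variant carried by a single
patient (the fixture's F404V) is *not* pathogenic under the recurrence
clause. Patient-level acquired-F404 incidence is unaffected because every
F404 patient also carries a recurrent F404L or F404I.

## Acquisition and clonality

Acquisition is a set difference over pathogenic keys, protein-level by
default (a patient whose F404L arises from two base changes acquires one
protein key; nucleotide-level keys remain available, and the fixtures
encode the one patient with five separate F404 base changes). Lost keys are
reported but never enter acquisition percentages. Clonality counts distinct
activating ESR1 protein changes; the default activating catalog is the
named hotspots (E380Q, S463P, D538G) plus any missense change at codons
536/537, and explicitly excludes F404X and H356Y, which alter the LBD
without activating the receptor. Percentages are rounded half-up at the
printed precision (integer for gene-level/acquisition figures, one decimal
for ESR1-variant and clonality figures); half-up reproduces 55.7, 72.5 and
5.8 exactly from their count/denominator pairs.

## Phasing

Evidence is molecule-level: each cfDNA fragment reports an allele at one or
both loci. The decision rule is this package's own design (the study whose
statistics the fixtures reproduce reports verdicts without an algorithm):
unphasable below `min_support = 3` double-covering molecules or when the
inter-locus distance exceeds the maximum fragment length; cis when the
alt-bearing molecules are ≥ 80% concordant (`n11/m ≥ 0.8`) with two-sided
Fisher p < 0.05; trans when both discordant cells are populated and `n11`
is within the 95th percentile of Binomial(n10+n01, error_rate) — the count
of double-mutant molecules sequencing error alone would fabricate;
ambiguous otherwise. Conditioning on alt-bearing molecules rather than the
full table makes the verdict robust to ctDNA dilution and to tumor-fraction
asymmetry between a germline-balanced partner and a subclonal mutation.
All four constants are configuration. Phasing is strictly pairwise: a
variant in trans with one partner may well be cis with another, and every
assessable pair is reported.

The Fisher p-value is computed by scipy; an independent full-enumeration
hypergeometric oracle in the test suite checks it on every 2×2 table with
total ≤ 20. The monotone-degradation property is tested as *data-quality*
degradation: regenerating the same pair configurations at rising per-base
error (with the caller told the true rate) never increases the number of
confident verdicts. The caller-side error parameter itself only loosens
the trans bound, so monotonicity in that parameter alone is not a property
the rule has or claims.

## Survival

KM estimation and the log-rank test delegate to lifelines (hand-enumerated
risk-set arithmetic on a six-patient configuration guards the wiring). The
two-group Cox fit is implemented in-package: Newton iteration on the
one-parameter partial likelihood with Breslow tie handling by default and
Efron by flag, SE from observed information, CI = exp(β̂ ± 1.96·SE).
Breslow-as-default with an Efron flag is the stated contract; lifelines
exposes only Efron, so it serves as the independent cross-check in tests
(the two agree to ~1e-6 on tie-free data). Diverging coefficients
(|β| > 15, the signature of complete separation) raise a ConvergenceError
rather than returning a number. Orientation is explicit on every result —
HR for "detected" vs "not detected", HR > 1 meaning worse PFS for the
detected group — because published two-group HRs are easily read with the
opposite orientation.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults are the study conditions: 79 patients; baseline
gene probabilities ESR1 0.96, PIK3CA 0.43, TP53 0.30; ESR1 variant
probabilities conditional on carriage equal to the published spectrum
(D538G 44/76, …); germline contamination ~1 call/patient with VAF from a
tight beta centred at 50% (sd 1%, deliberately exercising the ±2% band at
its boundary), population AF log-uniform in [1e-4, ~0.3], and a 50% chance
of an upstream flag; somatic VAF from beta(2, 18) (mean 10%). Acquisition:
ESR1 with probability 0.20 and non-ESR1 pathogenic with 0.39 per patient
(jointly ≈ 51% acquiring anything), F404 with probability 0.045 *only* for
patients with fulvestrant exposure and ≥ 1 activating ESR1 baseline
mutation — exactly zero otherwise — tagged with the activating partner it
rides in cis with. PFS is exponential with baseline median 2.2 months,
per-variant hazard multipliers (defaults 1.9 for Y537S, 0.36 for Y537C)
and administrative censoring at 24 months. Fragment simulation draws
lengths from a truncated normal (mean 167 bp, sd 20, max 350 — the cfDNA
nucleosomal peak), places fragments uniformly over positions covering at
least one locus, assigns haplotypes by tumor fraction and flips observed
alleles at the per-base error rate.

What the simulations do **not** model: real co-mutation structure (the
joint distribution across genes was never published; the deterministic
fixtures use an arbitrary cyclic fill consistent with the printed
marginals, and every acceptance statistic depends only on marginals),
copy-number alterations and fusions, VAF covariance with tumor fraction
over time, non-exponential hazards, and read-level sequence context.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated statistical model, not performance on real panel output.

## Problem sizes and numerical choices

Law-of-large-numbers checks run at n = 5000 patients (3 binomial SEs);
phasing recovery at 1000 simulated pairs of ~250 molecules; Cox CI coverage
over 200 replicates of n = 500 (accepting 90–99% empirical coverage);
KM median recovery at n = 5000 events. Newton iteration converges to
|step| < 1e-10 within 100 iterations; all simulation seeds are fixed
constants or derived from one user seed via `SeedSequence` substreams, and
identical seeds give byte-identical pipeline outputs.

## Known limitations

* The phasing rule's constants were chosen by design reasoning, not fit to
  data; with very low tumor fractions (< ~5%) pairs drift to
  ambiguous/unphasable before they miscall, by construction.
* The packaged CDS is a stand-in: inference at positions other than the
  anchored codons is arithmetically correct but not biologically meaningful
  for ESR1; supply a real transcript FASTA via `load_reference_cds(path)`
  for production use.
* The Cox implementation is strictly two-group (one binary covariate);
  multivariable adjustment and proportional-hazards diagnostics are out of
  scope.
* VCF support is a minimal documented dialect (CDS coordinates, String-typed
  VAF fields) meant for interchange, not a general-purpose VCF reader.
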