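"""Cohort/fragment simulators and the deterministic printed-count fixtures."""

import numpy as np
import pytest

from ctdnatrack.core import Timepoint, variant_key
from ctdnatrack.phasing import Allele
from ctdnatrack.synthetic import (
    CohortConfig,
    FragmentSimConfig,
    PHASING_FIXTURE_PAIRS,
    fixture_phasing_patients,
    simulate_cohort,
    simulate_fragments,
    simulate_two_group_survival,
)
from ctdnatrack.survival import cox_two_group


def _carriers(cohort, gene):
    return sum(
        any(c.gene == gene for c in tl.baseline_calls) for tl in cohort
    )


class TestCohortSimulator:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_patients=40, seed=7)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_different_seed_differs(self):
        a = simulate_cohort(CohortConfig(n_patients=40, seed=7))
        b = simulate_cohort(CohortConfig(n_patients=40, seed=8))
        assert a != b

    def test_marginal_frequency_converges(self):
        """Empirical ESR1 carrier frequency within 3 binomial SE of 0.96."""
        n = 5000
        cohort = simulate_cohort(CohortConfig(n_patients=n, seed=3))
        freq = _carriers(cohort, "ESR1") / n
        se = np.sqrt(0.96 * 0.04 / n)
        assert abs(freq - 0.96) <= 3 * se

    def test_f404_requires_fulvestrant_and_activating_partner(self):
        # fulvestrant exposure impossible -> no F404 acquisition anywhere
        cfg = CohortConfig(n_patients=300, seed=5, p_prior_fulvestrant=0.0, p_acquire_f404=1.0)
        for tl in simulate_cohort(cfg):
            assert not any(
                c.gene == "ESR1"
                and c.protein_change is not None
                and c.protein_change.codon_index == 404
                for c in tl.progression_calls or ()
            )
        # eligible patients acquire with certainty, tagged with the cis partner
        cfg = CohortConfig(n_patients=300, seed=5, p_acquire_f404=1.0)
        n_f404 = 0
        for tl in simulate_cohort(cfg):
            activating = {
                c.protein_change.render()
                for c in tl.baseline_calls
                if c.gene == "ESR1" and c.protein_change is not None
            }
            f404 = [
                c for c in tl.progression_calls or ()
                if c.gene == "ESR1"
                and c.protein_change is not None
                and c.protein_change.codon_index == 404
            ]
            if not (tl.prior_fulvestrant and activating):
                assert not f404
                continue
            assert len(f404) == 1 and f404[0].phase_partner in activating
            n_f404 += 1
        assert n_f404 > 200

    def test_acquisition_frequency_recovers_configuration(self):
        """Estimated per-patient ESR1 acquisition within 3 binomial SE."""
        n, p = 2000, 0.20
        cohort = simulate_cohort(CohortConfig(n_patients=n, seed=9))
        acquired = 0
        for tl in cohort:
            base = {
                variant_key(c)
                for c in tl.baseline_calls
                if c.gene == "ESR1" and c.protein_change is not None
            }
            prog = {
                variant_key(c)
                for c in tl.progression_calls or ()
                if c.gene == "ESR1" and c.protein_change is not None
            }
            acquired += bool(prog - base)
        # F404 acquisitions add a small increment on top of p_acquire_esr1
        est = acquired / n
        se = np.sqrt(p * (1 - p) / n)
        assert est >= p - 3 * se
        assert est <= p + 0.045 + 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(p_acquire_esr1=1.2)


class TestSurvivalSimulator:
    def test_hazard_ratio_recovered_within_ci(self):
        df = simulate_two_group_survival(2000, hazard_ratio=2.0, seed=4)
        res = cox_two_group(df.time, df.event, df.group)
        assert res.ci_low <= 2.0 <= res.ci_high


class TestFragmentSimulator:
    def test_same_seed_identical(self):
        cfg = FragmentSimConfig(truth="cis", n_molecules=100, seed=2)
        assert simulate_fragments(cfg) == simulate_fragments(cfg)

    def test_cis_without_error_has_no_discordant_doubles(self):
        obs = simulate_fragments(
            FragmentSimConfig(truth="cis", n_molecules=300, error_rate=0.0, seed=1)
        )
        for o in obs:
            if Allele.MISSING in (o.allele_a, o.allele_b):
                continue
            assert o.allele_a == o.allele_b

    def test_trans_without_error_has_no_double_mutants(self):
        obs = simulate_fragments(
            FragmentSimConfig(truth="trans", n_molecules=300, error_rate=0.0, seed=1)
        )
        assert not any(
            o.allele_a is Allele.ALT and o.allele_b is Allele.ALT for o in obs
        )

    def test_distant_loci_yield_single_locus_observations_only(self):
        obs = simulate_fragments(
            FragmentSimConfig(truth="cis", n_molecules=200, inter_locus_distance=10_000, seed=3)
        )
        assert len(obs) == 200
        assert all(Allele.MISSING in (o.allele_a, o.allele_b) for o in obs)


class TestFixtures:
    def test_baseline_printed_counts(self, baseline_cohort):
        assert len(baseline_cohort) == 79
        assert _carriers(baseline_cohort, "ESR1") == 76
        assert _carriers(baseline_cohort, "PIK3CA") == 34
        assert _carriers(baseline_cohort, "TP53") == 24
        d538g = sum(
            any(
                c.gene == "ESR1" and c.protein_change is not None
                and c.protein_change.render() == "D538G"
                for c in tl.baseline_calls
            )
            for tl in baseline_cohort
        )
        assert d538g == 44

    def test_baseline_has_no_progression_timepoint(self, baseline_cohort):
        assert all(not tl.has_progression for tl in baseline_cohort)

    def test_paired_cohort_shape(self, paired_cohort):
        assert len(paired_cohort) == 69
        assert all(tl.has_progression for tl in paired_cohort)
        assert all(tl.prior_fulvestrant for tl in paired_cohort)

    def test_one_patient_carries_five_separate_f404_base_changes(self, paired_cohort):
        by_id = {tl.patient_id: tl for tl in paired_cohort}
        f404 = [
            c for c in by_id["PP07"].progression_calls
            if c.protein_change is not None and c.protein_change.codon_index == 404
        ]
        assert len({variant_key(c, "nucleotide") for c in f404}) == 5
        assert {c.protein_change.render() for c in f404} == {"F404L", "F404I", "F404V"}

    def test_phasing_fixture_structure(self, phasing_fixture):
        assert len(phasing_fixture) == 7
        assert len(PHASING_FIXTURE_PAIRS) == 7
        truths = {(p, c): t for p, c, t in PHASING_FIXTURE_PAIRS}
        assert sum(t == "cis" for t in truths.values()) == 6
        # the trans-configured pair sits on the patient with extra D538G/S463P/Y537N
        (trans_key,) = [k for k, t in truths.items() if t == "trans"]
        assert trans_key[0] == "PP08"
        for task in phasing_fixture.values():
            doubles = sum(
                o.allele_a is not Allele.MISSING and o.allele_b is not Allele.MISSING
                for o in task.observations
            )
            assert doubles >= 30

    def test_phasing_fixture_deterministic(self):
        a = fixture_phasing_patients()
        b = fixture_phasing_patients()
        assert a == b
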