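"""Phase-table construction, Fisher oracle agreement, verdict behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctdnatrack.phasing import (
    Allele,
    MoleculeObservation,
    PhaseTable,
    PhaseVerdict,
    PhasingTask,
    build_phase_table,
    call_phase,
    fisher_exact_2x2,
    phase_pair_for_patient,
)
from ctdnatrack.synthetic import FragmentSimConfig, simulate_fragments

from _helpers import fisher_two_sided_enumeration


def _obs(mid, a, b):
    return MoleculeObservation(mid, Allele(a), Allele(b))


class TestBuildPhaseTable:
    def test_counts_double_covering_only(self):
        obs = [
            _obs("m1", "alt", "alt"), _obs("m2", "alt", "alt"), _obs("m3", "alt", "alt"),
            _obs("m4", "ref", "ref"), _obs("m5", "ref", "ref"),
            _obs("m6", "alt", "missing"), _obs("m7", "missing", "ref"),
        ]
        assert build_phase_table(obs) == PhaseTable(3, 0, 0, 2)

    def test_all_single_locus_gives_empty_table(self):
        obs = [_obs("m1", "alt", "missing"), _obs("m2", "missing", "ref")]
        assert build_phase_table(obs) == PhaseTable(0, 0, 0, 0)

    def test_order_invariant(self):
        obs = [_obs(f"m{i}", a, b) for i, (a, b) in enumerate(
            itertools.product(["ref", "alt"], repeat=2))]
        assert build_phase_table(obs) == build_phase_table(reversed(obs))

    def test_duplicate_molecule_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_phase_table([_obs("m1", "alt", "alt"), _obs("m1", "ref", "ref")])


class TestFisherExact:
    def test_empty_table_is_one(self):
        assert fisher_exact_2x2(PhaseTable(0, 0, 0, 0)) == 1.0

    def test_balanced_diagonal_table(self):
        # 2 / C(10, 5) two-sided, by full enumeration
        assert fisher_exact_2x2(PhaseTable(5, 0, 0, 5)) == pytest.approx(2 / 252, rel=1e-9)

    def test_matches_enumeration_oracle_on_all_small_tables(self):
        # exhaustive over every table with total <= 12
        for total in range(13):
            for n11 in range(total + 1):
                for n10 in range(total - n11 + 1):
                    for n01 in range(total - n11 - n10 + 1):
                        n00 = total - n11 - n10 - n01
                        t = PhaseTable(n11, n10, n01, n00)
                        assert fisher_exact_2x2(t) == pytest.approx(
                            fisher_two_sided_enumeration(n11, n10, n01, n00), rel=1e-8
                        ), t


class TestCallPhase:
    def test_perfect_cooccurrence_is_cis(self):
        assert call_phase(PhaseTable(20, 0, 0, 80)).verdict is PhaseVerdict.CIS

    def test_mutual_exclusivity_is_trans(self):
        assert call_phase(PhaseTable(0, 12, 9, 79)).verdict is PhaseVerdict.TRANS

    def test_error_consistent_double_mutant_still_trans(self):
        # one alt/alt molecule among 20 discordant is within the 1% error bound
        assert call_phase(PhaseTable(1, 10, 10, 100)).verdict is PhaseVerdict.TRANS

    def test_insufficient_molecules_unphasable(self):
        call = call_phase(PhaseTable(1, 0, 0, 1))
        assert call.verdict is PhaseVerdict.UNPHASABLE

    def test_mixed_signal_is_ambiguous(self):
        assert call_phase(PhaseTable(3, 3, 0, 50)).verdict is PhaseVerdict.AMBIGUOUS

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_phase(PhaseTable(1, 1, 1, 1), error_rate=0.7)
        with pytest.raises(ValueError):
            call_phase(PhaseTable(1, 1, 1, 1), min_support=0)

    @given(
        n11=st.integers(0, 40), n10=st.integers(0, 40),
        n01=st.integers(0, 40), n00=st.integers(0, 40),
    )
    def test_locus_swap_never_changes_verdict(self, n11, n10, n01, n00):
        t = PhaseTable(n11, n10, n01, n00)
        assert call_phase(t).verdict is call_phase(t.transpose()).verdict


class TestPhasePairForPatient:
    def test_missing_table_unphasable(self):
        call = phase_pair_for_patient(None)
        assert call.verdict is PhaseVerdict.UNPHASABLE
        assert "no molecule table" in call.reason

    def test_distant_loci_unphasable(self):
        task = PhasingTask("p", "a", "b", (), inter_locus_distance=10_000, max_fragment_length=350)
        call = phase_pair_for_patient(task)
        assert call.verdict is PhaseVerdict.UNPHASABLE
        assert "fragment length" in call.reason

    def test_fixture_pairs_resolve(self, phasing_fixture):
        verdicts = {
            key: phase_pair_for_patient(task).verdict
            for key, task in phasing_fixture.items()
        }
        assert verdicts[("PP08", "1210T>C")] is PhaseVerdict.TRANS
        cis = [k for k, v in verdicts.items() if v is PhaseVerdict.CIS]
        assert len(cis) == 6


class TestSimulatedRecovery:
    @staticmethod
    def _verdict_counts(n_pairs, error_rate, seed0):
        counts = {truth: {v: 0 for v in PhaseVerdict} for truth in ("cis", "trans")}
        for truth in ("cis", "trans"):
            for i in range(n_pairs):
                cfg = FragmentSimConfig(
                    truth=truth, n_molecules=250, error_rate=error_rate,
                    tumor_fraction=0.5, seed=seed0 + i,
                )
                table = build_phase_table(simulate_fragments(cfg))
                counts[truth][call_phase(table, error_rate=error_rate).verdict] += 1
        return counts

    def test_high_accuracy_no_cis_trans_confusion(self):
        """100 pairs per truth at 1% error: >=99% accuracy, errors only
        soften to ambiguous/unphasable, never flip cis<->trans."""
        counts = self._verdict_counts(100, 0.01, seed0=1000)
        assert counts["cis"][PhaseVerdict.TRANS] == 0
        assert counts["trans"][PhaseVerdict.CIS] == 0
        correct = counts["cis"][PhaseVerdict.CIS] + counts["trans"][PhaseVerdict.TRANS]
        assert correct / 200 >= 0.99

    def test_confident_verdicts_degrade_with_error(self):
        """Regenerating the same pair configurations at rising per-base error
        (caller told the true rate) never gains confident verdicts."""
        confident = []
        for err in (0.0, 0.01, 0.05, 0.10):
            counts = self._verdict_counts(50, err, seed0=4000)
            confident.append(
                sum(counts[t][v] for t in counts for v in (PhaseVerdict.CIS, PhaseVerdict.TRANS))
            )
        assert confident == sorted(confident, reverse=True)
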