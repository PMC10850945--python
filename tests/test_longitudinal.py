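"""Acquisition calling, ESR1 clonality dynamics, cohort summarization."""

import pytest

from ctdnatrack.core import Timepoint, variant_key
from ctdnatrack.longitudinal import (
    ClonalityTransition,
    EsrClonality,
    call_acquired,
    clonality_transition,
    esr1_clonality,
    round_half_up,
    summarize_cohort,
)

from _helpers import mk_classified

B, P = Timepoint.BASELINE, Timepoint.PROGRESSION


def _renders(calls):
    return {cc.call.protein_change.render() for cc in calls}


class TestCallAcquired:
    def test_new_progression_key_is_acquired(self):
        base = [mk_classified(protein="D538G", timepoint=B)]
        prog = [
            mk_classified(protein="D538G", timepoint=P),
            mk_classified(protein="F404L", hotspot=False, oncogenic=False, recurrence=2, timepoint=P),
        ]
        res = call_acquired("p", base, prog)
        assert _renders(res.acquired) == {"F404L"}
        assert _renders(res.maintained) == {"D538G"}
        assert res.lost == ()

    def test_identical_sets_acquire_and_lose_nothing(self):
        base = [mk_classified(protein="Y537S", timepoint=B)]
        prog = [mk_classified(protein="Y537S", timepoint=P)]
        res = call_acquired("p", base, prog)
        assert res.acquired == () and res.lost == ()
        assert _renders(res.maintained) == {"Y537S"}

    def test_disappearing_baseline_key_is_lost(self):
        res = call_acquired("p", [mk_classified(protein="Y537S", timepoint=B)], [])
        assert _renders(res.lost) == {"Y537S"}

    def test_missing_timepoint_is_explicitly_not_assessable(self):
        res = call_acquired("p", [mk_classified()], None)
        assert not res.assessable
        assert res.acquired == () and res.maintained == () and res.lost == ()

    def test_nonpathogenic_calls_never_enter_the_partition(self):
        base = []
        prog = [mk_classified(gene="GATA3", protein="P409A", hotspot=False, oncogenic=False, timepoint=P)]
        assert call_acquired("p", base, prog).acquired == ()

    def test_protein_level_collapses_base_changes(self):
        prog = [
            mk_classified(protein="F404L", cdna="1210T>C", hotspot=False, oncogenic=False,
                          recurrence=2, timepoint=P),
            mk_classified(protein="F404L", cdna="1212T>A", hotspot=False, oncogenic=False,
                          recurrence=2, timepoint=P),
        ]
        res = call_acquired("p", [], prog)
        assert len(res.acquired) == 1
        assert len(call_acquired("p", [], prog, key_level="nucleotide").acquired) == 2

    def test_targetable_subset(self):
        prog = [
            mk_classified(gene="ERBB2", protein="L755S", level="2B", timepoint=P),
            mk_classified(gene="TP53", protein="R175H", timepoint=P),
        ]
        res = call_acquired("p", [], prog)
        assert _renders(res.acquired_targetable) == {"L755S"}

    def test_key_conservation_on_fixture(self, paired_cohort, paired_classified):
        """|acquired| + |maintained| = progression keys; |lost| + |maintained| = baseline keys."""
        for tl in paired_cohort:
            base, prog = paired_classified[tl.patient_id]
            res = call_acquired(tl.patient_id, base, prog)
            prog_keys = {variant_key(cc.call) for cc in prog if cc.pathogenic}
            base_keys = {variant_key(cc.call) for cc in base if cc.pathogenic}
            assert len(res.acquired) + len(res.maintained) == len(prog_keys)
            assert len(res.lost) + len(res.maintained) == len(base_keys)
            acq_keys = {variant_key(cc.call) for cc in res.acquired}
            assert not acq_keys & base_keys


class TestClonality:
    def test_single_activating_variant_is_monoclonal(self):
        state = esr1_clonality([mk_classified(protein="D538G")])
        assert state.state is EsrClonality.MONOCLONAL

    def test_two_activating_variants_are_polyclonal(self):
        state = esr1_clonality(
            [mk_classified(protein="D538G"), mk_classified(protein="Y537S")]
        )
        assert state.state is EsrClonality.POLYCLONAL

    def test_f404_is_not_activating(self):
        state = esr1_clonality(
            [
                mk_classified(protein="D538G"),
                mk_classified(protein="F404L", hotspot=False, oncogenic=False, recurrence=2),
            ]
        )
        assert state.state is EsrClonality.MONOCLONAL
        assert state.activating_variants == frozenset({"D538G"})

    def test_h356y_is_not_activating(self):
        state = esr1_clonality(
            [mk_classified(protein="H356Y", hotspot=False, oncogenic=False)]
        )
        assert state.state is EsrClonality.NO_ESR1

    def test_l536_y537_families_count(self):
        state = esr1_clonality(
            [mk_classified(protein="L536P"), mk_classified(protein="Y537D")]
        )
        assert state.state is EsrClonality.POLYCLONAL

    def test_explicit_catalog_override(self):
        state = esr1_clonality(
            [mk_classified(protein="D538G")], activating=frozenset({"Y537S"})
        )
        assert state.state is EsrClonality.NO_ESR1

    @pytest.mark.parametrize(
        "b,p,expected",
        [
            ("mono", "mono", ClonalityTransition.MAINTAINED),
            ("poly", "poly", ClonalityTransition.MAINTAINED),
            ("none", "none", ClonalityTransition.MAINTAINED),
            ("mono", "poly", ClonalityTransition.ACQUIRED_POLYCLONAL),
            ("none", "poly", ClonalityTransition.ACQUIRED_POLYCLONAL),
            ("none", "mono", ClonalityTransition.GAINED_ESR1),
            ("poly", "mono", ClonalityTransition.REDUCED),
            ("mono", "none", ClonalityTransition.REDUCED),
            ("poly", "none", ClonalityTransition.REDUCED),
        ],
    )
    def test_transition_table(self, b, p, expected):
        variants = {
            "none": [],
            "mono": [mk_classified(protein="D538G")],
            "poly": [mk_classified(protein="D538G"), mk_classified(protein="Y537S")],
        }
        assert clonality_transition(
            esr1_clonality(variants[b]), esr1_clonality(variants[p])
        ) is expected


class TestSummaries:
    def test_rounding_half_up(self):
        assert round_half_up(2.5) == 3.0
        assert round_half_up(72.4637, 1) == 72.5
        assert round_half_up(5.797, 1) == 5.8
        assert round_half_up(50.72) == 51.0

    def test_permutation_invariance(self, paired_cohort):
        fwd = summarize_cohort(paired_cohort)
        rev = summarize_cohort(list(reversed(paired_cohort)))
        for attr in ("gene_incidence", "esr1_variants", "acquisition", "clonality"):
            assert getattr(fwd, attr).equals(getattr(rev, attr))

    def test_count_percent_consistency(self, baseline_cohort):
        s = summarize_cohort(baseline_cohort)
        for _, row in s.gene_incidence.iterrows():
            assert row["percent"] == round_half_up(100.0 * row["count"] / row["denominator"])
            assert row["count"] <= row["denominator"]
        for _, row in s.esr1_variants.iterrows():
            assert row["percent"] == round_half_up(100.0 * row["count"] / row["denominator"], 1)

    def test_single_patient_cohort(self, baseline_cohort):
        s = summarize_cohort([baseline_cohort[0]])
        row = s.gene_incidence.set_index("gene").loc["ESR1"]
        assert row["count"] == 1 and row["percent"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
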