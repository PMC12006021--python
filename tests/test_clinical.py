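"""Clinical stage: group assignment, symptom partition, the normalized
prevalence percent-change screen and its planted-enrichment recovery."""

import math

import numpy as np
import pytest

from promiscuity.clinical import (
    AFFECTING,
    NON_AFFECTING,
    TargetGroupAssignment,
    all_shared_prevalences,
    assign_groups,
    permutation_null,
    prevalence_change,
    soc_rollup,
    symptom_partition,
)
from promiscuity.io_formats import SideEffectTable
from promiscuity.synthetic import SymptomSpec, generate_side_effects


def _assignment(n_aff=4, n_non=4):
    return TargetGroupAssignment(
        target_group={},
        drug_group={
            **{f"A{i}": AFFECTING for i in range(n_aff)},
            **{f"N{i}": NON_AFFECTING for i in range(n_non)},
        },
    )


def _table(rows):
    return SideEffectTable(tuple(rows))


class TestAssignGroups:
    def test_no_hits_everything_non_affecting(self, make_target):
        targets = [make_target(target_id=f"T{i}", drug_ids=[f"D{i}"]) for i in range(3)]
        a = assign_groups(targets, [])
        assert set(a.target_group.values()) == {NON_AFFECTING}
        assert set(a.drug_group.values()) == {NON_AFFECTING}

    def test_all_hit_targets_affecting(self, make_target, make_hit):
        targets = [make_target(target_id=f"T{i}", drug_ids=[f"D{i}"]) for i in range(3)]
        hits = [make_hit(target_id=f"T{i}") for i in range(3)]
        a = assign_groups(targets, hits)
        assert set(a.target_group.values()) == {AFFECTING}

    def test_drug_with_mixed_targets_counted_affecting_only(self, make_target, make_hit):
        targets = [
            make_target(target_id="T_hit", drug_ids=["DX"]),
            make_target(target_id="T_miss", drug_ids=["DX"]),
        ]
        a = assign_groups(targets, [make_hit(target_id="T_hit")])
        assert a.drug_group["DX"] == AFFECTING

    def test_unlinked_target_warns_and_is_excluded_from_drug_level(self, make_target):
        targets = [make_target(target_id="T0", drug_ids=[]),
                   make_target(target_id="T1", drug_ids=["D1"])]
        with pytest.warns(UserWarning, match="without drug links"):
            a = assign_groups(targets, [])
        assert a.unlinked_targets == ("T0",)
        assert set(a.drug_group) == {"D1"}


class TestSymptomPartition:
    def test_single_group_all_symptoms_unique_to_it(self):
        a = _assignment(n_aff=2, n_non=1)
        table = _table([("A0", "nausea", "GI"), ("A1", "rash", "Skin")])
        ua, un, sh = symptom_partition(a, table)
        assert ua == {"nausea", "rash"} and un == set() and sh == set()

    def test_one_drug_per_group_makes_shared(self):
        table = _table([("A0", "nausea", "GI"), ("N0", "nausea", "GI")])
        ua, un, sh = symptom_partition(_assignment(), table)
        assert sh == {"nausea"} and not ua and not un

    def test_engineered_partition_counts(self):
        """6 symptoms -> 2 unique affecting, 1 unique non, 3 shared."""
        rows = [
            ("A0", "s_ua1", "SOC1"), ("A1", "s_ua2", "SOC1"),
            ("N0", "s_un1", "SOC2"),
            ("A0", "s_sh1", "SOC3"), ("N1", "s_sh1", "SOC3"),
            ("A1", "s_sh2", "SOC3"), ("N2", "s_sh2", "SOC3"),
            ("A2", "s_sh3", "SOC3"), ("N0", "s_sh3", "SOC3"),
        ]
        ua, un, sh = symptom_partition(_assignment(), _table(rows))
        assert (len(ua), len(un), len(sh)) == (2, 1, 3)
        assert len(ua) + len(un) + len(sh) == 6  # conservation

    def test_unlinked_drug_rows_dropped(self):
        table = _table([("A0", "nausea", "GI"), ("ZZZ", "phantom", "GI")])
        ua, un, sh = symptom_partition(_assignment(), table)
        assert "phantom" not in ua | un | sh

    def test_empty_table_rejected(self):
        with pytest.raises(Exception):
            symptom_partition(_assignment(), _table([]))


class TestPrevalenceChange:
    def test_hand_computed_plus_100(self):
        """Groups of 4; symptom in 4/4 affecting vs 2/4 non-affecting."""
        rows = [(f"A{i}", "s", "SOC") for i in range(4)]
        rows += [(f"N{i}", "s", "SOC") for i in range(2)]
        rows += [("A0", "other", "SOC"), ("N0", "other", "SOC")]
        out = prevalence_change(_assignment(), _table(rows), min_change=10.0)
        target = [p for p in out if p.symptom == "s"][0]
        assert target.p_affecting == 1.0
        assert target.p_non_affecting == 0.5
        assert target.percent_change == pytest.approx(100.0)

    def test_equal_prevalence_filtered_out(self):
        rows = [("A0", "s", "SOC"), ("A1", "s", "SOC"),
                ("N0", "s", "SOC"), ("N1", "s", "SOC")]
        assert prevalence_change(_assignment(), _table(rows)) == []

    def test_exactly_ten_percent_filtered(self):
        """'more than a 10% change' is strict: +10.0% exactly is dropped."""
        # groups of 10: 55% vs 50% -> +10.0% exactly
        a = _assignment(n_aff=20, n_non=20)
        rows = [(f"A{i}", "s", "SOC") for i in range(11)]
        rows += [(f"N{i}", "s", "SOC") for i in range(10)]
        prevs = all_shared_prevalences(a, _table(rows))
        assert prevs[0].percent_change == pytest.approx(10.0)
        assert prevalence_change(a, _table(rows), min_change=10.0) == []

    def test_sorted_by_absolute_change_descending(self):
        rows = [(f"A{i}", "big", "SOC") for i in range(4)]
        rows += [("N0", "big", "SOC")]
        rows += [("A0", "small", "SOC"), ("A1", "small", "SOC")]
        rows += [("N0", "small", "SOC")]
        out = prevalence_change(_assignment(), _table(rows))
        changes = [abs(p.percent_change) for p in out]
        assert changes == sorted(changes, reverse=True)

    def test_empty_group_rejected(self):
        a = TargetGroupAssignment(target_group={}, drug_group={"A0": AFFECTING})
        with pytest.raises(ValueError):
            prevalence_change(a, _table([("A0", "s", "SOC")]))

    def test_label_swap_inverts_percent_change(self):
        """Swapping group labels maps pc -> 100*(1/(1+pc/100) - 1)."""
        rows = [(f"A{i}", "s", "SOC") for i in range(3)]
        rows += [(f"N{i}", "s", "SOC") for i in range(1)]
        a = _assignment()
        swapped = TargetGroupAssignment(
            target_group={},
            drug_group={
                d: (AFFECTING if g == NON_AFFECTING else NON_AFFECTING)
                for d, g in a.drug_group.items()
            },
        )
        pc = all_shared_prevalences(a, _table(rows))[0].percent_change
        pc_swapped = all_shared_prevalences(swapped, _table(rows))[0].percent_change
        assert pc_swapped == pytest.approx(100.0 * (1.0 / (1.0 + pc / 100.0) - 1.0))

    def test_planted_enrichment_recovered_across_seeds(self):
        """A symptom planted at 0.6 vs 0.2 prevalence (groups of 100) is
        reported with a positive change in >=95/100 replicate seeds and a
        median change within 25% of the planted +200%."""
        a = _assignment(n_aff=100, n_non=100)
        aff = sorted(d for d, g in a.drug_group.items() if g == AFFECTING)
        non = sorted(d for d, g in a.drug_group.items() if g == NON_AFFECTING)
        spec = [
            SymptomSpec("planted", "Infections and infestations", 0.6, 0.2),
            SymptomSpec("background", "Gastrointestinal disorders", 0.4, 0.4),
        ]
        positive = 0
        changes = []
        for seed in range(100):
            table, _ = generate_side_effects(aff, non, spec, seed=seed)
            reported = {
                p.symptom: p for p in prevalence_change(a, table, min_change=10.0)
            }
            if "planted" in reported and reported["planted"].percent_change > 0:
                positive += 1
                changes.append(reported["planted"].percent_change)
        assert positive >= 95
        median = sorted(changes)[len(changes) // 2]
        assert median == pytest.approx(200.0, rel=0.25)


class TestSocRollup:
    def test_empty_input_empty_table(self):
        assert soc_rollup([]).empty

    def test_three_enriched_in_one_soc(self):
        rows = []
        for k in range(3):
            rows += [(f"A{i}", f"s{k}", "Infections") for i in range(3)]
            rows += [("N0", f"s{k}", "Infections")]
        out = prevalence_change(_assignment(), _table(rows))
        rollup = soc_rollup(out)
        assert rollup.loc[0, "affecting_enriched"] == 3
        assert rollup.loc[0, "non_affecting_enriched"] == 0

    def test_denominator_uses_all_shared(self):
        rows = [("A0", "enriched", "SOC"), ("A1", "enriched", "SOC"),
                ("A2", "enriched", "SOC"), ("N0", "enriched", "SOC"),
                ("A0", "flat", "SOC"), ("N0", "flat", "SOC"),
                ("A1", "flat", "SOC"), ("N1", "flat", "SOC")]
        a = _assignment()
        changed = prevalence_change(a, _table(rows))
        shared = all_shared_prevalences(a, _table(rows))
        rollup = soc_rollup(changed, shared)
        assert rollup.loc[0, "n_shared"] == 2
        assert rollup.loc[0, "affecting_enriched"] == 1


class TestPermutationNull:
    def test_planted_enrichment_has_small_p(self):
        a = _assignment(n_aff=50, n_non=50)
        aff = sorted(d for d, g in a.drug_group.items() if g == AFFECTING)
        non = sorted(d for d, g in a.drug_group.items() if g == NON_AFFECTING)
        table, _ = generate_side_effects(
            aff, non, [SymptomSpec("planted", "SOC", 0.7, 0.1)], seed=3
        )
        p = permutation_null(a, table, "planted", n_permutations=200, seed=1)
        assert p < 0.05

    def test_null_symptom_has_large_p(self):
        a = _assignment(n_aff=50, n_non=50)
        aff = sorted(d for d, g in a.drug_group.items() if g == AFFECTING)
        non = sorted(d for d, g in a.drug_group.items() if g == NON_AFFECTING)
        table, _ = generate_side_effects(
            aff, non, [SymptomSpec("flat", "SOC", 0.5, 0.5)], seed=4
        )
        p = permutation_null(a, table, "flat", n_permutations=200, seed=1)
        assert p > 0.05
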