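"""Screening stage: planted-identity recovery, strict threshold
semantics, identical-match counting and function concordance."""

import numpy as np
import pytest

from promiscuity.screen import (
    function_concordance,
    identical_matches,
    screen_targets,
    summarize_screen,
)
from promiscuity.synthetic import mutate_to_identity, random_sequence


@pytest.fixture(scope="module")
def base_sequence():
    rng = np.random.default_rng(42)
    return random_sequence(200, rng)


class TestScreenTargets:
    def test_identical_target_gives_single_identical_hit(self, scheme, make_target, make_entry, base_sequence):
        target = make_target(sequence=base_sequence, target_class="pathogen")
        entries = [
            make_entry(protein_id="SAME", sequence=base_sequence),
            make_entry(protein_id="OTHER",
                       sequence=random_sequence(200, np.random.default_rng(1))),
        ]
        hits = screen_targets([target], entries, scheme)
        assert [h.protein_id for h in hits] == ["SAME"]
        assert hits[0].is_identical
        assert hits[0].percent_identity == 100.0

    def test_planted_identity_ladder_recovery(self, scheme, make_target, make_entry, base_sequence):
        """Substitution-only plants at {20,35,50,65,80,95}% are recovered
        within +/-1 point and exactly those above 30% are called."""
        target = make_target(sequence=base_sequence)
        ladder = [20.0, 35.0, 50.0, 65.0, 80.0, 95.0]
        rng = np.random.default_rng(7)
        entries = [
            make_entry(protein_id=f"ID{t:.0f}",
                       sequence=mutate_to_identity(base_sequence, t, rng))
            for t in ladder
        ]
        hits = screen_targets([target], entries, scheme, similarity_threshold=30.0)
        called = {h.protein_id: h.percent_identity for h in hits}
        assert set(called) == {"ID35", "ID50", "ID65", "ID80", "ID95"}
        for t in (35, 50, 65, 80, 95):
            assert called[f"ID{t}"] == pytest.approx(t, abs=1.0)

    def test_exact_threshold_plant_excluded(self, scheme, make_target, make_entry, base_sequence):
        """'above a 30%' is strict: a plant at exactly 30.0% is not called.

        The two asserts before the screen validate the construct: the
        plant carries exactly 60/200 identities and its optimal global
        alignment is gapless, so the measured identity is exactly 30.0.
        """
        target = make_target(sequence=base_sequence)
        mutant = mutate_to_identity(base_sequence, 30.0, np.random.default_rng(0))
        assert sum(a == b for a, b in zip(base_sequence, mutant)) == 60  # 60/200
        entry = make_entry(protein_id="EXACT30", sequence=mutant)
        from promiscuity.align import global_align

        assert global_align(base_sequence, mutant, scheme).percent_identity == 30.0
        hits = screen_targets([target], [entry], scheme, similarity_threshold=30.0)
        assert hits == []

    def test_threshold_monotonicity(self, scheme, make_target, make_entry, base_sequence):
        target = make_target(sequence=base_sequence)
        rng = np.random.default_rng(9)
        entries = [
            make_entry(protein_id=f"P{i}",
                       sequence=mutate_to_identity(base_sequence, t, rng))
            for i, t in enumerate([35.0, 55.0, 75.0, 95.0])
        ]
        previous = None
        for threshold in (30.0, 50.0, 70.0, 90.0):
            ids = {h.protein_id for h in
                   screen_targets([target], entries, scheme,
                                  similarity_threshold=threshold)}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_invalid_threshold_rejected(self, scheme, make_target, make_entry):
        with pytest.raises(ValueError):
            screen_targets([make_target()], [make_entry()], scheme,
                           similarity_threshold=0.0)
        with pytest.raises(ValueError):
            screen_targets([make_target()], [make_entry()], scheme,
                           similarity_threshold=101.0)

    def test_output_sorted_and_conserved_across_biomes(self, scheme, make_target, make_entry, base_sequence):
        target = make_target(sequence=base_sequence)
        rng = np.random.default_rng(3)
        entries = [
            make_entry(protein_id=f"{b.upper()}{i}", biome=b,
                       sequence=mutate_to_identity(base_sequence, 80.0, rng))
            for b in ("vaginal", "gut", "oral") for i in range(2)
        ]
        hits = screen_targets([target], entries, scheme)
        keys = [(h.target_id, h.biome, h.protein_id) for h in hits]
        assert keys == sorted(keys)
        per_biome = {b: sum(1 for h in hits if h.biome == b)
                     for b in ("gut", "oral", "vaginal")}
        assert sum(per_biome.values()) == len(hits) == 6


class TestIdenticalMatches:
    def test_no_identical_hits_gives_empty_table(self, make_hit):
        table = identical_matches([make_hit(pid=80.0)])
        assert table.empty

    def test_protein_identical_to_two_targets_counted_once(self, make_hit):
        hits = [
            make_hit(target_id="PT1", protein_id="P1", pid=100.0, identical=True,
                     target_class="pathogen"),
            make_hit(target_id="PT2", protein_id="P1", pid=100.0, identical=True,
                     target_class="pathogen"),
        ]
        table = identical_matches(hits)
        assert table.loc[0, "n_identical_proteins"] == 1

    def test_planted_duplicates_counted_per_biome(self, scheme, make_target, make_entry, base_sequence):
        target = make_target(sequence=base_sequence, target_class="pathogen")
        entries = [
            make_entry(protein_id=f"{b}{i}", biome=b, sequence=base_sequence)
            for b in ("gut", "oral", "vaginal") for i in range(3)
        ]
        table = identical_matches(screen_targets([target], entries, scheme))
        assert sorted(table["n_identical_proteins"]) == [3, 3, 3]
        assert set(table["biome"]) == {"gut", "oral", "vaginal"}


class TestFunctionConcordance:
    def test_all_below_threshold_empty(self, make_hit):
        assert function_concordance([make_hit(pid=45.0)], 50.0).empty

    def test_exactly_fifty_percent_excluded(self, make_hit):
        """The function cutoff is 'over 50%', strict."""
        assert function_concordance([make_hit(pid=50.0)], 50.0).empty
        assert not function_concordance([make_hit(pid=50.1)], 50.0).empty

    def test_hypothetical_protein_mapping_retained_as_other(self, make_hit):
        hits = [make_hit(pid=60.0, target_function="dihydrofolate reductase",
                         function="hypothetical protein")]
        table = function_concordance(hits)
        assert table.loc[0, "relationship"] == "other"
        assert table.loc[0, "function_annotation"] == "hypothetical protein"

    def test_concordant_and_discordant_counts(self, make_hit):
        hits = (
            [make_hit(protein_id=f"C{i}", pid=70.0, target_function="kinase",
                      function="kinase") for i in range(3)]
            + [make_hit(protein_id=f"D{i}", pid=70.0, target_function="kinase",
                        function="hypothetical protein") for i in range(2)]
        )
        table = function_concordance(hits)
        by_rel = table.set_index("relationship")["count"]
        assert by_rel["identical function"] == 3
        assert by_rel["other"] == 2


class TestSummary:
    def test_counts_aggregate_to_totals(self, make_hit):
        hits = [
            make_hit(protein_id="A", biome="gut", pid=60.0, target_class="human"),
            make_hit(protein_id="B", biome="gut", pid=80.0, target_class="human"),
            make_hit(protein_id="C", biome="oral", pid=100.0, identical=True,
                     target_class="pathogen"),
        ]
        table = summarize_screen(hits)
        assert table["n_hits"].sum() == 3
        human_gut = table[(table.target_class == "human") & (table.biome == "gut")]
        assert human_gut["mean_identity"].iloc[0] == pytest.approx(70.0)
        assert table[table.target_class == "pathogen"]["n_identical"].iloc[0] == 1
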