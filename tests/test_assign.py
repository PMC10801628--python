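"""Two-pass species identification, metagenome selection, Krona export."""

import random

import pytest

from srnacore.assign import (
    SpeciesAssignment,
    build_metagenome,
    filter_hits_by_taxa,
    first_pass_rank,
    group_hits_by_read,
    krona_text_export,
    second_pass_assign,
    select_metagenome_species,
    subsample_reads,
)
from srnacore.io import BlastHit, ReadRecord
from srnacore.taxonomy import TaxonGroupSet


def H(query, taxid, bitscore):
    return BlastHit(query, f"subj{taxid}", taxid, 100.0, 20, bitscore)


class TestSubsample:
    def _reads(self, n):
        return [ReadRecord(f"r{i}", "ACGTACGTACGTACG") for i in range(n)]

    def test_small_input_returned_whole(self):
        reads = self._reads(100)
        assert subsample_reads(reads, 200, seed=1) == reads

    def test_deterministic_under_seed(self):
        reads = self._reads(5000)
        a = subsample_reads(reads, 200, seed=42)
        b = subsample_reads(reads, 200, seed=42)
        assert [r.read_id for r in a] == [r.read_id for r in b]
        c = subsample_reads(reads, 200, seed=43)
        assert [r.read_id for r in a] != [r.read_id for r in c]

    def test_inclusion_probability_uniform(self):
        reads = self._reads(2000)
        hits = [0] * 2000
        n_trials = 300
        for seed in range(n_trials):
            for r in subsample_reads(reads, 200, seed=seed):
                hits[int(r.read_id[1:])] += 1
        mean_rate = sum(hits) / (2000 * n_trials)
        assert mean_rate == pytest.approx(0.1, abs=1e-9)  # exactly 200/2000 drawn
        # no read is systematically favoured: every count within 6 sigma of
        # the binomial expectation (the extreme of 2000 reads sits near 4)
        sigma = (n_trials * 0.1 * 0.9) ** 0.5
        assert max(hits) < n_trials * 0.1 + 6 * sigma
        assert min(hits) > n_trials * 0.1 - 6 * sigma


class TestTaxonGroups:
    def test_host_taxid_maps_to_host_group(self, taxonomy):
        assert TaxonGroupSet().group_of(9606, taxonomy) == "Homo"

    def test_bacterial_descendant_maps_to_bacteria(self, taxonomy):
        # ancestor-walk oracle: E. coli 562 -> genus 561 -> Bacteria 2
        assert TaxonGroupSet().group_of(562, taxonomy) == "Bacteria"
        assert TaxonGroupSet().group_of(4932, taxonomy) == "Fungi"

    def test_hits_outside_all_groups_dropped(self, taxonomy):
        hits = [H("r1", 9606, 40.0), H("r2", 2759, 40.0)]  # Eukaryota root: no group
        tagged, dropped = filter_hits_by_taxa(hits, TaxonGroupSet(), taxonomy)
        assert [(h.taxon_id, g) for h, g in tagged] == [(9606, "Homo")]
        assert dropped == 1

    def test_unknown_taxid_dropped(self, taxonomy):
        tagged, dropped = filter_hits_by_taxa([H("r", 999999, 10.0)], TaxonGroupSet(), taxonomy)
        assert tagged == [] and dropped == 1

    def test_species_lifting(self, taxonomy):
        assert taxonomy.species_of(9606) == (9606, True)
        # genus-level taxid has no species ancestor: flagged, unchanged
        assert taxonomy.species_of(561) == (561, False)


class TestFirstPass:
    def test_frequency_of_presence_ranking(self):
        hits = {
            "r1": [H("r1", 100, 40.0)],
            "r2": [H("r2", 100, 40.0)],
            "r3": [H("r3", 100, 40.0)],
            "r4": [H("r4", 200, 40.0)],
        }
        table = first_pass_rank(hits, tolerance=0.0)
        assert [(row["taxon_id"], row["rank"]) for row in table] == [(100, 1), (200, 2)]

    def test_tie_broken_by_lower_taxid(self):
        hits = {f"r{i}": [H(f"r{i}", 300, 40.0), H(f"r{i}", 100, 40.0)] for i in range(5)}
        table = first_pass_rank(hits, tolerance=0.0)
        assert [row["taxon_id"] for row in table] == [100, 300]
        assert [row["n_reads_present"] for row in table] == [5, 5]

    def test_tolerance_zero_equals_per_read_max_oracle(self):
        rng = random.Random(0)
        hits = {}
        for i in range(200):
            read = f"r{i}"
            hits[read] = [
                H(read, rng.choice([100, 200, 300, 400]), round(rng.uniform(20, 50), 1))
                for _ in range(rng.randint(1, 6))
            ]
        table = first_pass_rank(hits, tolerance=0.0)
        presence = {}
        for read, read_hits in hits.items():
            best = max(h.bitscore for h in read_hits)
            for s in {h.taxon_id for h in read_hits if h.bitscore == best}:
                presence[s] = presence.get(s, 0) + 1
        assert {row["taxon_id"]: row["n_reads_present"] for row in table} == presence

    def test_counts_reads_not_hits(self):
        # many near-identical subject records must count once per read
        hits = {"r1": [H("r1", 100, 40.0)] * 10, "r2": [H("r2", 200, 40.0)]}
        table = first_pass_rank(hits, tolerance=0.0)
        assert {row["taxon_id"]: row["n_reads_present"] for row in table} == {100: 1, 200: 1}


class TestSecondPass:
    def test_higher_rank_wins_within_tolerance(self):
        # B is 0.5 bits behind but ranked better -> B wins at tolerance 1
        rank_table = [
            {"taxon_id": 200, "rank": 1},
            {"taxon_id": 100, "rank": 2},
        ]
        hits = {"r": [H("r", 100, 40.0), H("r", 200, 39.5)]}
        (a,) = second_pass_assign(hits, rank_table, tolerance=1.0)
        assert a.taxon_id == 200
        assert a.n_candidates == 2

    def test_tolerance_zero_is_best_hit_assignment(self):
        rank_table = [{"taxon_id": 200, "rank": 1}, {"taxon_id": 100, "rank": 2}]
        hits = {"r": [H("r", 100, 40.0), H("r", 200, 39.5)]}
        (a,) = second_pass_assign(hits, rank_table, tolerance=0.0)
        assert a.taxon_id == 100

    def test_missing_species_treated_as_worst_rank(self):
        hits = {"r": [H("r", 100, 40.0), H("r", 999, 40.0)]}
        (a,) = second_pass_assign(hits, [{"taxon_id": 100, "rank": 1}], tolerance=0.0)
        assert a.taxon_id == 100

    def test_permutation_invariance(self):
        rng = random.Random(3)
        hits = {}
        for i in range(100):
            read = f"r{i}"
            hits[read] = [
                H(read, rng.choice([100, 200, 300]), round(rng.uniform(20, 50), 1))
                for _ in range(rng.randint(1, 5))
            ]
        table = first_pass_rank(hits, tolerance=2.0)
        base = second_pass_assign(hits, table, tolerance=2.0)
        for seed in range(3):
            shuffled = {}
            for read, read_hits in hits.items():
                hs = list(read_hits)
                random.Random(seed).shuffle(hs)
                shuffled[read] = hs
            table2 = first_pass_rank(shuffled, tolerance=2.0)
            assert table2 == table
            assert second_pass_assign(shuffled, table2, tolerance=2.0) == base


class TestMetagenomeSelection:
    def _assignments(self, fractions, total=1000):
        out = []
        i = 0
        for taxid, frac in fractions.items():
            for _ in range(int(frac * total)):
                out.append(SpeciesAssignment(f"r{i}", taxid, 40.0, 1))
                i += 1
        return out

    def test_below_threshold_excluded(self):
        a = self._assignments({100: 0.995, 200: 0.005})
        assert [t for t, _ in select_metagenome_species(a)] == [100]

    def test_exact_threshold_excluded(self):
        a = self._assignments({100: 0.99, 200: 0.01})
        assert [t for t, _ in select_metagenome_species(a)] == [100]

    def test_fractions_and_order(self):
        a = self._assignments({100: 0.60, 200: 0.30, 300: 0.09, 400: 0.015})
        sel = select_metagenome_species(a)
        assert [t for t, _ in sel] == [100, 200, 300, 400]
        assert sel[0][1] > sel[1][1] > sel[2][1] > sel[3][1]

    def test_unassigned_reads_ignored(self):
        a = self._assignments({100: 1.0}) + [SpeciesAssignment("u", None, 0.0, 0)] * 50
        ((taxid, frac),) = select_metagenome_species(a)
        assert taxid == 100 and frac == 1.0


class TestBuildMetagenome:
    def test_descriptions_rewritten_and_host_first(self, tmp_path, taxonomy):
        g1 = tmp_path / "a.fa"
        g1.write_text(">c1\nACGT\n>c2\nGGGG\n")
        g2 = tmp_path / "b.fa"
        g2.write_text(">c1\nTTTT\n")
        out = tmp_path / "meta.fa"
        manifest = build_metagenome(
            [562, 9606], {562: g1, 9606: g2}, out, taxonomy
        )
        text = out.read_text()
        ids = [l[1:] for l in text.splitlines() if l.startswith(">")]
        assert ids[0].startswith("9606|Homo_sapiens|")  # host first
        assert len(ids) == 3
        assert len(set(ids)) == 3  # collision "c1" disambiguated by taxid prefix
        assert {row["status"] for row in manifest} == {"ok"}

    def test_missing_genome_recorded(self, tmp_path, taxonomy):
        g1 = tmp_path / "a.fa"
        g1.write_text(">c1\nACGT\n")
        manifest = build_metagenome(
            [562, 1280], {562: g1}, tmp_path / "m.fa", taxonomy
        )
        by_taxid = {row["taxon_id"]: row for row in manifest}
        assert by_taxid[1280]["status"] == "missing"
        assert by_taxid[562]["status"] == "ok"


class TestKrona:
    def test_single_species_line(self, taxonomy):
        a = [SpeciesAssignment(f"r{i}", 9606, 40.0, 1) for i in range(10)]
        text = krona_text_export(a, taxonomy)
        (line,) = text.strip().splitlines()
        fields = line.split("\t")
        assert fields[0] == "10"
        assert fields[1] == "root" and fields[-1] == "Homo sapiens"

    def test_counts_sum_to_assigned(self, taxonomy):
        a = (
            [SpeciesAssignment(f"h{i}", 9606, 40.0, 1) for i in range(7)]
            + [SpeciesAssignment(f"e{i}", 562, 40.0, 1) for i in range(3)]
            + [SpeciesAssignment("u", None, 0.0, 0)]
        )
        text = krona_text_export(a, taxonomy)
        total = sum(int(l.split("\t")[0]) for l in text.strip().splitlines())
        assert total == 10

    def test_lineage_matches_taxonomy_path(self, taxonomy):
        a = [SpeciesAssignment("r", 1280, 40.0, 1)]
        (line,) = krona_text_export(a, taxonomy).strip().splitlines()
        lineage = line.split("\t")[1:]
        oracle = [taxonomy.name(t) for t in taxonomy.lineage(1280)]
        assert lineage == oracle
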