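"""Multimapper reassignment, priority counting, strategy orchestration."""

import random

import pandas as pd
import pytest

from srnacore.counting import (
    INTRONIC,
    UNANNOTATED,
    Placement,
    catalogue_rna_types,
    count_with_priority,
    orchestrate_strategy,
    reassign_multimappers,
    summary_row,
)
from srnacore.harmonize import PrioritySchema, build_catalogue
from srnacore.io import GenomicFeature


def F(start, end, strand="+", name=None, rna_type="miRNA", source="db", seqid="c1"):
    return GenomicFeature(
        seqid=seqid, start=start, end=end, strand=strand,
        source_db=source, rna_type=rna_type, name=name or f"{rna_type}_{start}",
    )


def P(read_id, pos, seqid="c1", strand="+", length=20, score=0.0):
    return Placement(read_id, seqid, pos, strand, length, score)


class TestReassignMultimappers:
    def test_cluster_attracts_multimapper(self):
        placements = {f"u{i}": [P(f"u{i}", 1000 + i)] for i in range(10)}
        placements["m"] = [P("m", 1005), P("m", 9000)]
        chosen = reassign_multimappers(placements)
        assert chosen["m"].pos == 1005

    def test_zero_weight_ties_go_to_lowest_coordinate(self):
        chosen = reassign_multimappers({"m": [P("m", 5000), P("m", 100)]})
        assert chosen["m"].pos == 100

    def test_unique_reads_never_move(self):
        placements = {"u": [P("u", 42)], "m": [P("m", 40), P("m", 900)]}
        chosen = reassign_multimappers(placements)
        assert chosen["u"].pos == 42

    def test_second_pass_uses_first_pass_placements(self):
        # two multimappers support each other at 2000 only after pass 1
        placements = {
            "u1": [P("u1", 2000)],
            "m1": [P("m1", 2010), P("m1", 7000)],
            "m2": [P("m2", 7010), P("m2", 2020)],
        }
        chosen = reassign_multimappers(placements, passes=2)
        assert chosen["m1"].pos == 2010
        assert chosen["m2"].pos == 2020

    def test_strand_segregated_coverage(self):
        placements = {f"u{i}": [P(f"u{i}", 100 + i, strand="-")] for i in range(5)}
        placements["m"] = [P("m", 102, strand="+"), P("m", 104, strand="-")]
        chosen = reassign_multimappers(placements)
        # same locus on both strands: only the minus copy sees the coverage
        assert chosen["m"].strand == "-"


class TestCountWithPriority:
    def _catalogue(self, feats):
        by_source: dict = {}
        for f in feats:
            by_source.setdefault(f.source_db, []).append(f)
        return build_catalogue(sorted(by_source.items()))

    def test_mirna_outranks_pirna(self):
        cat = self._catalogue([
            F(100, 121, name="mir1", rna_type="miRNA", source="mirbase"),
            F(95, 130, name="pir1", rna_type="piRNA", source="pirbase"),
        ])
        counts = count_with_priority([P("r1", 105)], cat)
        assert counts.loc["mir1", "sample"] == 1
        assert counts.loc["pir1", "sample"] == 0 if "pir1" in counts.index else True

    def test_read_overlapping_nothing_is_unannotated(self):
        cat = self._catalogue([F(1000, 1100)])
        counts = count_with_priority([P("r1", 10)], cat)
        assert counts.loc[UNANNOTATED, "sample"] == 1

    def test_intronic_detection(self):
        cat = self._catalogue([F(100, 190, rna_type="mRNA", name="e1"),
                               F(330, 420, rna_type="mRNA", name="e2")])
        span = F(100, 420, rna_type="gene_span", name="g")
        counts = count_with_priority([P("r1", 250)], cat, gene_spans=[span])
        assert counts.loc[INTRONIC, "sample"] == 1

    def test_strandedness(self):
        cat = self._catalogue([F(100, 140, strand="+")])
        counts = count_with_priority([P("r1", 110, strand="-")], cat)
        assert counts.loc[UNANNOTATED, "sample"] == 1
        counts = count_with_priority([P("r1", 110, strand="-")], cat, stranded=False)
        assert counts.loc[UNANNOTATED, "sample"] == 0

    def test_zero_ambiguity_and_conservation_against_bruteforce(self):
        rng = random.Random(8)
        schema = PrioritySchema()
        feats = []
        for i in range(300):
            start = rng.randint(1, 20000)
            feats.append(
                F(start, start + rng.randint(20, 150),
                  strand=rng.choice("+-"),
                  rna_type=rng.choice(["miRNA", "tRNA", "rRNA", "mRNA", "piRNA", "lncRNA"]),
                  name=f"f{i}", source="db")
            )
        cat = self._catalogue(feats)
        placements = [
            P(f"r{i}", rng.randint(1, 20000), strand=rng.choice("+-"),
              length=rng.randint(15, 44))
            for i in range(2000)
        ]
        counts = count_with_priority(placements, cat)
        # conservation: every placed read counted exactly once, no ambiguous row
        assert counts["sample"].sum() == len(placements)
        assert not any("ambig" in str(ix).lower() for ix in counts.index)

        # brute-force per-read resolver over the merged catalogue
        def resolve(p):
            best = None
            for f in cat.features:
                if f.seqid != p.seqid or f.strand != p.strand:
                    continue
                if f.start > p.end or p.pos > f.end:
                    continue
                overlap = min(f.end, p.end) - max(f.start, p.pos) + 1
                key = (schema.priority(f.rna_type), -overlap, f.start, f.name)
                if best is None or key < best[0]:
                    best = (key, f.name)
            return best[1] if best else UNANNOTATED

        oracle: dict = {}
        for p in placements:
            oracle[resolve(p)] = oracle.get(resolve(p), 0) + 1
        ours = counts["sample"][counts["sample"] > 0].to_dict()
        assert ours == oracle

    def test_priority_monotonicity(self):
        # promoting piRNA above miRNA can only grow the piRNA count
        feats = [
            F(100, 121, name="mir1", rna_type="miRNA", source="a"),
            F(95, 130, name="pir1", rna_type="piRNA", source="b"),
        ]
        placements = [P(f"r{i}", 100 + i) for i in range(10)]
        default = build_catalogue([("a", [feats[0]]), ("b", [feats[1]])])
        flipped_schema = PrioritySchema(
            ordered_types=["piRNA"] + [t for t in default.schema.ordered_types if t != "piRNA"]
        )
        flipped = build_catalogue([("a", [feats[0]]), ("b", [feats[1]])], flipped_schema)
        c0 = count_with_priority(placements, default)
        c1 = count_with_priority(placements, flipped)
        n0 = c0.loc["pir1", "sample"] if "pir1" in c0.index else 0
        assert c1.loc["pir1", "sample"] >= n0


class TestRnaTypeCatalogue:
    def _setup(self, type_counts):
        feats, placements = [], []
        pos = 100
        i = 0
        for rna_type, n in type_counts.items():
            feats.append(F(pos, pos + 50, rna_type=rna_type, name=f"{rna_type}_x"))
            for _ in range(n):
                placements.append(P(f"r{i}", pos + 5))
                i += 1
            pos += 1000
        cat = build_catalogue([("db", feats)])
        counts = count_with_priority(placements, cat)
        return catalogue_rna_types(counts, cat)

    def test_all_mirna_is_100_percent(self):
        types = self._setup({"miRNA": 10})
        assert types.loc["miRNA", "sample"] == pytest.approx(100.0)

    def test_sixty_forty_split(self):
        types = self._setup({"miRNA": 60, "tRNA": 40})
        assert types.loc["miRNA", "sample"] == pytest.approx(60.0)
        assert types.loc["tRNA", "sample"] == pytest.approx(40.0)

    def test_percentages_sum_to_100(self):
        types = self._setup({"miRNA": 3, "tRNA": 5, "rRNA": 11, "piRNA": 2})
        body = types.loc[[ix for ix in types.index if not ix.startswith("#")]]
        assert body["sample"].sum() == pytest.approx(100.0, abs=0.1)

    def test_scale_invariance_under_read_duplication(self):
        a = self._setup({"miRNA": 6, "tRNA": 4})
        b = self._setup({"miRNA": 12, "tRNA": 8})
        pd.testing.assert_frame_equal(a, b)

    def test_zero_annotated_reads_gives_na(self):
        cat = build_catalogue([("db", [F(5000, 5050)])])
        counts = count_with_priority([P("r1", 10)], cat)
        types = catalogue_rna_types(counts, cat)
        body = types.loc[[ix for ix in types.index if not ix.startswith("#")]]
        assert body.isna().all().all() or body.empty


class TestOrchestrate:
    HOST = "9606|Homo_sapiens|hchr1"
    MICROBE = "562|Escherichia_coli|mc1"

    def test_host_only_read_is_host_under_both(self):
        host = {"r": [P("r", 100, seqid="hchr1", score=40.0)]}
        meta = {"r": [P("r", 100, seqid=self.HOST, score=40.0)]}
        for strategy in ("successive", "metagenome"):
            prov, _ = orchestrate_strategy(["r"], strategy, host, meta)
            assert prov["r"] == "host"

    def test_mismatched_host_vs_perfect_microbe(self):
        # host alignment carries 2 mismatches (score 30), microbe is perfect (40)
        host = {"r": [P("r", 100, seqid="hchr1", score=30.0)]}
        meta = {"r": [P("r", 100, seqid=self.HOST, score=30.0),
                      P("r", 55, seqid=self.MICROBE, score=40.0)]}
        prov_succ, _ = orchestrate_strategy(["r"], "successive", host, meta)
        prov_meta, _ = orchestrate_strategy(["r"], "metagenome", host, meta)
        assert prov_succ["r"] == "host"
        assert prov_meta["r"] == "other:562"

    def test_unmapped_read_unidentified(self):
        prov, _ = orchestrate_strategy(["r"], "metagenome", {}, {})
        assert prov["r"] is None

    def test_categories_partition_input(self):
        rng = random.Random(2)
        reads = [f"r{i}" for i in range(50)]
        host, meta = {}, {}
        for r in reads:
            kind = rng.random()
            if kind < 0.4:
                host[r] = [P(r, rng.randint(1, 500), seqid="hchr1", score=40.0)]
                meta[r] = [P(r, host[r][0].pos, seqid=self.HOST, score=40.0)]
            elif kind < 0.7:
                meta[r] = [P(r, rng.randint(1, 500), seqid=self.MICROBE, score=40.0)]
        prov, _ = orchestrate_strategy(reads, "metagenome", host, meta)
        assert set(prov) == set(reads)
        summ = summary_row(len(reads), 0, prov)
        total = sum(v for k, v in summ.items() if k.endswith("_pct"))
        assert total == pytest.approx(100.0)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            orchestrate_strategy([], "hybrid", {}, {})
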