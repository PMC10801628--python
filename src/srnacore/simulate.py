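"""Synthetic fixtures: toy genomes, overlapping annotations, reads and oracles.

Everything the pipeline consumes can be generated here, deterministically
under a seed, at desk scale: a toy host genome with multi-source
annotations that deliberately overlap both within and between sources
(including small RNAs nested inside tRNA loci, the classic ambiguity
trap), microbial genomes under a reduced taxonomy carrying the standard
screening group roots, read sets of 10–44 nt drawn from annotated
features with optional substitution errors, environment (no-template)
libraries with planted contaminants, and a naive exact/mismatch aligner
that stands in for BLAST and a short-read mapper on references of this
size.

Truth labels ride inside read ids (``species|feature|type|position``) so
evaluations need no side tables.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass

import numpy as np

from .harmonize import reverse_complement
from .io import BlastHit, GenomicFeature, ReadRecord, TaxonomyNode
from .counting import Placement
from .taxonomy import Taxonomy

HOST_TAXID = 9606
MICROBE_TAXIDS = (562, 1280)  # Escherichia coli, Staphylococcus aureus
CONTAMINANT_TAXID = 32630  # synthetic construct (reagent background)

BASES = "ACGT"


def _derive_seed(seed: int, *labels: str) -> int:
    """Stable stream-specific seed below 2^31 (independent of hash randomisation)."""
    return zlib.crc32(f"{seed}:{':'.join(labels)}".encode()) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    Ten samples of 10,000 reads each with read lengths uniform on
    10–44 nt reproduce the emulated study's scale; the uniform length
    range makes the sub-15-nt filter remove ~14% of raw reads.
    """

    seed: int = 0
    host_genome_length: int = 20000
    microbe_genome_lengths: tuple[int, ...] = (8000, 8000)
    contaminant_genome_length: int = 4000
    features_per_type: int = 6
    reads_per_sample: int = 10000
    n_test: int = 5
    n_control: int = 5
    read_length_range: tuple[int, int] = (10, 44)
    error_rate: float = 0.0
    microbial_read_fraction: float = 0.15
    intronic_read_fraction: float = 0.03
    background_read_fraction: float = 0.05
    env_reads: int = 400
    env_planted_per_sample: int = 30
    de_signal_features: int = 4
    de_fold_change: float = 4.0

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid read length range")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.host_genome_length <= 0 or any(
            L <= 0 for L in self.microbe_genome_lengths
        ):
            raise ValueError("genome lengths must be positive")


@dataclass
class ToyReferences:
    genomes: dict[int, dict[str, str]]  # taxid -> {seqid: sequence}
    host_taxid: int
    annotation_sources: list[tuple[str, list[GenomicFeature]]]
    gene_spans: list[GenomicFeature]
    taxonomy: Taxonomy
    contaminant_taxid: int = CONTAMINANT_TAXID

    def host_genome(self) -> dict[str, str]:
        return self.genomes[self.host_taxid]


def _toy_taxonomy_nodes() -> list[TaxonomyNode]:
    N = TaxonomyNode
    return [
        N(1, 1, "no rank", "root"),
        N(2, 1, "superkingdom", "Bacteria"),
        N(2157, 1, "superkingdom", "Archaea"),
        N(2759, 1, "superkingdom", "Eukaryota"),
        N(10239, 1, "superkingdom", "Viruses"),
        N(28384, 1, "no rank", "other sequences"),
        N(4751, 2759, "kingdom", "Fungi"),
        N(9604, 2759, "family", "Hominidae"),
        N(9605, 9604, "genus", "Homo"),
        N(9606, 9605, "species", "Homo sapiens"),
        N(561, 2, "genus", "Escherichia"),
        N(562, 561, "species", "Escherichia coli"),
        N(1279, 2, "genus", "Staphylococcus"),
        N(1280, 1279, "species", "Staphylococcus aureus"),
        N(4930, 4751, "genus", "Saccharomyces"),
        N(4932, 4930, "species", "Saccharomyces cerevisiae"),
        N(32630, 28384, "species", "synthetic construct"),
    ]


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


_FEATURE_PLAN = [
    # (source_db, rna_type, typical feature length)
    ("toy_mirdb", "miRNA", 22),
    ("toy_trnadb", "tRNA", 72),
    ("toy_ensembl", "rRNA", 120),
    ("toy_ensembl", "snoRNA", 70),
    ("toy_ensembl", "lncRNA", 200),
    ("toy_ensembl", "YRNA", 100),
    ("toy_pirdb", "piRNA", 28),
]


def make_toy_references(config: SimulationConfig) -> ToyReferences:
    """Generate genomes, deliberately overlapping annotations and a taxonomy.

    Within-source overlaps: every third feature of a source gets a shifted
    twin.  Cross-source overlaps: each tRNA locus hosts a nested piRNA
    entry (small RNA databases frequently annotate tRNA fragments as
    piRNAs), and mRNA exons get an overlapping lncRNA.  mRNA genes carry
    two exons; the enclosing span (exons + intron) is emitted separately
    for intronic-read detection.
    """
    rng = random.Random(config.seed)
    host = _random_dna(rng, config.host_genome_length)
    genomes: dict[int, dict[str, str]] = {HOST_TAXID: {"hchr1": host}}
    for taxid, length in zip(MICROBE_TAXIDS, config.microbe_genome_lengths):
        genomes[taxid] = {f"m{taxid}c1": _random_dna(rng, length)}
    genomes[CONTAMINANT_TAXID] = {
        "envc1": _random_dna(rng, config.contaminant_genome_length)
    }

    sources: dict[str, list[GenomicFeature]] = {}
    cursor = 50
    counter = {"n": 0}

    def place(source: str, rna_type: str, length: int, start: int, strand: str) -> GenomicFeature:
        counter["n"] += 1
        f = GenomicFeature(
            seqid="hchr1",
            start=start,
            end=start + length - 1,
            strand=strand,
            source_db=source,
            rna_type=rna_type,
            name=f"{rna_type}_{counter['n']:03d}",
        )
        sources.setdefault(source, []).append(f)
        return f

    gene_spans: list[GenomicFeature] = []
    glen = config.host_genome_length
    plan = list(_FEATURE_PLAN) * 1
    per_type = config.features_per_type
    for source, rna_type, flen in plan:
        if rna_type == "piRNA":
            continue  # nested below
        for i in range(per_type):
            gap = rng.randint(30, 120)
            start = cursor + gap
            if start + flen + 10 >= glen:
                raise ValueError("toy genome too small for the feature plan")
            strand = rng.choice("+-")
            f = place(source, rna_type, flen, start, strand)
            cursor = f.end
            if i % 3 == 2:  # within-source overlapping twin
                twin_start = f.start + max(3, flen // 3)
                twin = place(source, rna_type, flen, twin_start, strand)
                cursor = max(cursor, twin.end)
            if rna_type == "tRNA":
                # cross-source overlap: piRNA nested inside the tRNA locus
                off = rng.randint(2, max(2, flen - 30))
                place("toy_pirdb", "piRNA", 26, f.start + off, strand)

    # mRNA genes: two exons with an intron; span kept for intronic calls
    for i in range(per_type):
        gap = rng.randint(60, 150)
        exon_len, intron_len = 90, 140
        start = cursor + gap
        if start + 2 * exon_len + intron_len + 10 >= glen:
            raise ValueError("toy genome too small for mRNA genes")
        strand = rng.choice("+-")
        e1 = place("toy_ensembl", "mRNA", exon_len, start, strand)
        e2 = place(
            "toy_ensembl", "mRNA", exon_len, start + exon_len + intron_len, strand
        )
        counter["n"] += 1
        gene_spans.append(
            GenomicFeature(
                seqid="hchr1",
                start=e1.start,
                end=e2.end,
                strand=strand,
                source_db="toy_ensembl",
                rna_type="gene_span",
                name=f"gene_{i + 1:02d}",
                attributes={"intron_start": e1.end + 1, "intron_end": e2.start - 1},
            )
        )
        if i % 2 == 0:  # cross-source overlap with lncRNA
            place("toy_lncdb", "lncRNA", 160, e1.start + 30, strand)
        cursor = e2.end

    ordered_sources = [(name, sources[name]) for name in sorted(sources)]
    return ToyReferences(
        genomes=genomes,
        host_taxid=HOST_TAXID,
        annotation_sources=ordered_sources,
        gene_spans=gene_spans,
        taxonomy=Taxonomy(_toy_taxonomy_nodes()),
    )


def _feature_sequence(f: GenomicFeature, genome: dict[str, str]) -> str:
    seq = genome[f.seqid][f.start - 1 : f.end]
    return reverse_complement(seq) if f.strand == "-" else seq


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in BASES if x != b])
    return "".join(out)


def simulate_reads(
    references: ToyReferences,
    config: SimulationConfig,
    de_features: dict[str, float] | None = None,
) -> dict[str, list[ReadRecord]]:
    """Per-sample read sets (test + control) with truth in the read ids.

    Host reads are drawn from annotated features (all sources pooled,
    weighted by feature length) with uniform lengths in the configured
    range, strand-aware; a configurable fraction comes instead from random
    windows of the microbial genomes.  ``de_features`` maps feature names
    to a sampling-weight multiplier applied in test samples only, planting
    true differential expression.  Read ids encode
    ``sample|serial|taxid|feature|type|seqid:pos:strand``.
    """
    sample_names = [f"test{i + 1}" for i in range(config.n_test)] + [
        f"control{i + 1}" for i in range(config.n_control)
    ]
    groups = {s: ("test" if s.startswith("test") else "control") for s in sample_names}
    host_genome = references.host_genome()
    features = [f for _, fs in references.annotation_sources for f in fs]
    lo, hi = config.read_length_range
    de_features = de_features or {}

    samples: dict[str, list[ReadRecord]] = {}
    for si, sample in enumerate(sample_names):
        rng = random.Random(_derive_seed(config.seed, "reads", sample))
        weights = []
        for f in features:
            w = float(f.length)
            if groups[sample] == "test" and f.name in de_features:
                w *= de_features[f.name]
            weights.append(w)
        cum = np.cumsum(weights)
        reads: list[ReadRecord] = []
        for i in range(config.reads_per_sample):
            length = rng.randint(lo, hi)
            draw = rng.random()
            mic = config.microbial_read_fraction
            intron = mic + config.intronic_read_fraction
            background = intron + config.background_read_fraction
            if draw < mic:
                taxid = MICROBE_TAXIDS[rng.randrange(len(MICROBE_TAXIDS))]
                seqid, genome_seq = next(iter(references.genomes[taxid].items()))
                length = min(length, len(genome_seq))
                pos = rng.randint(0, len(genome_seq) - length)
                strand = rng.choice("+-")
                seq = genome_seq[pos : pos + length]
                if strand == "-":
                    seq = reverse_complement(seq)
                truth = f"{taxid}|.|microbial|{seqid}:{pos + 1}:{strand}"
            elif draw < intron and references.gene_spans:
                span = references.gene_spans[rng.randrange(len(references.gene_spans))]
                istart = span.attributes["intron_start"]
                iend = span.attributes["intron_end"]
                length = min(length, iend - istart + 1)
                pos = rng.randint(istart, iend - length + 1)
                seq = host_genome[span.seqid][pos - 1 : pos + length - 1]
                strand = span.strand
                if strand == "-":
                    seq = reverse_complement(seq)
                truth = f"{references.host_taxid}|{span.name}|intronic|{span.seqid}:{pos}:{strand}"
            elif draw < background:
                seqid, genome_seq = next(iter(host_genome.items()))
                length = min(length, len(genome_seq))
                pos0 = rng.randint(0, len(genome_seq) - length)
                strand = rng.choice("+-")
                seq = genome_seq[pos0 : pos0 + length]
                if strand == "-":
                    seq = reverse_complement(seq)
                truth = f"{references.host_taxid}|.|background|{seqid}:{pos0 + 1}:{strand}"
            else:
                j = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                f = features[min(j, len(features) - 1)]
                fseq = _feature_sequence(f, host_genome)
                length = min(length, len(fseq))
                off = rng.randint(0, len(fseq) - length)
                seq = fseq[off : off + length]
                if f.strand == "-":
                    pos = f.end - off - length + 1
                else:
                    pos = f.start + off
                truth = (
                    f"{references.host_taxid}|{f.name}|{f.rna_type}"
                    f"|{f.seqid}:{pos}:{f.strand}"
                )
            seq = _mutate(seq, config.error_rate, rng)
            reads.append(
                ReadRecord(
                    read_id=f"{sample}.{i + 1:05d}|{truth}",
                    sequence=seq,
                    sample_id=sample,
                    group=groups[sample],
                )
            )
        samples[sample] = reads
    return samples


def read_truth(read_id: str) -> dict:
    """Decode the truth fields carried in a simulated read id."""
    serial, taxid, feature, rna_type, locus = read_id.split("|")
    seqid, pos, strand = locus.rsplit(":", 2)
    return {
        "serial": serial,
        "taxon_id": int(taxid),
        "feature": feature,
        "rna_type": rna_type,
        "seqid": seqid,
        "pos": int(pos),
        "strand": strand,
    }


def simulate_environment_sample(
    references: ToyReferences,
    config: SimulationConfig,
    samples: dict[str, list[ReadRecord]] | None = None,
) -> tuple[list[ReadRecord], set[str]]:
    """Environment (no-template control) library with planted contaminants.

    Contains reads from the designated contaminant genome plus, when
    sample reads are supplied, planted contaminant sequences: for each
    sample, ``env_planted_per_sample`` reads are chosen; half their
    sequences enter the environment verbatim and half as a ≥15-nt
    substring (so the sample read *contains* the environment sequence).
    Returns the environment reads and the ids of sample reads that a
    correct environment filter must remove.
    """
    rng = random.Random(_derive_seed(config.seed, "env"))
    envc = references.genomes[references.contaminant_taxid]["envc1"]
    lo, hi = config.read_length_range
    env_reads: list[ReadRecord] = []
    for i in range(config.env_reads):
        length = rng.randint(max(lo, 15), hi)
        pos = rng.randint(0, len(envc) - length)
        env_reads.append(
            ReadRecord(
                read_id=f"env.{i + 1:05d}|{references.contaminant_taxid}|.|env|envc1:{pos + 1}:+",
                sequence=envc[pos : pos + length],
                sample_id="environment1",
                group="environment",
            )
        )
    planted: set[str] = set()
    if samples:
        for sample in sorted(samples):
            eligible = [r for r in samples[sample] if len(r.sequence) >= 16]
            picked = rng.sample(eligible, min(config.env_planted_per_sample, len(eligible)))
            for k, r in enumerate(picked):
                if k % 2 == 0:
                    seq = r.sequence
                else:  # substring of the sample read, >= 15 nt
                    sub_len = rng.randint(15, len(r.sequence) - 1)
                    off = rng.randint(0, len(r.sequence) - sub_len)
                    seq = r.sequence[off : off + sub_len]
                env_reads.append(
                    ReadRecord(
                        read_id=f"env.planted.{sample}.{k + 1:04d}",
                        sequence=seq,
                        sample_id="environment1",
                        group="environment",
                    )
                )
        # every sample read containing any planted environment sequence is a
        # true contaminant; record them via exact containment truth
        env_seqs = {r.sequence for r in env_reads if len(r.sequence) >= 15}
        for sample in sorted(samples):
            for r in samples[sample]:
                s = r.sequence
                if any(e in s for e in env_seqs if len(e) <= len(s)):
                    planted.add(r.read_id)
    return env_reads, planted


# ---------------------------------------------------------------------------
# Naive aligner oracle (stands in for BLAST / short-read mapping in tests)
# ---------------------------------------------------------------------------

def _find_all(text: str, pattern: str) -> list[int]:
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _mismatch_scan(text: np.ndarray, pattern: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(pos0, n_mismatches) for every window with ≤ max_mm substitutions."""
    L = len(pattern)
    if L > len(text):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(text, L)
    mm = (windows != pattern).sum(axis=1)
    return [(int(i), int(m)) for i, m in enumerate(mm) if m <= max_mm]


def naive_align(
    reads: list[ReadRecord],
    references: dict[str, str],
    max_mismatches: int = 0,
    taxids: dict[str, int] | None = None,
) -> tuple[dict[str, list[Placement]], list[BlastHit]]:
    """Complete substitution-only alignment of reads against small references.

    Reports every placement with at most ``max_mismatches`` substitutions
    on either strand (no indels).  The hit table mirrors BLAST tabular
    output with a documented bitscore proxy, ``2·matches − 3·mismatches``,
    monotone in the number of matches; it is NOT a BLAST statistic.  With
    ``taxids`` mapping reference seqids to taxa, hits carry those taxa.
    Exhaustive by construction, hence usable as the alignment oracle for
    references of a few megabases.
    """
    placements: dict[str, list[Placement]] = {}
    hits: list[BlastHit] = []
    encoded: dict[str, np.ndarray] = {}
    if max_mismatches > 0:
        for seqid, seq in references.items():
            encoded[seqid] = np.frombuffer(seq.encode(), dtype=np.uint8)

    for r in reads:
        found: list[tuple[str, int, str, int]] = []  # seqid, pos0, strand, mm
        for strand in ("+", "-"):
            query = r.sequence if strand == "+" else reverse_complement(r.sequence)
            for seqid in sorted(references):
                if max_mismatches == 0:
                    for pos in _find_all(references[seqid], query):
                        found.append((seqid, pos, strand, 0))
                else:
                    q = np.frombuffer(query.encode(), dtype=np.uint8)
                    for pos, mm in _mismatch_scan(encoded[seqid], q, max_mismatches):
                        found.append((seqid, pos, strand, mm))
        if not found:
            continue
        L = len(r.sequence)
        plist = []
        for seqid, pos, strand, mm in sorted(found):
            score = float(2 * (L - mm) - 3 * mm)
            plist.append(
                Placement(
                    read_id=r.read_id,
                    seqid=seqid,
                    pos=pos + 1,
                    strand=strand,
                    length=L,
                    score=score,
                )
            )
            taxid = (taxids or {}).get(seqid)
            if taxid is not None:
                hits.append(
                    BlastHit(
                        query_id=r.read_id,
                        subject_id=seqid,
                        taxon_id=taxid,
                        percent_identity=100.0 * (L - mm) / L,
                        aln_length=L,
                        bitscore=score,
                        evalue=0.0,
                    )
                )
        placements[r.read_id] = plist
    return placements, hits


def metagenome_references(
    references: ToyReferences, species: list[int] | None = None
) -> tuple[dict[str, str], dict[str, int]]:
    """Combined reference dict with metagenome-style ids 'taxid|name|contig'."""
    species = species if species is not None else sorted(references.genomes)
    combined: dict[str, str] = {}
    taxids: dict[str, int] = {}
    for taxid in species:
        if taxid not in references.genomes:
            continue
        name = (
            references.taxonomy.name(taxid).replace(" ", "_")
            if taxid in references.taxonomy
            else f"taxon{taxid}"
        )
        for contig, seq in references.genomes[taxid].items():
            seqid = f"{taxid}|{name}|{contig}"
            combined[seqid] = seq
            taxids[seqid] = taxid
    return combined, taxids
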