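"""Build a unified, priority-ordered annotation catalogue from heterogeneous sources.

Two distinct overlap problems are handled differently:

* overlaps *within* one source database are physically merged into union
  features (names fused, coverage conserved);
* overlaps *between* sources are kept and resolved per read at counting
  time by an ordered RNA-type priority schema (miRNA outranks tRNA, which
  outranks rRNA, and so on).

Merging is strand-aware: features on opposite strands never merge, because
small-RNA identity is strand-specific.  Overlap means at least one shared
base in 1-based inclusive coordinates; book-ended features do not merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GenomicFeature

DEFAULT_PRIORITY = [
    "miRNA",
    "tRNA",
    "rRNA",
    "mRNA",
    "processed_pseudogene",
    "snRNA",
    "snoRNA",
    "mtRNA",
    "piRNA",
    "lncRNA",
    "vaultRNA",
    "YRNA",
    "other_RNA",
    "repeat_tRNA",
    "repeat_rRNA",
    "repeat_other",
]

# common source-database biotype spellings → schema class
DEFAULT_TYPE_ALIASES = {
    "mirna": "miRNA",
    "pre_mirna": "miRNA",
    "mirna_hairpin": "miRNA",
    "trna": "tRNA",
    "trf": "tRNA",
    "rrna": "rRNA",
    "mrna": "mRNA",
    "protein_coding": "mRNA",
    "exon": "mRNA",
    "processed_pseudogene": "processed_pseudogene",
    "snrna": "snRNA",
    "snorna": "snoRNA",
    "mtrna": "mtRNA",
    "mt": "mtRNA",
    "mt_trna": "mtRNA",
    "mt_rrna": "mtRNA",
    "pirna": "piRNA",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "vaultrna": "vaultRNA",
    "vault_rna": "vaultRNA",
    "yrna": "YRNA",
    "y_rna": "YRNA",
    "misc_rna": "other_RNA",
    "repeat_trna": "repeat_tRNA",
    "repeat_rrna": "repeat_rRNA",
    "repeat": "repeat_other",
    "repeat_other": "repeat_other",
}


@dataclass
class PrioritySchema:
    """Ordered RNA-type classes, highest priority first."""

    ordered_types: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TYPE_ALIASES))
    fallback: str = "other_RNA"

    def __post_init__(self) -> None:
        if not self.ordered_types:
            raise ValueError("priority schema must not be empty")
        if len(set(self.ordered_types)) != len(self.ordered_types):
            raise ValueError("priority labels must be unique")
        self._rank = {label: i for i, label in enumerate(self.ordered_types)}

    def classify(self, rna_type: str) -> str:
        """Map a raw rna_type label to its priority class (fallback other_RNA)."""
        if rna_type in self._rank:
            return rna_type
        key = rna_type.strip().lower().replace(" ", "_").replace("-", "_")
        label = self.aliases.get(key)
        if label is not None and label in self._rank:
            return label
        return self.fallback

    def priority(self, rna_type: str) -> int:
        """Smaller is better; unknown types rank as the fallback class."""
        return self._rank[self.classify(rna_type)]


@dataclass
class MergeReport:
    """Per-source summary of within-source overlap merging."""

    source_db: str
    features_in: int
    features_merged: int

    @property
    def percent_merged(self) -> int:
        if self.features_in == 0:
            return 0
        return round(100 * self.features_merged / self.features_in)


@dataclass
class HarmonizedCatalogue:
    """All sources merged within themselves, tagged with priority classes.

    Cross-source overlaps are intentionally retained; they are resolved per
    read at counting time via the schema.
    """

    features: list[GenomicFeature]
    schema: PrioritySchema
    reports: list[MergeReport]
    unmapped_types: dict[str, int] = field(default_factory=dict)


MEMBERS_KEY = "members"


def merge_overlapping_features(
    features: list[GenomicFeature],
) -> tuple[list[GenomicFeature], MergeReport]:
    """Merge overlapping features from ONE source into union features.

    Within each (seqid, strand) group, transitively overlapping features
    (≥1 shared base) collapse into a single feature spanning min start to
    max end.  The union feature's name joins member names with ``|`` in
    coordinate order and keeps the member list under the ``members``
    attribute.  Every member of a ≥2-member union counts as merged.
    """
    if not features:
        return [], MergeReport("", 0, 0)
    source_dbs = {f.source_db for f in features}
    if len(source_dbs) > 1:
        raise ValueError(f"features from multiple sources: {sorted(source_dbs)}")
    source_db = next(iter(source_dbs))

    ordered = sorted(
        range(len(features)),
        key=lambda i: (
            features[i].seqid,
            features[i].strand,
            features[i].start,
            features[i].end,
            features[i].name,
        ),
    )
    merged: list[GenomicFeature] = []
    n_merged = 0
    cluster: list[GenomicFeature] = []

    def flush() -> None:
        nonlocal n_merged
        if not cluster:
            return
        if len(cluster) == 1:
            merged.append(cluster[0])
            return
        n_merged += len(cluster)
        members = sorted(cluster, key=lambda f: (f.start, f.end, f.name))
        names = [m.name for m in members]
        first = members[0]
        attrs = {MEMBERS_KEY: names}
        merged.append(
            GenomicFeature(
                seqid=first.seqid,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                strand=first.strand,
                source_db=source_db,
                rna_type=first.rna_type,
                name="|".join(names),
                attributes=attrs,
            )
        )

    prev_key: tuple | None = None
    cluster_end = -1
    for i in ordered:
        f = features[i]
        key = (f.seqid, f.strand)
        if key != prev_key or f.start > cluster_end:
            flush()
            cluster = [f]
            cluster_end = f.end
            prev_key = key
        else:
            cluster.append(f)
            cluster_end = max(cluster_end, f.end)
    flush()

    return merged, MergeReport(source_db, len(features), n_merged)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence starts."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def place_fasta_on_genome(
    sequences: list[tuple[str, str]],
    genome: dict[str, str],
    max_hits: int = 100,
    source_db: str = "placed",
    rna_type: str = "other_RNA",
) -> tuple[list[GenomicFeature], list[str]]:
    """Place sequences on a genome by exact, full-length, ungapped matching.

    Every exact occurrence on either strand yields one feature
    (reverse-complement occurrences get strand '-').  Sequences with zero
    occurrences are returned in the skipped list; sequences with more
    occurrences than ``max_hits`` keep the first ``max_hits`` placements in
    genome order and are flagged via the ``truncated`` attribute.
    """
    features: list[GenomicFeature] = []
    skipped: list[str] = []
    contigs = sorted(genome)
    for name, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
        query = seq.upper().replace("U", "T")
        rc = reverse_complement(query)
        placements: list[tuple[str, int, str]] = []
        for contig in contigs:
            text = genome[contig]
            for pos in _find_all(text, query):
                placements.append((contig, pos, "+"))
            for pos in _find_all(text, rc):
                placements.append((contig, pos, "-"))
        if not placements:
            skipped.append(name)
            continue
        placements.sort(key=lambda p: (p[0], p[1], p[2]))
        truncated = len(placements) > max_hits
        for contig, pos, strand in placements[:max_hits]:
            attrs: dict = {"placed_from": name}
            if truncated:
                attrs["truncated"] = True
            features.append(
                GenomicFeature(
                    seqid=contig,
                    start=pos + 1,
                    end=pos + len(query),
                    strand=strand,
                    source_db=source_db,
                    rna_type=rna_type,
                    name=name,
                    attributes=attrs,
                )
            )
    return features, skipped


def derive_trf_annotation(
    trna_features: list[GenomicFeature],
) -> list[GenomicFeature]:
    """Split each tRNA locus into 5' and 3' fragment sub-features (tRFs).

    The locus is halved at floor(length/2) in transcript orientation: the
    5' fragment takes the first floor(length/2) bases from the 5' end, the
    3' fragment the remainder.  On the minus strand the 5' fragment
    therefore occupies the higher-coordinate half.  Loci shorter than 2 nt
    are skipped.
    """
    out: list[GenomicFeature] = []
    for f in trna_features:
        length = f.end - f.start + 1
        if length < 2:
            continue
        half = length // 2
        if f.strand == "-":
            five = (f.end - half + 1, f.end)
            three = (f.start, f.end - half)
        else:
            five = (f.start, f.start + half - 1)
            three = (f.start + half, f.end)
        for (start, end), suffix in ((five, "-5p"), (three, "-3p")):
            out.append(
                GenomicFeature(
                    seqid=f.seqid,
                    start=start,
                    end=end,
                    strand=f.strand,
                    source_db=f.source_db,
                    rna_type=f.rna_type,
                    name=f.name + suffix,
                    attributes={"parent": f.name},
                )
            )
    return out


def build_catalogue(
    sources: list[tuple[str, list[GenomicFeature]]],
    schema: PrioritySchema | None = None,
) -> HarmonizedCatalogue:
    """Merge each source internally, classify types, keep cross-source overlaps."""
    schema = schema or PrioritySchema()
    all_features: list[GenomicFeature] = []
    reports: list[MergeReport] = []
    unmapped: dict[str, int] = {}
    for source_db, features in sources:
        tagged = []
        for f in features:
            if f.source_db != source_db:
                f = GenomicFeature(
                    f.seqid, f.start, f.end, f.strand,
                    source_db, f.rna_type, f.name, dict(f.attributes),
                )
            tagged.append(f)
        merged, report = merge_overlapping_features(tagged) if tagged else ([], MergeReport(source_db, 0, 0))
        if report.source_db == "":
            report = MergeReport(source_db, 0, 0)
        for f in merged:
            klass = schema.classify(f.rna_type)
            if klass == schema.fallback and f.rna_type not in schema._rank:
                key = f.rna_type.strip().lower().replace(" ", "_").replace("-", "_")
                if schema.aliases.get(key) is None:
                    unmapped[f.rna_type] = unmapped.get(f.rna_type, 0) + 1
            f.attributes["priority_class"] = klass
        all_features.extend(merged)
        reports.append(report)
    return HarmonizedCatalogue(all_features, schema, reports, unmapped)


def merge_report_table(reports: list[MergeReport]) -> list[dict]:
    """Rows mirroring the published per-database merge summary."""
    return [
        {
            "Database": r.source_db,
            "Features": r.features_in,
            "Merged": r.features_merged,
            "%Merged": r.percent_merged,
        }
        for r in reports
    ]
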