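"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates in the public data model are 1-based inclusive,
matching GTF/SAM conventions; any half-open arithmetic is internal.
Sequence records are normalised on input: bases uppercased and RNA ``U``
converted to ``T`` so that RNA-space databases (e.g. mature miRNA FASTA)
can be matched exactly against DNA genomes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

VALID_GROUPS = frozenset({"test", "control", "environment", "ignore"})

_RNA_TO_DNA = str.maketrans("acgtunU", "ACGTTNT")


class ParseError(ValueError):
    """Malformed record in an input file (carries file context in message)."""


@dataclass
class ReadRecord:
    """One small-RNA read with its sample of origin and group label."""

    read_id: str
    sequence: str
    quality: str | None = None
    sample_id: str = ""
    group: str = "test"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for read {self.read_id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"group {self.group!r} not in {sorted(VALID_GROUPS)}"
            )


@dataclass
class GenomicFeature:
    """One annotated interval (1-based inclusive) with source database and RNA type."""

    seqid: str
    start: int
    end: int
    strand: str
    source_db: str
    rna_type: str
    name: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"non-positive coordinates for {self.name!r}")
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} for {self.name!r}"
            )
        if not self.rna_type:
            raise ValueError(f"empty rna_type for {self.name!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.name!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicFeature") -> bool:
        """≥1 shared base, same seqid; strand is NOT checked here."""
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class BlastHit:
    """One query→subject alignment record with taxid and bitscore."""

    query_id: str
    subject_id: str
    taxon_id: int
    percent_identity: float
    aln_length: int
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("negative bitscore")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.taxon_id <= 0:
            raise ValueError("taxon_id must be positive")


@dataclass
class TaxonomyNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, gzipped: bool | None = None):
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, "rt")
    return open(path, "rt")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.translate(_RNA_TO_DNA).upper()


def read_sequences(
    path: str | Path,
    format: str | None = None,
    gzipped: bool | None = None,
    sample_id: str = "",
    group: str = "test",
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) FASTA or FASTQ file.

    ``format`` is inferred from the filename when omitted.  Sequences are
    normalised (uppercase, U→T).  A FASTQ record whose quality string does
    not match its sequence length raises :class:`ParseError`.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        if stem.endswith((".fq", ".fastq")):
            format = "fastq"
        elif stem.endswith((".fa", ".fasta", ".fna")):
            format = "fasta"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")

    with _open_text(path, gzipped) as handle:
        try:
            for rec in SeqIO.parse(handle, format):
                qual = None
                if format == "fastq":
                    phred = rec.letter_annotations.get("phred_quality")
                    if phred is not None:
                        qual = "".join(chr(q + 33) for q in phred)
                yield ReadRecord(
                    read_id=rec.id,
                    sequence=normalize_sequence(str(rec.seq)),
                    quality=qual,
                    sample_id=sample_id,
                    group=group,
                )
        except ValueError as exc:  # biopython parse failures
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[ReadRecord | tuple], path: str | Path) -> None:
    """Write records (ReadRecord or (name, sequence) pairs) as FASTA."""
    with open(path, "wt") as out:
        for rec in records:
            if isinstance(rec, ReadRecord):
                out.write(f">{rec.read_id}\n{rec.sequence}\n")
            else:
                name, seq = rec
                out.write(f">{name}\n{seq}\n")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "wt") as out:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as {seqid: uppercase DNA string}."""
    with _open_text(path) as handle:
        return {
            rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        }


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict:
    attrs: dict = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(text: str) -> dict:
    attrs: dict = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gtf(path: str | Path, source_db: str | None = None) -> list[GenomicFeature]:
    """Parse a GTF2.2 (or GFF3) file into GenomicFeatures.

    GFF3 ``ID``/``Name`` attributes are lifted into the attribute mapping;
    the feature name comes from ``gene_name``/``gene_id`` (GTF) or
    ``Name``/``ID`` (GFF3), falling back to ``<seqid>:<start>-<end>``.
    The feature-type column 3 becomes ``rna_type`` unless a ``gene_biotype``
    / ``biotype`` attribute overrides it.
    """
    path = Path(path)
    features: list[GenomicFeature] = []
    gff3 = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##gff-version 3"):
                    gff3 = True
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = (
                _parse_gff3_attributes(attr_s)
                if (gff3 or "=" in attr_s.split(";")[0] and '"' not in attr_s)
                else _parse_gtf_attributes(attr_s)
            )
            name = (
                attrs.get("gene_name")
                or attrs.get("Name")
                or attrs.get("gene_id")
                or attrs.get("ID")
                or f"{seqid}:{start}-{end}"
            )
            rna_type = attrs.get("gene_biotype") or attrs.get("biotype") or ftype
            features.append(
                GenomicFeature(
                    seqid=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else ".",
                    source_db=source_db or source,
                    rna_type=rna_type,
                    name=name,
                    attributes=attrs,
                )
            )
    return features


def write_gtf(features: Sequence[GenomicFeature], path: str | Path) -> None:
    """Write features as GTF; round-trips the canonical field subset."""
    with open(path, "wt") as out:
        for f in features:
            attrs = {
                "gene_id": f.name,
                "gene_name": f.name,
                "gene_biotype": f.rna_type,
            }
            for key, value in f.attributes.items():
                if key in attrs:
                    continue
                if isinstance(value, (list, tuple)):
                    value = "|".join(map(str, value))
                attrs[key] = value
            attr_s = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            out.write(
                f"{f.seqid}\t{f.source_db}\t{f.rna_type}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

DEFAULT_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore staxids"
).split()


def read_blast_tab(
    path: str | Path,
    column_spec: Sequence[str] = DEFAULT_BLAST_COLUMNS,
) -> list[BlastHit]:
    """Parse BLAST outfmt-6-style tabular output.

    ``column_spec`` names the columns; it must include ``qseqid``,
    ``bitscore`` and ``staxids``.  A multi-valued ``staxids`` cell
    ("123;456") expands into one hit per taxid, sharing the other fields.
    """
    spec = list(column_spec)
    for required in ("qseqid", "bitscore", "staxids"):
        if required not in spec:
            raise ValueError(f"column_spec lacks required column {required!r}")
    idx = {name: i for i, name in enumerate(spec)}
    hits: list[BlastHit] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < len(spec):
                raise ParseError(f"{path}:{lineno}: expected {len(spec)} columns")

            def get(name: str, default: str = "0") -> str:
                return cols[idx[name]] if name in idx else default

            for taxid_s in get("staxids").split(";"):
                taxid_s = taxid_s.strip()
                if not taxid_s or taxid_s == "N/A":
                    continue
                hits.append(
                    BlastHit(
                        query_id=get("qseqid"),
                        subject_id=get("sseqid", ""),
                        taxon_id=int(taxid_s),
                        percent_identity=float(get("pident", "100")),
                        aln_length=int(get("length", "0")),
                        bitscore=float(get("bitscore")),
                        evalue=float(get("evalue", "0")),
                    )
                )
    return hits


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path) -> None:
    """Write hits in the default outfmt-6+staxids dialect (query coords omitted)."""
    with open(path, "wt") as out:
        for h in hits:
            out.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.evalue:g}\t{h.bitscore:g}\t{h.taxon_id}\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam_alignments(
    path: str | Path,
) -> tuple[dict[str, list[tuple[str, int, str]]], list[str]]:
    """Group all placements of each read from a SAM file.

    Returns ``(placements, unmapped)`` where ``placements`` maps read id to
    a list of ``(seqid, pos_1based, strand)`` covering primary and secondary
    records, and ``unmapped`` lists ids of reads whose records are all
    unmapped.
    """
    placements: dict[str, list[tuple[str, int, str]]] = {}
    unmapped: list[str] = []
    seen_unmapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                if aln.query_name not in seen_unmapped:
                    seen_unmapped.add(aln.query_name)
                    unmapped.append(aln.query_name)
                continue
            strand = "-" if aln.is_reverse else "+"
            placements.setdefault(aln.query_name, []).append(
                (aln.reference_name, aln.reference_start + 1, strand)
            )
    # a read with any mapped record is not unmapped
    unmapped = [r for r in unmapped if r not in placements]
    return placements, unmapped


# ---------------------------------------------------------------------------
# Taxonomy table (reduced two-column-file free dialect: single TSV)
# ---------------------------------------------------------------------------

def read_taxonomy_table(path: str | Path) -> list[TaxonomyNode]:
    """Read a taxonomy TSV with columns taxon_id, parent_id, rank, name.

    A header line is permitted and detected by a non-integer first field.
    """
    nodes: list[TaxonomyNode] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                taxid = int(cols[0])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-integer taxon_id")
            nodes.append(TaxonomyNode(taxid, int(cols[1]), cols[2], cols[3]))
    return nodes


def write_taxonomy_table(nodes: Sequence[TaxonomyNode], path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("taxon_id\tparent_id\trank\tname\n")
        for n in nodes:
            out.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")
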