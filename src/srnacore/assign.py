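"""Two-pass species identification from BLAST-style hits.

A representative random subset of reads is searched against a sequence
database; species are ranked in a first pass by their *frequency of
presence* — the number of reads for which the species appears among the
near-best hits — and in a second pass each read is assigned to the
qualifying species with the best first-pass rank.  "Near-best" is
formalised as bitscore within an additive tolerance (default 2 bits) of
the read's best bitscore.  Species whose assigned-read fraction exceeds a
threshold (default 1%, strict) are selected for metagenome construction.

All ties break by ascending taxid so outputs are reproducible and
invariant under permutation of the hit records.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .io import BlastHit, ReadRecord
from .taxonomy import TaxonGroupSet, Taxonomy

DEFAULT_SUBSET_SIZE = 200
DEFAULT_TOLERANCE = 2.0
DEFAULT_METAGENOME_THRESHOLD = 0.01


@dataclass
class SpeciesAssignment:
    read_id: str
    taxon_id: int | None  # None = unassigned
    bitscore: float
    n_candidates: int


def subsample_reads(
    reads: Sequence[ReadRecord], n: int = DEFAULT_SUBSET_SIZE, seed: int = 0
) -> list[ReadRecord]:
    """Uniform sample without replacement, reproducible under seed.

    Returns all reads when there are no more than ``n``.
    """
    if n < 1:
        raise ValueError("subset size must be >= 1")
    if len(reads) <= n:
        return list(reads)
    rng = random.Random(seed)
    idx = rng.sample(range(len(reads)), n)
    return [reads[i] for i in sorted(idx)]


def group_hits_by_read(hits: Iterable[BlastHit]) -> dict[str, list[BlastHit]]:
    by_read: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h)
    return by_read


def filter_hits_by_taxa(
    hits: Iterable[BlastHit],
    groups: TaxonGroupSet,
    taxonomy: Taxonomy,
) -> tuple[list[tuple[BlastHit, str]], int]:
    """Tag each hit with the first group containing its taxid.

    Hits whose taxid is absent from the taxonomy or outside every group
    subtree are dropped; the count of dropped hits is returned.
    """
    tagged: list[tuple[BlastHit, str]] = []
    dropped = 0
    for h in hits:
        group = groups.group_of(h.taxon_id, taxonomy)
        if group is None:
            dropped += 1
            continue
        tagged.append((h, group))
    return tagged, dropped


def _species_taxid(taxid: int, taxonomy: Taxonomy | None) -> int:
    if taxonomy is None or taxid not in taxonomy:
        return taxid
    species, _ = taxonomy.species_of(taxid)
    return species


def _qualifying_species(
    read_hits: Sequence[BlastHit], tolerance: float, taxonomy: Taxonomy | None
) -> tuple[set[int], float]:
    """Species within tolerance of the read's best bitscore, plus that best score."""
    best = max(h.bitscore for h in read_hits)
    species = {
        _species_taxid(h.taxon_id, taxonomy)
        for h in read_hits
        if h.bitscore >= best - tolerance
    }
    return species, best


def first_pass_rank(
    hits_by_read: dict[str, Sequence[BlastHit]],
    tolerance: float = DEFAULT_TOLERANCE,
    taxonomy: Taxonomy | None = None,
) -> list[dict]:
    """Rank species by the number of reads in which they qualify.

    A species qualifies in a read when one of its hits scores within
    ``tolerance`` bits of the read's best hit.  Rows are sorted by
    ``n_reads_present`` descending, ties by ascending taxid; rank 1 is the
    most frequent.  Hit taxids are lifted to species level when a taxonomy
    is supplied.
    """
    presence: dict[int, int] = {}
    for read_id in sorted(hits_by_read):
        read_hits = hits_by_read[read_id]
        if not read_hits:
            continue
        species, _ = _qualifying_species(read_hits, tolerance, taxonomy)
        for s in species:
            presence[s] = presence.get(s, 0) + 1
    ordered = sorted(presence.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {
            "taxon_id": taxid,
            "name": taxonomy.name(taxid) if taxonomy and taxid in taxonomy else str(taxid),
            "n_reads_present": n,
            "rank": i + 1,
        }
        for i, (taxid, n) in enumerate(ordered)
    ]


def second_pass_assign(
    hits_by_read: dict[str, Sequence[BlastHit]],
    rank_table: Sequence[dict],
    tolerance: float = DEFAULT_TOLERANCE,
    taxonomy: Taxonomy | None = None,
) -> list[SpeciesAssignment]:
    """Assign each read to the best-ranked species among its near-best hits.

    Candidates are the species scoring within ``tolerance`` of the read's
    best bitscore; the one with the best (smallest) first-pass rank wins,
    ties by ascending taxid.  Species missing from the rank table count as
    worst rank.  Reads with no hits are unassigned.  Output order follows
    sorted read ids and is independent of hit input order.
    """
    rank_of = {row["taxon_id"]: row["rank"] for row in rank_table}
    worst = len(rank_of) + 1
    out: list[SpeciesAssignment] = []
    for read_id in sorted(hits_by_read):
        read_hits = hits_by_read[read_id]
        if not read_hits:
            out.append(SpeciesAssignment(read_id, None, 0.0, 0))
            continue
        candidates, best = _qualifying_species(read_hits, tolerance, taxonomy)
        winner = min(candidates, key=lambda s: (rank_of.get(s, worst), s))
        win_score = max(
            h.bitscore
            for h in read_hits
            if _species_taxid(h.taxon_id, taxonomy) == winner
        )
        out.append(SpeciesAssignment(read_id, winner, win_score, len(candidates)))
    return out


def select_metagenome_species(
    assignments: Sequence[SpeciesAssignment],
    threshold_fraction: float = DEFAULT_METAGENOME_THRESHOLD,
) -> list[tuple[int, float]]:
    """Species whose assigned-read fraction strictly exceeds the threshold.

    Fractions are over assigned reads.  Returns (taxid, fraction) sorted by
    fraction descending, ties by ascending taxid.
    """
    counts: dict[int, int] = {}
    total = 0
    for a in assignments:
        if a.taxon_id is None:
            continue
        total += 1
        counts[a.taxon_id] = counts.get(a.taxon_id, 0) + 1
    if total == 0:
        return []
    rows = [
        (taxid, n / total)
        for taxid, n in counts.items()
        if n / total > threshold_fraction
    ]
    rows.sort(key=lambda kv: (-kv[1], kv[0]))
    return rows


def build_metagenome(
    species: Sequence[int],
    genome_files: dict[int, str | Path],
    out_fasta: str | Path,
    taxonomy: Taxonomy | None = None,
    host_taxid: int = 9606,
) -> list[dict]:
    """Concatenate per-species genome FASTAs into one metagenome FASTA.

    Record ids are rewritten to ``taxid|species_name|original_id`` so that
    collisions across source files cannot occur and every contig is
    traceable to its species.  The host genome is written first when
    selected.  Returns the manifest: one row per requested species with
    its source file, record count and status (ok / missing).
    """
    ordered = sorted(species, key=lambda t: (t != host_taxid, t))
    manifest: list[dict] = []
    with open(out_fasta, "wt") as out:
        for taxid in ordered:
            name = (
                taxonomy.name(taxid).replace(" ", "_")
                if taxonomy and taxid in taxonomy
                else f"taxon{taxid}"
            )
            path = genome_files.get(taxid)
            if path is None or not Path(path).exists():
                manifest.append(
                    {"taxon_id": taxid, "name": name, "source": str(path or ""),
                     "n_records": 0, "status": "missing"}
                )
                continue
            n = 0
            for rec in SeqIO.parse(str(path), "fasta"):
                out.write(f">{taxid}|{name}|{rec.id}\n{str(rec.seq).upper()}\n")
                n += 1
            manifest.append(
                {"taxon_id": taxid, "name": name, "source": str(path),
                 "n_records": n, "status": "ok"}
            )
    return manifest


def krona_text_export(
    assignments: Sequence[SpeciesAssignment],
    taxonomy: Taxonomy,
) -> str:
    """Krona-importable text: per species one line 'count<TAB>lineage…'.

    Lineage runs root→species by taxon names; line order follows ascending
    taxid; counts sum to the number of assigned reads.
    """
    counts: dict[int, int] = {}
    for a in assignments:
        if a.taxon_id is None:
            continue
        counts[a.taxon_id] = counts.get(a.taxon_id, 0) + 1
    lines = []
    for taxid in sorted(counts):
        if taxid in taxonomy:
            lineage = [taxonomy.name(t) for t in taxonomy.lineage(taxid)]
        else:
            lineage = [str(taxid)]
        lines.append("\t".join([str(counts[taxid])] + lineage))
    return "\n".join(lines) + ("\n" if lines else "")
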