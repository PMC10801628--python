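"""Alignment-free differential expression over exact unique read sequences.

Instead of mapping reads to a reference, the distinct read sequences
themselves are the expression features: a matrix of sequence × sample
occurrence counts is built, reduced by a keep-hits predicate, tested for
differential expression with a negative-binomial count model
(median-of-ratios normalisation, Wald test, Benjamini–Hochberg
adjustment), capped at 1000 upregulated and 1000 downregulated
sequences, greedily clustered at an identity threshold, and summarised by
per-cluster consensus sequences with a provisional source label from
BLAST-style hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import BlastHit, ReadRecord
from .taxonomy import TaxonGroupSet, Taxonomy

DEFAULT_KEEP_COUNT = 2
DEFAULT_KEEP_SAMPLES = 2
DEFAULT_CAP = 1000
DEFAULT_IDENTITY = 0.8


def collapse_sequences(
    samples: dict[str, Iterable[ReadRecord | str]]
) -> pd.DataFrame:
    """Unique-sequence × sample occurrence-count matrix.

    Cell (s, j) is the number of reads in sample j whose sequence is
    exactly s; column sums equal per-sample read counts.
    """
    columns: dict[str, dict[str, int]] = {}
    for sample_id, reads in samples.items():
        col: dict[str, int] = {}
        for r in reads:
            seq = r.sequence if isinstance(r, ReadRecord) else r
            col[seq] = col.get(seq, 0) + 1
        columns[sample_id] = col
    all_seqs = sorted({s for col in columns.values() for s in col})
    data = {
        sample_id: [col.get(s, 0) for s in all_seqs]
        for sample_id, col in columns.items()
    }
    return pd.DataFrame(data, index=all_seqs, dtype=int)


def filter_keep_hits(
    matrix: pd.DataFrame,
    min_count: int = DEFAULT_KEEP_COUNT,
    min_samples: int = DEFAULT_KEEP_SAMPLES,
) -> pd.DataFrame:
    """Keep rows counted ≥ min_count in ≥ min_samples samples."""
    mask = (matrix >= min_count).sum(axis=1) >= min_samples
    out = matrix.loc[mask]
    if out.empty and not matrix.empty:
        warnings.warn("keep-hits filter removed every sequence", stacklevel=2)
    return out


def differential_expression(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial test of test-vs-control per row.

    Delegates the count model to pydeseq2 (median-of-ratios size factors,
    per-row NB dispersion, Wald test, BH adjustment) with a fixed
    ``~condition`` design; the fit path contains no randomisation, so the
    result is deterministic given the matrix.  Works identically for
    feature-count and sequence-count matrices.

    Returns a frame indexed like ``matrix`` with columns baseMean,
    log2FoldChange (test vs control), pvalue, padj and significant.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    labels = {s: groups[s] for s in matrix.columns}
    for lab in ("test", "control"):
        n = sum(1 for v in labels.values() if v == lab)
        if n == 0:
            raise ValueError(f"group {lab!r} has no samples")
        if n < 2:
            raise ValueError(f"group {lab!r} needs >= 2 samples, has {n}")
    if matrix.empty:
        return pd.DataFrame(
            columns=["baseMean", "log2FoldChange", "pvalue", "padj", "significant"]
        )

    counts = matrix.T.astype(int)
    counts.index = counts.index.astype(str)
    metadata = pd.DataFrame(
        {"condition": [labels[s] for s in matrix.columns]},
        index=counts.index,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=counts, metadata=metadata, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "test", "control"], quiet=True
        )
        stats.summary()
    res = stats.results_df.copy()
    res.index = matrix.index
    res = res[["baseMean", "log2FoldChange", "pvalue", "padj"]]
    res["significant"] = (
        res["padj"].notna()
        & (res["padj"] < padj_threshold)
        & (res["log2FoldChange"].abs() >= lfc_threshold)
    )
    return res


def select_top_sequences(
    de_table: pd.DataFrame,
    cap_up: int = DEFAULT_CAP,
    cap_down: int = DEFAULT_CAP,
) -> pd.DataFrame:
    """Cap significant rows at ``cap_up`` upregulated and ``cap_down`` down.

    Each direction is sorted by adjusted p ascending; ties by |log2FC|
    ascending, then row-key lexicographic order, then truncated.
    """
    sig = de_table[de_table["significant"]]
    picked = []
    for direction, cap in (("up", cap_up), ("down", cap_down)):
        side = sig[sig["log2FoldChange"] > 0] if direction == "up" else sig[
            sig["log2FoldChange"] < 0
        ]
        order = sorted(
            side.index,
            key=lambda k: (
                side.loc[k, "padj"],
                abs(side.loc[k, "log2FoldChange"]),
                str(k),
            ),
        )
        picked.extend(order[:cap])
    return de_table.loc[picked]


# ---------------------------------------------------------------------------
# Greedy centroid clustering with consensus calling
# ---------------------------------------------------------------------------

@dataclass
class SequenceCluster:
    centroid: str
    members: list[str]
    consensus: str = ""
    mean_identity: float = 1.0
    borderline: list[str] = field(default_factory=list)


def pairwise_identity(a: str, b: str) -> float:
    """Matches / alignment columns under unit-cost global (NW) alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for count, op in _parse_cigar(res["cigar"]):
        columns += count
        if op == "=":
            matches += count
    return matches / columns if columns else 1.0


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def _aligned_to_centroid(centroid: str, member: str) -> list[str]:
    """Member bases per centroid column ('' = deletion; insertions dropped)."""
    res = edlib.align(member, centroid, mode="NW", task="path")
    cols: list[str] = []
    qi = ti = 0
    for count, op in _parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            for _ in range(count):
                cols.append(member[qi])
                qi += 1
                ti += 1
        elif op == "D":  # gap in query = centroid column with no member base
            for _ in range(count):
                cols.append("")
                ti += 1
        elif op == "I":  # insertion in member relative to centroid
            qi += count
    return cols


def cluster_and_consensus(
    sequences: Sequence[str],
    weights: Sequence[float] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[SequenceCluster]:
    """Greedy centroid clustering with per-column majority consensus.

    Sequences are visited in weight (total count) descending order, ties
    lexicographic; each joins the first centroid at global-alignment
    identity ≥ threshold, else founds a new cluster.  The consensus spans
    the centroid columns; each column takes the majority base among
    members' aligned bases (ties by alphabetical base, empty columns keep
    the centroid base).  Members whose identity to the final consensus
    falls below the threshold are flagged borderline, not evicted.
    """
    if weights is None:
        order = sorted(set(sequences))
        # preserve duplicate multiplicity as weight
        counts: dict[str, int] = {}
        for s in sequences:
            counts[s] = counts.get(s, 0) + 1
        order = sorted(counts, key=lambda s: (-counts[s], s))
    else:
        if len(weights) != len(sequences):
            raise ValueError("weights length mismatch")
        w: dict[str, float] = {}
        for s, x in zip(sequences, weights):
            w[s] = w.get(s, 0.0) + x
        order = sorted(w, key=lambda s: (-w[s], s))

    clusters: list[SequenceCluster] = []
    for seq in order:
        placed = False
        for cl in clusters:
            if pairwise_identity(seq, cl.centroid) >= identity_threshold:
                cl.members.append(seq)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(centroid=seq, members=[seq]))

    for cl in clusters:
        columns: list[list[str]] = [[] for _ in cl.centroid]
        for member in cl.members:
            for i, base in enumerate(_aligned_to_centroid(cl.centroid, member)):
                if base:
                    columns[i].append(base)
        consensus = []
        for i, votes in enumerate(columns):
            if not votes:
                consensus.append(cl.centroid[i])
                continue
            tally: dict[str, int] = {}
            for b in votes:
                tally[b] = tally.get(b, 0) + 1
            best = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            consensus.append(best)
        cl.consensus = "".join(consensus)
        idents = [pairwise_identity(m, cl.consensus) for m in cl.members]
        cl.mean_identity = float(np.mean(idents)) if idents else 1.0
        cl.borderline = [
            m for m, ident in zip(cl.members, idents) if ident < identity_threshold
        ]
    return clusters


def annotate_selected(
    sequences: Sequence[str],
    hits: Sequence[BlastHit],
    taxonomy: Taxonomy,
    groups: TaxonGroupSet | None = None,
) -> dict[str, str]:
    """Provisional source label per sequence from its best-bitscore hit.

    Labels: ``human`` (Homo group), ``bacterial`` (Bacteria group),
    ``other`` (any other group), ``unknown`` (no hit / unresolvable).
    Ties in bitscore break by ascending taxid, so the label is invariant
    under hit-order permutation.
    """
    groups = groups or TaxonGroupSet()
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    labels: dict[str, str] = {}
    for seq in sequences:
        seq_hits = by_query.get(seq, [])
        if not seq_hits:
            labels[seq] = "unknown"
            continue
        best = min(seq_hits, key=lambda h: (-h.bitscore, h.taxon_id))
        group = groups.group_of(best.taxon_id, taxonomy)
        if group == "Homo":
            labels[seq] = "human"
        elif group == "Bacteria":
            labels[seq] = "bacterial"
        elif group is None:
            labels[seq] = "unknown"
        else:
            labels[seq] = "other"
    return labels
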