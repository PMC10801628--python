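"""End-to-end orchestration: filters → species identification → counting → DE.

The pipeline wires the library stages together on in-memory fixtures
(typically produced by :mod:`srnacore.simulate`) and writes a diff-able
TSV report set.  Every stage logs its input/output read counts so each
printed percentage is recomputable from the shipped intermediates, and
the whole run is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from . import __version__
from .alignment_free import (
    annotate_selected,
    cluster_and_consensus,
    collapse_sequences,
    differential_expression,
    filter_keep_hits,
    select_top_sequences,
)
from .assign import (
    first_pass_rank,
    group_hits_by_read,
    krona_text_export,
    second_pass_assign,
    select_metagenome_species,
    subsample_reads,
)
from .contamination import build_environment_index, filter_environment, length_filter
from .counting import (
    INTRONIC,
    UNANNOTATED,
    Placement,
    catalogue_rna_types,
    count_with_priority,
    orchestrate_strategy,
    summary_row,
)
from .harmonize import PrioritySchema, build_catalogue, merge_report_table
from .io import ReadRecord
from .simulate import (
    SimulationConfig,
    ToyReferences,
    metagenome_references,
    naive_align,
)
from .taxonomy import TaxonGroupSet


@dataclass
class RunConfig:
    """All pipeline parameters in one place (recorded in the run manifest)."""

    seed: int = 0
    strategy: str = "metagenome"  # or "successive"
    min_length: int = 15
    subset_size: int = 200
    tolerance: float = 2.0
    metagenome_threshold: float = 0.01
    keep_count: int = 2
    keep_samples: int = 2
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    cap_up: int = 1000
    cap_down: int = 1000
    identity_threshold: float = 0.8
    max_mismatches: int = 0
    run_de: bool = True
    run_alignment_free: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def strip_metagenome_prefix(p: Placement) -> Placement:
    """Project a metagenome placement back onto plain contig coordinates."""
    parts = p.seqid.split("|")
    if len(parts) == 3 and parts[0].isdigit():
        return Placement(p.read_id, parts[2], p.pos, p.strand, p.length, p.score)
    return p


def run_pipeline(
    references: ToyReferences,
    samples: dict[str, list[ReadRecord]],
    env_reads: list[ReadRecord],
    config: RunConfig,
    outdir: str | Path,
) -> dict:
    """Execute every stage and write the TSV report set to ``outdir``.

    Returns a results dict with the key tables (counts, catalogues,
    summaries, DE, alignment-free selection) for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **fields) -> None:
        log.append({"stage": name, **fields})

    # ---- harmonized catalogue from the reference annotation sources ----
    schema = PrioritySchema()
    catalogue = build_catalogue(references.annotation_sources, schema)
    pd.DataFrame(merge_report_table(catalogue.reports)).to_csv(
        outdir / "merge_report.tsv", sep="\t", index=False
    )

    # ---- per-sample filters ----
    groups = {s: reads[0].group if reads else "test" for s, reads in samples.items()}
    kept: dict[str, list[ReadRecord]] = {}
    n_input: dict[str, int] = {}
    n_filtered: dict[str, int] = {}
    index = build_environment_index(env_reads, config.min_length)
    for sample in sorted(samples):
        reads = samples[sample]
        n_input[sample] = len(reads)
        long_enough, removed_short = length_filter(reads, config.min_length)
        survivors, removed_env, env_stats = filter_environment(long_enough, index)
        kept[sample] = survivors
        n_filtered[sample] = len(removed_short) + len(removed_env)
        stage(
            "filter",
            sample=sample,
            n_input=len(reads),
            n_short=len(removed_short),
            n_environment=len(removed_env),
            n_kept=len(survivors),
        )

    # ---- species identification on a random subset ----
    pooled = [r for s in sorted(kept) for r in kept[s]]
    subset = subsample_reads(pooled, config.subset_size, seed=config.seed)
    blast_refs, blast_taxids = metagenome_references(references)
    _, subset_hits = naive_align(
        subset, blast_refs, max_mismatches=config.max_mismatches, taxids=blast_taxids
    )
    taxonomy = references.taxonomy
    group_set = TaxonGroupSet()
    from .assign import filter_hits_by_taxa

    tagged, n_dropped = filter_hits_by_taxa(subset_hits, group_set, taxonomy)
    hits_by_read = group_hits_by_read(h for h, _ in tagged)
    rank_table = first_pass_rank(hits_by_read, config.tolerance, taxonomy)
    assignments = second_pass_assign(hits_by_read, rank_table, config.tolerance, taxonomy)
    pd.DataFrame(rank_table).to_csv(outdir / "species_ranks.tsv", sep="\t", index=False)
    (outdir / "krona.txt").write_text(krona_text_export(assignments, taxonomy))
    selected = select_metagenome_species(assignments, config.metagenome_threshold)
    stage(
        "assign_taxa",
        subset_size=len(subset),
        n_hits=len(subset_hits),
        n_dropped_hits=n_dropped,
        n_species_selected=len(selected),
    )

    # ---- metagenome + full alignment ----
    meta_species = [t for t, _ in selected]
    if references.host_taxid not in meta_species:
        meta_species.insert(0, references.host_taxid)
    meta_refs, meta_taxids = metagenome_references(references, meta_species)
    manifest_rows = [
        {"taxon_id": t, "fraction": round(fr, 6)} for t, fr in selected
    ]
    pd.DataFrame(manifest_rows).to_csv(
        outdir / "metagenome_manifest.tsv", sep="\t", index=False
    )

    host_refs = {
        seqid: seq for seqid, seq in meta_refs.items()
        if meta_taxids[seqid] == references.host_taxid
    }

    results: dict = {
        "catalogue": catalogue,
        "rank_table": rank_table,
        "selected_species": selected,
    }
    all_counts: dict[str, pd.Series] = {}
    summaries = []
    species_catalogue_rows = []
    per_sample_counts: list[pd.DataFrame] = []
    for sample in sorted(kept):
        reads = kept[sample]
        host_pl, _ = naive_align(reads, host_refs, config.max_mismatches)
        meta_pl, _ = naive_align(reads, meta_refs, config.max_mismatches)
        provenance, final = orchestrate_strategy(
            [r.read_id for r in reads],
            config.strategy,
            host_pl,
            meta_pl,
            host_taxid=references.host_taxid,
        )
        host_final = {
            rid: strip_metagenome_prefix(p)
            for rid, p in final.items()
            if provenance.get(rid) == "host"
        }
        counts = count_with_priority(
            host_final,
            catalogue,
            sample_of_read={rid: sample for rid in host_final},
            gene_spans=references.gene_spans,
        )
        per_sample_counts.append(counts)
        summ = summary_row(
            n_input[sample], n_filtered[sample], provenance, counts
        )
        summ["sample"] = sample
        summaries.append(summ)
        sp_counts: dict[str, int] = {}
        for v in provenance.values():
            if v and v.startswith("other:"):
                taxid = int(v.split(":")[1])
                name = taxonomy.name(taxid) if taxid in taxonomy else str(taxid)
                sp_counts[name] = sp_counts.get(name, 0) + 1
        host_n = sum(1 for v in provenance.values() if v == "host")
        species_catalogue_rows.append(
            {"sample": sample, taxonomy.name(references.host_taxid): host_n, **sp_counts}
        )
        stage("orchestrate", sample=sample, strategy=config.strategy,
              n_host=host_n, n_other=sum(sp_counts.values()),
              n_unidentified=sum(1 for v in provenance.values() if v is None))

    counts = pd.concat(per_sample_counts, axis=1).fillna(0).astype(int)
    # stable row order: features sorted, reserved rows last
    feature_rows = sorted(r for r in counts.index if r not in (UNANNOTATED, INTRONIC))
    counts = counts.reindex(feature_rows + [INTRONIC, UNANNOTATED]).fillna(0).astype(int)
    counts = counts[sorted(counts.columns)]
    counts.to_csv(outdir / "feature_counts.tsv", sep="\t")
    results["counts"] = counts

    types = catalogue_rna_types(counts, catalogue)
    types.to_csv(outdir / "rna_type_catalogue.tsv", sep="\t", float_format="%.4f")
    results["rna_types"] = types

    species_df = pd.DataFrame(species_catalogue_rows).fillna(0)
    species_df = species_df.set_index("sample").astype(int).sort_index()
    species_df.to_csv(outdir / "species_catalogue.tsv", sep="\t")
    results["species_catalogue"] = species_df

    summary_df = pd.DataFrame(summaries).set_index("sample").sort_index()
    summary_df.to_csv(outdir / "summary.tsv", sep="\t", float_format="%.4f")
    results["summary"] = summary_df

    corr = spearman_correlation_table(counts)
    corr.to_csv(outdir / "spearman_correlation.tsv", sep="\t", float_format="%.6f")
    results["spearman"] = corr

    # ---- differential expression on feature counts ----
    group_map = {s: g for s, g in groups.items() if g in ("test", "control")}
    n_test = sum(1 for g in group_map.values() if g == "test")
    n_ctrl = sum(1 for g in group_map.values() if g == "control")
    de = None
    if config.run_de and n_test >= 2 and n_ctrl >= 2:
        feature_counts = counts.drop(index=[INTRONIC, UNANNOTATED], errors="ignore")
        feature_counts = feature_counts[[s for s in counts.columns if s in group_map]]
        feature_counts = feature_counts[feature_counts.sum(axis=1) > 0]
        if not feature_counts.empty:
            de = differential_expression(
                feature_counts, group_map, config.lfc_threshold, config.padj_threshold
            )
            de.to_csv(outdir / "de_features.tsv", sep="\t", float_format="%.6g")
    if de is None:
        pd.DataFrame(
            columns=["baseMean", "log2FoldChange", "pvalue", "padj", "significant"]
        ).to_csv(outdir / "de_features.tsv", sep="\t")
    results["de_features"] = de

    # ---- alignment-free branch ----
    if config.run_alignment_free and n_test >= 2 and n_ctrl >= 2:
        af = run_alignment_free(kept, group_map, references, config, outdir)
        results["alignment_free"] = af

    stage("done", version=__version__, seed=config.seed)
    pd.DataFrame(log).to_csv(outdir / "stage_log.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "strategy": config.strategy,
        "parameters": {
            k: v for k, v in vars(config).items() if not isinstance(v, SimulationConfig)
        },
        "simulation": vars(config.simulation),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return results


def run_alignment_free(
    kept: dict[str, list[ReadRecord]],
    group_map: dict[str, str],
    references: ToyReferences,
    config: RunConfig,
    outdir: Path,
) -> dict:
    """Collapse → keep-hits → DE → cap → cluster → provisional source labels."""
    matrix = collapse_sequences(
        {s: kept[s] for s in sorted(kept) if s in group_map}
    )
    filtered = filter_keep_hits(matrix, config.keep_count, config.keep_samples)
    out: dict = {"matrix_rows": len(matrix), "filtered_rows": len(filtered)}
    if filtered.empty:
        pd.DataFrame().to_csv(outdir / "af_selected.tsv", sep="\t")
        return out
    de = differential_expression(
        filtered, group_map, config.lfc_threshold, config.padj_threshold
    )
    selected = select_top_sequences(de, config.cap_up, config.cap_down)
    out["n_significant"] = int(de["significant"].sum())
    out["n_selected"] = len(selected)
    weights = filtered.loc[selected.index].sum(axis=1) if len(selected) else None
    clusters = cluster_and_consensus(
        list(selected.index),
        weights=list(weights) if weights is not None else None,
        identity_threshold=config.identity_threshold,
    )
    blast_refs, blast_taxids = metagenome_references(references)
    probe_reads = [
        ReadRecord(read_id=seq, sequence=seq, sample_id="af", group="test")
        for seq in selected.index
    ]
    _, hits = naive_align(probe_reads, blast_refs, taxids=blast_taxids)
    labels = annotate_selected(list(selected.index), hits, references.taxonomy)
    sel_out = selected.copy()
    sel_out["source"] = [labels[s] for s in sel_out.index]
    cluster_of = {}
    for i, cl in enumerate(clusters):
        for m in cl.members:
            cluster_of[m] = i + 1
    sel_out["cluster"] = [cluster_of.get(s, 0) for s in sel_out.index]
    sel_out.to_csv(outdir / "af_selected.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        [
            {
                "cluster": i + 1,
                "n_members": len(cl.members),
                "consensus": cl.consensus,
                "mean_identity": round(cl.mean_identity, 4),
                "n_borderline": len(cl.borderline),
            }
            for i, cl in enumerate(clusters)
        ]
    ).to_csv(outdir / "af_clusters.tsv", sep="\t", index=False)
    out["n_clusters"] = len(clusters)
    out["labels"] = labels
    out["de"] = de
    out["selected"] = sel_out
    return out


def spearman_correlation_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample × sample Spearman correlation (average ranks on ties).

    Pairs involving a constant column are undefined and reported NA; the
    diagonal is 1 for non-constant samples.
    """
    samples = list(counts.columns)
    n = len(samples)
    mat = np.full((n, n), np.nan)
    values = counts.to_numpy(dtype=float)
    constant = [bool(np.all(values[:, j] == values[0, j])) for j in range(n)]
    for i in range(n):
        for j in range(i, n):
            if constant[i] or constant[j]:
                continue
            if i == j:
                mat[i, j] = 1.0
                continue
            rho = scipy_stats.spearmanr(values[:, i], values[:, j]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=samples, columns=samples)
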