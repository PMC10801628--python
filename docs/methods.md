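# Methods

This note documents the models, rules and numerical choices behind
`srnacore`, in the order the pipeline applies them, followed by what the
synthetic fixtures do and do not emulate.

## Coordinates, sequences, formats

All public coordinates are 1-based inclusive (GTF/SAM convention);
half-open arithmetic is internal only. Input sequences are uppercased
and RNA `U` is mapped to `T` on read-in, so RNA-space databases (mature
miRNA FASTA) can be matched exactly against DNA genomes. GTF is the
canonical annotation representation; GFF3 input is mapped into it with
`ID`/`Name` lifted into the attribute map. BLAST tabular input follows
the outfmt-6 layout with a trailing `staxids` column; a multi-valued
taxid cell (`123;456`) expands into one hit per taxid so all downstream
ranking arithmetic is per-(hit, taxon) and order-independent.

## Annotation harmonization

Overlap comes in two kinds and is treated differently:

- **Within one source database** features are physically merged.
  Merging is transitive (overlap closure), strand-aware (small-RNA
  identity is strand-specific, so features on opposite strands never
  merge), and an overlap means ≥1 shared base; book-ended features
  (`end = next.start − 1`) do not merge. A union feature spans min
  start → max end of its members, its name joins member names with `|`
  in coordinate order, and the member list is kept in a `members`
  attribute. Per-source merge reports count every member of a ≥2-member
  union as "merged" and give `round(100·merged/in)`.
- **Between sources** features are left in place; the conflict is
  resolved per read at counting time by the RNA-type priority schema.
  This preserves the information that, e.g., a piRNA database entry
  sits inside a tRNA locus, while guaranteeing each read one label.

The priority schema is an ordered list of 16 type classes (miRNA first,
repeats last). Raw biotype strings are normalised through an alias map
(`protein_coding` → mRNA, `Mt_tRNA` → mtRNA, …); unknown types fall into
`other_RNA` and are logged. FASTA-only databases are placed on the
genome by exact, full-length, ungapped string matching on both strands
(reverse-complement occurrences get strand `−`); sequences with no
occurrence are reported as skipped, and placements are capped at
`max_hits = 100` per sequence (in genome order, flagged) to bound repeat
explosion. tRF sub-annotations halve each tRNA locus at
`floor(length/2)` in transcript orientation — the 5′ fragment takes the
first half, so on the minus strand it occupies the higher-coordinate
half. The halving rule is a documented, configurable convention; no
standard fragment boundary definition exists at annotation level.

## Contamination filtering

Environment (no-template) control libraries capture reagent- and
lab-specific RNA. A sample read is removed iff its sequence equals an
indexed environment sequence or contains one as a contiguous substring,
forward orientation only (library reads are oriented; reverse-complement
matching is off by default). Environment sequences shorter than the
minimum read length (15 nt, matching the read-length filter) are not
indexed, so trivially short patterns cannot delete everything. The index
is length-stratified exact hashing: for each indexed length L, every
length-L substring of the query is probed in a hash set — a few hundred
O(1) probes per ≤50 nt read, exactly equivalent to the naive quadratic
scan (property-tested). Symmetric containment (sample read inside a
longer environment read) is available behind a `contain_both` flag,
default off.

## Two-pass species identification

A uniform random subset of reads (default 200; reproducible under the
seed) is searched against the sequence database; each hit is mapped to
the first of 15 ordered taxon groups (host genus, Bacteria, Fungi,
Viruses, Archaea, the protist supergroups, other sequences) whose
subtree contains its taxid; hits outside every group are dropped and
counted. Hit taxids at or below species rank are lifted to their species
ancestor; taxa above species rank are kept and flagged.

"Similar BLAST score" is formalised as bitscore within an additive
tolerance Δ (default 2 bits) of the read's best bitscore. Pass 1 ranks
species by *frequency of presence*: the number of reads (not hits — this
is robust to databases with many near-identical subject records) in
which the species appears among the near-best hits; ties break by
ascending taxid. Pass 2 assigns each read to the near-best species with
the best pass-1 rank (species missing from the table count as worst
rank). At Δ = 0 the scheme degenerates to best-bitscore assignment with
rank tie-breaking only at exact score ties. All outputs are invariant
under permutation of the hit records.

Species whose assigned-read fraction strictly exceeds 1% are selected
for the metagenome; the combined FASTA rewrites record ids to
`taxid|species_name|original_id` (collision-proof, traceable), host
genome first. Per-species read counts are exported as Krona-importable
text (`count TAB lineage…`).

## Counting

Multi-mapped reads are first reduced to one placement: uniquely placed
reads anchor a coverage profile; each candidate placement of a
multi-mapper is weighted by the number of already-placed read starts
within ±50 nt on the same (contig, strand), the heaviest candidate wins,
ties go to the lowest (contig, coordinate), and a second pass recomputes
weights including first-pass placements. This is a deliberate
simplification of coverage-guided repositioning tools, keeping their
contract (exactly one placement per mapped read, decided by local
coverage) while remaining a few lines of auditable arithmetic.

Counting then resolves each placed read to exactly one feature: among
features sharing ≥1 base on the same strand (an unstranded flag exists),
the best priority class wins; within a class the largest overlap, then
the lowest start. Reads overlapping no feature but lying inside a
protein-coding gene span are reported in a reserved `__intronic__` row
("intronic" is defined exactly so — the term has no standard definition
at this level); all other feature-free reads go to `__unannotated__`.
There is no ambiguous category, and the matrix column sums equal the
per-sample counted-read numbers, which the pipeline cross-checks
against the orchestrator's read counts at run time.

Two orchestration strategies partition each sample's reads into
host / other-species(taxid) / unidentified: *successive* lets host
placements consume reads first and assigns only the remainder from
metagenome placements; *metagenome* pools all placements, keeps only the
best-scoring ones per read, and lets coverage-guided reassignment decide
— so a read with a slightly imperfect host match and a perfect microbial
match goes to the microbe under *metagenome* but to the host under
*successive*. The per-sample summary row (percent filtered, annotated,
ambiguous, unannotated incl. intronic, other species, unidentified)
always sums to 100; the ambiguous entry is measured (count-matrix
surplus over host reads), not asserted.

The RNA-type catalogue reports, per sample, each priority class as a
percentage of annotated non-intronic reads; intronic and unannotated
are shown as separate absolute counts, and samples with zero annotated
reads give NA.

## Differential expression

Both the feature-count and unique-sequence matrices use the same
engine: a per-row negative-binomial model with median-of-ratios size
factors, Wald test of the test-vs-control effect and Benjamini–Hochberg
adjustment, delegated to pydeseq2 with a fixed `~condition` design. The
fit path contains no randomisation, so results are bit-reproducible for
a given matrix. Significance requires BH-adjusted p below the threshold
(default 0.05) and |log2FC| at or above the threshold (default 1).

The alignment-free branch collapses reads to exact unique sequences
(counts conserved per sample), applies the keep-hits filter — keep rows
with count ≥ 2 in ≥ 2 samples, both configurable; the predicate form is
this package's definition of the adjustable dataset-reduction variable —
and caps the tested selection at 1000 upregulated and 1000 downregulated
sequences, each side ordered by adjusted p ascending with ties broken by
|log2FC| ascending then sequence lexicographic order.

Selected sequences are clustered greedily: visited in total-count
descending order, each joins the first centroid with global-alignment
identity ≥ 0.8, else founds a cluster. Identity = matches / alignment
columns under unit-cost Needleman–Wunsch (computed from edlib's
alignment path). The consensus spans the centroid's columns and takes
the per-column majority base over the members' centroid-anchored
alignments (ties alphabetical; empty columns keep the centroid base);
members below threshold identity to the final consensus are flagged
borderline rather than evicted, so clusters always partition the input.
Greedy centroid clustering replaces an external multiple-aligner
dependency while preserving the contract: clusters plus consensus
sequences plus a provisional source label (human / bacterial / other /
unknown) from each sequence's best-bitscore hit.

## Simulator and what the tests show

The toy design: one host contig (20 kb default) carrying seven
annotation sources with within-source overlapping twins and two planted
cross-source traps (piRNA entries nested in tRNA loci; lncRNAs across
mRNA exons); two-exon mRNA genes whose spans support intronic calls;
two microbial genomes (8 kb each) and a contaminant genome under a
17-node taxonomy containing the screening group roots. Reads are drawn
from annotated features (length-weighted), uniform 10–44 nt —
which makes the <15 nt filter remove ~14% of raw reads — with
configurable fractions of microbial, intronic and intergenic background
reads and optional substitution errors; truth labels ride in read ids.
Default scale is 10 samples × 10,000 reads. The environment library
mixes contaminant-genome reads with planted copies (exact and
substring) of sample reads, providing known-truth positives for the
filter. The naive aligner reports *every* placement within the
substitution budget on either strand, with a bitscore proxy of
2·matches − 3·mismatches — monotone in matches, adequate for ordering,
and explicitly not a BLAST statistic. Everything is deterministic under
the seed (stream-specific seeds derived by CRC, independent of Python
hash randomisation).

Passing tests therefore demonstrate the *algorithms*: oracle-exact
merging, filter decisions identical to naive scans, order-invariant
two-pass assignment with ≥95% species sensitivity/specificity on the
error-free two-species control at ≥18 nt, calibrated DE (null type-I
error ≈5%, ≥90% recovery of 8-fold spikes at n = 5+5), and structurally
zero ambiguous reads. They do not demonstrate performance on real data:
real genomes have repeats, homology and composition bias that toy
random genomes lack; real read sets carry indels, quality decay and
isomiR-style end variation the simulator does not model; and published
headline figures obtained against full genome/annotation databases with
external aligners are expected to differ from their desk-scale analogues
here.

## Limitations

- Exact-substring contaminant matching; no mismatch tolerance.
- The coverage-guided reassignment is a simplified window-weight scheme,
  not a reimplementation of any published repositioning algorithm.
- Greedy centroid clustering approximates MSA-based clustering; cluster
  boundaries depend on visiting order at borderline identities.
- isomiR analysis, piRNA-cluster analysis, fractional/EM multimapper
  counting and plot rendering are out of scope.
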