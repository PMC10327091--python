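# Methods

## Overview

`virocell` analyses droplet scRNA-seq of a mixed protist community to (i)
call actively infected cells from viral marker-gene UMIs, (ii) assign each
infected cell a host taxonomy from per-cell assembled 18S contigs, (iii)
pair each host with the viral family dominating its viral reads, and (iv)
relate infection of a focal taxon to its bloom trajectory. A synthetic
community generator with planted ground truth stands in for real community
FASTQs and curated databases, which makes the full pipeline testable at
desk scale.

## Infection calling

Reads are assigned to viral marker genes by a six-frame translated search
(default) or exact nucleotide containment; reads whose best score is tied
between two genes are left unassigned (unique-mapping semantics), and
reads sharing (barcode, gene, UMI) collapse to one molecule. A cell is
*highly infected* iff it expresses ≥ 2 viral genes, has ≥ 1 gene with ≥ 2
UMIs, and carries ≥ 10 viral UMIs in total. The first two criteria are
read literally as independent conditions; whether the ">1 UMI" gene must
coincide with one of the ">1 genes" is ambiguous in prose, but under the
literal reading both variants coincide whenever the total-UMI floor is
met, and both boundary readings are unit-tested. Adding viral UMIs can
never un-call a cell (monotonicity), and a 9-vs-10 total flips the call.

Cell-level QC (used before community mapping, where whole-library totals
exist) drops zero-UMI cells, then cells at or beyond the nearest-rank
1st/99th percentile of the remaining totals. When more than 2% of cells tie
exactly at a boundary value the boundary itself is retained (removal
becomes strict), so a degenerate all-equal table loses only its zero cells.
QC is deliberately not applied to the viral-only count table: the top-1%
rule would preferentially delete the most infected cells.

## Host assignment

Per cell, reads are pooled by barcode, poly-A-trimmed (trailing run of
≥ 10 A allowing one non-A base; reads < 30 nt dropped), and assembled by
greedy exact suffix–prefix overlap merging with `min_overlap = 21` nt —
the lower k-mer size of the transcriptome assembler it replaces. Both
orientations are considered; fragments are kept in canonical orientation
(lexicographically smaller of sequence and reverse complement), exact
duplicates are collapsed first, and ties between equal-length overlaps are
broken toward the lexicographically smallest merged sequence, which makes
the output independent of read order. Greedy exact merging is adequate
*only* because simulated reads are error-free exact substrings; this is
the stated boundary of the stand-in (no error correction, no
repeat/bubble resolution).

Contigs ≥ 100 nt are searched against the 18S databases at 99% identity,
E ≤ 1e-10, ≥ 100 bp, keeping the single top-bitscore passing hit per
database. One agreed group assigns the contig; hits spanning ≥ 2 groups
make it *nonspecific*; a group outside the configured list becomes
*other_eukaryote*; no passing hit means *unassigned* (this folds the
usual rRNA pre-filter into the alignment gates — the downstream decision
is identical). At cell level, nonspecific/unassigned contigs are ignored;
≥ 2 distinct groups among the rest conservatively *omit* the cell, which
is exactly the signature a cross-taxon barcode doublet leaves. Doublets of
two same-taxon cells are biologically invisible to this rule and are not
counted against it. The multi-group test uses per-database best hits by
default; a flag switches to all passing hits, since the stricter reading
is defensible.

Rare subpopulations too sparse for per-cell assembly are identified by
pooling reads from all of their barcodes, assembling jointly, and
searching at a relaxed 90% identity gate; the result ranks reference
species by best identity with supporting-contig counts.

## Virus pairing

Pairing uses raw reads, not UMIs — infection calling and pairing are two
distinct quantification passes, matching the workflow this package
reproduces. Each read's best translated hit contributes one count to that
protein's viral family. A cell enters the pair table only if its host call
is specific and its best family holds ≥ 10 reads; links with ≥ 10% of the
cell's viral reads are reported and a link is *unambiguous* at ≥ 90%. All
three thresholds are inclusive boundaries and unit-tested as such. The 10%
rule is display-level only; it does not feed back into the unambiguity
rule. Cells whose best family is the configured dominant virus are removed
before pairing, and |dominant set| + |other set| always equals the number
of highly infected cells. Per-gene viral expression is summarised as
summed UMIs with a log2(x+1) transform (the +1 pseudocount makes
unexpressed genes report 0; the upstream expected-count estimator is
replaced by direct UMI sums).

## Homology core

Nucleotide search is exact maximal-scoring *ungapped* local alignment over
both strands: exact 11-mer seeds select (subject, diagonal) pairs and each
seeded diagonal is rescored exhaustively (maximal contiguous-segment
score), so any alignment containing an 11-mer exact match is found at its
true optimum; alignments scoring < 22 are not reported. Scoring is +1/−2
with λ = 1.28, K = 0.46; protein scoring is BLOSUM62 with λ = 0.267,
K = 0.041 — published convention values, not fitted quantities. Identity
is matches/alignment-length, reported to one decimal; N never matches.
Ties resolve toward lower subject start, then the plus strand, then lower
query start, and within a diagonal toward the shortest segment. E-values
use the total database length; a 100-nt perfect match against a 1-Mb
database scores far below the 1e-10 gate, so the strict gate is passable
by design. The translated search translates all six frames (stops break
segments, codons with N translate to X), seeds on exact 5-mers and extends
ungapped; its minimum raw score defaults to 65, calibrated once
on the generator's regime so that random host 60-mers essentially never
reach it while true in-frame viral reads always do (the two score
populations are separated by a wide margin; the prescribed <1% false-hit
bound is met with room to spare). Gapped alignment, low-complexity seed
masking and profile/HMM search are out of scope.

## Synthetic community generator

The generator emulates: a six-taxon community dominated by one bloomer
(60%) with a rare class at 0.4% of cells; four labelled viral families
with ≥ 4 marker genes each (PolB/MCP/TopoII plus chaperone analogs); a
12-entry infection table whose default expression fraction (6–8% of a
cell's reads) yields ≳ 70 expected viral UMIs per infected cell; ambient
viral background (default 0.3% of an uninfected cell's reads, one knob
covering both free virions and grazing); 2% barcode doublets; and a bloom
trajectory in which the rare class rises 1% → 6% → 1% while its infected
fraction peaks at 86% one day after peak abundance, with single-cell
sampling on four interleaved days.

Sequences evolve by per-site substitution from independent random
ancestors — no indels, keeping the ungapped aligner exact. Each taxon has
an 1800-nt 18S analog in two copies ≥ 99% identical, with cross-taxon
identity far below the 90% ceiling, and 20 mRNAs of 300–2000 nt; viral
genes are stop-free random codon sequences whose frame-0 translation is
stored as the protein. Reads are exact 60-mers with uniform start; each
molecule gets a distinct UMI within its barcode (UMI collisions across
4^12 space are ignored); reads per cell are log-normal with median 1200
(σ = 0.2). A fixed 4% of each cell's reads come from its own 18S so that
per-cell taxonomy is assemblable: with uniform 60-mer starts on 1800 nt
and a 21-nt overlap floor, ~45–50 rRNA reads per cell are needed for a
≥ 100-nt 18S contig to form with high probability, which sets the joint
choice of rRNA share and read depth (the rRNA carry-through magnitude is a
free parameter of the regime, not a measured quantity).

What the generator does **not** emulate — sequencing error, PCR
duplication, barcode errors, chimeras, 3'-end positional bias, expression
heterogeneity within a taxon, partial/segmented transcripts, and real
database redundancy. Passing tests therefore demonstrate the logical
correctness and threshold behaviour of the pipeline, not its robustness to
the error structure of real droplet data.

## Community map and dynamics

The combined reference is curated from infected-cell contigs plus known
gene sets: sequences dominated by homopolymer/dinucleotide repeats
(windowed score, window 64, ≥ 50% repeat coverage) are removed and
near-duplicates (exact or ≥ 99%-identity containment) collapse onto the
longer sequence. All cells are quantified by unique verbatim containment
on either strand, QC-filtered on the combined totals, normalised to the
median library size, sqrt-scaled, reduced by exact-SVD PCA (50
components) and embedded with UMAP (neighbors 7, min_dist 0.4, spread 2,
fixed seed). Embedding coordinates are deterministic under a seed but not
meaningful across implementations; the contract is neighbourhood fidelity
(nearest-neighbour taxon agreement, silhouette), not coordinates. Cells
with ≥ 10 viral UMIs on the same matrix are flagged infected.

Relative abundance is each taxon's fraction of per-day ASV counts
excluding metazoans. The demise report finds the focal taxon's peak day
(argmax, earliest on ties), the first later day at ≤ half the peak
(configurable ratio — the source workflow describes a 6% → 1% crash
without a formal rule), and the sampled day of maximum infected fraction;
the *infection-associated demise* flag requires peak infection inside the
closed [peak, decline] window and is labelled in the report as an explicit
operationalisation of a qualitative pattern.

## Numerical and design notes

- Determinism: one integer seed fixes references, reads, tables, and every
  CLI stage byte-for-byte; UMAP runs single-threaded under its seed.
- The two QC examples a maintainer might expect — "remove the boundary
  cell" and "idempotent on re-run" — cannot both hold for any fixed
  percentile rule on distinct totals; the inclusive nearest-rank rule was
  kept and idempotence is only guaranteed in the degenerate all-tied case.
- Read→gene ambiguity discards the read rather than assigning fractions;
  family profiles still count such reads via the deterministic best-hit
  tie rule (lexicographic subject id, then lower frame).
- `argmax_family` ties resolve to the lexicographically first family.
- Degenerate inputs: empty FASTA → empty list; zero cells → empty
  experiment; an all-excluded ASV day, an empty pooled cell set, empty
  reference databases, and sub-neighbour cell counts raise errors naming
  the offending item.
- Problem sizes in the test-suite and acceptance script (500-cell main
  run, 90-cell embedding, 100 assembly transcripts, 10,000 ASVs/day,
  50–100 dynamics replicates) are the package's chosen desk-scale study
  conditions.

## Known limitations

Ungapped alignment cannot model indel divergence; the greedy assembler
requires error-free reads; translated-search scoring is not comparable to
external aligner scores (only best-hit semantics are preserved);
containment quantification requires reads to be exact substrings of the
reference; and the demise flag is a descriptive rule, not a causal test.
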