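"""Viral marker-gene UMI quantification and highly-infected cell calling.

A cell is called *highly infected* when all three criteria hold: it
expresses more than one viral marker gene, at least one gene has a UMI
count greater than one, and it carries at least 10 viral UMIs in total.
The multi-gene / multi-UMI requirements guard against ambient virions and
ingestion-derived signal; the total-UMI floor guards against sparse noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse

from .homology import ProteinSearcher, revcomp, DEFAULT_MIN_AA_SCORE
from .io import ReadPair, SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CellUMITable",
    "InfectionCall",
    "count_viral_umis",
    "assign_reads_to_genes",
    "qc_filter_cells",
    "call_highly_infected",
    "partition_by_dominant_virus",
]

HIGHLY_INFECTED_MIN_TOTAL_UMIS = 10


@dataclass
class CellUMITable:
    """Sparse barcode x gene UMI counts with a source tag per gene."""

    barcodes: list[str]
    genes: list[str]
    sources: list[str]  # per gene: viral-marker | host | custom
    counts: scipy.sparse.csr_matrix

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape does not match barcodes x genes")
        if len(self.sources) != len(self.genes):
            raise ValueError("one source tag per gene required")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def total_umis(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, keep: Sequence[int]) -> "CellUMITable":
        keep = list(keep)
        return CellUMITable(
            barcodes=[self.barcodes[i] for i in keep],
            genes=list(self.genes),
            sources=list(self.sources),
            counts=self.counts[keep, :],
        )

    def subset_source(self, source: str) -> "CellUMITable":
        keep = [j for j, s in enumerate(self.sources) if s == source]
        return CellUMITable(
            barcodes=list(self.barcodes),
            genes=[self.genes[j] for j in keep],
            sources=[source] * len(keep),
            counts=self.counts[:, keep],
        )

    def row(self, barcode: str) -> dict[str, int]:
        i = self.barcodes.index(barcode)
        r = self.counts[i].tocoo()
        return {self.genes[j]: int(v) for j, v in zip(r.col, r.data)}


@dataclass
class InfectionCall:
    """Per-cell screening result; ``highly_infected`` is determined by the
    three-part criterion and nothing else."""

    barcode: str
    n_viral_genes_expressed: int
    max_gene_umis: int
    total_viral_umis: int
    highly_infected: bool

    @staticmethod
    def from_counts(barcode: str, gene_umis: dict[str, int]) -> "InfectionCall":
        expressed = {g: c for g, c in gene_umis.items() if c >= 1}
        n_genes = len(expressed)
        max_umis = max(expressed.values(), default=0)
        total = sum(expressed.values())
        return InfectionCall(
            barcode=barcode,
            n_viral_genes_expressed=n_genes,
            max_gene_umis=max_umis,
            total_viral_umis=total,
            highly_infected=(
                n_genes > 1
                and max_umis > 1
                and total >= HIGHLY_INFECTED_MIN_TOTAL_UMIS
            ),
        )


# ---------------------------------------------------------------------------
# read -> gene assignment

def assign_reads_to_genes(
    reads: Sequence[ReadPair],
    viral_ref: Sequence[SeqRecord],
    mode: str = "translated",
    min_aa_score: int = DEFAULT_MIN_AA_SCORE,
) -> list[Optional[tuple[str, str]]]:
    """Per-read (gene, family) assignment against the viral marker reference.

    ``mode='translated'`` uses the six-frame protein search; a read maps to
    a gene only when that gene's proteins hold the unique best score.
    ``mode='containment'`` assigns a read contained verbatim (either strand)
    in exactly one gene's nucleotide sequence. Unassigned reads yield None.
    """
    if mode == "translated":
        searcher = ProteinSearcher(list(viral_ref), min_aa_score=min_aa_score)
        return searcher.assign_reads([r.cdna for r in reads])
    if mode == "containment":
        k = 21
        index: dict[str, set[int]] = {}
        for gi, rec in enumerate(viral_ref):
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], set()).add(gi)
        out: list[Optional[tuple[str, str]]] = []
        for read in reads:
            genes: set[int] = set()
            for seq in (read.cdna, revcomp(read.cdna)):
                if len(seq) < k:
                    continue
                for gi in index.get(seq[:k], ()):
                    if seq in viral_ref[gi].sequence:
                        genes.add(gi)
            if len(genes) == 1:
                gi = genes.pop()
                rec = viral_ref[gi]
                out.append((rec.meta.get("gene", rec.id), rec.meta.get("family", "")))
            else:
                out.append(None)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def count_viral_umis(
    reads: Sequence[ReadPair],
    viral_ref: Sequence[SeqRecord],
    mode: str = "translated",
    min_aa_score: int = DEFAULT_MIN_AA_SCORE,
    assignments: Optional[list[Optional[tuple[str, str]]]] = None,
) -> CellUMITable:
    """UMI counts per (barcode, viral gene).

    Reads sharing (barcode, gene, UMI) collapse to one molecule. Reads with
    no unique best gene are left unassigned (counted in a log message).
    Precomputed ``assignments`` from :func:`assign_reads_to_genes` may be
    supplied to avoid a second search pass.
    """
    if assignments is None:
        assignments = assign_reads_to_genes(reads, viral_ref, mode, min_aa_score)
    molecules: set[tuple[str, str, str]] = set()
    n_unassigned = 0
    for read, asn in zip(reads, assignments):
        if asn is None:
            n_unassigned += 1
            continue
        molecules.add((read.barcode, asn[0], read.umi))
    logger.info(
        "assigned %d/%d reads to viral genes (%d unassigned)",
        len(reads) - n_unassigned,
        len(reads),
        n_unassigned,
    )
    barcodes = sorted({r.barcode for r in reads})
    genes = sorted({rec.meta.get("gene", rec.id) for rec in viral_ref})
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: j for j, g in enumerate(genes)}
    counts = scipy.sparse.dok_matrix((len(barcodes), len(genes)), dtype=np.int64)
    for bc, gene, _umi in molecules:
        counts[bc_idx[bc], g_idx[gene]] += 1
    return CellUMITable(
        barcodes=barcodes,
        genes=genes,
        sources=["viral-marker"] * len(genes),
        counts=counts.tocsr(),
    )


# ---------------------------------------------------------------------------
# QC and calling

def qc_filter_cells(table: CellUMITable) -> CellUMITable:
    """Drop zero-UMI cells, then the lowest and highest 1% of totals.

    Percentiles use the nearest-rank convention on the remaining totals and
    the boundary values are removed too, except when more than 2% of cells
    tie exactly at a boundary (a degenerate pile-up), in which case only
    cells strictly beyond it are removed.
    """
    if table.n_cells == 0:
        raise ValueError("empty table")
    totals = table.total_umis()
    nonzero = np.flatnonzero(totals > 0)
    t = totals[nonzero]
    n = len(t)
    if n == 0:
        raise ValueError("all cells have zero UMIs")
    srt = np.sort(t)
    lo = srt[max(math.ceil(0.01 * n), 1) - 1]
    hi = srt[max(math.ceil(0.99 * n), 1) - 1]
    lo_tied = np.sum(t == lo) > 0.02 * n
    hi_tied = np.sum(t == hi) > 0.02 * n
    drop_low = (t < lo) if lo_tied else (t <= lo)
    drop_high = (t > hi) if hi_tied else (t >= hi)
    keep = nonzero[~(drop_low | drop_high)]
    if len(keep) < 3:
        raise ValueError(f"fewer than 3 cells remain after QC ({len(keep)})")
    return table.subset_cells(keep)


def call_highly_infected(table: CellUMITable) -> list[InfectionCall]:
    """One three-criterion call per cell of a viral-marker count table."""
    calls = []
    mat = table.counts
    for i, bc in enumerate(table.barcodes):
        row = mat[i].tocoo()
        gene_umis = {table.genes[j]: int(v) for j, v in zip(row.col, row.data) if v}
        calls.append(InfectionCall.from_counts(bc, gene_umis))
    return calls


def partition_by_dominant_virus(
    calls: Sequence[InfectionCall],
    profiles: dict[str, "object"],
    dominant_family: str,
) -> tuple[list[str], list[str]]:
    """Split highly-infected barcodes by whether their best-matching family
    is the dominant one (whose host-virus pair is already known and would
    swamp the analysis). Returns (dominant_set, other_set); the two lists
    partition the highly-infected set."""
    dominant, other = [], []
    for call in calls:
        if not call.highly_infected:
            continue
        profile = profiles.get(call.barcode)
        argmax = getattr(profile, "argmax_family", None) if profile else None
        if argmax == dominant_family:
            dominant.append(call.barcode)
        else:
            other.append(call.barcode)
    return dominant, other
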