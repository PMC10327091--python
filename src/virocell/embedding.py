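"""Whole-community quantification and 2-D embedding with infection overlay.

A combined host-virus reference is curated from infected-cell contigs plus
known gene sets (repeat-dominated sequences removed, near-duplicates
collapsed), all cells are quantified against it, and the QC-filtered count
matrix is library-size normalised, sqrt-scaled, reduced by exact-SVD PCA
and embedded in two dimensions with UMAP. Cells carrying >=10 viral UMIs
on the same matrix are flagged infected in the overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse
from sklearn.decomposition import PCA

from .homology import NucleotideSearcher, revcomp
from .io import ReadPair, SeqRecord
from .screen import CellUMITable

__all__ = [
    "EmbeddingResult",
    "build_hostvirus_reference",
    "quantify_cells",
    "normalize_and_embed",
    "overlay_infection",
    "repeat_fraction",
    "plot_embedding",
]

OVERLAY_MIN_VIRAL_UMIS = 10


@dataclass
class EmbeddingResult:
    barcodes: list[str]
    coords: np.ndarray  # n x 2
    taxon_labels: Optional[list[str]] = None
    infected_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.barcodes), 2):
            raise ValueError("coords must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")


# ---------------------------------------------------------------------------
# reference curation

def repeat_fraction(seq: str, window: int = 64) -> float:
    """Windowed repeat score: fraction of the sequence covered by 64-nt
    windows in which at least half the positions sit inside homopolymer
    (run >=6) or dinucleotide-period (run >=8) repeats."""
    n = len(seq)
    if n == 0:
        return 0.0
    marked = np.zeros(n, dtype=bool)
    i = 0
    while i < n:  # homopolymer runs
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 6:
            marked[i:j] = True
        i = j
    i = 0
    while i < n - 1:  # period-2 runs
        j = i + 2
        while j < n and seq[j] == seq[j - 2]:
            j += 1
        if j - i >= 8 and seq[i] != seq[i + 1]:
            marked[i:j] = True
            i = j
        else:
            i += 1
    window = min(window, n)
    step = max(window // 2, 1)
    flagged = np.zeros(n, dtype=bool)
    for start in range(0, n - window + 1, step):
        if marked[start : start + window].mean() >= 0.5:
            flagged[start : start + window] = True
    if marked[n - window :].mean() >= 0.5:
        flagged[n - window :] = True
    return float(flagged.mean())


def build_hostvirus_reference(
    infected_contigs: Sequence[SeqRecord],
    known_gene_sets: Sequence[SeqRecord] = (),
    max_repeat_fraction: float = 0.5,
    dedup_identity: float = 99.0,
) -> list[SeqRecord]:
    """Curated nucleotide reference: contigs + known genes, repeats removed,
    near-duplicate containments collapsed onto the longer sequence.

    Input records should carry a ``source`` meta tag (``host`` or
    ``viral``); it is preserved so downstream counts can be split.
    """
    candidates = sorted(
        list(infected_contigs) + list(known_gene_sets),
        key=lambda r: (-len(r), r.id),
    )
    kept: list[SeqRecord] = []
    kept_seqs: set[str] = set()
    searcher: Optional[NucleotideSearcher] = None
    pending: list[SeqRecord] = []

    def flush_index() -> None:
        nonlocal searcher, pending
        if pending:
            searcher = NucleotideSearcher(kept)
            pending = []

    for rec in candidates:
        if repeat_fraction(rec.sequence) >= max_repeat_fraction:
            continue
        if rec.sequence in kept_seqs or revcomp(rec.sequence) in kept_seqs:
            continue
        if len(pending) >= 200:
            flush_index()
        duplicate = False
        if searcher is not None:
            for hit in searcher.best_per_subject(rec.sequence):
                if (
                    hit.identity >= dedup_identity
                    and hit.aln_len >= dedup_identity / 100.0 * len(rec)
                ):
                    duplicate = True
                    break
        if not duplicate:
            for prev in pending:
                if rec.sequence in prev.sequence or revcomp(rec.sequence) in prev.sequence:
                    duplicate = True
                    break
        if duplicate:
            continue
        kept.append(rec)
        kept_seqs.add(rec.sequence)
        pending.append(rec)
    if not kept:
        raise ValueError("reference curation removed every sequence")
    return kept


# ---------------------------------------------------------------------------
# quantification

def quantify_cells(
    reads: Sequence[ReadPair], reference: Sequence[SeqRecord]
) -> CellUMITable:
    """UMI counts of all reads against the combined reference.

    A read is assigned to the unique reference sequence containing it
    verbatim on either strand (reads matching several references are
    dropped, mirroring unique-mapping semantics); (barcode, gene, UMI)
    duplicates collapse to one molecule.
    """
    if not reference:
        raise ValueError("empty reference")
    k = 21
    index: dict[str, set[int]] = {}
    for gi, rec in enumerate(reference):
        seq = rec.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], set()).add(gi)
    molecules: set[tuple[str, int, str]] = set()
    for read in reads:
        hits: set[int] = set()
        for seq in (read.cdna, revcomp(read.cdna)):
            if len(seq) < k:
                continue
            for gi in index.get(seq[:k], ()):
                if seq in reference[gi].sequence:
                    hits.add(gi)
        if len(hits) == 1:
            molecules.add((read.barcode, hits.pop(), read.umi))
    barcodes = sorted({r.barcode for r in reads})
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    counts = scipy.sparse.dok_matrix((len(barcodes), len(reference)), dtype=np.int64)
    for bc, gi, _umi in molecules:
        counts[bc_idx[bc], gi] += 1
    return CellUMITable(
        barcodes=barcodes,
        genes=[rec.id for rec in reference],
        sources=[rec.meta.get("source", "custom") for rec in reference],
        counts=counts.tocsr(),
    )


# ---------------------------------------------------------------------------
# normalisation and embedding

def normalize_and_embed(
    table: CellUMITable,
    n_pcs: int = 50,
    n_neighbors: int = 7,
    min_dist: float = 0.4,
    spread: float = 2.0,
    seed: int = 0,
    taxon_labels: Optional[Sequence[str]] = None,
) -> EmbeddingResult:
    """Filter rare genes, normalise, and embed cells in two dimensions.

    Genes present in fewer than 2 cells are dropped; each cell's counts are
    scaled to the median library size and square-root transformed; the
    matrix is reduced to ``n_pcs`` exact-SVD principal components and
    embedded with UMAP under the given neighbourhood parameters. The seed
    fixes both PCA sign conventions and the UMAP layout.
    """
    import umap  # deferred: heavy import

    n_cells = table.n_cells
    if n_cells < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n_cells}"
        )
    X = table.counts.toarray().astype(float)
    present_in = (X > 0).sum(axis=0)
    X = X[:, present_in >= 2]
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cells with zero UMIs must be removed before embedding")
    median = float(np.median(totals))
    X = X / totals[:, None] * median
    X = np.sqrt(X)
    n_comp = int(min(n_pcs, n_cells - 1, X.shape[1]))
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        spread=spread,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(pcs), dtype=float)
    return EmbeddingResult(
        barcodes=list(table.barcodes),
        coords=coords,
        taxon_labels=list(taxon_labels) if taxon_labels is not None else None,
    )


def overlay_infection(
    embedding: EmbeddingResult, viral_umi_table: CellUMITable
) -> EmbeddingResult:
    """Flag embedded cells with >=10 viral UMIs as infected (in place)."""
    totals = dict(
        zip(viral_umi_table.barcodes, viral_umi_table.total_umis().tolist())
    )
    missing = [bc for bc in embedding.barcodes if bc not in totals]
    if missing:
        raise ValueError(f"barcodes missing from viral UMI table: {missing[:3]}...")
    embedding.infected_flags = np.array(
        [totals[bc] >= OVERLAY_MIN_VIRAL_UMIS for bc in embedding.barcodes]
    )
    return embedding


def plot_embedding(embedding: EmbeddingResult, path: str) -> None:
    """Scatter the embedding, colouring by taxon and enlarging infected cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    labels = embedding.taxon_labels or ["cell"] * len(embedding.barcodes)
    infected = (
        embedding.infected_flags
        if embedding.infected_flags is not None
        else np.zeros(len(embedding.barcodes), dtype=bool)
    )
    for label in sorted(set(labels)):
        sel = np.array([l == label for l in labels])
        for inf, size in ((False, 8), (True, 40)):
            pick = sel & (infected == inf)
            if pick.any():
                ax.scatter(
                    embedding.coords[pick, 0],
                    embedding.coords[pick, 1],
                    s=size,
                    label=label if not inf else None,
                    edgecolors="black" if inf else "none",
                    linewidths=0.5,
                )
    ax.legend(markerscale=1.5, fontsize=7, loc="best")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
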