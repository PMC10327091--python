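"""Thresholded best-hit 18S taxonomy with conservative conflict omission.

Each contig is aligned against one or more 18S reference databases at a
strict gate (99% identity, E <= 1e-10, >=100 bp by default); per database
only the top-bitscore passing hit is kept. A contig whose kept hits span
two or more taxonomic groups is *nonspecific*; a cell whose specifically
assigned contigs span two or more groups is conservatively *omitted* —
the signature a barcode doublet leaves. Hits to groups outside the
configured group list are pooled as ``other_eukaryote``.

The rRNA pre-filter used with real data is folded into the alignment
gates: a contig with no passing 18S hit is simply ``unassigned``, which
leads to the identical downstream decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .assembly import Contig, greedy_assemble, trim_reads
from .homology import HomologyHit, NucleotideSearcher
from .io import ReadPair, SeqRecord

__all__ = [
    "TaxonomyCall",
    "DEFAULT_GROUPS",
    "assign_contig_taxon",
    "assign_cell_taxon",
    "identify_pooled_subpopulation",
]

# the taxonomic groups prevalent in the bloom community
DEFAULT_GROUPS = [
    "Bacillariophyta",
    "Prymnesiophyceae",
    "Chrysophyceae",
    "MAST-3",
    "Katablepharidaceae",
    "Pseudofungi",
    "Lobosa",
    "Ciliphora",
    "Dinoflagellata",
    "Cercozoa",
]

OTHER_EUKARYOTE = "other_eukaryote"
NONSPECIFIC = "nonspecific"
OMITTED = "omitted"
UNASSIGNED = "unassigned"
_NON_GROUPS = {NONSPECIFIC, OMITTED, UNASSIGNED}


@dataclass
class TaxonomyCall:
    subject_level: str  # contig | cell
    id: str
    group: str
    evidence: list[HomologyHit] = field(default_factory=list)

    @property
    def is_specific(self) -> bool:
        return self.group not in _NON_GROUPS


Database = Union[Sequence[SeqRecord], NucleotideSearcher]


def _as_searcher(db: Database) -> NucleotideSearcher:
    if isinstance(db, NucleotideSearcher):
        return db
    if not db:
        raise ValueError("empty 18S reference database")
    return NucleotideSearcher(list(db))


def assign_contig_taxon(
    contig: Contig,
    ref_dbs: Sequence[Database],
    min_identity: float = 99.0,
    max_evalue: float = 1e-10,
    min_len: int = 100,
    groups: Optional[Sequence[str]] = None,
    all_hits: bool = False,
) -> TaxonomyCall:
    """Best-hit group call for one contig.

    Per database the single top-bitscore hit passing all three gates is
    kept (``all_hits=True`` instead considers every passing hit, the
    stricter reading of multi-group matching). Kept hits agreeing on one
    group give that group; groups outside ``groups`` map to
    ``other_eukaryote``; disagreement gives ``nonspecific``; no passing hit
    gives ``unassigned``.
    """
    if not ref_dbs:
        raise ValueError("no reference databases supplied")
    groups = list(groups) if groups is not None else DEFAULT_GROUPS
    kept: list[HomologyHit] = []
    for db in ref_dbs:
        searcher = _as_searcher(db)
        hits = searcher.search(
            contig.sequence, min_identity, max_evalue, min_len, query_id=contig.contig_id
        )
        if not hits:
            continue
        kept.extend(hits if all_hits else hits[:1])
    if not kept:
        return TaxonomyCall("contig", contig.contig_id, UNASSIGNED)
    raw_groups = {h.group_label for h in kept}
    if len(raw_groups) > 1:
        return TaxonomyCall("contig", contig.contig_id, NONSPECIFIC, kept)
    (raw,) = raw_groups
    group = raw if raw in groups else OTHER_EUKARYOTE
    return TaxonomyCall("contig", contig.contig_id, group, kept)


def assign_cell_taxon(
    contig_calls: Sequence[TaxonomyCall], cell_id: str = ""
) -> TaxonomyCall:
    """Cell-level group from its contig calls.

    Nonspecific and unassigned contigs are ignored; among the rest, zero
    distinct groups gives ``unassigned``, one gives that group
    (``other_eukaryote`` counts as a group), and two or more give
    ``omitted`` — a cell transcribing 18S from multiple groups is dropped
    rather than guessed at.
    """
    specific = [c for c in contig_calls if c.is_specific]
    cell_groups = sorted({c.group for c in specific})
    evidence = [h for c in specific for h in c.evidence]
    if not cell_id and contig_calls:
        cell_id = contig_calls[0].id.rsplit("_c", 1)[0]
    if not cell_groups:
        return TaxonomyCall("cell", cell_id, UNASSIGNED)
    if len(cell_groups) == 1:
        return TaxonomyCall("cell", cell_id, cell_groups[0], evidence)
    return TaxonomyCall("cell", cell_id, OMITTED, evidence)


def identify_pooled_subpopulation(
    cells: Sequence[str],
    reads: Sequence[ReadPair],
    ref_db: Database,
    min_identity: float = 90.0,
    max_evalue: float = 1e-10,
    min_len: int = 100,
    min_overlap: int = 21,
) -> pd.DataFrame:
    """Joint assembly of a cell subpopulation with relaxed-identity search.

    Reads from every listed barcode are pooled, trimmed and assembled
    together — the deeper pooled coverage resolves subpopulations too rare
    for reliable per-cell assembly — then contigs are aligned at a relaxed
    identity gate (90% by default). Returns one row per reference species
    (``species`` metadata, falling back to the subject id) with the best
    identity, best bitscore and number of supporting contigs, ranked by
    identity.
    """
    if not cells:
        raise ValueError("empty cell set")
    cellset = set(cells)
    pooled = [r for r in reads if r.barcode in cellset]
    contigs = greedy_assemble(trim_reads(pooled), min_overlap, barcode="pooled")
    contigs = [c for c in contigs if c.length >= min_len]
    columns = ["species", "best_identity", "best_bitscore", "n_contigs"]
    if not contigs:
        warnings.warn("no contigs of sufficient length; empty species table")
        return pd.DataFrame(columns=columns)
    searcher = _as_searcher(ref_db)
    by_subject = {r.id: r for r in searcher.db}
    rows: dict[str, dict] = {}
    for contig in contigs:
        hits = searcher.search(
            contig.sequence, min_identity, max_evalue, min_len, query_id=contig.contig_id
        )
        if not hits:
            continue
        best = hits[0]
        rec = by_subject[best.subject_id]
        species = rec.meta.get("species", rec.id)
        row = rows.setdefault(
            species,
            {"species": species, "best_identity": 0.0, "best_bitscore": 0.0, "n_contigs": 0},
        )
        row["best_identity"] = max(row["best_identity"], best.identity)
        row["best_bitscore"] = max(row["best_bitscore"], best.bit_score)
        row["n_contigs"] += 1
    if not rows:
        warnings.warn("no contig passed the relaxed identity gate")
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows.values(), columns=columns)
    return table.sort_values(
        ["best_identity", "best_bitscore", "species"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
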