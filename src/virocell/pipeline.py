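"""End-to-end orchestration: screen -> assemble -> assign -> pair.

One translated search pass over all reads serves both UMI counting
(infection calling) and family profiling (pairing); per-cell assembly and
18S taxonomy are run for the highly-infected cells, as in the original
workflow, or for every cell on request (doublet/conflict analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .assembly import greedy_assemble, trim_reads
from .homology import NucleotideSearcher, ProteinSearcher, DEFAULT_MIN_AA_SCORE
from .io import ReadPair
from .pairing import ViralProfile, build_pair_table
from .screen import CellUMITable, InfectionCall, call_highly_infected, count_viral_umis
from .simulate import ReferenceSet
from .taxonomy import TaxonomyCall, assign_cell_taxon, assign_contig_taxon

__all__ = ["PipelineResult", "run_pair_pipeline", "assign_cells_taxonomy"]


@dataclass
class PipelineResult:
    viral_umis: CellUMITable
    calls: list[InfectionCall]
    profiles: dict[str, ViralProfile]
    host_calls: dict[str, TaxonomyCall]
    dominant_barcodes: list[str]
    other_barcodes: list[str]
    pairs: pd.DataFrame
    summary: pd.DataFrame
    contigs_by_cell: dict[str, list] = field(default_factory=dict)

    @property
    def highly_infected_barcodes(self) -> list[str]:
        return [c.barcode for c in self.calls if c.highly_infected]

    def recovered_pairs(self) -> set[tuple[str, str]]:
        """Distinct (host group, family) pairs in the summary table."""
        return set(zip(self.summary["host_group"], self.summary["family"]))


def assign_cells_taxonomy(
    reads_by_barcode: dict[str, list[ReadPair]],
    barcodes: Sequence[str],
    ref_dbs: Sequence,
    groups: Optional[Sequence[str]] = None,
    min_identity: float = 99.0,
    max_evalue: float = 1e-10,
    min_len: int = 100,
    min_overlap: int = 21,
) -> tuple[dict[str, TaxonomyCall], dict[str, list]]:
    """Per-cell assembly and 18S best-hit taxonomy for the given barcodes."""
    searchers = [
        db if isinstance(db, NucleotideSearcher) else NucleotideSearcher(list(db))
        for db in ref_dbs
    ]
    host_calls: dict[str, TaxonomyCall] = {}
    contigs_by_cell: dict[str, list] = {}
    for bc in barcodes:
        cell_reads = reads_by_barcode.get(bc, [])
        contigs = greedy_assemble(cell_reads, min_overlap, barcode=bc)
        contigs = [c for c in contigs if c.length >= min_len]
        contigs_by_cell[bc] = contigs
        contig_calls = [
            assign_contig_taxon(
                c, searchers, min_identity, max_evalue, min_len, groups=groups
            )
            for c in contigs
        ]
        host_calls[bc] = assign_cell_taxon(contig_calls, cell_id=bc)
    return host_calls, contigs_by_cell


def run_pair_pipeline(
    reads: Sequence[ReadPair],
    refs: ReferenceSet,
    dominant_family: Optional[str] = None,
    groups: Optional[Sequence[str]] = None,
    min_aa_score: int = DEFAULT_MIN_AA_SCORE,
    assign_all_cells: bool = False,
) -> PipelineResult:
    """Full host-virus pairing analysis of one experiment.

    ``groups`` defaults to the taxa named in the 18S reference; pass
    ``assign_all_cells=True`` to run assembly/taxonomy on every barcode
    (needed when studying the conflict-omission rule itself).
    """
    trimmed = trim_reads(reads)
    if groups is None:
        groups = sorted({r.meta["group"] for r in refs.host_18s if "group" in r.meta})

    searcher = ProteinSearcher(refs.viral_proteins, min_aa_score=min_aa_score)
    assignments = searcher.analyze_reads([r.cdna for r in trimmed])

    viral_umis = count_viral_umis(
        trimmed,
        refs.viral_proteins,
        assignments=[
            (a.gene, a.family) if a is not None and a.gene is not None else None
            for a in assignments
        ],
    )
    calls = call_highly_infected(viral_umis)

    family_counts: dict[str, dict[str, int]] = {}
    for read, a in zip(trimmed, assignments):
        if a is None:
            continue
        fam = family_counts.setdefault(read.barcode, {})
        fam[a.family] = fam.get(a.family, 0) + 1
    profiles = {
        bc: ViralProfile(barcode=bc, family_read_counts=counts)
        for bc, counts in family_counts.items()
    }

    dominant, other = [], []
    for call in calls:
        if not call.highly_infected:
            continue
        profile = profiles.get(call.barcode)
        if profile is not None and profile.argmax_family == dominant_family:
            dominant.append(call.barcode)
        else:
            other.append(call.barcode)

    reads_by_barcode: dict[str, list[ReadPair]] = {}
    for r in trimmed:
        reads_by_barcode.setdefault(r.barcode, []).append(r)
    targets = (
        sorted(reads_by_barcode)
        if assign_all_cells
        else [c.barcode for c in calls if c.highly_infected]
    )
    host_calls, contigs_by_cell = assign_cells_taxonomy(
        reads_by_barcode, targets, [refs.host_18s], groups=groups
    )

    pairs, summary = build_pair_table(calls, profiles, host_calls, dominant_family)
    return PipelineResult(
        viral_umis=viral_umis,
        calls=calls,
        profiles=profiles,
        host_calls=host_calls,
        dominant_barcodes=dominant,
        other_barcodes=other,
        pairs=pairs,
        summary=summary,
        contigs_by_cell=contigs_by_cell,
    )
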