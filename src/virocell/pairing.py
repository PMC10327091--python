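"""Host-virus link classification from per-cell viral family profiles.

Infection calling uses UMIs, but pairing uses raw reads: each read of an
infected cell is compared to the labelled viral protein database and its
best match contributes one count to that protein's family. A cell enters
the pair table only when its host taxonomy is specific and its best family
holds at least 10 reads; links representing at least 10% of the cell's
viral reads are reported, and a link is *unambiguous* when one family
holds at least 90% of them. Cells whose best family is the dominant,
already-characterised virus are excluded so rarer pairs become visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .homology import ProteinSearcher, DEFAULT_MIN_AA_SCORE
from .io import ReadPair, SeqRecord
from .screen import CellUMITable, InfectionCall
from .taxonomy import TaxonomyCall

__all__ = [
    "ViralProfile",
    "HostVirusLink",
    "viral_read_profile",
    "profile_from_counts",
    "classify_links",
    "build_pair_table",
    "viral_gene_expression",
]

MIN_FAMILY_READS = 10
MIN_LINK_FRACTION = 0.10
UNAMBIGUOUS_FRACTION = 0.90


@dataclass
class ViralProfile:
    """Per-cell viral read counts by family."""

    barcode: str
    family_read_counts: dict[str, int]
    total_viral_reads: int = 0
    fractions: dict[str, float] = field(default_factory=dict)
    argmax_family: Optional[str] = None

    def __post_init__(self) -> None:
        self.total_viral_reads = sum(self.family_read_counts.values())
        if self.total_viral_reads > 0:
            self.fractions = {
                f: c / self.total_viral_reads
                for f, c in self.family_read_counts.items()
            }
            # ties resolve toward the lexicographically first family
            self.argmax_family = max(
                sorted(self.family_read_counts), key=self.family_read_counts.get
            )
        else:
            self.fractions = {}
            self.argmax_family = None


@dataclass
class HostVirusLink:
    barcode: str
    host_group: str
    family: str
    read_count: int
    fraction: float
    link_class: str  # unambiguous | ambiguous


def profile_from_counts(barcode: str, family_counts: dict[str, int]) -> ViralProfile:
    return ViralProfile(barcode=barcode, family_read_counts=dict(family_counts))


def viral_read_profile(
    reads: Sequence[ReadPair],
    protein_db: Sequence[SeqRecord] | ProteinSearcher,
    min_aa_score: int = DEFAULT_MIN_AA_SCORE,
    barcode: str = "",
) -> ViralProfile:
    """Family profile of one cell's reads via translated best hits.

    Reads without a hit are excluded from the total; each hit read counts
    once toward its best-matching protein's family.
    """
    searcher = (
        protein_db
        if isinstance(protein_db, ProteinSearcher)
        else ProteinSearcher(list(protein_db), min_aa_score=min_aa_score)
    )
    if not barcode:
        barcodes = {r.barcode for r in reads}
        barcode = barcodes.pop() if len(barcodes) == 1 else "pooled"
    counts: dict[str, int] = {}
    mask = searcher.prefilter([r.cdna for r in reads])
    for ri in np.flatnonzero(mask):
        hit = searcher.best_hit(reads[ri].cdna)
        if hit is not None:
            counts[hit.group_label] = counts.get(hit.group_label, 0) + 1
    return ViralProfile(barcode=barcode, family_read_counts=counts)


def classify_links(
    profile: ViralProfile, host_call: TaxonomyCall
) -> list[HostVirusLink]:
    """Reportable links for one cell, empty unless the cell is eligible.

    Eligibility requires a specific host group and >=10 reads in the best
    family; both the 10% display floor and the 90% unambiguity rule are
    inclusive boundaries.
    """
    if not host_call.is_specific:
        return []
    if not profile.family_read_counts:
        return []
    if max(profile.family_read_counts.values()) < MIN_FAMILY_READS:
        return []
    links = []
    for family in sorted(profile.family_read_counts):
        frac = profile.fractions[family]
        if frac + 1e-12 < MIN_LINK_FRACTION:
            continue
        links.append(
            HostVirusLink(
                barcode=profile.barcode,
                host_group=host_call.group,
                family=family,
                read_count=profile.family_read_counts[family],
                fraction=frac,
                link_class=(
                    "unambiguous" if frac + 1e-12 >= UNAMBIGUOUS_FRACTION else "ambiguous"
                ),
            )
        )
    return links


def build_pair_table(
    calls: Sequence[InfectionCall],
    profiles: dict[str, ViralProfile],
    host_calls: dict[str, TaxonomyCall],
    dominant_family: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair table and per-(host, family) summary over highly-infected cells.

    Cells whose best-matching family is ``dominant_family`` are excluded
    before link classification. Rows are ordered by (host group, family,
    barcode); the summary counts cells and link classes per pair.
    """
    link_rows = []
    for call in calls:
        if not call.highly_infected:
            continue
        profile = profiles.get(call.barcode)
        if profile is None:
            continue
        if dominant_family is not None and profile.argmax_family == dominant_family:
            continue
        host = host_calls.get(call.barcode)
        if host is None:
            continue
        for link in classify_links(profile, host):
            link_rows.append(
                {
                    "barcode": link.barcode,
                    "host_group": link.host_group,
                    "family": link.family,
                    "reads": link.read_count,
                    "fraction": link.fraction,
                    "link_class": link.link_class,
                }
            )
    pair_cols = ["barcode", "host_group", "family", "reads", "fraction", "link_class"]
    pairs = pd.DataFrame(link_rows, columns=pair_cols)
    pairs = pairs.sort_values(["host_group", "family", "barcode"]).reset_index(drop=True)
    if len(pairs):
        summary = (
            pairs.groupby(["host_group", "family"])
            .agg(
                n_cells=("barcode", "nunique"),
                n_unambiguous=("link_class", lambda s: int((s == "unambiguous").sum())),
                n_ambiguous=("link_class", lambda s: int((s == "ambiguous").sum())),
            )
            .reset_index()
            .sort_values(["host_group", "family"])
            .reset_index(drop=True)
        )
    else:
        summary = pd.DataFrame(
            columns=["host_group", "family", "n_cells", "n_unambiguous", "n_ambiguous"]
        )
    return pairs, summary


def viral_gene_expression(
    table: CellUMITable,
    cells: Sequence[str],
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Summed per-gene viral UMIs over the listed cells, log2(count+1).

    Mirrors an expected-count expression summary for the genes of a paired
    virus; UMI sums stand in for expected counts here, with a +1
    pseudocount before the log so unexpressed genes report 0.
    """
    cellset = set(cells)
    idx = [i for i, bc in enumerate(table.barcodes) if bc in cellset]
    if genes is None:
        gene_idx = list(range(len(table.genes)))
    else:
        wanted = set(genes)
        gene_idx = [j for j, g in enumerate(table.genes) if g in wanted]
    sub = table.counts[idx, :][:, gene_idx]
    sums = np.asarray(sub.sum(axis=0)).ravel()
    out = pd.DataFrame(
        {
            "gene": [table.genes[j] for j in gene_idx],
            "total_umis": sums.astype(int),
            "log2_expression": np.log2(sums + 1.0),
        }
    )
    return out.sort_values(
        ["log2_expression", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
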