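"""Bloom dynamics: relative abundance, infected fraction, demise report.

Relative abundance is computed per taxon as its fraction of all amplicon
sequence variants excluding metazoans. The demise report links the focal
taxon's abundance trajectory to its infection level: it finds the peak
day, the first post-peak day at which abundance has at least halved, and
the sampled day of maximum infected fraction, and flags the series as
*infection-associated demise* when peak infection falls inside the
peak-to-decline window. The flag is an explicit operationalisation of a
qualitative pattern and is labelled as such in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .screen import InfectionCall
from .taxonomy import TaxonomyCall

__all__ = [
    "AbundanceSeries",
    "DemiseReport",
    "relative_abundance",
    "infected_fraction",
    "demise_report",
]

DEFAULT_EXCLUDE = frozenset({"Metazoa"})


@dataclass
class AbundanceSeries:
    """Per-day relative abundances (metazoans excluded) for one focal taxon."""

    days: list[int]
    fractions: pd.DataFrame  # index day, columns taxa, rows sum to 1
    focal_taxon: str
    infected_fraction_per_day: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if ((self.fractions < -1e-12).any().any()) or (abs(sums - 1.0) > 1e-9).any():
            raise ValueError("per-day fractions must lie in [0,1] and sum to 1")
        if self.focal_taxon not in self.fractions.columns:
            raise ValueError(f"focal taxon {self.focal_taxon} absent from table")

    def focal(self) -> pd.Series:
        return self.fractions[self.focal_taxon]


def relative_abundance(
    asv_table: pd.DataFrame,
    exclude_taxa: Sequence[str] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """Per-day taxon fractions from a long ASV table (day, taxon, count).

    Counts of excluded taxa (metazoans by default) are removed from both
    numerator and denominator. A day whose counts are entirely excluded is
    an error naming the day.
    """
    if (asv_table["count"] < 0).any():
        raise ValueError("negative ASV counts")
    excl = set(exclude_taxa)
    kept = asv_table[~asv_table["taxon"].isin(excl)]
    wide = kept.pivot_table(
        index="day", columns="taxon", values="count", aggfunc="sum", fill_value=0
    ).astype(float)
    for day in sorted(asv_table["day"].unique()):
        if day not in wide.index or wide.loc[day].sum() == 0:
            raise ValueError(f"day {day}: no non-excluded ASV counts")
    return wide.div(wide.sum(axis=1), axis=0)


def infected_fraction(
    calls: Sequence[InfectionCall],
    host_calls: dict[str, TaxonomyCall],
    focal_group: str,
) -> tuple[float, int, int]:
    """(fraction, n_infected, n_focal) of highly-infected cells within the
    focal group in one sample. With zero focal cells the fraction is 0 and
    n_focal reports 0."""
    focal_barcodes = {
        bc for bc, call in host_calls.items() if call.group == focal_group
    }
    n_focal = len(focal_barcodes)
    n_infected = sum(
        1 for c in calls if c.highly_infected and c.barcode in focal_barcodes
    )
    fraction = n_infected / n_focal if n_focal else 0.0
    return fraction, n_infected, n_focal


@dataclass
class DemiseReport:
    focal_taxon: str
    peak_day: int
    peak_fraction: float
    decline_day: Optional[int]
    max_infection_day: Optional[int]
    max_infection_fraction: Optional[float]
    infection_associated_demise: bool
    note: str = (
        "flag is an explicit operationalisation: peak infection sampled "
        "within [peak day, first day at <= half of peak abundance]"
    )


def demise_report(
    series: AbundanceSeries, decline_ratio: float = 0.5
) -> DemiseReport:
    """Peak, decline and infection timing of the focal taxon.

    Peak day is the abundance argmax (earliest on ties); the decline day is
    the first later day with abundance <= ``decline_ratio`` times the peak
    (None for a monotone series); infection is evaluated on the sampled
    days only. The demise flag requires the max-infection day to lie inside
    the closed [peak, decline] window.
    """
    if len(series.days) < 3:
        raise ValueError("need at least 3 days")
    focal = series.focal()
    peak_day = int(focal.idxmax())
    peak_fraction = float(focal.loc[peak_day])
    decline_day = None
    for day in [d for d in series.days if d > peak_day]:
        if focal.loc[day] <= decline_ratio * peak_fraction:
            decline_day = int(day)
            break
    inf = series.infected_fraction_per_day
    if inf:
        max_infection_day = max(sorted(inf), key=inf.get)
        max_infection_fraction = inf[max_infection_day]
    else:
        max_infection_day = None
        max_infection_fraction = None
    flagged = (
        decline_day is not None
        and max_infection_day is not None
        and peak_day <= max_infection_day <= decline_day
    )
    return DemiseReport(
        focal_taxon=series.focal_taxon,
        peak_day=peak_day,
        peak_fraction=peak_fraction,
        decline_day=decline_day,
        max_infection_day=max_infection_day,
        max_infection_fraction=max_infection_fraction,
        infection_associated_demise=flagged,
    )
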