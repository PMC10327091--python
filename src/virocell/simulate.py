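"""Synthetic plankton-community scRNA-seq generator with planted infections.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-taxon protist community with one dominant bloomer and rare
classes, per-cell infection by labelled giant-virus families at configurable
expression levels, ambient (free-virion / ingestion-derived) viral
background, barcode doublets, and a bloom time series in which an infected
rare class rises and crashes.

Sequences evolve by per-site substitution from independent random ancestors
(no indels), which keeps the ungapped aligner exact and the identity bands
controllable. Reads are error-free 60-mer substrings with uniform start;
each molecule receives a distinct UMI within its barcode.

One integer seed reproduces references, reads and tables bit-exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .homology import _CODON_AA, _AA_STOP, AA_ALPHABET, global_identity
from .io import BARCODE_LEN, CDNA_LEN, UMI_LEN, ReadPair, SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityConfig",
    "InfectionEntry",
    "ReferenceSet",
    "GroundTruth",
    "Trajectory",
    "default_config",
    "bloom_trajectory",
    "simulate_references",
    "simulate_experiment",
    "simulate_timeseries",
]

_BASES = np.array(list("ACGT"))

# marker-gene name pool: polymerase, capsid, topoisomerase plus chaperone analogs
MARKER_GENE_POOL = ["PolB", "MCP", "TopoII", "HSP70", "HSP90", "RNAPL", "VLTF3", "ATPase"]

DEFAULT_TAXA = {
    "Prymnesiophyceae": 0.60,  # the dominant bloomer (E. huxleyi analog)
    "Bacillariophyta": 0.15,
    "Dinoflagellata": 0.12,
    "Chrysophyceae": 0.08,
    "Cercozoa": 0.046,
    "Katablepharidaceae": 0.004,  # rare class, <0.5% of cells
}

DEFAULT_FAMILIES = ["Coccolithoviridae", "IM_01", "IM_07", "IM_16"]


@dataclass(frozen=True)
class InfectionEntry:
    taxon: str
    family: str
    fraction_infected: float
    expression_fraction: float


# planted infections: the dominant taxon is mostly hit by the dominant
# (coccolithovirus-analog) family; rarer taxa carry the Imitervirales-like
# families, with the rare class fully infected at elevated expression.
DEFAULT_INFECTIONS = [
    InfectionEntry("Prymnesiophyceae", "Coccolithoviridae", 0.30, 0.06),
    InfectionEntry("Prymnesiophyceae", "IM_01", 0.05, 0.06),
    InfectionEntry("Prymnesiophyceae", "IM_07", 0.03, 0.06),
    InfectionEntry("Bacillariophyta", "IM_01", 0.20, 0.06),
    InfectionEntry("Bacillariophyta", "IM_16", 0.10, 0.06),
    InfectionEntry("Dinoflagellata", "IM_07", 0.15, 0.06),
    InfectionEntry("Dinoflagellata", "IM_16", 0.10, 0.06),
    InfectionEntry("Chrysophyceae", "IM_01", 0.25, 0.06),
    InfectionEntry("Chrysophyceae", "IM_07", 0.15, 0.06),
    InfectionEntry("Cercozoa", "IM_01", 0.20, 0.06),
    InfectionEntry("Cercozoa", "IM_16", 0.20, 0.06),
    InfectionEntry("Katablepharidaceae", "IM_07", 1.00, 0.08),
]


@dataclass
class CommunityConfig:
    """Study conditions for the synthetic community.

    ``reads_per_cell`` is either ``("lognormal", median, sigma)`` or
    ``("fixed", n)``. ``rrna_share`` is the fraction of each cell's reads
    drawn from its own 18S analog so that per-cell taxonomy is assemblable
    from 60-mers. ``marker_gene_weights`` optionally skews which marker
    genes an infected cell expresses (default uniform).
    """

    taxon_names: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    taxon_cell_fractions: list[float] = field(
        default_factory=lambda: list(DEFAULT_TAXA.values())
    )
    dominant_taxon: str = "Prymnesiophyceae"
    dominant_family: str = "Coccolithoviridae"
    family_names: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    marker_genes_per_family: int = 5
    infection_table: list[InfectionEntry] = field(
        default_factory=lambda: list(DEFAULT_INFECTIONS)
    )
    ambient_viral_rate: float = 0.003
    doublet_rate: float = 0.02
    n_cells: int = 500
    reads_per_cell: tuple = ("lognormal", 1200, 0.2)
    rrna_share: float = 0.04
    mrna_per_taxon: int = 20
    n_18s_variants: int = 2
    marker_gene_weights: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.taxon_cell_fractions, dtype=float)
        if len(fr) != len(self.taxon_names):
            raise ValueError("taxon_names and taxon_cell_fractions differ in length")
        if ((fr < 0) | (fr > 1)).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("taxon cell fractions must lie in [0,1] and sum to 1")
        if self.marker_genes_per_family < 4:
            raise ValueError("need at least 4 marker genes per family")
        if self.marker_genes_per_family > len(MARKER_GENE_POOL):
            raise ValueError(f"at most {len(MARKER_GENE_POOL)} marker genes supported")
        if not 0 <= self.ambient_viral_rate < 1 or not 0 <= self.doublet_rate < 1:
            raise ValueError("rates must lie in [0,1)")
        per_taxon: dict[str, float] = {}
        for e in self.infection_table:
            if e.taxon not in self.taxon_names:
                raise ValueError(f"infection entry names unknown taxon {e.taxon}")
            if e.family not in self.family_names:
                raise ValueError(f"infection entry names unknown family {e.family}")
            if not 0 <= e.fraction_infected <= 1 or not 0 < e.expression_fraction < 1:
                raise ValueError("infection fractions must lie in [0,1]")
            per_taxon[e.taxon] = per_taxon.get(e.taxon, 0.0) + e.fraction_infected
        for taxon, tot in per_taxon.items():
            if tot > 1 + 1e-9:
                raise ValueError(f"infected fractions for {taxon} sum to {tot} > 1")

    @property
    def taxon_fraction(self) -> dict[str, float]:
        return dict(zip(self.taxon_names, self.taxon_cell_fractions))


def default_config(**overrides) -> CommunityConfig:
    """The default study conditions; keyword overrides replace fields."""
    return CommunityConfig(**overrides)


@dataclass
class ReferenceSet:
    """Labelled FASTA collections produced by :func:`simulate_references`."""

    host_18s: list[SeqRecord]
    host_mrna: list[SeqRecord]
    viral_genes: list[SeqRecord]
    viral_proteins: list[SeqRecord]

    def mrna_by_taxon(self, taxon: str) -> list[SeqRecord]:
        return [r for r in self.host_mrna if r.meta["group"] == taxon]

    def r18s_by_taxon(self, taxon: str) -> list[SeqRecord]:
        return [r for r in self.host_18s if r.meta["group"] == taxon]

    def genes_by_family(self, family: str) -> list[SeqRecord]:
        return [r for r in self.viral_genes if r.meta["family"] == family]


@dataclass
class GroundTruth:
    """Per-cell planted truth; ``day_composition`` is set in time-series mode."""

    cells: pd.DataFrame
    day_composition: Optional[pd.DataFrame] = None

    @property
    def barcodes(self) -> list[str]:
        return list(self.cells["barcode"])

    def infected_pairs(self, exclude_family: Optional[str] = None) -> set[tuple[str, str]]:
        """Realized planted (taxon, family) pairs among non-doublet infected cells."""
        df = self.cells
        sel = df["infected"] & ~df["doublet"]
        if exclude_family is not None:
            sel &= df["family"] != exclude_family
        return set(zip(df.loc[sel, "taxon"], df.loc[sel, "family"]))


# ---------------------------------------------------------------------------
# reference simulation

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


_NONSTOP_CODONS = [
    i for i in range(64) if _CODON_AA[i] != _AA_STOP
]


def _codon_str(idx: int) -> str:
    return "ACGT"[idx // 16] + "ACGT"[(idx // 4) % 4] + "ACGT"[idx % 4]


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    picks = rng.integers(0, len(_NONSTOP_CODONS), n_codons)
    return "".join(_codon_str(_NONSTOP_CODONS[i]) for i in picks)


def _translate0(gene: str) -> str:
    codes = np.array(
        ["ACGT".index(b) for b in gene[: len(gene) // 3 * 3]], dtype=np.int64
    ).reshape(-1, 3)
    idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
    return "".join(AA_ALPHABET[a] for a in _CODON_AA[idx])


def simulate_references(config: CommunityConfig) -> ReferenceSet:
    """Generate 18S, mRNA and viral marker references under the config seed.

    Per taxon: one 1800-nt 18S analog in ``n_18s_variants`` copies that are
    >=99% identical to each other, plus ``mrna_per_taxon`` transcripts of
    300-2000 nt. Distinct taxa (and distinct viral families) descend from
    independent random ancestors, so cross-taxon 18S identity and
    cross-family protein identity sit far below the 90% / 60% ceilings.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    host_18s: list[SeqRecord] = []
    host_mrna: list[SeqRecord] = []
    base_18s: dict[str, str] = {}
    for taxon in config.taxon_names:
        base = _random_seq(rng, 1800)
        base_18s[taxon] = base
        for other, oseq in base_18s.items():
            if other != taxon and global_identity(base, oseq) >= 90.0:
                raise ValueError(
                    "could not keep cross-taxon 18S identity below 90%; "
                    "try fewer taxa"
                )
        species = f"{taxon}_sp1"
        for v in range(1, config.n_18s_variants + 1):
            var = _mutate(rng, base, 0.003)
            if global_identity(var, base) < 99.0:
                raise ValueError("18S variant drifted below 99% identity")
            host_18s.append(
                SeqRecord(
                    id=f"18S_{taxon}_v{v}",
                    sequence=var,
                    description=f"group={taxon} species={species}",
                )
            )
        for j in range(config.mrna_per_taxon):
            length = int(rng.integers(300, 2001))
            host_mrna.append(
                SeqRecord(
                    id=f"mRNA_{taxon}_{j:03d}",
                    sequence=_random_seq(rng, length),
                    description=f"group={taxon}",
                )
            )

    viral_genes: list[SeqRecord] = []
    viral_proteins: list[SeqRecord] = []
    gene_names = MARKER_GENE_POOL[: config.marker_genes_per_family]
    proteins_by_family: dict[str, list[str]] = {}
    for family in config.family_names:
        proteins_by_family[family] = []
        for gene in gene_names:
            nt = _random_gene(rng, int(rng.integers(200, 401)))
            prot = _translate0(nt)
            for other, plist in proteins_by_family.items():
                if other == family:
                    continue
                for p in plist:
                    n = min(len(p), len(prot))
                    ident = 100.0 * sum(
                        a == b for a, b in zip(p[:n], prot[:n])
                    ) / n
                    if ident >= 60.0:
                        raise ValueError(
                            "cross-family protein identity reached 60%; "
                            "try fewer families"
                        )
            proteins_by_family[family].append(prot)
            meta = f"gene={gene} family={family} virus=GV_{family}"
            viral_genes.append(
                SeqRecord(id=f"{family}_{gene}", sequence=nt, description=meta)
            )
            viral_proteins.append(
                SeqRecord(id=f"{family}_{gene}", sequence=prot, description=meta)
            )
    return ReferenceSet(host_18s, host_mrna, viral_genes, viral_proteins)


# ---------------------------------------------------------------------------
# experiment simulation

def _make_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(_BASES[rng.integers(0, 4, BARCODE_LEN)])
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _umi_strings(rng: np.random.Generator, n: int, used: set[int]) -> list[str]:
    """n distinct UMIs (as 12-mers) not colliding with ``used`` (per barcode)."""
    out: list[int] = []
    while len(out) < n:
        draw = rng.integers(0, 4**UMI_LEN, n - len(out))
        for v in draw:
            v = int(v)
            if v not in used:
                used.add(v)
                out.append(v)
    strings = []
    for v in out:
        chars = []
        for _ in range(UMI_LEN):
            chars.append("ACGT"[v & 3])
            v >>= 2
        strings.append("".join(chars))
    return strings


def _draw_reads_per_cell(rng: np.random.Generator, config: CommunityConfig) -> int:
    kind = config.reads_per_cell[0]
    if kind == "fixed":
        return int(config.reads_per_cell[1])
    if kind == "lognormal":
        _, median, sigma = config.reads_per_cell
        return max(60, int(round(float(rng.lognormal(np.log(median), sigma)))))
    raise ValueError(f"unknown reads_per_cell spec {config.reads_per_cell!r}")


class _Sampler:
    """Uniform 60-mer sampler over a transcript set (transcripts >=60 nt)."""

    def __init__(self, records: Sequence[SeqRecord], weights=None):
        usable = []
        w = []
        for i, r in enumerate(records):
            if len(r) < CDNA_LEN:
                logger.warning("transcript %s shorter than %d nt; excluded", r.id, CDNA_LEN)
                continue
            usable.append(r)
            w.append(1.0 if weights is None else weights[i])
        if not usable:
            raise ValueError("no transcript long enough to sample reads from")
        self.records = usable
        self.p = np.asarray(w) / np.sum(w)
        self.span = np.array([len(r) - CDNA_LEN + 1 for r in usable])

    def draw(self, rng: np.random.Generator, n: int) -> list[str]:
        idx = rng.choice(len(self.records), size=n, p=self.p)
        starts = (rng.random(n) * self.span[idx]).astype(np.int64)
        return [
            self.records[i].sequence[s : s + CDNA_LEN]
            for i, s in zip(idx, starts)
        ]


def _constituent(rng: np.random.Generator, config: CommunityConfig):
    """Draw (taxon, infection entry or None) for one cell constituent."""
    taxon = rng.choice(config.taxon_names, p=np.asarray(config.taxon_cell_fractions))
    entries = [e for e in config.infection_table if e.taxon == taxon]
    u = rng.random()
    acc = 0.0
    for e in entries:
        acc += e.fraction_infected
        if u < acc:
            return str(taxon), e
    return str(taxon), None


def simulate_experiment(
    refs: ReferenceSet, config: CommunityConfig
) -> tuple[list[ReadPair], GroundTruth]:
    """Generate barcoded reads and per-cell ground truth.

    An infected constituent devotes ``expression_fraction`` of its reads to
    its family's marker genes; every constituent devotes ``rrna_share`` to
    its own 18S and the remainder to host mRNA; uninfected constituents
    replace ``ambient_viral_rate`` of their reads with ambient viral reads
    from random families. Doublet barcodes merge two independently drawn
    constituents. ``true_viral_umis`` counts every viral-origin molecule
    (planted plus ambient).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_cells
    barcodes = _make_barcodes(rng, n)
    n_doublets = int(round(config.doublet_rate * n))
    doublet_idx = set(
        rng.choice(n, size=n_doublets, replace=False).tolist() if n_doublets else []
    )

    mrna_samplers = {t: _Sampler(refs.mrna_by_taxon(t)) for t in config.taxon_names}
    r18s = {t: refs.r18s_by_taxon(t) for t in config.taxon_names}
    gene_weights = None
    if config.marker_gene_weights:
        gene_weights = config.marker_gene_weights
    viral_samplers = {}
    for fam in config.family_names:
        genes = refs.genes_by_family(fam)
        w = None
        if gene_weights is not None:
            w = [gene_weights.get(g.meta["gene"], 1.0) for g in genes]
        viral_samplers[fam] = _Sampler(genes, w)
    all_viral = _Sampler(refs.viral_genes)

    reads: list[ReadPair] = []
    rows = []
    read_no = 0
    for ci in range(n):
        bc = barcodes[ci]
        is_doublet = ci in doublet_idx
        constituents = [_constituent(rng, config) for _ in range(2 if is_doublet else 1)]
        used_umis: set[int] = set()
        cell_viral = 0
        cell_reads = 0
        cdnas: list[str] = []
        for taxon, entry in constituents:
            r = _draw_reads_per_cell(rng, config)
            cell_reads += r
            p_rrna = config.rrna_share
            if entry is not None:
                p_v = entry.expression_fraction
                counts = rng.multinomial(r, [p_v, p_rrna, 1.0 - p_v - p_rrna])
                n_viral, n_rrna, n_mrna = map(int, counts)
                cdnas.extend(viral_samplers[entry.family].draw(rng, n_viral))
            else:
                p_v = config.ambient_viral_rate
                counts = rng.multinomial(r, [p_v, p_rrna, 1.0 - p_v - p_rrna])
                n_viral, n_rrna, n_mrna = map(int, counts)
                cdnas.extend(all_viral.draw(rng, n_viral))
            cell_viral += n_viral
            variants = r18s[taxon]
            variant = variants[rng.integers(0, len(variants))]
            vs = variant.sequence
            starts = (rng.random(n_rrna) * (len(vs) - CDNA_LEN + 1)).astype(np.int64)
            cdnas.extend(vs[s : s + CDNA_LEN] for s in starts)
            cdnas.extend(mrna_samplers[taxon].draw(rng, n_mrna))
        umis = _umi_strings(rng, len(cdnas), used_umis)
        for cdna, umi in zip(cdnas, umis):
            reads.append(
                ReadPair(barcode=bc, umi=umi, cdna=cdna, read_id=f"r{read_no:08d}")
            )
            read_no += 1
        (taxon1, entry1) = constituents[0]
        taxon2 = constituents[1][0] if is_doublet else ""
        infecting = [e for _, e in constituents if e is not None]
        rows.append(
            {
                "barcode": bc,
                "taxon": taxon1,
                "taxon2": taxon2,
                "infected": bool(infecting),
                "family": infecting[0].family if infecting else "",
                "doublet": is_doublet,
                "true_viral_umis": cell_viral,
                "n_reads": cell_reads,
            }
        )
    truth = GroundTruth(cells=pd.DataFrame(rows))
    return reads, truth


# ---------------------------------------------------------------------------
# time series

@dataclass
class Trajectory:
    """Per-day community fractions (including a Metazoa pseudo-taxon) and the
    focal taxon's per-day infected fraction; ``sc_days`` lists the days on
    which single-cell experiments are sampled."""

    days: list[int]
    fractions: dict[int, dict[str, float]]
    focal_taxon: str
    infected_fraction: dict[int, float]
    sc_days: list[int]

    def __post_init__(self) -> None:
        for day in self.days:
            fr = self.fractions[day]
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"day {day}: fractions sum to {total}, not 1")


def bloom_trajectory(
    config: Optional[CommunityConfig] = None,
    metazoan_fraction: float = 0.30,
) -> Trajectory:
    """A rare-class bloom-and-crash: the focal taxon rises 1% -> 6% -> 1%
    while its infected fraction peaks at 86% one day after peak abundance."""
    config = config or default_config()
    focal = "Katablepharidaceae"
    days = list(range(13, 24))
    focal_frac = {
        13: 0.01, 14: 0.01, 15: 0.01, 16: 0.02, 17: 0.03, 18: 0.045,
        19: 0.06, 20: 0.03, 21: 0.01, 22: 0.01, 23: 0.01,
    }
    others = [t for t in config.taxon_names if t != focal]
    base = np.array([config.taxon_fraction[t] for t in others])
    base = base / base.sum()
    fractions = {}
    for day in days:
        rest = 1.0 - metazoan_fraction - focal_frac[day] * (1.0 - metazoan_fraction)
        day_fr = {"Metazoa": metazoan_fraction, focal: focal_frac[day] * (1.0 - metazoan_fraction)}
        for t, b in zip(others, base):
            day_fr[t] = rest * b
        fractions[day] = day_fr
    infected = {13: 0.0, 15: 0.10, 19: 0.50, 20: 0.86}
    return Trajectory(
        days=days,
        fractions=fractions,
        focal_taxon=focal,
        infected_fraction=infected,
        sc_days=[13, 15, 19, 20],
    )


def _truth_only_day(
    rng: np.random.Generator,
    config: CommunityConfig,
    taxon_p: dict[str, float],
    focal: str,
    infected_fraction: float,
    n_cells: int,
) -> pd.DataFrame:
    taxa = list(taxon_p)
    p = np.array([taxon_p[t] for t in taxa])
    p = p / p.sum()
    focal_entry = next(
        (e for e in config.infection_table if e.taxon == focal), None
    )
    family = focal_entry.family if focal_entry else "IM_07"
    draws = rng.choice(len(taxa), size=n_cells, p=p)
    rows = []
    for i, ti in enumerate(draws):
        taxon = taxa[ti]
        infected = bool(taxon == focal and rng.random() < infected_fraction)
        rows.append(
            {
                "barcode": f"cell{i:05d}",
                "taxon": taxon,
                "taxon2": "",
                "infected": infected,
                "family": family if infected else "",
                "doublet": False,
                "true_viral_umis": 0,
                "n_reads": 0,
            }
        )
    return pd.DataFrame(rows)


def simulate_timeseries(
    config: CommunityConfig,
    days: Sequence[int],
    trajectory: Trajectory,
    n_asv_draws: int = 10_000,
    n_sc_cells: int = 300,
    with_reads: bool = False,
):
    """Multinomial ASV tables per day plus per-sampled-day experiments.

    Returns ``(asv_table, experiments)`` where ``asv_table`` has columns
    day/taxon/count (a Metazoa pseudo-taxon included) and ``experiments``
    maps each ``trajectory.sc_days`` day either to a truth-only
    :class:`GroundTruth` (default) or, with ``with_reads=True``, to a
    ``(reads, truth)`` pair from a full experiment whose community
    composition matches that day.
    """
    if list(days) != list(trajectory.days):
        raise ValueError("days do not match the trajectory length")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    for day in days:
        fr = trajectory.fractions[day]
        taxa = list(fr)
        counts = rng.multinomial(n_asv_draws, np.array([fr[t] for t in taxa]))
        for t, c in zip(taxa, counts):
            rows.append({"day": day, "taxon": t, "count": int(c)})
    asv = pd.DataFrame(rows)

    experiments = {}
    for day in trajectory.sc_days:
        inf = trajectory.infected_fraction.get(day, 0.0)
        fr = {
            t: v for t, v in trajectory.fractions[day].items() if t != "Metazoa"
        }
        if with_reads:
            tot = sum(fr.values())
            focal = trajectory.focal_taxon
            table = [
                InfectionEntry(focal, e.family, inf, e.expression_fraction)
                for e in config.infection_table
                if e.taxon == focal
            ][:1]
            day_config = CommunityConfig(
                taxon_names=list(fr),
                taxon_cell_fractions=[v / tot for v in fr.values()],
                dominant_taxon=config.dominant_taxon,
                dominant_family=config.dominant_family,
                family_names=config.family_names,
                marker_genes_per_family=config.marker_genes_per_family,
                infection_table=table,
                ambient_viral_rate=0.0,
                doublet_rate=0.0,
                n_cells=n_sc_cells,
                reads_per_cell=config.reads_per_cell,
                rrna_share=config.rrna_share,
                mrna_per_taxon=config.mrna_per_taxon,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            refs = simulate_references(day_config)
            experiments[day] = simulate_experiment(refs, day_config)
        else:
            cells = _truth_only_day(
                rng, config, fr, trajectory.focal_taxon, inf, n_sc_cells
            )
            comp = (
                cells.groupby("taxon").size().rename("n_cells").reset_index()
            )
            comp["day"] = day
            experiments[day] = GroundTruth(cells=cells, day_composition=comp)
    return asv, experiments
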