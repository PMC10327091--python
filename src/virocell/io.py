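"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects are deliberately strict: malformed input is rejected with the
offending line or read id rather than silently repaired, so that simulator
output and pipeline output stay byte-reproducible.

FASTA descriptions carry record metadata as space-separated ``key=value``
tokens (e.g. ``group=Katablepharidaceae family=IM_07 gene=PolB``); tokens
without ``=`` are preserved verbatim. Sparse count matrices are written as
1-based MatrixMarket triplets next to ``barcodes.tsv`` and ``features.tsv``,
the common single-cell interchange layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRecord",
    "ReadPair",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_paired_fastq",
    "write_paired_fastq",
    "write_umi_matrix",
    "read_umi_matrix",
]

BARCODE_LEN = 16
UMI_LEN = 12
CDNA_LEN = 60

_NT = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def _parse_meta(description: str) -> dict[str, str]:
    meta = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


@dataclass
class SeqRecord:
    """One FASTA record; ``meta`` is a parsed view of the description."""

    id: str
    sequence: str
    description: str = ""
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.meta:
            self.meta = _parse_meta(self.description)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_nucleotide(self) -> bool:
        return set(self.sequence) <= _NT


@dataclass(frozen=True)
class ReadPair:
    """A barcoded droplet read: 16 nt cell barcode + 12 nt UMI + cDNA."""

    barcode: str
    umi: str
    cdna: str
    read_id: str


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Parse FASTA into :class:`SeqRecord` objects, in file order.

    Raises :class:`FormatError` on a sequence line before the first header
    (with its line number) or on duplicate record ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    lineno_of_header = 0

    def flush() -> None:
        if header is None:
            return
        name, _, desc = header.partition(" ")
        if not name:
            raise FormatError(f"line {lineno_of_header}: empty FASTA header")
        if name in seen:
            raise FormatError(f"duplicate record id: {name}")
        seen.add(name)
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {name} has no sequence")
        records.append(SeqRecord(id=name, sequence=seq, description=desc.strip()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                lineno_of_header = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip().upper())
        flush()
    return records


def write_fasta(records: list[SeqRecord], path: str | os.PathLike) -> None:
    """Write records one sequence per line (no wrapping), preserving descriptions."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.description:
                fh.write(f">{rec.id} {rec.description}\n")
            else:
                fh.write(f">{rec.id}\n")
            fh.write(rec.sequence + "\n")


def read_paired_fastq(path_r1: str | os.PathLike, path_r2: str | os.PathLike) -> list[ReadPair]:
    """Parse paired FASTQ where R1 = 16 nt barcode + 12 nt UMI and R2 = 60 nt cDNA.

    Record order is preserved; ids must match pairwise (ignoring a trailing
    ``/1`` / ``/2`` suffix) and R1 entries must be exactly 28 nt.
    """
    pairs: list[ReadPair] = []
    with open(path_r1) as fh1, open(path_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, _q1), (t2, s2, _q2) in zip(it1, it2, strict=True):
            id1 = t1.split()[0].removesuffix("/1")
            id2 = t2.split()[0].removesuffix("/2")
            if id1 != id2:
                raise FormatError(f"unmatched read ids: {id1!r} vs {id2!r}")
            if len(s1) != BARCODE_LEN + UMI_LEN:
                raise FormatError(
                    f"read {id1}: R1 length {len(s1)} != {BARCODE_LEN + UMI_LEN}"
                )
            s2 = s2.upper()
            if len(s2) != CDNA_LEN:
                raise FormatError(f"read {id1}: R2 length {len(s2)} != {CDNA_LEN}")
            if not set(s2) <= _NT:
                raise FormatError(f"read {id1}: cDNA contains non-ACGTN characters")
            s1 = s1.upper()
            pairs.append(
                ReadPair(
                    barcode=s1[:BARCODE_LEN],
                    umi=s1[BARCODE_LEN:],
                    cdna=s2,
                    read_id=id1,
                )
            )
    return pairs


def write_paired_fastq(
    pairs: list[ReadPair], path_r1: str | os.PathLike, path_r2: str | os.PathLike
) -> None:
    with open(path_r1, "w") as fh1, open(path_r2, "w") as fh2:
        for p in pairs:
            r1 = p.barcode + p.umi
            fh1.write(f"@{p.read_id}\n{r1}\n+\n{'I' * len(r1)}\n")
            fh2.write(f"@{p.read_id}\n{p.cdna}\n+\n{'I' * len(p.cdna)}\n")


def write_umi_matrix(table, out_dir: str | os.PathLike) -> None:
    """Write a :class:`~virocell.screen.CellUMITable` as matrix.mtx + barcodes.tsv + features.tsv."""
    counts = scipy.sparse.coo_matrix(table.counts)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("UMI counts must be nonnegative")
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        counts.astype(np.int64),
        field="integer",
    )
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("barcode\n")
        for bc in table.barcodes:
            fh.write(bc + "\n")
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        fh.write("gene\tsource\n")
        for gene, source in zip(table.genes, table.sources):
            fh.write(f"{gene}\t{source}\n")


def read_umi_matrix(in_dir: str | os.PathLike):
    """Inverse of :func:`write_umi_matrix`; exact on counts."""
    from .screen import CellUMITable  # local import to avoid a cycle

    counts = scipy.io.mmread(os.path.join(in_dir, "matrix.mtx")).tocsr()
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("UMI counts must be nonnegative")
    with open(os.path.join(in_dir, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh][1:]
    genes, sources = [], []
    with open(os.path.join(in_dir, "features.tsv")) as fh:
        next(fh)
        for line in fh:
            gene, _, source = line.rstrip("\n").partition("\t")
            genes.append(gene)
            sources.append(source)
    return CellUMITable(
        barcodes=barcodes, genes=genes, sources=sources, counts=counts.astype(np.int64)
    )
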