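"""Per-cell read pooling, poly-A trimming and greedy overlap assembly.

Reads are pooled by their droplet barcode and assembled by iteratively
merging the pair of sequences with the longest exact suffix-prefix overlap
(>= ``min_overlap``, default 21 nt), considering both orientations of every
fragment. Greedy exact-overlap merging is adequate here because simulated
reads are error-free exact substrings of their source transcripts; it
stands in for a De-Bruijn transcriptome assembler, whose k=21 lower k-mer
size motivates the default overlap floor.

Determinism: exact duplicates are collapsed first, merges are ordered by
(overlap length desc, lexicographically smallest merged sequence), and all
fragments are kept in canonical orientation — the lexicographically smaller
of (seq, revcomp(seq)) — so output does not depend on input read order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence, Union

from .homology import revcomp
from .io import ReadPair

__all__ = ["Contig", "pool_reads_by_barcode", "trim_reads", "greedy_assemble"]

MIN_CONTIG_LEN = 60
MIN_READ_LEN_AFTER_TRIM = 30
POLYA_MIN_RUN = 10

_SEED = 21  # overlap candidates are found through this anchor length


@dataclass
class Contig:
    cell_barcode: str
    contig_id: str
    sequence: str
    n_reads: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def pool_reads_by_barcode(
    reads: Sequence[ReadPair], barcode: str
) -> list[ReadPair]:
    """All reads carrying exactly this barcode, in input order."""
    return [r for r in reads if r.barcode == barcode]


def _trim_one(cdna: str) -> str:
    """Remove a trailing poly-A run of >=10 A allowing one non-A base."""
    n = len(cdna)
    for i in range(n):
        if cdna[i] != "A":
            continue
        suffix = cdna[i:]
        non_a = sum(1 for c in suffix if c != "A")
        if non_a <= 1 and len(suffix) - non_a >= POLYA_MIN_RUN:
            return cdna[:i]
    return cdna


def trim_reads(reads: Sequence[ReadPair]) -> list[ReadPair]:
    """Poly-A-trim each read's cDNA; drop reads shorter than 30 nt after."""
    out = []
    for r in reads:
        trimmed = _trim_one(r.cdna)
        if len(trimmed) < MIN_READ_LEN_AFTER_TRIM:
            continue
        if trimmed == r.cdna:
            out.append(r)
        else:
            out.append(ReadPair(r.barcode, r.umi, trimmed, r.read_id))
    return out


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


class _Assembler:
    def __init__(self, seqs: Sequence[str], min_overlap: int):
        if min_overlap < _SEED:
            raise ValueError(f"min_overlap below {_SEED} is not supported")
        self.min_overlap = min_overlap
        counts: dict[str, int] = {}
        for s in seqs:
            c = _canonical(s)
            counts[c] = counts.get(c, 0) + 1
        self.seqs: list[str] = []  # canonical orientation per fragment
        self.n_reads: list[int] = []
        self.alive: list[bool] = []
        # Q: anchor 21-mer -> occurrences (frag, orient, pos) at pos <= len-21
        self.q_index: dict[str, list[tuple[int, int, int]]] = {}
        # P: 21-nt prefix -> oriented fragments starting with it
        self.p_index: dict[str, list[tuple[int, int]]] = {}
        self.heap: list[tuple] = []
        for c in sorted(counts):
            self._add_fragment(c, counts[c], register_only=True)
        for fid in range(len(self.seqs)):
            self._push_candidates_as_b(fid)

    def _oriented(self, fid: int, orient: int) -> str:
        return self.seqs[fid] if orient == 0 else revcomp(self.seqs[fid])

    def _add_fragment(self, seq: str, n_reads: int, register_only: bool = False) -> int:
        fid = len(self.seqs)
        self.seqs.append(seq)
        self.n_reads.append(n_reads)
        self.alive.append(True)
        for orient in (0, 1):
            s = self._oriented(fid, orient)
            if len(s) < _SEED:
                continue
            self.p_index.setdefault(s[:_SEED], []).append((fid, orient))
            for pos in range(len(s) - _SEED + 1):
                self.q_index.setdefault(s[pos : pos + _SEED], []).append(
                    (fid, orient, pos)
                )
        if not register_only:
            self._push_candidates_as_b(fid)
            self._push_candidates_as_a(fid)
        return fid

    def _push(self, a: int, oa: int, b: int, ob: int, k: int) -> None:
        if k < self.min_overlap:
            return
        sa = self._oriented(a, oa)
        sb = self._oriented(b, ob)
        if k > len(sa) or k > len(sb):
            return
        if sa[len(sa) - k :] != sb[:k]:
            return
        merged = _canonical(sa + sb[k:])
        heapq.heappush(self.heap, (-k, merged, a, oa, b, ob))

    def _push_candidates_as_b(self, b: int) -> None:
        """Overlaps where some fragment's suffix matches b's prefix."""
        for ob in (0, 1):
            sb = self._oriented(b, ob)
            if len(sb) < _SEED:
                continue
            for a, oa, pos in self.q_index.get(sb[:_SEED], ()):
                if a == b or not self.alive[a]:
                    continue
                k = len(self.seqs[a]) - pos
                self._push(a, oa, b, ob, k)

    def _push_candidates_as_a(self, a: int) -> None:
        """Overlaps where a's suffix matches some fragment's prefix."""
        for oa in (0, 1):
            sa = self._oriented(a, oa)
            for i in range(max(0, len(sa) - _SEED + 1)):
                k = len(sa) - i
                if k < self.min_overlap:
                    break
                for b, ob in self.p_index.get(sa[i : i + _SEED], ()):
                    if b == a or not self.alive[b]:
                        continue
                    self._push(a, oa, b, ob, k)

    def run(self) -> None:
        while self.heap:
            negk, _merged, a, oa, b, ob = heapq.heappop(self.heap)
            if not (self.alive[a] and self.alive[b]):
                continue
            k = -negk
            sa = self._oriented(a, oa)
            sb = self._oriented(b, ob)
            self.alive[a] = False
            self.alive[b] = False
            self._add_fragment(
                _canonical(sa + sb[k:]), self.n_reads[a] + self.n_reads[b]
            )

    def fragments(self) -> list[tuple[str, int]]:
        return [
            (self.seqs[i], self.n_reads[i])
            for i in range(len(self.seqs))
            if self.alive[i]
        ]


def greedy_assemble(
    reads: Sequence[Union[ReadPair, str]],
    min_overlap: int = 21,
    barcode: str = "",
) -> list[Contig]:
    """Assemble trimmed reads into contigs of >=60 nt.

    Fragments shorter than 60 nt after merging stops are not reported as
    contigs, so ``sum(c.n_reads) <= len(reads)`` with equality when every
    read lands in a contig. Contigs are sorted longest-first and named
    ``<barcode>_c<rank>``.
    """
    seqs = [r.cdna if isinstance(r, ReadPair) else r for r in reads]
    if not barcode:
        barcodes = {r.barcode for r in reads if isinstance(r, ReadPair)}
        barcode = barcodes.pop() if len(barcodes) == 1 else "pooled"
    if not seqs:
        return []
    asm = _Assembler(seqs, min_overlap)
    asm.run()
    frags = [
        (seq, n) for seq, n in asm.fragments() if len(seq) >= MIN_CONTIG_LEN
    ]
    frags.sort(key=lambda f: (-len(f[0]), f[0]))
    return [
        Contig(
            cell_barcode=barcode,
            contig_id=f"{barcode}_c{rank}",
            sequence=seq,
            n_reads=n,
        )
        for rank, (seq, n) in enumerate(frags, start=1)
    ]
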