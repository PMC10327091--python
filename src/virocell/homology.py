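"""Ungapped local homology search with BLAST-like statistics.

Two search modes back the pipeline:

* nucleotide: exact maximal-scoring ungapped local alignment over both
  strands, found by 11-mer exact seeding followed by exact rescoring of
  every seeded diagonal (max-scoring contiguous segment), with
  Karlin-Altschul bit scores and E-values;
* translated: six-frame translation of a short read (stop codons break
  segments), 5-mer amino-acid seeding and ungapped BLOSUM62 extension
  against a labelled protein database, best hit retained.

Alignments are ungapped by design: the simulator introduces substitutions
but no indels, so the maximal ungapped segment is the exact optimum in the
regime the pipeline operates in. This is the package's major simplification
relative to general-purpose aligners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import SeqRecord

__all__ = [
    "ScoringScheme",
    "HomologyHit",
    "ReadAssignment",
    "NT_SCHEME",
    "PROTEIN_LAMBDA",
    "PROTEIN_K",
    "DEFAULT_MIN_AA_SCORE",
    "MIN_NT_RAW_SCORE",
    "revcomp",
    "global_identity",
    "bit_score",
    "e_value",
    "ungapped_local_align",
    "search_nucleotide",
    "search_translated",
    "NucleotideSearcher",
    "ProteinSearcher",
]

# ---------------------------------------------------------------------------
# scoring parameters

MIN_NT_RAW_SCORE = 22  # alignments scoring below this are not reported
SEED_K_NT = 11
SEED_K_AA = 5
DEFAULT_MIN_AA_SCORE = 65  # calibrated: false hits on host 60-mers top out <55, true in-frame reads score >=~80

# standard Karlin-Altschul parameters for +1/-2 nucleotide scoring
PROTEIN_LAMBDA = 0.267
PROTEIN_K = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores with their Karlin-Altschul lambda and K."""

    match: int = 1
    mismatch: int = -2
    lambda_: float = 1.28
    k_: float = 0.46

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be >0 and mismatch <0")
        if self.lambda_ <= 0 or not 0 < self.k_ < 1:
            raise ValueError("invalid Karlin-Altschul parameters")


NT_SCHEME = ScoringScheme()


@dataclass
class HomologyHit:
    """One ungapped local alignment with BLAST-style statistics.

    Coordinates are 0-based half-open; for minus-strand nucleotide hits the
    query coordinates refer to the original (forward) query sequence. For
    translated hits coordinates are amino-acid offsets within the translated
    frame and the subject protein, and ``frame`` is +1..+3/-1..-3 where a
    negative frame means that offset on the reverse complement.
    """

    query_id: str
    subject_id: str
    group_label: str
    identity: float
    aln_len: int
    raw_score: int
    bit_score: float
    e_value: float
    strand: str
    frame: Optional[int]
    q_start: int
    q_end: int
    s_start: int
    s_end: int


# ---------------------------------------------------------------------------
# sequence encoding

_NT_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_X = AA_ALPHABET.index("X")
_AA_STOP = AA_ALPHABET.index("*")
_AA_CODE = {a: i for i, a in enumerate(AA_ALPHABET)}

# codon index b0*16+b1*4+b2 (ACGT -> 0..3) -> amino-acid code
_CODON_AA = np.full(64, _AA_X, dtype=np.uint8)
for _codon, _aa in standard_dna_table.forward_table.items():
    _idx = _NT_CODE[ord(_codon[0])] * 16 + _NT_CODE[ord(_codon[1])] * 4 + _NT_CODE[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_CODE[_aa]
for _codon in standard_dna_table.stop_codons:
    _idx = _NT_CODE[ord(_codon[0])] * 16 + _NT_CODE[ord(_codon[1])] * 4 + _NT_CODE[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_STOP

_B62 = substitution_matrices.load("BLOSUM62")
BLOSUM62 = np.zeros((24, 24), dtype=np.int64)
for _a in AA_ALPHABET:
    for _b in AA_ALPHABET:
        BLOSUM62[_AA_CODE[_a], _AA_CODE[_b]] = int(_B62[_a, _b])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def global_identity(a: str, b: str) -> float:
    """Positional percent identity of two equal-length (or truncated) sequences."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    ea, eb = encode_nt(a[:n]), encode_nt(b[:n])
    matches = int(np.sum((ea == eb) & (ea != 4)))
    return 100.0 * matches / n


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics

def bit_score(raw_score: float, scheme: ScoringScheme = NT_SCHEME) -> float:
    """Normalised score S' = (lambda*S - ln K) / ln 2."""
    return (scheme.lambda_ * raw_score - math.log(scheme.k_)) / math.log(2.0)


def e_value(bits: float, query_len: int, db_len: int) -> float:
    """Expected chance alignments E = m*n*2^(-S')."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    # work in logs to avoid underflow to zero for strong hits
    log10_e = math.log10(query_len) + math.log10(db_len) - bits * math.log10(2.0)
    return 10.0 ** max(log10_e, -323.0) if log10_e > -323 else 0.0


# ---------------------------------------------------------------------------
# exact best segment on one diagonal

def _best_segment(scores: np.ndarray) -> Optional[tuple[int, int, int]]:
    """Maximal-scoring contiguous segment of ``scores``.

    Returns (score, start, end) with 0-based half-open [start, end);
    ties resolved toward the smallest start, then the smallest end.
    Returns None if every segment scores <= 0.
    """
    cs = np.concatenate(([0], np.cumsum(scores)))
    runmin = np.minimum.accumulate(cs[:-1])
    endscore = cs[1:] - runmin
    best = int(endscore.max()) if endscore.size else 0
    if best <= 0:
        return None
    ends = np.flatnonzero(endscore == best)
    cand = []
    for j in ends:
        start = int(np.argmax(cs[: j + 1] == runmin[j]))
        cand.append((start, int(j) + 1))
    start, end = min(cand)
    return best, start, end


def _diagonal_scores(q: np.ndarray, s: np.ndarray, d: int, scheme: ScoringScheme):
    """Per-position scores along diagonal d (s_pos = q_pos + d)."""
    i0 = max(0, -d)
    i1 = min(len(q), len(s) - d)
    if i1 <= i0:
        return None, i0
    qs = q[i0:i1]
    ss = s[i0 + d : i1 + d]
    eq = (qs == ss) & (qs != 4) & (ss != 4)
    return np.where(eq, scheme.match, scheme.mismatch).astype(np.int64), i0


def _align_diagonals(
    q: np.ndarray, s: np.ndarray, diagonals, scheme: ScoringScheme
) -> Optional[tuple[int, int, int, int]]:
    """Best segment over the given diagonals.

    Returns (raw, q_start, s_start, length); ties toward lower s_start then
    lower q_start.
    """
    best = None
    for d in sorted(diagonals):
        arr, i0 = _diagonal_scores(q, s, d, scheme)
        if arr is None:
            continue
        seg = _best_segment(arr)
        if seg is None:
            continue
        raw, t0, t1 = seg
        q0 = i0 + t0
        s0 = q0 + d
        key = (-raw, s0, q0)
        if best is None or key < best[0]:
            best = (key, (raw, q0, s0, t1 - t0))
    return None if best is None else best[1]


def _count_matches(q: np.ndarray, s: np.ndarray) -> int:
    return int(np.sum((q == s) & (q != 4) & (s != 4)))


# ---------------------------------------------------------------------------
# nucleotide search

class NucleotideSearcher:
    """Seed-and-rescore ungapped search of queries against a fixed database.

    The database is indexed once by exact 11-mers; each query is scanned
    against the index, and every seeded (subject, diagonal) pair is rescored
    exhaustively, so any alignment containing an exact 11-mer match is found
    at its true optimum.
    """

    def __init__(self, db: Sequence[SeqRecord], scheme: ScoringScheme = NT_SCHEME):
        if not all(isinstance(r, SeqRecord) for r in db):
            raise TypeError("db must be a sequence of SeqRecord")
        self.db = list(db)
        self.scheme = scheme
        self.db_len = sum(len(r) for r in db)
        self._encoded = [encode_nt(r.sequence) for r in db]
        index: dict[str, list[tuple[int, int]]] = {}
        for si, rec in enumerate(self.db):
            seq = rec.sequence
            for pos in range(len(seq) - SEED_K_NT + 1):
                kmer = seq[pos : pos + SEED_K_NT]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((si, pos))
        self._index = index

    def _seed_diagonals(self, qseq: str) -> dict[int, set[int]]:
        diags: dict[int, set[int]] = {}
        for i in range(len(qseq) - SEED_K_NT + 1):
            kmer = qseq[i : i + SEED_K_NT]
            if "N" in kmer:
                continue
            for si, pos in self._index.get(kmer, ()):
                diags.setdefault(si, set()).add(pos - i)
        return diags

    def best_per_subject(
        self, query: str, query_id: str = "query", pair_evalue: bool = False
    ) -> list[HomologyHit]:
        """Best alignment per subject (both strands), unfiltered except the raw-score floor."""
        lq = len(query)
        if lq == 0:
            return []
        hits: dict[int, tuple] = {}
        for strand in "+-":
            qseq = query if strand == "+" else revcomp(query)
            qarr = encode_nt(qseq)
            for si, diags in self._seed_diagonals(qseq).items():
                res = _align_diagonals(qarr, self._encoded[si], diags, self.scheme)
                if res is None:
                    continue
                raw, q0, s0, length = res
                if raw < MIN_NT_RAW_SCORE:
                    continue
                key = (-raw, s0, 0 if strand == "+" else 1, q0)
                if si not in hits or key < hits[si][0]:
                    hits[si] = (key, strand, raw, q0, s0, length)
        out = []
        for si, (_key, strand, raw, q0, s0, length) in hits.items():
            rec = self.db[si]
            qseq = query if strand == "+" else revcomp(query)
            matches = _count_matches(
                encode_nt(qseq)[q0 : q0 + length], self._encoded[si][s0 : s0 + length]
            )
            if strand == "+":
                oq0, oq1 = q0, q0 + length
            else:  # map back onto the forward query
                oq0, oq1 = lq - (q0 + length), lq - q0
            bits = bit_score(raw, self.scheme)
            n = len(rec) if pair_evalue else self.db_len
            out.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=rec.id,
                    group_label=rec.meta.get("group", rec.meta.get("family", "")),
                    identity=round(100.0 * matches / length, 1),
                    aln_len=length,
                    raw_score=raw,
                    bit_score=bits,
                    e_value=e_value(bits, lq, n),
                    strand=strand,
                    frame=None,
                    q_start=oq0,
                    q_end=oq1,
                    s_start=s0,
                    s_end=s0 + length,
                )
            )
        return out

    def search(
        self,
        query: str,
        min_identity: float,
        max_evalue: float,
        min_len: int,
        query_id: str = "query",
    ) -> list[HomologyHit]:
        """One best hit per subject passing all three gates, sorted by bit score."""
        hits = [
            h
            for h in self.best_per_subject(query, query_id)
            if h.identity >= min_identity
            and h.e_value <= max_evalue
            and h.aln_len >= min_len
        ]
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        return hits


def ungapped_local_align(
    query: str, subject: str, scheme: ScoringScheme = NT_SCHEME
) -> Optional[HomologyHit]:
    """Exact best ungapped local alignment of query vs subject (both strands).

    Returns None for empty input or when the best raw score is below
    :data:`MIN_NT_RAW_SCORE`. Ties resolve toward lower subject start, then
    the plus strand.
    """
    if not query or not subject:
        return None
    searcher = NucleotideSearcher([SeqRecord(id="subject", sequence=subject)], scheme)
    hits = searcher.best_per_subject(query, pair_evalue=True)
    return hits[0] if hits else None


def search_nucleotide(
    query: str,
    db: Sequence[SeqRecord],
    min_identity: float,
    max_evalue: float,
    min_len: int,
    scheme: ScoringScheme = NT_SCHEME,
    query_id: str = "query",
) -> list[HomologyHit]:
    """Convenience one-shot search; build a :class:`NucleotideSearcher` for many queries."""
    if not (0 <= min_identity <= 100) or max_evalue < 0 or min_len < 0:
        raise ValueError("invalid thresholds")
    if not db:
        return []
    return NucleotideSearcher(db, scheme).search(
        query, min_identity, max_evalue, min_len, query_id
    )


# ---------------------------------------------------------------------------
# translated search

def _pack5(arr: np.ndarray) -> np.ndarray:
    """Rolling base-24 codes of all length-5 windows of an aa-code array."""
    if len(arr) < SEED_K_AA:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    return (
        a[:-4] * 24**4 + a[1:-3] * 24**3 + a[2:-2] * 24**2 + a[3:-1] * 24 + a[4:]
    )


def translate_frames(read: str) -> list[tuple[int, np.ndarray]]:
    """Six-frame translation as (frame label, aa-code array) pairs.

    Frames are labelled +1..+3 for offsets 0..2 on the forward read and
    -1..-3 for offsets 0..2 on its reverse complement. Codons containing N
    translate to X.
    """
    frames = []
    for strand, seq in ((1, read), (-1, revcomp(read))):
        codes = encode_nt(seq)
        for off in range(3):
            ncod = (len(seq) - off) // 3
            if ncod == 0:
                frames.append((strand * (off + 1), np.empty(0, dtype=np.uint8)))
                continue
            b = codes[off : off + 3 * ncod].reshape(ncod, 3)
            valid = (b < 4).all(axis=1)
            idx = (
                b[:, 0].astype(np.int64) * 16
                + b[:, 1].astype(np.int64) * 4
                + b[:, 2].astype(np.int64)
            )
            idx[~valid] = 0
            aa = _CODON_AA[idx].copy()
            aa[~valid] = _AA_X
            frames.append((strand * (off + 1), aa))
    return frames


class ProteinSearcher:
    """Six-frame translated search of 60-nt reads against a protein database.

    Proteins must carry ``family`` metadata (and typically ``gene``). Stop
    codons break the translated read into segments; segments of >=5 aa are
    seeded by exact 5-mers and each seeded diagonal is rescored exhaustively
    with BLOSUM62.
    """

    def __init__(
        self,
        protein_db: Sequence[SeqRecord],
        min_aa_score: int = DEFAULT_MIN_AA_SCORE,
    ):
        if not protein_db:
            raise ValueError("protein database is empty")
        for rec in protein_db:
            if "family" not in rec.meta:
                raise ValueError(f"protein {rec.id} lacks family metadata")
        self.db = list(protein_db)
        self.min_aa_score = min_aa_score
        self.db_len = sum(len(r) for r in self.db)
        self._encoded = [
            np.array([_AA_CODE.get(a, _AA_X) for a in r.sequence], dtype=np.uint8)
            for r in self.db
        ]
        index: dict[int, list[tuple[int, int]]] = {}
        for pi, arr in enumerate(self._encoded):
            for pos, code in enumerate(_pack5(arr)):
                index.setdefault(int(code), []).append((pi, pos))
        self._index = index
        self._codes = np.array(sorted(index), dtype=np.int64)

    # -- single read ------------------------------------------------------

    def _frame_candidates(self, aa: np.ndarray):
        """(protein, diagonal) pairs seeded by exact 5-mers in this frame."""
        codes = _pack5(aa)
        cands = set()
        for qpos, code in enumerate(codes):
            window = aa[qpos : qpos + SEED_K_AA]
            if (window == _AA_STOP).any() or (window == _AA_X).any():
                continue
            for pi, ppos in self._index.get(int(code), ()):
                cands.add((pi, ppos - qpos))
        return cands

    def hits(
        self, read: str, query_id: str = "read", _candidates=None
    ) -> list[HomologyHit]:
        """All seeded hits scoring >= min_aa_score, best-first.

        Sorted by (raw score desc, subject id, frame); at most one hit per
        subject survives. ``_candidates`` optionally supplies precomputed
        (frame, protein, diagonal) seeds from the batched path.
        """
        per_subject: dict[int, tuple] = {}
        for frame, aa in translate_frames(read):
            if len(aa) < SEED_K_AA:
                continue
            if _candidates is None:
                cand = self._frame_candidates(aa)
            else:
                cand = {(pi, d) for f, pi, d in _candidates if f == frame}
            for pi, d in sorted(cand):
                p = self._encoded[pi]
                i0 = max(0, -d)
                i1 = min(len(aa), len(p) - d)
                if i1 <= i0:
                    continue
                qs = aa[i0:i1].astype(np.int64)
                ss = p[i0 + d : i1 + d].astype(np.int64)
                scores = BLOSUM62[qs, ss]
                scores[qs == _AA_STOP] = -(10**6)  # stops end a segment
                seg = _best_segment(scores)
                if seg is None:
                    continue
                raw, t0, t1 = seg
                if raw < self.min_aa_score:
                    continue
                q0 = i0 + t0
                s0 = q0 + d
                length = t1 - t0
                matches = int(np.sum(qs[t0:t1] == ss[t0:t1]))
                key = (-raw, self.db[pi].id, _frame_order(frame), s0)
                if pi not in per_subject or key < per_subject[pi][0]:
                    per_subject[pi] = (key, frame, raw, q0, s0, length, matches)
        out = []
        for pi, (_key, frame, raw, q0, s0, length, matches) in per_subject.items():
            rec = self.db[pi]
            bits = bit_score(raw, ScoringScheme(1, -1, PROTEIN_LAMBDA, PROTEIN_K))
            out.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=rec.id,
                    group_label=rec.meta["family"],
                    identity=round(100.0 * matches / length, 1),
                    aln_len=length,
                    raw_score=raw,
                    bit_score=bits,
                    e_value=e_value(bits, max(len(read) // 3, 1), self.db_len),
                    strand="+" if frame > 0 else "-",
                    frame=frame,
                    q_start=q0,
                    q_end=q0 + length,
                    s_start=s0,
                    s_end=s0 + length,
                )
            )
        out.sort(key=lambda h: (-h.raw_score, h.subject_id, _frame_order(h.frame)))
        return out

    def best_hit(self, read: str, query_id: str = "read") -> Optional[HomologyHit]:
        """Single best hit (ties: lexicographic subject id, then lower frame)."""
        hits = self.hits(read, query_id)
        return hits[0] if hits else None

    def analyze(self, read: str, _candidates=None) -> Optional["ReadAssignment"]:
        """Best hit plus unique-gene resolution for one read.

        ``gene`` is None when two distinct genes tie for the best score
        (such reads are excluded from UMI counting but still profile to the
        best hit's family under the deterministic tie rule).
        """
        hits = self.hits(read, _candidates=_candidates)
        if not hits:
            return None
        best = hits[0]
        gene: Optional[str] = self.db_gene(best.subject_id)
        for h in hits[1:]:
            if h.raw_score < best.raw_score:
                break
            if self.db_gene(h.subject_id) != gene:
                gene = None  # two genes tie for best score
                break
        return ReadAssignment(gene=gene, family=best.group_label, hit=best)

    def assign_gene(self, read: str) -> Optional[tuple[str, str]]:
        """(gene, family) of the unique best-scoring gene, or None on a tie."""
        a = self.analyze(read)
        if a is None or a.gene is None:
            return None
        return a.gene, a.family

    def db_gene(self, subject_id: str) -> str:
        for rec in self.db:
            if rec.id == subject_id:
                return rec.meta.get("gene", rec.id)
        raise KeyError(subject_id)

    # -- batched reads ----------------------------------------------------

    def batch_candidates(
        self, reads: Sequence[str]
    ) -> dict[int, set[tuple[int, int, int]]]:
        """Seeded (frame, protein, diagonal) triples per read, vectorised.

        Reads are grouped by length so translation is a pure array
        operation; the candidate sets are exactly those the per-read path
        would find, and a read absent from the result has no exact 5-aa
        seed and therefore cannot produce a hit.
        """
        by_len: dict[int, list[int]] = {}
        for ri, read in enumerate(reads):
            by_len.setdefault(len(read), []).append(ri)
        out: dict[int, set[tuple[int, int, int]]] = {}
        for length, idxs in sorted(by_len.items()):
            if length < 3 * SEED_K_AA:
                continue
            buf = "".join(reads[ri] for ri in idxs).encode("ascii")
            codes = _NT_CODE[np.frombuffer(buf, dtype=np.uint8)].reshape(
                len(idxs), length
            )
            rc = np.where(codes == 4, 4, 3 - codes)[:, ::-1]
            for sign, strand_codes in ((1, codes), (-1, rc)):
                for off in range(3):
                    ncod = (length - off) // 3
                    if ncod < SEED_K_AA:
                        continue
                    b = strand_codes[:, off : off + 3 * ncod].reshape(-1, ncod, 3)
                    valid = (b < 4).all(axis=2)
                    cidx = (
                        b[:, :, 0].astype(np.int64) * 16
                        + b[:, :, 1].astype(np.int64) * 4
                        + b[:, :, 2].astype(np.int64)
                    )
                    cidx[~valid] = 0
                    aa = _CODON_AA[cidx].astype(np.int64)
                    aa[~valid] = _AA_X
                    c5 = (
                        aa[:, :-4] * 24**4
                        + aa[:, 1:-3] * 24**3
                        + aa[:, 2:-2] * 24**2
                        + aa[:, 3:-1] * 24
                        + aa[:, 4:]
                    )
                    bad = aa >= _AA_X  # X or stop cannot seed
                    badw = (
                        bad[:, :-4]
                        | bad[:, 1:-3]
                        | bad[:, 2:-2]
                        | bad[:, 3:-1]
                        | bad[:, 4:]
                    )
                    c5[badw] = -1
                    hit = np.isin(c5, self._codes)
                    frame = sign * (off + 1)
                    for row, qpos in zip(*np.nonzero(hit)):
                        ri = idxs[row]
                        for pi, ppos in self._index.get(int(c5[row, qpos]), ()):
                            out.setdefault(ri, set()).add((frame, pi, ppos - int(qpos)))
        return out

    def prefilter(self, reads: Sequence[str]) -> np.ndarray:
        """Boolean mask of reads sharing at least one exact 5-aa seed with the db.

        A read with no seed cannot produce a hit, so False entries are exact
        negatives; True entries still require full scoring.
        """
        mask = np.zeros(len(reads), dtype=bool)
        mask[list(self.batch_candidates(reads))] = True
        return mask

    def analyze_reads(self, reads: Sequence[str]) -> list[Optional["ReadAssignment"]]:
        """Per-read :meth:`analyze` with the vectorised seed prefilter."""
        out: list[Optional[ReadAssignment]] = [None] * len(reads)
        for ri, cands in self.batch_candidates(reads).items():
            out[ri] = self.analyze(reads[ri], _candidates=cands)
        return out

    def assign_reads(self, reads: Sequence[str]) -> list[Optional[tuple[str, str]]]:
        """Per-read unique best (gene, family) assignment; None if no hit or ambiguous."""
        return [
            (a.gene, a.family) if a is not None and a.gene is not None else None
            for a in self.analyze_reads(reads)
        ]


@dataclass
class ReadAssignment:
    """Resolved translated search of one read: unique best gene (or None on
    a cross-gene tie) and the best hit's family."""

    gene: Optional[str]
    family: str
    hit: HomologyHit


def _frame_order(frame: int) -> int:
    """Sort key implementing 'lower frame': numeric order -3<-2<-1<+1<+2<+3."""
    return frame


def search_translated(
    read: str,
    protein_db: Sequence[SeqRecord],
    min_aa_score: int = DEFAULT_MIN_AA_SCORE,
) -> Optional[HomologyHit]:
    """Best translated hit of a short read against a labelled protein database."""
    return ProteinSearcher(protein_db, min_aa_score).best_hit(read)
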