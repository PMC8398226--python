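"""Reference local protein aligner and tabular-hit I/O.

Provides an exact affine-gap Smith-Waterman aligner (BLOSUM62, gap 11/1 by
default) with Karlin-Altschul statistics, a catalog search that emits hits in
the same shape as BLAST tabular output, and a reader/writer for the
``outfmt6+qlen`` dialect (the 12 standard tab-separated columns plus query
length as column 13).  The aligner targets correctness at desk scale: full
dynamic programming, no heuristic seeding.

Statistics follow the standard Karlin-Altschul form::

    bitscore = (lambda * S - ln K) / ln 2
    evalue   = m' * n' * 2 ** (-bitscore)

with the effective search space ``m' * n'`` taken as query length times the
total residue count of the searched database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from . import _dp
from .registry import QueryRegistry, evalue_threshold_for

#: Residue alphabet accepted by the aligner (BLOSUM62 letters incl. ambiguity).
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def _load_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    n = len(ALPHABET)
    sub = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sub[i, j] = int(mat[a, b])
    return sub


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def encode(seq: str) -> np.ndarray:
    """Encode a one-letter amino-acid string as alphabet indices."""
    try:
        return np.array([_AA_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid residue character {exc.args[0]!r}") from None


@dataclass(frozen=True)
class AlignerParams:
    """Aligner and statistics parameters (BLAST-compatible defaults)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    k_const: float = 0.041
    db_size_letters: int = 0  # 0 -> size of the searched FASTA
    max_targets: int = 100_000

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self) -> np.ndarray:
        if self.matrix_name not in _MATRIX_CACHE:
            _MATRIX_CACHE[self.matrix_name] = _load_matrix(self.matrix_name)
        return _MATRIX_CACHE[self.matrix_name]


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query/subject pair (1-based inclusive)."""

    score: int
    qstart: int
    qend: int
    sstart: int
    send: int
    n_ident: int
    n_cols: int
    n_mismatch: int
    n_gap_opens: int

    @property
    def pid(self) -> float:
        return 100.0 * self.n_ident / self.n_cols if self.n_cols else 0.0


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-representative hit in BLAST tabular shape."""

    query_id: str
    target_id: str
    pid: float
    aln_length: int
    mismatch: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int

    @property
    def qcov(self) -> float:
        """Percent query coverage: aligned query span over query length."""
        return 100.0 * (self.qend - self.qstart + 1) / self.qlen

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"{self.query_id}->{self.target_id}: bad query coordinates "
                f"{self.qstart}..{self.qend} (qlen {self.qlen})"
            )
        if not (0.0 <= self.pid <= 100.0):
            raise ValueError(f"pid {self.pid} outside [0, 100]")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


def local_score(query_seq: str, subject_seq: str, params: AlignerParams | None = None) -> int:
    """Best local-alignment raw score (0 when nothing aligns positively)."""
    if not query_seq or not subject_seq:
        raise ValueError("sequences must be non-empty")
    params = params or AlignerParams()
    return int(
        _dp.sw_score(
            encode(query_seq), encode(subject_seq), params.matrix,
            params.gap_open, params.gap_extend,
        )
    )


def align_local(query_seq: str, subject_seq: str, params: AlignerParams | None = None) -> LocalAlignment:
    """Maximal-scoring local alignment under affine gap penalties.

    Traceback is deterministic: at score ties the diagonal (match) move is
    preferred over the vertical (gap in subject), which is preferred over the
    horizontal (gap in query).
    """
    if not query_seq or not subject_seq:
        raise ValueError("sequences must be non-empty")
    params = params or AlignerParams()
    q = encode(query_seq)
    s = encode(subject_seq)
    H, E, F, best, bi, bj = _dp.sw_matrices(q, s, params.matrix, params.gap_open, params.gap_extend)
    return _traceback(q, s, params, H, E, F, int(best), int(bi), int(bj))


def _traceback(q, s, params, H, E, F, best, bi, bj) -> LocalAlignment:
    sub = params.matrix
    go = params.gap_open + params.gap_extend
    ge = params.gap_extend
    i, j = bi, bj
    n_ident = n_cols = n_mismatch = n_gap_opens = 0
    state = "H"
    if best == 0:
        raise ValueError("no positive-scoring local alignment")
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            # tie order: diagonal > up (gap in subject) > left (gap in query)
            if h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                n_cols += 1
                if q[i - 1] == s[j - 1]:
                    n_ident += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            n_cols += 1
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
                n_gap_opens += 1
            else:
                assert F[i, j] == F[i - 1, j] - ge
            i -= 1
        else:  # state E: gap in query, consume subject
            n_cols += 1
            if E[i, j] == H[i, j - 1] - go:
                state = "H"
                n_gap_opens += 1
            else:
                assert E[i, j] == E[i, j - 1] - ge
            j -= 1
    return LocalAlignment(
        score=best,
        qstart=i + 1,
        qend=bi,
        sstart=j + 1,
        send=bj,
        n_ident=n_ident,
        n_cols=n_cols,
        n_mismatch=n_mismatch,
        n_gap_opens=n_gap_opens,
    )


def hit_statistics(
    raw_score: float, params: AlignerParams, qlen: int, subject_len: int = 0
) -> tuple[float, float]:
    """(bitscore, evalue) for a raw alignment score.

    The effective search space is ``qlen * db_size_letters`` when the database
    size is set, else ``qlen * subject_len`` for a single pairwise comparison.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    bitscore = (params.lambda_ * raw_score - math.log(params.k_const)) / math.log(2.0)
    n_letters = params.db_size_letters or subject_len
    space = float(qlen) * float(n_letters)
    evalue = space * 2.0 ** (-bitscore)
    return bitscore, evalue


def _min_raw_score(params: AlignerParams, qlen: int, db_letters: int, evalue_cutoff: float) -> int:
    """Smallest integer raw score whose e-value passes the cutoff."""
    space = float(qlen) * float(db_letters)
    min_bit = math.log2(space / evalue_cutoff)
    s = (min_bit * math.log(2.0) + math.log(params.k_const)) / params.lambda_
    return max(0, math.ceil(s - 1e-9))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; record id is the header's first token."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def search_catalog(
    registry: QueryRegistry,
    representative_fasta: str | Path,
    params: AlignerParams | None = None,
    canonical_only: bool = True,
) -> list[AlignmentHit]:
    """Search every (canonical) registry query against a representative FASTA.

    Emits at most ``max_targets`` hits per query, each already passing the
    query's class e-value cutoff; at most one alignment (the best) per
    query-subject pair.  Hits are ordered per query by descending bitscore,
    ties by target id.
    """
    params = params or AlignerParams()
    subjects = read_fasta(representative_fasta)
    if params.db_size_letters == 0:
        params = replace(params, db_size_letters=sum(len(s) for _, s in subjects))
    encoded = [(sid, seq, encode(seq)) for sid, seq in subjects]
    sub_matrix = params.matrix
    queries = registry.canonical_queries() if canonical_only else registry.queries
    hits: list[AlignmentHit] = []
    for query in queries:
        cutoff = evalue_threshold_for(query)
        q = encode(query.sequence)
        s_min = _min_raw_score(params, query.length, params.db_size_letters, cutoff)
        q_hits: list[AlignmentHit] = []
        for sid, s_seq, s_enc in encoded:
            score = _dp.sw_score(q, s_enc, sub_matrix, params.gap_open, params.gap_extend)
            if score < s_min:
                continue
            aln = align_local(query.sequence, s_seq, params)
            bitscore, evalue = hit_statistics(aln.score, params, query.length)
            if evalue > cutoff:
                continue
            q_hits.append(
                AlignmentHit(
                    query_id=query.query_id,
                    target_id=sid,
                    pid=aln.pid,
                    aln_length=aln.n_cols,
                    mismatch=aln.n_mismatch,
                    gap_opens=aln.n_gap_opens,
                    qstart=aln.qstart,
                    qend=aln.qend,
                    sstart=aln.sstart,
                    send=aln.send,
                    evalue=evalue,
                    bitscore=bitscore,
                    qlen=query.length,
                )
            )
        q_hits.sort(key=lambda h: (-h.bitscore, h.target_id))
        hits.extend(q_hits[: params.max_targets])
    return hits


class TabularFormatError(ValueError):
    """Malformed row in a tabular hit file (carries the line number)."""


_N_COLUMNS = 13  # outfmt6+qlen


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as ``outfmt6+qlen`` TSV (12 standard columns plus qlen)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.pid:.3f}\t{h.aln_length}\t"
                f"{h.mismatch}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.3e}\t{h.bitscore:.3f}\t{h.qlen}\n"
            )


def read_tabular_hits(
    path: str | Path,
    dialect: str = "outfmt6+qlen",
    qlen_by_query: dict[str, int] | None = None,
    strict: bool = True,
) -> Iterator[AlignmentHit]:
    """Parse tabular hits.

    ``outfmt6+qlen``: 13 columns with query length last.  ``outfmt6``: the 12
    standard columns, with query lengths supplied via ``qlen_by_query``.
    Malformed rows raise :class:`TabularFormatError` naming the line, or are
    skipped when ``strict`` is false.
    """
    if dialect not in {"outfmt6+qlen", "outfmt6"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    want = _N_COLUMNS if dialect == "outfmt6+qlen" else _N_COLUMNS - 1
    if dialect == "outfmt6" and qlen_by_query is None:
        raise ValueError("dialect 'outfmt6' requires qlen_by_query")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != want:
                    raise ValueError(f"expected {want} columns, got {len(fields)}")
                if dialect == "outfmt6+qlen":
                    qlen = int(fields[12])
                else:
                    qlen = qlen_by_query[fields[0]]  # type: ignore[index]
                yield AlignmentHit(
                    query_id=fields[0],
                    target_id=fields[1],
                    pid=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    qlen=qlen,
                )
            except (ValueError, KeyError) as exc:
                if strict:
                    raise TabularFormatError(f"line {lineno}: {exc}") from exc
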