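"""Pairwise protein similarity search in BLAST-tabular-compatible form.

Local protein-protein alignment (affine-gap Smith-Waterman over BLOSUM62,
via Biopython's C aligner), Karlin-Altschul E-values, a shared-k-mer
prefiltered all-vs-all search, six-frame ORF extraction, protein-vs-genome
search, and a reader/writer for 12-column BLAST tabular files with two
optional extension columns (query_coverage, subject_frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from numba import njit

from ._core import InputError, ParseError, ProteinRecord

_ALPHABET_X = "ACDEFGHIKLMNPQRSTVWYX"
_VALID_AA = set(_ALPHABET_X)
_ENCODE_TABLE = np.full(256, 20, dtype=np.uint8)  # unknowns -> X
for _i, _c in enumerate(_ALPHABET_X):
    _ENCODE_TABLE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_score_fast(a: np.ndarray, b: np.ndarray, submat: np.ndarray,
                   open_ext: int, ext: int) -> int:
    """Optimal local affine-gap alignment score (Gotoh recurrences).

    Exact same optimum as the traceback aligner; used to screen pairs
    before paying for a traceback. ``open_ext`` is the cost of the first
    gap column (gap_open + gap_extend), ``ext`` of each further column.
    """
    m = len(b)
    neg = -(10 ** 9)
    h_prev = np.zeros(m + 1, dtype=np.int64)    # H, Ix, Iy of row i-1
    ix_prev = np.full(m + 1, neg, dtype=np.int64)
    iy_prev = np.full(m + 1, neg, dtype=np.int64)
    h_row = np.zeros(m + 1, dtype=np.int64)
    ix_row = np.full(m + 1, neg, dtype=np.int64)
    iy_row = np.full(m + 1, neg, dtype=np.int64)
    best = 0
    for i in range(len(a)):
        ca = a[i]
        h_row[0] = 0
        ix_row[0] = neg
        iy_row[0] = neg
        for j in range(1, m + 1):
            ix_row[j] = max(h_prev[j] - open_ext, ix_prev[j] - ext)
            iy_row[j] = max(h_row[j - 1] - open_ext, iy_row[j - 1] - ext)
            diag = max(h_prev[j - 1], ix_prev[j - 1], iy_prev[j - 1], 0)
            h = diag + submat[ca, b[j - 1]]
            if h < 0:
                h = 0
            h_row[j] = h
            if h > best:
                best = h
        h_prev, h_row = h_row, h_prev
        ix_prev, ix_row = ix_row, ix_prev
        iy_prev, iy_row = iy_row, iy_prev
    return best


def _blosum62_with_neutral_x():
    """BLOSUM62 restricted to the 20 residues + X, with X scoring 0
    against everything (universal neutral mismatch)."""
    base = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "X" or b == "X":
                mat[a, b] = 0.0
            else:
                mat[a, b] = base[a, b]
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul statistics.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST
    convention). ``lam``/``k_param`` are the published gapped
    BLOSUM62/11/1 parameters; ``db_letters`` is the effective subject
    search-space size used in E = K*m*n*exp(-lam*S).
    """

    matrix: object
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k_param: float = 0.041
    db_letters: float = 1.0e6

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 1):
            raise InputError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.k_param <= 0:
            raise InputError("Karlin-Altschul parameters must be positive")

    @classmethod
    def blosum62(cls, db_letters: float = 1.0e6, gap_open: int = 11,
                 gap_extend: int = 1) -> "ScoringScheme":
        return cls(_blosum62_with_neutral_x(), gap_open, gap_extend,
                   db_letters=db_letters)

    def int_submatrix(self) -> np.ndarray:
        """Integer 21x21 substitution matrix for the fast score kernel."""
        mat = np.zeros((21, 21), dtype=np.int64)
        for i, x in enumerate(_ALPHABET_X):
            for j, y in enumerate(_ALPHABET_X):
                mat[i, j] = int(self.matrix[x, y])
        return mat

    def aligner(self) -> PairwiseAligner:
        al = PairwiseAligner(mode="local")
        al.substitution_matrix = self.matrix
        # Biopython charges open_gap_score on the first gap column, so a
        # length-k gap costs open + (k-1)*extend; shift to match open + k*extend.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@dataclass
class HitRecord:
    """One pairwise local-alignment match, BLAST-tabular compatible.

    Coordinates are 1-based inclusive. ``percent_identity`` uses alignment
    columns as denominator; ``query_coverage`` uses full query length.
    Genome hits carry a signed ``frame`` (negative = minus strand) and
    subject coordinates in genome bases.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    query_coverage: float | None = None
    frame: int | None = None

    def validate(self, line: int | None = None) -> None:
        where = f" (line {line})" if line is not None else ""
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ParseError(f"percent identity out of range{where}")
        if self.evalue < 0:
            raise ParseError(f"negative E-value{where}")
        if self.query_start > self.query_end or self.subject_start > self.subject_end:
            raise ParseError(f"start > end{where}")
        if self.query_start < 1 or self.subject_start < 1:
            raise ParseError(f"coordinates must be 1-based{where}")
        if self.alignment_length < 1:
            raise ParseError(f"alignment length < 1{where}")
        if self.query_coverage is not None and not 0.0 < self.query_coverage <= 1.0:
            raise ParseError(f"query coverage out of (0, 1]{where}")

    @property
    def strand(self) -> str | None:
        if self.frame is None:
            return None
        return "+" if self.frame > 0 else "-"


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of one sequence pair."""

    score: float
    columns: int
    identities: int
    mismatches: int
    gap_opens: int
    a_start: int  # 0-based half-open spans
    a_end: int
    b_start: int
    b_end: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.columns


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID_AA:
        return seq
    return "".join(c if c in _VALID_AA else "X" for c in seq)


def smith_waterman(seq_a: str, seq_b: str,
                   scheme: ScoringScheme) -> LocalAlignment | None:
    """Optimal local alignment under affine gaps; None if no positive score.

    Residues outside the 20-letter alphabet are treated as X (score 0
    against everything).
    """
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    seq_a, seq_b = _sanitize(seq_a), _sanitize(seq_b)
    al = scheme.aligner()
    score = al.score(seq_a, seq_b)
    if score <= 0:
        return None
    aln = al.align(seq_a, seq_b)[0]
    seg_a, seg_b = aln.aligned
    identities = 0
    aligned_pairs = 0
    for (as_, ae), (bs, be) in zip(seg_a, seg_b):
        aligned_pairs += ae - as_
        for x, y in zip(seq_a[as_:ae], seq_b[bs:be]):
            if x == y:
                identities += 1
    a_start, a_end = int(seg_a[0][0]), int(seg_a[-1][1])
    b_start, b_end = int(seg_b[0][0]), int(seg_b[-1][1])
    columns = aligned_pairs
    gap_opens = 0
    for i in range(1, len(seg_a)):
        gap_a = seg_a[i][0] - seg_a[i - 1][1]
        gap_b = seg_b[i][0] - seg_b[i - 1][1]
        columns += gap_a + gap_b
        gap_opens += (gap_a > 0) + (gap_b > 0)
    mismatches = aligned_pairs - identities
    return LocalAlignment(float(score), columns, identities, mismatches,
                          gap_opens, a_start, a_end, b_start, b_end)


def evalue_of(score: float, query_len: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise InputError("score must be >= 0")
    return scheme.k_param * query_len * scheme.db_letters * math.exp(-scheme.lam * score)


def bitscore_of(score: float, scheme: ScoringScheme) -> float:
    return (scheme.lam * score - math.log(scheme.k_param)) / math.log(2.0)


def _min_score_for_evalue(evalue_max: float, query_len: int,
                          scheme: ScoringScheme) -> float:
    """Smallest raw score whose E-value is <= evalue_max."""
    return math.log(scheme.k_param * query_len * scheme.db_letters / evalue_max) \
        / scheme.lam


def hit_from_alignment(query: ProteinRecord, subject_id: str, subject_len: int,
                       aln: LocalAlignment, scheme: ScoringScheme) -> HitRecord:
    ev = evalue_of(aln.score, len(query), scheme)
    return HitRecord(
        query_id=query.gene_id, subject_id=subject_id,
        percent_identity=round(aln.percent_identity, 2),
        alignment_length=aln.columns, mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        query_start=aln.a_start + 1, query_end=aln.a_end,
        subject_start=aln.b_start + 1, subject_end=aln.b_end,
        evalue=ev, bitscore=round(bitscore_of(aln.score, scheme), 1),
        query_coverage=(aln.a_end - aln.a_start) / len(query),
    )


# ---------------------------------------------------------------------------
# k-mer prefilter and all-vs-all search


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_pairs(seqs_a: Sequence[str], seqs_b: Sequence[str],
                      k: int = 4, min_shared: int = 2,
                      self_mode: bool = False) -> set[tuple[int, int]]:
    """Index pairs (i, j) sharing >= min_shared distinct k-mers.

    With ``self_mode`` the two lists are the same sequences and only i < j
    pairs are returned.
    """
    index_b: dict[str, list[int]] = {}
    for j, s in enumerate(seqs_b):
        for kmer in _kmer_set(s, k):
            index_b.setdefault(kmer, []).append(j)
    counts: dict[tuple[int, int], int] = {}
    for i, s in enumerate(seqs_a):
        for kmer in _kmer_set(s, k):
            for j in index_b.get(kmer, ()):
                if self_mode and j <= i:
                    continue
                key = (i, j)
                counts[key] = counts.get(key, 0) + 1
    return {pair for pair, c in counts.items() if c >= min_shared}


def all_vs_all(proteome_a: Sequence[ProteinRecord],
               proteome_b: Sequence[ProteinRecord],
               scheme: ScoringScheme | None = None,
               prefilter: bool = True,
               evalue_max: float = 10.0,
               k: int = 4, min_shared: int = 2) -> list[HitRecord]:
    """Best-hit-per-pair similarity search, both directions.

    Each retained pair yields one HitRecord per direction (E-values differ
    because the subject search space differs). Self-hits are excluded when
    the two proteomes are the same object. Output sorted by
    (query_id, evalue, subject_id).
    """
    if not proteome_a or not proteome_b:
        raise InputError("empty proteome")
    self_mode = proteome_a is proteome_b
    seqs_a = [_sanitize(r.seq) for r in proteome_a]
    seqs_b = seqs_a if self_mode else [_sanitize(r.seq) for r in proteome_b]
    if prefilter:
        pairs = shared_kmer_pairs(seqs_a, seqs_b, k, min_shared, self_mode)
    else:
        if self_mode:
            pairs = {(i, j) for i in range(len(seqs_a))
                     for j in range(i + 1, len(seqs_a))}
        else:
            pairs = {(i, j) for i in range(len(seqs_a))
                     for j in range(len(seqs_b))}
    letters_a = float(sum(len(s) for s in seqs_a))
    letters_b = letters_a if self_mode else float(sum(len(s) for s in seqs_b))
    base = scheme if scheme is not None else ScoringScheme.blosum62()
    scheme_ab = replace(base, db_letters=letters_b)  # a queries vs b database
    scheme_ba = replace(base, db_letters=letters_a)
    enc_a = [_encode(s) for s in seqs_a]
    enc_b = enc_a if self_mode else [_encode(s) for s in seqs_b]
    submat = base.int_submatrix()
    open_ext = base.gap_open + base.gap_extend
    hits: list[HitRecord] = []
    for i, j in sorted(pairs):
        qa, qb = proteome_a[i], proteome_b[j]
        score = _sw_score_fast(enc_a[i], enc_b[j], submat, open_ext,
                               base.gap_extend)
        if score <= 0:
            continue
        # cheapest direction check before paying for the traceback
        e_ab = evalue_of(score, len(qa), scheme_ab)
        e_ba = evalue_of(score, len(qb), scheme_ba)
        if min(e_ab, e_ba) > evalue_max:
            continue
        aln = smith_waterman(seqs_a[i], seqs_b[j], base)
        if aln is None:
            continue
        if e_ab <= evalue_max:
            hits.append(hit_from_alignment(qa, qb.gene_id, len(qb), aln, scheme_ab))
        if e_ba <= evalue_max:
            flipped = LocalAlignment(aln.score, aln.columns, aln.identities,
                                     aln.mismatches, aln.gap_opens,
                                     aln.b_start, aln.b_end,
                                     aln.a_start, aln.a_end)
            hits.append(hit_from_alignment(qb, qa.gene_id, len(qa), flipped,
                                           scheme_ba))
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Six-frame ORFs and protein-vs-genome search


@dataclass(frozen=True)
class Orf:
    """A maximal stop-free translated segment with genome coordinates."""

    peptide: str
    frame: int    # +1..+3 / -1..-3
    strand: str
    start: int    # 1-based inclusive genome coordinates, start < end
    end: int


def sixframe_orfs(genome: str, min_aa: int = 30) -> list[Orf]:
    """All maximal stop-free translated segments of length >= min_aa
    from all six frames. N translates to X."""
    genome = genome.upper()
    bad = set(genome) - set("ACGTN")
    if bad:
        raise InputError(f"genome contains invalid characters {sorted(bad)}")
    L = len(genome)
    orfs: list[Orf] = []
    for strand, seq in (("+", genome), ("-", str(Seq(genome).reverse_complement()))):
        for f in range(3):
            usable = (len(seq) - f) // 3
            if usable < min_aa:
                continue
            peptide = str(Seq(seq[f:f + usable * 3]).translate())
            start_aa = 0
            for segment in peptide.split("*"):
                if len(segment) >= min_aa:
                    i, j = start_aa, start_aa + len(segment)
                    if strand == "+":
                        g_start, g_end = f + 3 * i + 1, f + 3 * j
                        frame = f + 1
                    else:
                        g_start, g_end = L - f - 3 * j + 1, L - f - 3 * i
                        frame = -(f + 1)
                    orfs.append(Orf(segment, frame, strand, g_start, g_end))
                start_aa += len(segment) + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


def protein_vs_genome(proteins: Sequence[ProteinRecord],
                      genome: tuple[str, str],
                      scheme: ScoringScheme | None = None,
                      min_aa: int = 30,
                      evalue_max: float = 10.0,
                      prefilter: bool = True,
                      k: int = 4, min_shared: int = 2) -> list[HitRecord]:
    """Align proteins against the six-frame ORF set of a genome.

    One best hit per (protein, ORF) is kept; subject coordinates are
    genome bases, with the ORF's signed frame recorded.
    """
    if not proteins:
        raise InputError("empty protein list")
    chrom_id, genome_seq = genome
    orfs = sixframe_orfs(genome_seq, min_aa)
    if not orfs:
        return []
    seqs_p = [_sanitize(r.seq) for r in proteins]
    seqs_o = [o.peptide for o in orfs]
    if prefilter:
        pairs = shared_kmer_pairs(seqs_p, seqs_o, k, min_shared)
    else:
        pairs = {(i, j) for i in range(len(seqs_p)) for j in range(len(seqs_o))}
    base = scheme if scheme is not None else ScoringScheme.blosum62()
    # search space: total translated residues offered to each query
    sch = replace(base, db_letters=float(sum(len(s) for s in seqs_o)))
    enc_p = [_encode(s) for s in seqs_p]
    enc_o = [_encode(s) for s in seqs_o]
    submat = base.int_submatrix()
    open_ext = base.gap_open + base.gap_extend
    hits: list[HitRecord] = []
    for i, j in sorted(pairs):
        score = _sw_score_fast(enc_p[i], enc_o[j], submat, open_ext,
                               base.gap_extend)
        if score <= 0:
            continue
        if evalue_of(score, len(proteins[i]), sch) > evalue_max:
            continue
        aln = smith_waterman(seqs_p[i], seqs_o[j], base)
        if aln is None:
            continue
        hit = hit_from_alignment(proteins[i], chrom_id, len(seqs_o[j]), aln, sch)
        orf = orfs[j]
        # map ORF-local residue span to genome bases
        if orf.strand == "+":
            s_start = orf.start + 3 * aln.b_start
            s_end = orf.start + 3 * aln.b_end - 1
        else:
            s_end = orf.end - 3 * aln.b_start
            s_start = orf.end - 3 * aln.b_end + 1
        hit.subject_start, hit.subject_end = s_start, s_end
        hit.frame = orf.frame
        hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_start))
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular I/O (outfmt 6 + optional query_coverage, subject_frame)

_COLUMNS_12 = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "query_start", "query_end",
    "subject_start", "subject_end", "evalue", "bitscore",
]


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as 14-column extended BLAST tabular (no header)."""
    with open(path, "w") as fh:
        for h in hits:
            cov = "" if h.query_coverage is None else repr(float(h.query_coverage))
            frame = "" if h.frame is None else str(h.frame)
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                str(h.alignment_length), str(h.mismatches), str(h.gap_opens),
                str(h.query_start), str(h.query_end),
                str(h.subject_start), str(h.subject_end),
                repr(float(h.evalue)), f"{h.bitscore:.1f}", cov, frame,
            ]) + "\n")


def read_hits(path: str | Path,
              query_lengths: dict[str, int] | None = None) -> list[HitRecord]:
    """Read 12-column BLAST tabular, with two optional extension columns
    (query_coverage, subject_frame).

    For plain 12-column files, coverage is recomputed as
    (qend - qstart + 1) / query_len when ``query_lengths`` is supplied.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13, 14):
                raise ParseError(
                    f"line {lineno}: expected 12-14 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                hit = HitRecord(
                    query_id=parts[0], subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    query_start=int(parts[6]), query_end=int(parts[7]),
                    subject_start=int(parts[8]), subject_end=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                )
                if len(parts) >= 13 and parts[12] != "":
                    hit.query_coverage = float(parts[12])
                if len(parts) == 14 and parts[13] != "":
                    hit.frame = int(parts[13])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if hit.query_coverage is None and query_lengths is not None:
                qlen = query_lengths.get(hit.query_id)
                if qlen:
                    hit.query_coverage = (hit.query_end - hit.query_start + 1) / qlen
            hit.validate(lineno)
            hits.append(hit)
    return hits
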