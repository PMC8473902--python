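"""Self-contained pairwise nucleotide alignment kernel.

Seed-chain-extend local alignment used by the OrthoANI and MLST stages:

1. exact k-mer seeds (default k = 15) are located on both strands with a
   2-bit rolling index of the subject;
2. co-linear seeds are grouped by diagonal into candidate regions;
3. each candidate is extended with a banded affine-gap Smith-Waterman
   (defaults: match +1, mismatch -2, gap open -5, gap extend -2, band 32)
   and the highest-scoring hit is returned.

A global (Needleman-Wunsch) mode over full sequences supports per-locus
alignment in the MLST stage.

Conventions: coordinates are 0-based half-open internally (1-based
inclusive only in written reports); hits on the reverse strand carry
subject coordinates on the forward subject and query coordinates on the
original query; ``N`` never counts as a match (scored as a mismatch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numba import njit

__all__ = [
    "GenomeSeq",
    "Genome",
    "LocalHit",
    "AlignParams",
    "best_local_hit",
    "global_align",
    "revcomp",
    "read_fasta",
    "write_fasta",
]

_ALPHABET = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(seq: str, seq_id: str) -> str:
    s = seq.upper()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    known = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not known.all():
        n_bad = int((~known).sum())
        warnings.warn(
            f"{seq_id}: {n_bad} non-ACGTN characters mapped to N", stacklevel=3
        )
        arr = arr.copy()
        arr[~known] = ord("N")
        s = arr.tobytes().decode("ascii")
    return s


@dataclass
class GenomeSeq:
    """A single nucleotide sequence (contig or complete genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.sequence = _clean_sequence(self.sequence, self.id)
        self._encoded: dict = {}
        self._index: dict = {}

    def __len__(self) -> int:
        return len(self.sequence)

    def encoded(self) -> np.ndarray:
        """Sequence as int8 codes A=0 C=1 G=2 T=3 N=4 (cached)."""
        if "fwd" not in self._encoded:
            arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
            self._encoded["fwd"] = _ENCODE[arr]
        return self._encoded["fwd"]

    def kmer_index(self, k: int) -> dict:
        """Hash of every N-free k-mer to its start positions (cached)."""
        if k not in self._index:
            self._index[k] = _build_index(self.encoded(), k)
        return self._index[k]


@dataclass
class Genome:
    """A (possibly multi-contig) genome assembly."""

    id: str
    contigs: list  # list[GenomeSeq]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.id!r} has no contigs")

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @classmethod
    def single(cls, id: str, sequence: str) -> "Genome":
        return cls(id, [GenomeSeq(id, sequence)])


@dataclass
class LocalHit:
    """Best local alignment of a query against a subject."""

    query_id: str
    q_start: int  # 0-based half-open on the original query
    q_end: int
    subject_id: str
    s_start: int  # 0-based half-open on the forward subject
    s_end: int
    strand: str  # '+' or '-'
    score: int
    matches: int
    aligned_length: int
    gaps: int = 0
    query_length: int = 0

    @property
    def identity(self) -> float:
        """Percent identity over aligned columns (gaps count as columns)."""
        return 100.0 * self.matches / self.aligned_length

    @property
    def coverage(self) -> float:
        """Aligned query span as a fraction of the query length."""
        return (self.q_end - self.q_start) / self.query_length

    @property
    def s_mid(self) -> float:
        return (self.s_start + self.s_end) / 2.0


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters of the kernel."""

    k: int = 15
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # cost of the first base of a gap
    gap_extend: int = -2
    band: int = 32
    max_candidates: int = 4
    max_dp_cells: int = 4_000_000  # seedless fallback ceiling

    def __post_init__(self) -> None:
        if not 4 <= self.k <= 31:
            raise ValueError("k must be between 4 and 31")
        if self.band < 1:
            raise ValueError("band must be positive")


# -- k-mer machinery --------------------------------------------------------


def _build_index(enc: np.ndarray, k: int) -> dict:
    hashes, positions = _kmer_hashes(enc, k)
    index: dict = {}
    order = np.argsort(hashes, kind="stable")
    hs = hashes[order]
    ps = positions[order]
    if hs.size == 0:
        return index
    bounds = np.flatnonzero(np.diff(hs)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [hs.size]))
    for s, e in zip(starts, ends):
        index[int(hs[s])] = ps[s:e]
    return index


@njit(cache=True)
def _kmer_hashes(enc, k):
    n = enc.size
    out_h = np.empty(max(n - k + 1, 0), dtype=np.int64)
    out_p = np.empty(max(n - k + 1, 0), dtype=np.int64)
    count = 0
    h = 0
    valid = 0  # run length of non-N bases ending here
    mask = (1 << (2 * k)) - 1
    for i in range(n):
        c = enc[i]
        if c >= 4:
            valid = 0
            h = 0
            continue
        h = ((h << 2) | c) & mask
        valid += 1
        if valid >= k:
            out_h[count] = h
            out_p[count] = i - k + 1
            count += 1
    return out_h[:count], out_p[:count]


# -- banded affine Smith-Waterman (numba) -----------------------------------
# Diagonal d = j - i where i indexes the query, j the subject window.
# Cells with d outside [dlo, dhi] are unreachable.  Pointer codes for H:
# 0 stop, 1 diagonal, 2 from E (gap consuming subject), 3 from F (gap
# consuming query).  E/F pointers: 1 opened from H, 0 extended.


@njit(cache=True)
def _banded_sw(x, y, dlo, dhi, match, mismatch, gap_open, gap_extend):
    m = x.size
    n = y.size
    w = dhi - dlo + 1
    NEG = np.int64(-(10 ** 12))
    H = np.full((m + 1, w), NEG, dtype=np.int64)
    E = np.full((m + 1, w), NEG, dtype=np.int64)
    F = np.full((m + 1, w), NEG, dtype=np.int64)
    PH = np.zeros((m + 1, w), dtype=np.int8)
    PE = np.zeros((m + 1, w), dtype=np.int8)
    PF = np.zeros((m + 1, w), dtype=np.int8)
    for i in range(m + 1):
        jlo = i + dlo
        jhi = i + dhi
        if jlo < 0:
            jlo = 0
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            c = j - i - dlo
            if c < 0 or c >= w:
                continue
            if i == 0 or j == 0:
                H[i, c] = 0
                continue
            # E: gap consuming subject (move left in j)
            e = NEG
            pe = np.int8(0)
            if c - 1 >= 0:
                open_sc = H[i, c - 1] + gap_open
                ext_sc = E[i, c - 1] + gap_extend
                if open_sc >= ext_sc:
                    e = open_sc
                    pe = np.int8(1)
                else:
                    e = ext_sc
                    pe = np.int8(0)
            # F: gap consuming query (move up in i)
            f = NEG
            pf = np.int8(0)
            if c + 1 < w:
                open_sc = H[i - 1, c + 1] + gap_open
                ext_sc = F[i - 1, c + 1] + gap_extend
                if open_sc >= ext_sc:
                    f = open_sc
                    pf = np.int8(1)
                else:
                    f = ext_sc
                    pf = np.int8(0)
            # diagonal
            diag = NEG
            if H[i - 1, c] > NEG // 2:
                xa = x[i - 1]
                yb = y[j - 1]
                s = match if (xa == yb and xa < 4 and yb < 4) else mismatch
                diag = H[i - 1, c] + s
            best = np.int64(0)
            ph = np.int8(0)
            if diag > best:
                best = diag
                ph = np.int8(1)
            if e > best:
                best = e
                ph = np.int8(2)
            if f > best:
                best = f
                ph = np.int8(3)
            H[i, c] = best
            E[i, c] = e
            F[i, c] = f
            PH[i, c] = ph
            PE[i, c] = pe
            PF[i, c] = pf
    # locate the maximum
    best_score = np.int64(0)
    bi = 0
    bj = 0
    for i in range(m + 1):
        jlo = max(i + dlo, 0)
        jhi = min(i + dhi, n)
        for j in range(jlo, jhi + 1):
            c = j - i - dlo
            if 0 <= c < w and H[i, c] > best_score:
                best_score = H[i, c]
                bi = i
                bj = j
    if best_score <= 0:
        return (np.int64(0), 0, 0, 0, 0, 0, 0, 0)
    # traceback
    i = bi
    j = bj
    matches = 0
    aligned = 0
    gaps = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        c = j - i - dlo
        if state == 0:
            p = PH[i, c]
            if p == 0:
                break
            if p == 1:
                xa = x[i - 1]
                yb = y[j - 1]
                if xa == yb and xa < 4:
                    matches += 1
                aligned += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap consuming subject
            p = PE[i, c]
            aligned += 1
            gaps += 1
            j -= 1
            if p == 1:
                state = 0
        else:  # gap consuming query
            p = PF[i, c]
            aligned += 1
            gaps += 1
            i -= 1
            if p == 1:
                state = 0
    return (best_score, i, bi, j, bj, matches, aligned, gaps)


@njit(cache=True)
def _global_nw(x, y, match, mismatch, gap_open, gap_extend):
    """Full affine Needleman-Wunsch; returns (score, path codes).

    Path codes, from alignment start: 1 diagonal, 2 gap in query (consumes
    subject), 3 gap in subject (consumes query).
    """
    m = x.size
    n = y.size
    NEG = np.int64(-(10 ** 12))
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    PH = np.zeros((m + 1, n + 1), dtype=np.int8)
    PE = np.zeros((m + 1, n + 1), dtype=np.int8)
    PF = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = gap_open + gap_extend * (j - 1)
        H[0, j] = E[0, j]
        PH[0, j] = 2
        PE[0, j] = 1 if j == 1 else 0
    for i in range(1, m + 1):
        F[i, 0] = gap_open + gap_extend * (i - 1)
        H[i, 0] = F[i, 0]
        PH[i, 0] = 3
        PF[i, 0] = 1 if i == 1 else 0
        for j in range(1, n + 1):
            open_sc = H[i, j - 1] + gap_open
            ext_sc = E[i, j - 1] + gap_extend
            if open_sc >= ext_sc:
                E[i, j] = open_sc
                PE[i, j] = 1
            else:
                E[i, j] = ext_sc
                PE[i, j] = 0
            open_sc = H[i - 1, j] + gap_open
            ext_sc = F[i - 1, j] + gap_extend
            if open_sc >= ext_sc:
                F[i, j] = open_sc
                PF[i, j] = 1
            else:
                F[i, j] = ext_sc
                PF[i, j] = 0
            xa = x[i - 1]
            yb = y[j - 1]
            s = match if (xa == yb and xa < 4 and yb < 4) else mismatch
            diag = H[i - 1, j - 1] + s
            best = diag
            ph = np.int8(1)
            if E[i, j] > best:
                best = E[i, j]
                ph = np.int8(2)
            if F[i, j] > best:
                best = F[i, j]
                ph = np.int8(3)
            H[i, j] = best
            PH[i, j] = ph
    # traceback
    path = np.empty(m + n, dtype=np.int8)
    count = 0
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 1:
                path[count] = 1
                count += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            path[count] = 2
            count += 1
            p = PE[i, j]
            j -= 1
            if p == 1:
                state = 0
        else:
            path[count] = 3
            count += 1
            p = PF[i, j]
            i -= 1
            if p == 1:
                state = 0
    return H[m, n], path[:count][::-1].copy()


# -- public operations ------------------------------------------------------


def _candidate_regions(seeds_q: np.ndarray, seeds_s: np.ndarray,
                       p: AlignParams, m: int, n: int) -> list:
    """Group seeds into diagonal bands; return [(dlo, dhi, n_seeds), ...]."""
    diags = seeds_s - seeds_q
    order = np.argsort(diags, kind="stable")
    diags = diags[order]
    groups = []
    start = 0
    for i in range(1, diags.size + 1):
        if i == diags.size or diags[i] - diags[i - 1] > p.band:
            dmin = int(diags[start])
            dmax = int(diags[i - 1])
            groups.append((dmin - p.band, dmax + p.band, i - start))
            start = i
    groups.sort(key=lambda g: (-g[2], g[0]))
    return groups[: p.max_candidates]


def _search_one_strand(qenc: np.ndarray, subject: GenomeSeq, p: AlignParams):
    index = subject.kmer_index(p.k)
    qh, qp = _kmer_hashes(qenc, p.k)
    sq = []
    ss = []
    for h, pos in zip(qh, qp):
        hits = index.get(int(h))
        if hits is not None and hits.size <= 1000:  # skip ultra-repetitive seeds
            sq.append(np.full(hits.size, pos, dtype=np.int64))
            ss.append(hits)
    senc = subject.encoded()
    m, n = qenc.size, senc.size
    if not sq:
        if m * n <= p.max_dp_cells:
            regions = [(-m, n, 0)]  # full matrix
        else:
            return None
    else:
        regions = _candidate_regions(np.concatenate(sq), np.concatenate(ss), p, m, n)
    best = None
    for dlo, dhi, _ in regions:
        dlo = max(dlo, -m)
        dhi = min(dhi, n)
        res = _banded_sw(qenc, senc, np.int64(dlo), np.int64(dhi),
                         p.match, p.mismatch, p.gap_open, p.gap_extend)
        score = int(res[0])
        if score > 0 and (best is None or score > best[0]):
            best = tuple(int(v) for v in res)
    return best


def best_local_hit(query: GenomeSeq, subject, params: AlignParams = AlignParams()):
    """Highest-scoring local alignment of ``query`` against ``subject``.

    ``subject`` may be a :class:`GenomeSeq` or a multi-contig
    :class:`Genome` (each contig searched, never across junctions).  Both
    query strands are searched.  Returns a :class:`LocalHit` or ``None``
    when no positive-scoring alignment is found.
    """
    if params.k > len(query):
        raise ValueError(
            f"k={params.k} exceeds query length {len(query)}"
        )
    contigs = subject.contigs if isinstance(subject, Genome) else [subject]
    m = len(query)
    q_fwd = query.encoded()
    q_rev = _ENCODE[
        np.frombuffer(revcomp(query.sequence).encode("ascii"), dtype=np.uint8)
    ]
    best_hit = None
    for contig in contigs:
        for strand, qenc in (("+", q_fwd), ("-", q_rev)):
            res = _search_one_strand(qenc, contig, params)
            if res is None:
                continue
            score, qs, qe, ss, se, matches, aligned, gaps = res
            if strand == "-":
                qs, qe = m - qe, m - qs
            hit = LocalHit(
                query_id=query.id, q_start=qs, q_end=qe,
                subject_id=contig.id, s_start=ss, s_end=se,
                strand=strand, score=score, matches=matches,
                aligned_length=aligned, gaps=gaps, query_length=m,
            )
            if best_hit is None or (hit.score, hit.strand == "+", -hit.s_start) > (
                best_hit.score, best_hit.strand == "+", -best_hit.s_start
            ):
                best_hit = hit
    return best_hit


def global_align(a: GenomeSeq, b: GenomeSeq, params: AlignParams = AlignParams()):
    """Affine-gap global alignment; returns (score, gapped_a, gapped_b)."""
    score, path = _global_nw(a.encoded(), b.encoded(),
                             params.match, params.mismatch,
                             params.gap_open, params.gap_extend)
    ga, gb = [], []
    i = j = 0
    for op in path:
        if op == 1:
            ga.append(a.sequence[i]); gb.append(b.sequence[j]); i += 1; j += 1
        elif op == 2:
            ga.append("-"); gb.append(b.sequence[j]); j += 1
        else:
            ga.append(a.sequence[i]); gb.append("-"); i += 1
    return int(score), "".join(ga), "".join(gb)


# -- FASTA IO ---------------------------------------------------------------


def read_fasta(path) -> Genome:
    """Read a (possibly multi-contig) FASTA file into a Genome."""
    path = Path(path)
    contigs = [GenomeSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return Genome(path.stem, contigs)


def write_fasta(records, path) -> None:
    """Write GenomeSeq records (or a Genome's contigs) to FASTA."""
    if isinstance(records, Genome):
        records = records.contigs
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")
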