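"""Candidate identification and redundancy reduction.

Mirrors the field's HMM-search -> length-filter -> CD-HIT stage with three
auditable primitives:

* a strict length filter (``length > min_len``, ``length <= max_len``);
* global percent identity, defined as the number of identically aligned
  residue pairs under the optimal BLOSUM62 affine-gap global alignment
  (maximizing matches among equal-score optima) divided by the shorter
  sequence length -- the CD-HIT normalisation convention, under which a
  fragment contained in a longer sequence scores 1.0;
* greedy longest-first clustering at an identity threshold, and a best-hit
  local-alignment screen against an annotated reference panel.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .panel import ReferencePanel
from .records import ProteinRecord

GAP_OPEN = -11
GAP_EXTEND = -1


def _blosum62_codes() -> np.ndarray:
    """BLOSUM62 as a 26x26 integer table indexed by (ord(residue) - 65)."""
    matrix = substitution_matrices.load("BLOSUM62")
    table = np.zeros((26, 26), dtype=np.int64)
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    for a in letters:
        for b in letters:
            table[ord(a) - 65, ord(b) - 65] = int(matrix[a, b])
    return table


_SUB = _blosum62_codes()
_NEG = -(2 ** 40)


def _gotoh_kernel(a, b, sub, open_gap, extend_gap):  # pragma: no cover
    """Affine-gap global alignment (Gotoh): maximal score, and maximal match
    count among equal-score alignments.  States: M (residue pair), X (gap in
    b, consuming a), Y (gap in a, consuming b); end gaps are penalised."""
    n, m = a.size, b.size
    ms = np.full(m + 1, _NEG, np.int64)
    xs = np.full(m + 1, _NEG, np.int64)
    ys = np.full(m + 1, _NEG, np.int64)
    mm = np.zeros(m + 1, np.int64)
    xm = np.zeros(m + 1, np.int64)
    ym = np.zeros(m + 1, np.int64)
    ms[0] = 0
    for j in range(1, m + 1):
        ys[j] = open_gap + (j - 1) * extend_gap
    pm_s = np.empty(m + 1, np.int64)
    px_s = np.empty(m + 1, np.int64)
    py_s = np.empty(m + 1, np.int64)
    pm_m = np.empty(m + 1, np.int64)
    px_m = np.empty(m + 1, np.int64)
    py_m = np.empty(m + 1, np.int64)
    for i in range(1, n + 1):
        pm_s[:] = ms
        px_s[:] = xs
        py_s[:] = ys
        pm_m[:] = mm
        px_m[:] = xm
        py_m[:] = ym
        ms[0] = _NEG
        ys[0] = _NEG
        mm[0] = 0
        ym[0] = 0
        xs[0] = open_gap + (i - 1) * extend_gap
        xm[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            # M: best predecessor at (i-1, j-1) plus the substitution score
            s_in, m_in = pm_s[j - 1], pm_m[j - 1]
            if px_s[j - 1] > s_in or (px_s[j - 1] == s_in and px_m[j - 1] > m_in):
                s_in, m_in = px_s[j - 1], px_m[j - 1]
            if py_s[j - 1] > s_in or (py_s[j - 1] == s_in and py_m[j - 1] > m_in):
                s_in, m_in = py_s[j - 1], py_m[j - 1]
            bj = b[j - 1]
            ms[j] = s_in + sub[ai - 65, bj - 65]
            mm[j] = m_in + (1 if ai == bj else 0)
            # X: gap in b, consuming a_i, from row i-1 at the same column
            s_in, m_in = pm_s[j] + open_gap, pm_m[j]
            if px_s[j] + extend_gap > s_in or (
                px_s[j] + extend_gap == s_in and px_m[j] > m_in
            ):
                s_in, m_in = px_s[j] + extend_gap, px_m[j]
            if py_s[j] + open_gap > s_in or (
                py_s[j] + open_gap == s_in and py_m[j] > m_in
            ):
                s_in, m_in = py_s[j] + open_gap, py_m[j]
            xs[j], xm[j] = s_in, m_in
            # Y: gap in a, consuming b_j, from column j-1 in the current row
            s_in, m_in = ms[j - 1] + open_gap, mm[j - 1]
            if xs[j - 1] + open_gap > s_in or (
                xs[j - 1] + open_gap == s_in and xm[j - 1] > m_in
            ):
                s_in, m_in = xs[j - 1] + open_gap, xm[j - 1]
            if ys[j - 1] + extend_gap > s_in or (
                ys[j - 1] + extend_gap == s_in and ym[j - 1] > m_in
            ):
                s_in, m_in = ys[j - 1] + extend_gap, ym[j - 1]
            ys[j], ym[j] = s_in, m_in
    best_s, best_m = ms[m], mm[m]
    if xs[m] > best_s or (xs[m] == best_s and xm[m] > best_m):
        best_s, best_m = xs[m], xm[m]
    if ys[m] > best_s or (ys[m] == best_s and ym[m] > best_m):
        best_s, best_m = ys[m], ym[m]
    return best_s, best_m


def _lcs_kernel(a, b):  # pragma: no cover
    """Longest common subsequence length: an upper bound on the number of
    identically aligned pairs under ANY global alignment, used to prune
    pairs that cannot reach an identity threshold."""
    m = b.size
    prev = np.zeros(m + 1, np.int64)
    cur = np.zeros(m + 1, np.int64)
    for i in range(a.size):
        ai = a[i]
        for j in range(1, m + 1):
            best = prev[j]
            diag = prev[j - 1] + (1 if b[j - 1] == ai else 0)
            if diag > best:
                best = diag
            if cur[j - 1] > best:
                best = cur[j - 1]
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


try:  # numba gives ~100x faster kernels; the pure-python paths are identical
    from numba import njit

    _gotoh = njit(cache=True)(_gotoh_kernel)
    _lcs = njit(cache=True)(_lcs_kernel)
except Exception:  # pragma: no cover
    _gotoh = _gotoh_kernel
    _lcs = _lcs_kernel


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def identity_upper_bound(a: str, b: str) -> float:
    """LCS / shorter length: never below the true pairwise identity."""
    return int(_lcs(_codes(a), _codes(b))) / min(len(a), len(b))


def _composition(seq: str) -> np.ndarray:
    """Residue counts over A..Z; aligned matches never exceed the multiset
    intersection of two compositions."""
    return np.bincount(_codes(seq) - 65, minlength=26)


def global_alignment_stats(a: str, b: str) -> tuple[int, int]:
    """(optimal global score, matches in the match-maximal optimal alignment)
    under BLOSUM62 with affine gaps (open -11, extend -1), end gaps scored."""
    return tuple(int(v) for v in _gotoh(_codes(a), _codes(b), _SUB,
                                        GAP_OPEN, GAP_EXTEND))


def filter_by_length(records: Iterable[ProteinRecord], min_len: int,
                     max_len: int | None = None) -> list[ProteinRecord]:
    """Keep records with ``min_len < length <= max_len``, preserving order.

    The lower bound is strict ("greater than N residues"); the upper bound is
    inclusive.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is not None and max_len <= min_len:
        raise ValueError("max_len must exceed min_len")
    hi = float("inf") if max_len is None else max_len
    return [r for r in records if min_len < len(r) <= hi]


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Fraction of identically aligned residue pairs under the optimal global
    alignment, normalised by the shorter sequence length.

    Symmetric; a fragment fully contained in a longer sequence scores 1.0.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be nonempty")
    _, matches = global_alignment_stats(sa, sb)
    return matches / min(len(sa), len(sb))


@dataclass
class Cluster:
    """A dereplication cluster: founder representative plus members."""

    representative: str
    members: list[str]
    identities: list[float]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")

    def __len__(self) -> int:
        return len(self.members)


def dereplicate_greedy(records: Sequence[ProteinRecord],
                       threshold: float) -> list[Cluster]:
    """CD-HIT-style greedy clustering.

    Records are visited longest-first (ties: lexicographic id); each joins the
    first existing cluster whose representative matches at >= ``threshold``
    identity, otherwise it founds a new cluster.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    comps = {r.id: _composition(r.sequence) for r in ordered}
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            # Two successively tighter upper bounds on identity (shared
            # residue composition, then LCS) prune pairs that cannot reach
            # the threshold before the full alignment runs.
            shorter = min(len(rec), len(rep))
            comp_bound = int(
                np.minimum(comps[rec.id], comps[rep.id]).sum()) / shorter
            if comp_bound < threshold:
                continue
            if identity_upper_bound(rec.sequence, rep.sequence) < threshold:
                continue
            ident = pairwise_identity(rec, rep)
            if ident >= threshold:
                cluster.members.append(rec.id)
                cluster.identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec.id, members=[rec.id],
                                    identities=[1.0]))
            reps.append(rec)
    return clusters


def representatives(clusters: Iterable[Cluster],
                    records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    by_id = {r.id: r for r in records}
    return [by_id[c.representative] for c in clusters]


@functools.lru_cache(maxsize=4)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class ScreenHit:
    """Best panel hit for one query under local alignment."""

    query_id: str
    ref_id: str | None
    identity: float
    coverage: float
    passed: bool


def _local_hit(query_seq: str, ref_seq: str) -> tuple[float, float, float]:
    """(score, identity over aligned columns, reference coverage)."""
    aln = _local_aligner().align(ref_seq, query_seq)
    if len(aln) == 0:  # pragma: no cover - BLOSUM62 always aligns something
        return 0.0, 0.0, 0.0
    best = aln[0]
    identities = best.counts().identities
    length = best.length
    ref_blocks = best.aligned[0]
    span = ref_blocks[-1][1] - ref_blocks[0][0] if len(ref_blocks) else 0
    identity = identities / length if length else 0.0
    coverage = span / len(ref_seq)
    return float(best.score), identity, coverage


def screen_candidates(records: Iterable[ProteinRecord], panel: ReferencePanel,
                      min_identity: float = 0.25,
                      min_coverage: float = 0.5) -> list[ScreenHit]:
    """Best-hit local-alignment screen versus the annotated panel.

    A record passes iff some reference is hit at >= ``min_identity`` over an
    aligned span covering >= ``min_coverage`` of that reference; the passing
    hit with the highest identity (else the overall best-scoring hit) is
    attached.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    hits: list[ScreenHit] = []
    for rec in records:
        best_pass: tuple[float, str, float, float] | None = None
        best_any: tuple[float, str, float, float] | None = None
        for entry in panel:
            score, ident, cov = _local_hit(rec.sequence, entry.sequence)
            key = (score, entry.id, ident, cov)
            if best_any is None or score > best_any[0]:
                best_any = key
            if ident >= min_identity and cov >= min_coverage:
                if best_pass is None or ident > best_pass[2]:
                    best_pass = key
        chosen = best_pass if best_pass is not None else best_any
        assert chosen is not None
        hits.append(
            ScreenHit(
                query_id=rec.id,
                ref_id=chosen[1],
                identity=chosen[2],
                coverage=chosen[3],
                passed=best_pass is not None,
            )
        )
    return hits


def passing_records(records: Sequence[ProteinRecord],
                    hits: Sequence[ScreenHit]) -> list[ProteinRecord]:
    ok = {h.query_id for h in hits if h.passed}
    return [r for r in records if r.id in ok]
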