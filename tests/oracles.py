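"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and separate from the package
implementation: exhaustive recursions and literal rule transcriptions whose
correctness is self-evident at small input sizes.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_global_alignments(a: str, b: str, open_gap: float = -11.0,
                                extend_gap: float = -1.0):
    """(score, matches) for every global alignment of two tiny strings,
    with affine end-gap-penalised scoring.  Exponential: keep len <= ~7."""
    out: list[tuple[float, int]] = []

    def rec(i, j, prev, score, matches):
        if i == len(a) and j == len(b):
            out.append((score, matches))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M",
                score + _BLOSUM62[a[i], b[j]], matches + (a[i] == b[j]))
        if i < len(a):  # gap in b
            rec(i + 1, j, "A",
                score + (extend_gap if prev == "A" else open_gap), matches)
        if j < len(b):  # gap in a
            rec(i, j + 1, "B",
                score + (extend_gap if prev == "B" else open_gap), matches)

    rec(0, 0, "M", 0.0, 0)
    return out


def best_global_alignment_score(a: str, b: str) -> float:
    return max(score for score, _ in enumerate_global_alignments(a, b))


def best_score_and_matches(a: str, b: str) -> tuple[float, int]:
    """Optimal score, and the maximal match count among optimal alignments."""
    alignments = enumerate_global_alignments(a, b)
    best = max(score for score, _ in alignments)
    matches = max(m for score, m in alignments if score == best)
    return best, matches


def identity_oracle(a: str, b: str) -> float:
    """Matches under the (match-maximal) optimal global alignment / shorter
    length.  Tiny strings only."""
    _, matches = best_score_and_matches(a, b)
    return matches / min(len(a), len(b))


def greedy_clusters_oracle(records, threshold: float, identity_fn):
    """Reference greedy rule: longest-first (ties by id), join the first
    cluster whose representative matches at >= threshold, else found one.
    Returns {representative_id: [member ids]}.  The identity matrix is
    supplied by the caller; this oracle checks only the clustering logic."""
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: dict[str, list[str]] = {}
    reps: dict[str, str] = {}  # rep id -> sequence
    for rec in ordered:
        for rep_id, rep_seq in reps.items():
            if identity_fn(rec.sequence, rep_seq) >= threshold:
                clusters[rep_id].append(rec.id)
                break
        else:
            clusters[rec.id] = [rec.id]
            reps[rec.id] = rec.sequence
    return clusters


def metal_rule_oracle(triplet: str) -> str:
    """Literal transcription of the motif rule: D-x-D lanthanide,
    D-x-{A,T,S} calcium, gap at a coordinating position incomplete,
    anything else unknown."""
    first, third = triplet[0], triplet[2]
    if first == "D" and third == "D":
        return "lanthanide"
    if first == "D" and third in ("A", "T", "S"):
        return "calcium"
    if first == "-" or third == "-":
        return "incomplete"
    return "unknown"
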