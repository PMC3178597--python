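"""Pairwise and progressive multiple alignment.

A linear-gap dynamic-programming aligner in two modes: global
(Needleman–Wunsch) and overlap (terminal gaps free, as in contig
assembly).  Identity is computed over the doubly-occupied overlap
region only: a column matches iff both symbols are identical non-gaps;
internal gap columns inside the overlap count against identity.  This
mirrors the "minimum match percentage / minimum overlap" semantics of
assembly software used to build alignment groups.

The multiple aligner is progressive: a neighbor-joining guide tree on
pairwise alignment distances (1 - identity), then profile-profile DP
with mean-pairwise column scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .distance import DistanceMatrix, Tree, TreeNode, nj_tree
from .io import GAP, SequenceRecord


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for the linear-gap DP aligner.

    ``terminal_gaps_free=True`` selects overlap mode (leading/trailing
    gaps score 0), the mode used for clustering identities.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    terminal_gaps_free: bool = False

    def __post_init__(self) -> None:
        if self.gap >= 0:
            raise AlignmentError("gap penalty must be negative")
        if self.match <= self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")


#: default parameters for clustering identity (overlap mode)
OVERLAP_PARAMS = AlignmentParams(terminal_gaps_free=True)


@dataclass(frozen=True)
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    score: float
    overlap_start: int  # 1-based column of first doubly-occupied position
    overlap_end: int    # 1-based column of last doubly-occupied position
    overlap_len: int
    identity: float


def _score_grid(a: str, b: str, params: AlignmentParams) -> np.ndarray:
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    return np.where(av[:, None] == bv[None, :], params.match, params.mismatch)


def _fill(S: np.ndarray, params: AlignmentParams) -> np.ndarray:
    """DP table H (m+1 x n+1) under linear gaps.

    Rows are vectorized: the within-row left-gap recursion
    H[i,j] = max(E[j], H[i,j-1] + g) is solved with a running maximum of
    E[j] - j*g.
    """
    m, n = S.shape
    g = params.gap
    free = params.terminal_gaps_free
    H = np.zeros((m + 1, n + 1))
    jj = np.arange(n + 1)
    if not free:
        H[0] = jj * g
    col0 = np.zeros(m + 1) if free else np.arange(m + 1) * g
    H[:, 0] = col0
    for i in range(1, m + 1):
        E = np.empty(n + 1)
        E[0] = H[i, 0]
        E[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + g)
        H[i] = np.maximum.accumulate(E - jj * g) + jj * g
    return H


def _traceback(a: str, b: str, H: np.ndarray, S: np.ndarray,
               params: AlignmentParams, end: tuple[int, int]) -> tuple[str, str]:
    g = params.gap
    i, j = end
    m, n = S.shape
    out_a: list[str] = []
    out_b: list[str] = []
    # trailing free gaps (overlap mode endpoint off the corner)
    if i < m:
        out_a.extend(reversed(a[i:]))
        out_b.extend(GAP * (m - i))
    if j < n:
        out_a.extend(GAP * (n - j))
        out_b.extend(reversed(b[j:]))
    tol = 1e-9
    free = params.terminal_gaps_free
    while i > 0 and j > 0:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= tol:
            i, j = i - 1, j - 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif abs(h - (H[i - 1, j] + g)) <= tol:
            i -= 1
            out_a.append(a[i])
            out_b.append(GAP)
        else:
            j -= 1
            out_a.append(GAP)
            out_b.append(b[j])
        if free and (i == 0 or j == 0):
            break
    # leading gaps (free in overlap mode, penalized in global mode)
    out_a.extend(GAP * j)
    out_b.extend(reversed(b[:j]))
    out_a.extend(reversed(a[:i]))
    out_b.extend(GAP * i)
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _identity_stats(aligned_a: str, aligned_b: str) -> tuple[int, int, int, float]:
    occ = [k for k, (x, y) in enumerate(zip(aligned_a, aligned_b))
           if x != GAP and y != GAP]
    if not occ:
        return 0, -1, 0, 0.0
    start, end = occ[0], occ[-1]
    span_a = aligned_a[start:end + 1]
    span_b = aligned_b[start:end + 1]
    matches = sum(1 for x, y in zip(span_a, span_b) if x == y and x != GAP)
    overlap_len = end - start + 1
    return start + 1, end + 1, overlap_len, matches / overlap_len


def align_pair(a: SequenceRecord | str, b: SequenceRecord | str,
               params: AlignmentParams = AlignmentParams()) -> PairwiseResult:
    """Optimal pairwise alignment of two unaligned DNA sequences.

    Traceback ties prefer diagonal, then up (gap in ``b``), then left
    moves, making the reported alignment deterministic.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise AlignmentError("cannot align an empty sequence")
    if GAP in sa or GAP in sb:
        raise AlignmentError("inputs to align_pair must be unaligned (no '-')")
    S = _score_grid(sa, sb, params)
    H = _fill(S, params)
    m, n = S.shape
    if params.terminal_gaps_free:
        # best endpoint anywhere on the last row or column
        best = (H[m, n], (m, n))
        for i in range(m + 1):
            if H[i, n] > best[0] + 1e-9:
                best = (H[i, n], (i, n))
        for j in range(n + 1):
            if H[m, j] > best[0] + 1e-9:
                best = (H[m, j], (m, j))
        score, end = best
    else:
        score, end = H[m, n], (m, n)
    aligned_a, aligned_b = _traceback(sa, sb, H, S, params, end)
    start, stop, olen, ident = _identity_stats(aligned_a, aligned_b)
    return PairwiseResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        overlap_start=start,
        overlap_end=stop,
        overlap_len=olen,
        identity=ident,
    )


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_columns(rows: list[str]) -> tuple[np.ndarray, list[str], dict[str, int]]:
    symbols = sorted({ch for r in rows for ch in r})
    index = {s: k for k, s in enumerate(symbols)}
    L = len(rows[0])
    counts = np.zeros((L, len(symbols)))
    for r in rows:
        for pos, ch in enumerate(r):
            counts[pos, index[ch]] += 1
    return counts, symbols, index


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    params: AlignmentParams) -> tuple[list[str], list[str]]:
    """Profile-profile DP under mean-pairwise column scoring."""
    symbols = sorted({ch for r in rows_a + rows_b for ch in r} | {GAP})
    index = {s: k for k, s in enumerate(symbols)}
    k = len(symbols)
    # symbol-pair scores: gap/gap 0, gap/base gap penalty, identical bases match
    M = np.full((k, k), params.mismatch)
    gi = index[GAP]
    for s, si in index.items():
        M[si, si] = params.match if s != GAP else 0.0
        M[si, gi] = M[gi, si] = params.gap
    M[gi, gi] = 0.0

    def counts(rows):
        L = len(rows[0])
        c = np.zeros((L, k))
        for r in rows:
            for pos, ch in enumerate(r):
                c[pos, index[ch]] += 1
        return c

    ca, cb = counts(rows_a), counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    S = (ca @ M @ cb.T) / (na * nb)
    # cost of aligning a column against an all-gap column in the other profile
    gap_a = (ca @ M[:, gi]) / na  # per column of A
    gap_b = (cb @ M[:, gi]) / nb  # per column of B
    La, Lb = len(gap_a), len(gap_b)
    H = np.zeros((La + 1, Lb + 1))
    H[:, 0] = np.concatenate(([0.0], np.cumsum(gap_a)))
    H[0, :] = np.concatenate(([0.0], np.cumsum(gap_b)))
    cum_b = H[0, :].copy()
    for i in range(1, La + 1):
        E = np.empty(Lb + 1)
        E[0] = H[i, 0]
        E[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + gap_a[i - 1])
        H[i] = np.maximum.accumulate(E - cum_b) + cum_b
    # traceback: diagonal > up > left
    i, j = La, Lb
    cols: list[tuple[bool, bool]] = []  # (consume A column, consume B column)
    tol = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= tol:
            cols.append((True, True))
            i, j = i - 1, j - 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] + gap_a[i - 1])) <= tol:
            cols.append((True, False))
            i -= 1
        else:
            cols.append((False, True))
            j -= 1
    cols.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    pa = pb = 0
    for take_a, take_b in cols:
        for r_idx, r in enumerate(rows_a):
            out_a[r_idx] += r[pa] if take_a else GAP
        for r_idx, r in enumerate(rows_b):
            out_b[r_idx] += r[pb] if take_b else GAP
        pa += take_a
        pb += take_b
    return out_a, out_b


def progressive_msa(records: list[SequenceRecord],
                    params: AlignmentParams = AlignmentParams()) -> list[SequenceRecord]:
    """Progressive multiple alignment; output order matches input order.

    Degapping any output row returns its input sequence unchanged.
    """
    if len(records) == 0:
        raise AlignmentError("no records to align")
    if len(records) == 1:
        warnings.warn("progressive_msa called with a single record; returned unchanged")
        return list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate record ids in MSA input")
    if len(records) == 2:
        res = align_pair(records[0], records[1], params)
        return [replace(records[0], residues=res.aligned_a),
                replace(records[1], residues=res.aligned_b)]

    n = len(records)
    dists = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = align_pair(records[i], records[j], params)
            dists[i, j] = dists[j, i] = 1.0 - r.identity
    guide = nj_tree(DistanceMatrix(ids=list(ids), values=dists))
    by_id = {r.id: r for r in records}

    def build(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [by_id[node.label].residues], [node.label]
        rows, labels = build(node.children[0])
        for child in node.children[1:]:
            rows_c, labels_c = build(child)
            rows, rows_c = _merge_profiles(rows, rows_c, params)
            rows = rows + rows_c
            labels = labels + labels_c
        return rows, labels

    rows, labels = build(guide.root)
    aligned = dict(zip(labels, rows))
    return [replace(r, residues=aligned[r.id]) for r in records]
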