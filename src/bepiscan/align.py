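"""Alignment machinery: global alignment, ungapped database search, bit scores.

Two distinct alignment operations are used by the epitope predictor:

* ``global_align`` — Needleman–Wunsch/Gotoh global alignment with affine
  gaps and free end gaps (EMBOSS-needle conventions: gap open 10, gap
  extend 0.5, BLOSUM62).  Used for dataset similarity statistics and
  redundancy reduction.

* ``find_ungapped_hits`` — exact enumeration of every maximal ungapped
  local hit (equal-length query/subject segments) against a database of
  epitope peptides, qualifying a window by length >= ``min_length`` and
  identity >= ``min_identity_pct``.  The engine is a seed-and-verify scan:
  the seed word length is derived from the thresholds so that every
  qualifying window provably contains an exact seed match, hence the
  result is identical to an exhaustive all-windows enumeration.

Hit raw scores are BLOSUM62 sums; bit scores use the Karlin–Altschul
rescaling ``(lambda * raw - ln K) / ln 2`` with the standard ungapped
BLOSUM62 constants by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import BLOSUM62, encode
from .datasets import EpitopeDataset

__all__ = [
    "SearchParams",
    "GlobalAlignment",
    "UngappedHit",
    "EpitopeSearchIndex",
    "global_align",
    "mean_pairwise_identity",
    "find_ungapped_hits",
    "bit_score",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the ungapped hit search.

    min_length : minimum hit length in residues (default 8).
    min_identity_pct : minimum hit identity in percent (default 80).
    allow_gaps : gapped mode is unsupported; must be False.
    lam, karlin_k : Karlin–Altschul parameters for bit scoring
        (defaults: ungapped BLOSUM62, lambda=0.3176, K=0.134).
    per_subject_best_only : report only the best-scoring hit per database
        record (ties: longest, then smallest query start).
    """

    min_length: int = 8
    min_identity_pct: float = 80.0
    allow_gaps: bool = False
    lam: float = 0.3176
    karlin_k: float = 0.134
    per_subject_best_only: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.allow_gaps:
            raise NotImplementedError("gapped hit mode is not supported")


def bit_score(raw_score: float, params: SearchParams = SearchParams()) -> float:
    """Karlin–Altschul bit score: ``(lambda * raw - ln K) / ln 2``."""
    if not (params.lam > 0) or not (params.karlin_k > 0):
        raise ValueError("lambda and K must be positive")
    return (params.lam * raw_score - math.log(params.karlin_k)) / math.log(2)


# ---------------------------------------------------------------------------
# Global alignment (Gotoh, affine gaps, free end gaps)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalAlignment:
    """A global alignment of two sequences with percent identity."""

    aligned_a: str
    aligned_b: str
    identity_pct: float
    score: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def global_align(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: np.ndarray = BLOSUM62,
) -> GlobalAlignment:
    """Optimal global affine-gap alignment with free end gaps.

    Gap cost follows the EMBOSS convention: a gap of length L costs
    ``gap_open + L * gap_extend``; end gaps are free.  Traceback ties are
    broken deterministically preferring diagonal over up (gap in ``b``)
    over left (gap in ``a``).  ``identity_pct`` is computed over the full
    alignment length, end gaps included.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    go = gap_open + gap_extend  # cost of a gap's first residue
    ge = gap_extend

    # state 0 = M (diagonal), 1 = X (up: a-residue vs gap), 2 = Y (left)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading gap in b
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free leading gap in a

    sub = matrix
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        srow = sub[ea[i - 1]]
        for j in range(1, m + 1):
            s = srow[eb[j - 1]]
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge)

    # free trailing gaps: best cell on the last row or column, preferring
    # (n, m), then the last column bottom-up, then the last row right-to-left
    def cell_best(i: int, j: int) -> float:
        return max(M[i][j], X[i][j], Y[i][j])

    end_i, end_j, best = n, m, cell_best(n, m)
    for i in range(n - 1, -1, -1):
        v = cell_best(i, m)
        if v > best:
            end_i, end_j, best = i, m, v
    for j in range(m - 1, -1, -1):
        v = cell_best(n, j)
        if v > best:
            end_i, end_j, best = n, j, v

    out_a: list[str] = []
    out_b: list[str] = []
    # trailing free gaps
    if end_i < n:
        out_a.append(a[end_i:][::-1])
        out_b.append("-" * (n - end_i))
    if end_j < m:
        out_a.append("-" * (m - end_j))
        out_b.append(b[end_j:][::-1])

    i, j = end_i, end_j
    # entry state: prefer M over X over Y on ties
    if M[i][j] == best:
        state = 0
    elif X[i][j] == best:
        state = 1
    else:
        state = 2

    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i][j] - sub[ea[i - 1]][eb[j - 1]]
            i, j = i - 1, j - 1
            if M[i][j] == prev:
                state = 0
            elif X[i][j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            v = X[i][j]
            i -= 1
            if j == 0:
                state = 1  # free leading gap column
            elif M[i][j] - go == v:
                state = 0
            elif X[i][j] - ge == v:
                state = 1
            else:
                state = 2
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            v = Y[i][j]
            j -= 1
            if i == 0:
                state = 2
            elif M[i][j] - go == v:
                state = 0
            elif X[i][j] - go == v:
                state = 1
            else:
                state = 2

    # leading free gaps for whatever prefix remains
    if i > 0:
        out_a.append(a[:i][::-1])
        out_b.append("-" * i)
    if j > 0:
        out_a.append("-" * j)
        out_b.append(b[:j][::-1])

    aligned_a = "".join(out_a)[::-1]
    aligned_b = "".join(out_b)[::-1]
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    identity = 100.0 * matches / len(aligned_a)
    return GlobalAlignment(aligned_a, aligned_b, identity, float(best))


def mean_pairwise_identity(
    ds_a: EpitopeDataset,
    ds_b: EpitopeDataset | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> dict:
    """Mean and population std of pairwise global-alignment identity.

    Within-dataset mode (``ds_b is None``): identity over all ordered pairs
    (i, j), i != j (N x (N-1) alignments).  Cross-dataset mode: all pairs
    (a, b).  ``max_pairs`` switches to a seeded random subsample of that
    pair population, for datasets where the full quadratic sweep is
    impractical.  Identity is over the full alignment length (needle
    convention).
    """
    within = ds_b is None
    if within and len(ds_a) < 2:
        raise ValueError("within-dataset mode needs at least 2 records")
    if not within and (len(ds_a) == 0 or len(ds_b) == 0):
        raise ValueError("datasets must be non-empty")

    vals: list[float] = []
    if max_pairs is None:
        if within:
            seqs = ds_a.sequences
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    v = global_align(seqs[i], seqs[j]).identity_pct
                    vals.append(v)
                    vals.append(v)  # ordered pairs (i,j) and (j,i)
        else:
            for ra in ds_a:
                for rb in ds_b:
                    vals.append(
                        global_align(ra.sequence, rb.sequence).identity_pct
                    )
    else:
        rng = np.random.default_rng(seed)
        n_a = len(ds_a)
        n_b = n_a if within else len(ds_b)
        count = 0
        while count < max_pairs:
            i = int(rng.integers(n_a))
            j = int(rng.integers(n_b))
            if within and i == j:
                continue
            other = ds_a if within else ds_b
            vals.append(
                global_align(ds_a[i].sequence, other[j].sequence).identity_pct
            )
            count += 1
    arr = np.asarray(vals)
    return {
        "mean_pct": float(arr.mean()),
        "std_pct": float(arr.std()),
        "n_pairs": len(vals),
    }


# ---------------------------------------------------------------------------
# Ungapped hit search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UngappedHit:
    """An ungapped query/subject segment pair (1-based inclusive coords)."""

    query_start: int
    query_end: int
    subject_id: str
    subject_start: int
    subject_end: int
    length: int
    identity_pct: float
    raw_score: int
    bit_score: float


def _window_qualifies(matches: int, length: int, min_identity_pct: float) -> bool:
    return matches * 100.0 >= min_identity_pct * length - 1e-9


def _seed_word_length(
    min_length: int, min_identity_pct: float, max_window: int
) -> int:
    """Longest word k s.t. every qualifying window contains an exact k-run.

    A window of length L with the minimum qualifying number of matches has
    its matches split into at most (mismatches + 1) runs, the longest of
    which is at least ceil(matches_min / (mismatches + 1)); k is the
    minimum of that bound over all admissible window lengths.
    """
    k = min_length
    for L in range(min_length, max(max_window, min_length) + 1):
        matches_min = math.ceil(min_identity_pct * L / 100.0 - 1e-9)
        mism = L - matches_min
        if matches_min <= 0:
            return 1
        k = min(k, math.ceil(matches_min / (mism + 1)))
    return max(1, k)


class EpitopeSearchIndex:
    """A seed-word index over an epitope database for repeated exact search.

    Building the index once and calling :meth:`search` for many queries is
    the fast path used by cross-validation; ``find_ungapped_hits`` is the
    one-shot convenience wrapper.
    """

    def __init__(self, db: EpitopeDataset, params: SearchParams = SearchParams()):
        if len(db) == 0:
            raise ValueError("database must be non-empty")
        self.db = db
        self.params = params
        self._enc = [encode(r.sequence) for r in db]
        max_len = max(len(e) for e in self._enc)
        self.k = min(
            _seed_word_length(params.min_length, params.min_identity_pct, max_len),
            min(len(e) for e in self._enc),
        )
        self._seeds: dict[bytes, list[tuple[int, int]]] = {}
        for si, e in enumerate(self._enc):
            buf = e.tobytes()
            for pos in range(len(e) - self.k + 1):
                self._seeds.setdefault(buf[pos : pos + self.k], []).append(
                    (si, pos)
                )

    def _candidate_diagonals(self, q: np.ndarray) -> list[tuple[int, int]]:
        cand: set[tuple[int, int]] = set()
        buf = q.tobytes()
        for qi in range(len(q) - self.k + 1):
            for si, sp in self._seeds.get(buf[qi : qi + self.k], ()):
                cand.add((si, qi - sp))
        return sorted(cand)

    def _diagonal_hits(
        self, q: np.ndarray, si: int, diag: int
    ) -> list[UngappedHit]:
        p = self.params
        s = self._enc[si]
        i0 = max(0, diag)
        j0 = i0 - diag
        d = min(len(q) - i0, len(s) - j0)
        if d < p.min_length:
            return []
        qseg = q[i0 : i0 + d]
        sseg = s[j0 : j0 + d]
        m = (qseg == sseg).astype(np.int64)
        c = np.concatenate(([0], np.cumsum(m)))
        sp = np.concatenate(
            ([0], np.cumsum(BLOSUM62[qseg, sseg]))
        )
        wins: list[tuple[int, int, int]] = []  # (start, length, matches)
        for L in range(p.min_length, d + 1):
            matches = c[L:] - c[:-L]
            ok = matches * 100.0 >= p.min_identity_pct * L - 1e-9
            for a in np.nonzero(ok)[0]:
                wins.append((int(a), L, int(matches[a])))
        if not wins:
            return []
        # suppress windows contained in another qualifying window on this
        # diagonal
        maximal = [
            (a, L, mt)
            for (a, L, mt) in wins
            if not any(
                L2 > L and a2 <= a and a2 + L2 >= a + L
                for (a2, L2, _) in wins
            )
        ]
        hits = []
        for a, L, mt in maximal:
            raw = int(sp[a + L] - sp[a])
            hits.append(
                UngappedHit(
                    query_start=i0 + a + 1,
                    query_end=i0 + a + L,
                    subject_id=self.db[si].id,
                    subject_start=j0 + a + 1,
                    subject_end=j0 + a + L,
                    length=L,
                    identity_pct=100.0 * mt / L,
                    raw_score=raw,
                    bit_score=bit_score(raw, p),
                )
            )
        return hits

    def search(self, query: str) -> list[UngappedHit]:
        """All maximal qualifying ungapped hits of ``query`` in the database.

        With ``per_subject_best_only`` (the default) only each subject's
        highest-raw-score hit is kept (ties: longest, then smallest query
        start).  Hits are sorted by query start, then descending bit score.
        """
        q = encode(query)
        per_subject: dict[int, list[UngappedHit]] = {}
        for si, diag in self._candidate_diagonals(q):
            hs = self._diagonal_hits(q, si, diag)
            if hs:
                per_subject.setdefault(si, []).extend(hs)
        hits: list[UngappedHit] = []
        for si in sorted(per_subject):
            hs = per_subject[si]
            if self.params.per_subject_best_only:
                hs = [
                    max(
                        hs,
                        key=lambda h: (h.raw_score, h.length, -h.query_start),
                    )
                ]
            hits.extend(hs)
        hits.sort(key=lambda h: (h.query_start, -h.bit_score, h.subject_id))
        return hits

    def has_hit(self, query: str) -> bool:
        """True iff the query has at least one qualifying hit (short-circuit)."""
        q = encode(query)
        for si, diag in self._candidate_diagonals(q):
            if self._diagonal_hits(q, si, diag):
                return True
        return False


def find_ungapped_hits(
    query: str, db: EpitopeDataset, params: SearchParams = SearchParams()
) -> list[UngappedHit]:
    """Exhaustive ungapped hit search of ``query`` against ``db``."""
    return EpitopeSearchIndex(db, params).search(query)


def hits_to_frame(hits: Sequence[UngappedHit], query_id: str, db: EpitopeDataset):
    """Hit table as a DataFrame in the standard report schema."""
    import pandas as pd

    neut = {r.id: r.neutralizing for r in db}
    return pd.DataFrame(
        [
            {
                "query_id": query_id,
                "query_start": h.query_start,
                "query_end": h.query_end,
                "subject_id": h.subject_id,
                "subject_start": h.subject_start,
                "subject_end": h.subject_end,
                "length": h.length,
                "identity_pct": round(h.identity_pct, 2),
                "raw_score": h.raw_score,
                "bit_score": round(h.bit_score, 2),
                "neutralizing": neut.get(h.subject_id, False),
            }
            for h in hits
        ],
        columns=[
            "query_id", "query_start", "query_end", "subject_id",
            "subject_start", "subject_end", "length", "identity_pct",
            "raw_score", "bit_score", "neutralizing",
        ],
    )
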