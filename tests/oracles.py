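"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the package's search/profile code paths: the
hit oracle enumerates every (record, query-offset, subject-offset,
length) window directly on strings, and the metric oracle evaluates the
closed-form definitions.
"""

from __future__ import annotations

import math

from bepiscan.alphabet import blosum62_score


def naive_ungapped_hits(query, db, params):
    """Enumerate-filter-maximalize reference for the ungapped search.

    Returns per-hit tuples (query_start, query_end, subject_id,
    subject_start, subject_end, length, matches, raw_score), sorted.
    """
    out = []
    for rec in db:
        s = rec.sequence
        wins = []
        for qs in range(len(query)):
            for ss in range(len(s)):
                max_l = min(len(query) - qs, len(s) - ss)
                for L in range(params.min_length, max_l + 1):
                    m = sum(1 for t in range(L) if query[qs + t] == s[ss + t])
                    if m * 100.0 >= params.min_identity_pct * L - 1e-9:
                        wins.append((qs, ss, L, m))
        maximal = [
            w for w in wins
            if not any(
                (w2[0] - w2[1]) == (w[0] - w[1])  # same diagonal
                and w2[2] > w[2]
                and w2[0] <= w[0]
                and w2[0] + w2[2] >= w[0] + w[2]
                for w2 in wins
            )
        ]
        hits = []
        for qs, ss, L, m in maximal:
            raw = sum(blosum62_score(query[qs + t], s[ss + t]) for t in range(L))
            hits.append((qs + 1, qs + L, rec.id, ss + 1, ss + L, L, m, raw))
        if hits and params.per_subject_best_only:
            hits = [max(hits, key=lambda h: (h[7], h[5], -h[0]))]
        out.extend(hits)
    return sorted(out)


def hit_key(h):
    """Comparable tuple of an UngappedHit matching the oracle's rows."""
    matches = round(h.identity_pct * h.length / 100.0)
    return (
        h.query_start, h.query_end, h.subject_id,
        h.subject_start, h.subject_end, h.length, matches, h.raw_score,
    )


def naive_metrics(tp, fp, tn, fn):
    """Closed-form SE/SP/ACC/MCC."""
    se = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fp + tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tn + fn) * (tp + fn) * (tn + fp) * (tp + fp)
    )
    return se, sp, acc, mcc


def random_dataset(rng, n_records, len_lo=8, len_hi=25, prefix="r"):
    """Uniform-alphabet random dataset (test-local helper)."""
    from bepiscan import EpitopeDataset, EpitopeRecord

    aa = list("ACDEFGHIKLMNPQRSTVWY")
    recs = []
    for i in range(n_records):
        L = int(rng.integers(len_lo, len_hi + 1))
        recs.append(
            EpitopeRecord(f"{prefix}{i}", "".join(rng.choice(aa, L)))
        )
    return EpitopeDataset(recs)
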