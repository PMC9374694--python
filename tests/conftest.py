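import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bepiscan import EpitopeDataset, EpitopeRecord, SearchParams


def make_dataset(seqs, label=None, prefix="s", neutralizing=()):
    recs = [
        EpitopeRecord(
            f"{prefix}{i}", seq, neutralizing=(i in set(neutralizing))
        )
        for i, seq in enumerate(seqs)
    ]
    return EpitopeDataset(recs, label=label)


@pytest.fixture
def default_params():
    return SearchParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def plant_epitopes(seed, db, k=3, gap=15, params=None):
    """Plant k exact db epitopes in a random protein with no spurious hits.

    Separating gaps are random sequence, redrawn (deterministically) until
    every ungapped hit of the scan lies inside a planted interval — the
    "no spurious hits" study condition for core-recovery checks.  Returns
    (protein, [(start, end)] 1-based planted intervals).
    """
    import bepiscan as bpk

    params = params or SearchParams()
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for attempt in range(50):
        r = np.random.default_rng([seed, attempt])
        pieces, planted, pos = [], [], 1
        for i in range(k):
            g = "".join(r.choice(aa, gap))
            pieces.append(g)
            pos += len(g)
            rec = db[i % len(db)]
            planted.append((pos, pos + len(rec) - 1))
            pieces.append(rec.sequence)
            pos += len(rec)
        pieces.append("".join(r.choice(aa, gap)))
        protein = "".join(pieces)
        hits = bpk.find_ungapped_hits(protein, db, params)
        if all(
            any(h.query_start >= s and h.query_end <= e for s, e in planted)
            for h in hits
        ):
            return protein, planted
    raise RuntimeError("could not build a spurious-hit-free fixture")
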