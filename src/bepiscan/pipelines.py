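"""End-to-end pipelines: database bundles and the synthetic benchmark.

A "database bundle" is the engine-agnostic replacement for a formatted
binary search database: a directory holding the normalized FASTA, the
metadata TSV and a summary JSON (record counts, length statistics,
composition).  The synthetic benchmark generates, from one seed, a
parent epitope pool, near-duplicate positives and composition/length-
matched random negatives, ready for cross-validation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__ as _version
from .datasets import (
    DEFAULT_EPITOPE_LENGTHS,
    CompositionTable,
    EpitopeDataset,
    LengthDistribution,
    aa_frequencies,
    filter_by_length,
    length_stats,
    make_fixture_positives,
    random_peptides,
    read_fasta,
    reduce_redundancy,
    swissprot_background,
    write_fasta,
)

logger = logging.getLogger("bepiscan.pipelines")

__all__ = ["make_database_bundle", "simulate_benchmark", "write_run_config"]


def write_run_config(out_dir: str | Path, subcommand: str, config: dict) -> Path:
    """Write the resolved run configuration (and version) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    payload = {"tool": "bepiscan", "version": _version,
               "subcommand": subcommand, **config}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def make_database_bundle(
    fasta: str | Path,
    out_dir: str | Path,
    min_len: int = 8,
    max_len: int = 25,
    reduce_redundancy_pct: float | None = None,
) -> dict:
    """Curate a FASTA into a database bundle directory; return its summary.

    Applies the alphabet policy (non-standard records dropped at load) and
    the length filter; redundancy reduction is optional (off by default,
    for pre-curated inputs).  Raises if the curated database is empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = read_fasta(fasta, label="positive")
    n_loaded = len(ds)
    ds = filter_by_length(ds, min_len, max_len)
    n_length = len(ds)
    if reduce_redundancy_pct is not None:
        ds = reduce_redundancy(ds, reduce_redundancy_pct)
    if len(ds) == 0:
        raise ValueError("database is empty after curation")

    write_fasta(ds, out_dir / "db.fasta")
    ls = length_stats(ds)
    comp = aa_frequencies(ds)
    summary = {
        "n_records": len(ds),
        "n_loaded": n_loaded,
        "n_after_length_filter": n_length,
        "n_neutralizing": sum(1 for r in ds if r.neutralizing),
        "length_mean": round(ls["mean"], 4),
        "length_std": round(ls["std"], 4),
        "length_median": ls["median"],
        "composition": {k: round(v, 6) for k, v in comp.as_dict().items()},
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "makedb: %d loaded -> %d after length filter -> %d in bundle",
        n_loaded, n_length, len(ds),
    )
    return summary


def simulate_benchmark(
    n_pos: int,
    n_neg: int,
    mismatch_frac: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_db: int | None = None,
    background: CompositionTable | None = None,
    lengths: LengthDistribution | None = None,
) -> tuple[EpitopeDataset, EpitopeDataset, EpitopeDataset]:
    """Generate a synthetic benchmark: (parent db, positives, negatives).

    The parent pool holds ``n_db`` random background-composition peptides
    (default ``max(25, n_pos // 20)``, so each parent epitope is
    represented by ~20 near-duplicate positives and held-out copies are
    matched by training-fold twins).  Positives are near-duplicates of
    parents with up to ``mismatch_frac`` substitutions; negatives are
    independent random peptides with the same composition and length
    distribution.  Deterministic given ``seed``; written to ``out_dir``
    when given.
    """
    if n_pos < 10 or n_neg < 10:
        raise ValueError("n_pos and n_neg must be >= 10")
    background = background or swissprot_background()
    lengths = lengths or DEFAULT_EPITOPE_LENGTHS
    if n_db is None:
        n_db = max(25, n_pos // 20)
    db = random_peptides(
        n_db, background, lengths, seed=[seed, 10], id_prefix="dbpep"
    )
    positives = make_fixture_positives(
        db, n_pos, mismatch_frac, seed=[seed, 11], id_prefix="pos"
    )
    negatives = random_peptides(
        n_neg, background, lengths, seed=[seed, 12], id_prefix="neg"
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(db, out_dir / "db.fasta")
        write_fasta(positives, out_dir / "positives.fasta")
        write_fasta(negatives, out_dir / "negatives.fasta")
        write_run_config(
            out_dir,
            "simulate",
            {
                "n_pos": n_pos, "n_neg": n_neg, "n_db": n_db,
                "mismatch_frac": mismatch_frac, "seed": seed,
            },
        )
    return db, positives, negatives
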