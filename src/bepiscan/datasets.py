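"""Epitope/peptide dataset handling: IO, curation, statistics, generators.

The central objects are :class:`EpitopeRecord` (one peptide with identity
metadata and a neutralizing-antibody flag) and :class:`EpitopeDataset` (an
ordered, id-unique collection with a positive/negative label).  Curation
follows the construction rules of linear B cell epitope reference sets:
peptides restricted to 8–25 residues, and redundancy reduced so that no
two retained peptides share >= 90% sequence identity.

Synthetic-data generators live here too: ``random_peptides`` draws
background-composition peptides with a prescribed length distribution
(the standard construction of non-epitope negative sets), and
``make_fixture_positives`` produces near-duplicates of database entries
(the positive fixture for benchmark experiments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, AA_SET

logger = logging.getLogger("bepiscan.datasets")

__all__ = [
    "EpitopeRecord",
    "EpitopeDataset",
    "CompositionTable",
    "LengthDistribution",
    "DEFAULT_EPITOPE_LENGTHS",
    "swissprot_background",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "reduce_redundancy",
    "aa_frequencies",
    "aa_enrichment",
    "length_stats",
    "random_peptides",
    "make_fixture_positives",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class EpitopeRecord:
    """A single peptide with identity metadata.

    Parameters
    ----------
    id : unique record identifier within a dataset.
    sequence : uppercase amino-acid string over the 20-letter alphabet.
    source : free-text antigen/organism annotation (may be empty).
    neutralizing : whether the epitope is targeted by neutralizing antibodies.
    """

    id: str
    sequence: str
    source: str = ""
    neutralizing: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not AA_SET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - AA_SET)
            raise ValueError(
                f"record {self.id!r}: non-standard residues {bad!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EpitopeDataset:
    """An ordered collection of :class:`EpitopeRecord` with unique ids."""

    records: list[EpitopeRecord] = field(default_factory=list)
    label: str | None = None  # "positive" | "negative" | None
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EpitopeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EpitopeRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Iterable[int]) -> "EpitopeDataset":
        recs = [self.records[i] for i in indices]
        return EpitopeDataset(recs, label=self.label, provenance=self.provenance)

    def get(self, rec_id: str) -> EpitopeRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


# ---------------------------------------------------------------------------
# Composition and length-distribution tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionTable:
    """Amino-acid frequencies (fractions summing to 1) over the 20 residues."""

    frequencies: tuple[float, ...]  # ordered as alphabet.AMINO_ACIDS

    def __post_init__(self) -> None:
        if len(self.frequencies) != 20:
            raise ValueError("composition table must have 20 entries")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("negative frequency")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies sum to {sum(self.frequencies)!r}, expected 1"
            )

    def __getitem__(self, aa: str) -> float:
        return self.frequencies[AMINO_ACIDS.index(aa)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AMINO_ACIDS, self.frequencies))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    @classmethod
    def from_dict(cls, d: Mapping[str, float], normalize: bool = False) -> "CompositionTable":
        vals = np.array([float(d.get(aa, 0.0)) for aa in AMINO_ACIDS])
        if normalize:
            vals = vals / vals.sum()
        return cls(tuple(vals.tolist()))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CompositionTable":
        total = sum(counts.get(aa, 0) for aa in AMINO_ACIDS)
        if total == 0:
            raise ValueError("no residues counted")
        return cls(tuple(counts.get(aa, 0) / total for aa in AMINO_ACIDS))

    @classmethod
    def load(cls, path: str | Path) -> "CompositionTable":
        """Read a composition from a 2-column TSV (aa, frequency) or YAML map."""
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            with open(path) as fh:
                d = yaml.safe_load(fh)
            return cls.from_dict(d, normalize=True)
        df = pd.read_csv(path, sep="\t")
        return cls.from_dict(
            dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))),
            normalize=True,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"aa": list(AMINO_ACIDS), "frequency": list(self.frequencies)}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LengthDistribution:
    """Probability per integer peptide length; probabilities sum to 1."""

    probabilities: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("empty length distribution")
        if any(l < 1 or p < 0 for l, p in self.probabilities):
            raise ValueError("invalid length or probability")
        if abs(sum(p for _, p in self.probabilities) - 1.0) > 1e-9:
            raise ValueError("length probabilities must sum to 1")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for l, _ in self.probabilities], dtype=int)

    @property
    def probs(self) -> np.ndarray:
        return np.array([p for _, p in self.probabilities], dtype=float)

    def as_dict(self) -> dict[int, float]:
        return dict(self.probabilities)

    @classmethod
    def from_dict(cls, d: Mapping[int, float], normalize: bool = False) -> "LengthDistribution":
        items = sorted((int(k), float(v)) for k, v in d.items())
        if normalize:
            tot = sum(v for _, v in items)
            items = [(k, v / tot) for k, v in items]
        return cls(tuple(items))

    @classmethod
    def load(cls, path: str | Path) -> "LengthDistribution":
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            with open(path) as fh:
                d = yaml.safe_load(fh)
            return cls.from_dict(d, normalize=True)
        df = pd.read_csv(path, sep="\t")
        return cls.from_dict(
            dict(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(float))),
            normalize=True,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"length": [l for l, _ in self.probabilities],
             "probability": [p for _, p in self.probabilities]}
        ).to_csv(path, sep="\t", index=False)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.lengths, size=n, p=self.probs)


def swissprot_background() -> CompositionTable:
    """The packaged UniProtKB/Swiss-Prot amino-acid background composition."""
    with resources.files("bepiscan.data").joinpath(
        "swissprot_composition.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return CompositionTable.from_dict(
        dict(zip(df["aa"], df["frequency"])), normalize=True
    )


#: Default peptide-length distribution for fixture generation: a right-skewed
#: distribution on 8..25 calibrated to the reference epitope-set statistics
#: (mean 13.91, population std 2.85, median 12).
DEFAULT_EPITOPE_LENGTHS = LengthDistribution.from_dict(
    {
        8: 0.00063, 9: 0.00377, 10: 0.02354, 11: 0.13433, 12: 0.34273,
        13: 0.09642, 14: 0.04319, 15: 0.04056, 16: 0.06039, 17: 0.08966,
        18: 0.08688, 19: 0.04879, 20: 0.01911, 21: 0.00653, 22: 0.00223,
        23: 0.00081, 24: 0.00031, 25: 0.00012,
    }
)


# ---------------------------------------------------------------------------
# FASTA + metadata IO
# ---------------------------------------------------------------------------


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in {"true", "1", "yes"}


def read_fasta(
    path: str | Path,
    label: str | None = None,
    drop_invalid: bool = True,
) -> EpitopeDataset:
    """Read a FASTA file (plus an optional sibling ``<stem>.meta.tsv``).

    The description line may carry a ``neutralizing=true|false`` key; a
    sibling metadata TSV with columns ``id``, ``source``, ``neutralizing``
    is merged when present (TSV values win).  Records with residues outside
    the 20-letter alphabet are dropped with a warning (``drop_invalid=True``,
    the default) or raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    # fail early, with a line number, on content that is not FASTA at all
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            logger.warning("%s: empty FASTA file", path)
            return EpitopeDataset([], label=label, provenance=str(path))

    meta: dict[str, dict] = {}
    meta_path = path.with_name(path.stem + ".meta.tsv")
    if meta_path.exists():
        mdf = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        for _, row in mdf.iterrows():
            meta[str(row["id"])] = {
                "source": str(row.get("source", "")),
                "neutralizing": _parse_bool(row.get("neutralizing", "false")),
            }

    records: list[EpitopeRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        neut = False
        source = ""
        for tok in rec.description.split()[1:]:
            if tok.lower().startswith("neutralizing="):
                neut = _parse_bool(tok.split("=", 1)[1])
            elif tok.lower().startswith("source="):
                source = tok.split("=", 1)[1]
        if rec.id in meta:
            source = meta[rec.id]["source"] or source
            neut = meta[rec.id]["neutralizing"]
        if not seq or not AA_SET.issuperset(seq):
            if drop_invalid:
                n_dropped += 1
                logger.warning(
                    "%s: dropping record %r (non-standard residues)", path, rec.id
                )
                continue
            raise ValueError(f"record {rec.id!r}: non-standard residues")
        records.append(
            EpitopeRecord(id=rec.id, sequence=seq, source=source, neutralizing=neut)
        )
    if n_dropped:
        logger.warning("%s: dropped %d record(s) at load", path, n_dropped)
    return EpitopeDataset(records, label=label, provenance=str(path))


def write_fasta(
    ds: EpitopeDataset, path: str | Path, with_meta: bool = True, width: int = 60
) -> None:
    """Write a dataset as FASTA (wrapped) plus a sibling ``<stem>.meta.tsv``."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in ds:
            header = f">{r.id}"
            if r.neutralizing:
                header += " neutralizing=true"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")
    if with_meta:
        meta_path = path.with_name(path.stem + ".meta.tsv")
        pd.DataFrame(
            {
                "id": ds.ids,
                "source": [r.source for r in ds],
                "neutralizing": [str(r.neutralizing).lower() for r in ds],
            }
        ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------


def filter_by_length(
    ds: EpitopeDataset, min_len: int = 8, max_len: int = 25
) -> EpitopeDataset:
    """Keep records with ``min_len <= length <= max_len`` (order preserved)."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    kept = [r for r in ds if min_len <= len(r) <= max_len]
    removed = len(ds) - len(kept)
    if removed:
        logger.info("filter_by_length: removed %d of %d records", removed, len(ds))
    return EpitopeDataset(kept, label=ds.label, provenance=ds.provenance)


def pairwise_identity_shorter(a: str, b: str) -> float:
    """Percent identity between two sequences over the shorter sequence length.

    Identical aligned positions come from the needle-style global alignment;
    the denominator is the shorter sequence length (the CD-HIT convention
    used for redundancy thresholds).
    """
    from .align import global_align  # local import avoids a module cycle

    aln = global_align(a, b)
    matches = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return 100.0 * matches / min(len(a), len(b))


def reduce_redundancy(
    ds: EpitopeDataset, max_identity_pct: float = 90.0
) -> EpitopeDataset:
    """Greedy redundancy reduction at an identity threshold (default 90%).

    Records are visited longest-first (ties: input order); a record is kept
    iff its identity to every already-kept record is strictly below the
    threshold.  Output preserves original input order.
    """
    order = sorted(range(len(ds)), key=lambda i: (-len(ds[i]), i))
    kept_idx: list[int] = []
    for i in order:
        seq = ds[i].sequence
        if all(
            pairwise_identity_shorter(seq, ds[j].sequence) < max_identity_pct
            for j in kept_idx
        ):
            kept_idx.append(i)
    kept_idx.sort()
    removed = len(ds) - len(kept_idx)
    if removed:
        logger.info(
            "reduce_redundancy: removed %d of %d records at >= %.6g%% identity",
            removed, len(ds), max_identity_pct,
        )
    return ds.subset(kept_idx)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def aa_frequencies(ds: EpitopeDataset) -> CompositionTable:
    """Pooled residue frequencies over all sequences in the dataset."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    for r in ds:
        for c in r.sequence:
            counts[c] += 1
    return CompositionTable.from_counts(counts)


def aa_enrichment(
    ds_freq: CompositionTable, background: CompositionTable
) -> dict[str, float]:
    """Per-residue log2 enrichment of dataset frequencies over a background.

    A zero background frequency is an error; a zero dataset frequency maps
    to ``-inf`` (the residue is absent from the dataset).
    """
    out: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        bg = background[aa]
        if bg <= 0:
            raise ValueError(f"background frequency for {aa} is not positive")
        f = ds_freq[aa]
        out[aa] = float(np.log2(f / bg)) if f > 0 else float("-inf")
    return out


def length_stats(ds: EpitopeDataset) -> dict:
    """Mean, population std, median and empirical distribution of lengths."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    lengths = np.array([len(r) for r in ds], dtype=float)
    vals, counts = np.unique(lengths.astype(int), return_counts=True)
    dist = LengthDistribution.from_dict(
        {int(v): c / len(lengths) for v, c in zip(vals, counts)}, normalize=True
    )
    return {
        "mean": float(lengths.mean()),
        "std": float(lengths.std()),  # population std (ddof=0)
        "median": float(np.median(lengths)),
        "distribution": dist,
    }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def random_peptides(
    n: int,
    background: CompositionTable | None = None,
    lengths: LengthDistribution | None = None,
    seed: int | Sequence[int] = 0,
    id_prefix: str = "rand",
) -> EpitopeDataset:
    """Random peptides: lengths from ``lengths``, residues i.i.d. ``background``.

    This is the standard construction of "non-epitope" negative sets:
    background amino-acid composition with a length distribution matched to
    the positive set.  Deterministic given ``seed``.  Redundancy reduction,
    when wanted, is the caller's step (``reduce_redundancy``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    background = background or swissprot_background()
    lengths = lengths or DEFAULT_EPITOPE_LENGTHS
    rng = np.random.default_rng(seed)
    lens = lengths.sample(rng, n)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    probs = background.as_array()
    records = []
    for i, L in enumerate(lens):
        codes = rng.choice(20, size=int(L), p=probs)
        records.append(
            EpitopeRecord(
                id=f"{id_prefix}_{i + 1}",
                sequence=aa[codes].tobytes().decode("ascii"),
            )
        )
    return EpitopeDataset(records, label="negative", provenance=f"random seed={seed}")


def make_fixture_positives(
    db: EpitopeDataset,
    n: int,
    max_mismatch_frac: float = 0.0,
    seed: int | Sequence[int] = 0,
    id_prefix: str = "fixpos",
) -> EpitopeDataset:
    """Near-duplicates of random database records (positive test fixture).

    Each output peptide copies a uniformly chosen record of ``db`` with at
    most ``floor(max_mismatch_frac * length)`` substitutions at random
    positions; ``source`` records the parent id.  Deterministic given seed.
    """
    if len(db) == 0:
        raise ValueError("db must be non-empty")
    if not (0 <= max_mismatch_frac < 0.2):
        raise ValueError("max_mismatch_frac must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        parent = db[int(rng.integers(len(db)))]
        seq = list(parent.sequence)
        n_sub = int(np.floor(max_mismatch_frac * len(seq)))
        if n_sub:
            pos = rng.choice(len(seq), size=n_sub, replace=False)
            for p in pos:
                alternatives = [a for a in AMINO_ACIDS if a != seq[p]]
                seq[p] = alternatives[int(rng.integers(19))]
        records.append(
            EpitopeRecord(
                id=f"{id_prefix}_{i + 1}",
                sequence="".join(seq),
                source=f"parent={parent.id}",
                neutralizing=parent.neutralizing,
            )
        )
    return EpitopeDataset(
        records, label="positive", provenance=f"fixture seed={seed}"
    )
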