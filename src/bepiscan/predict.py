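"""Epitope prediction: peptide classification and protein scanning.

Peptide mode: a query peptide is called an epitope iff it produces at
least one qualifying ungapped hit (length >= 8, identity >= 80% by
default) against the epitope database.

Protein mode: all qualifying hits over the protein are collected, per
residue the number of covering hits is tallied (B), and B is z-scored
over the whole protein:

    Z_B = (B - mu_B) / sigma_B

with mu_B and sigma_B the mean and population standard deviation of B
over all residues (residues in no hit have B = 0).  Contiguous stretches
of covered residues are then segmented into non-overlapping epitope
cores of >= 8 residues whose Z_B values are >= those of the residues
flanking the core; cores are annotated with the best supporting bit
score and, when per-residue accessibility/flexibility tracks are
supplied, their means over the core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import EpitopeSearchIndex, SearchParams, UngappedHit
from .datasets import EpitopeDataset

__all__ = [
    "ResidueProfile",
    "EpitopeCore",
    "Prediction",
    "classify_peptide",
    "residue_profile",
    "extract_cores",
    "scan_protein",
]


@dataclass(frozen=True)
class ResidueProfile:
    """Per-residue hit tally B and its z-score Z_B over a protein query."""

    B: np.ndarray  # int tally, one entry per residue
    Z: np.ndarray  # z-scored tally
    mu: float
    sigma: float  # population std of B

    def __len__(self) -> int:
        return len(self.B)


@dataclass(frozen=True)
class EpitopeCore:
    """A non-overlapping predicted epitope segment (1-based inclusive)."""

    start: int
    end: int
    peptide: str
    bit_score: float
    neutralizing_support: bool = False
    accessibility: float | None = None
    flexibility: float | None = None
    supporting_hits: tuple[UngappedHit, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Prediction:
    """Outcome of a peptide classification or a protein scan."""

    query_id: str
    verdict: str | None = None  # "epitope" | "non-epitope" (peptide mode)
    hits: tuple[UngappedHit, ...] = ()
    cores: tuple[EpitopeCore, ...] = ()  # protein mode
    profile: ResidueProfile | None = None  # protein mode


def classify_peptide(
    peptide: str,
    db: EpitopeDataset | EpitopeSearchIndex,
    params: SearchParams = SearchParams(),
    query_id: str = "query",
) -> Prediction:
    """Epitope / non-epitope verdict for a peptide query.

    The verdict is "epitope" iff at least one qualifying ungapped hit to
    the database exists; the hits are attached for reporting.  A prebuilt
    :class:`EpitopeSearchIndex` may be passed instead of a dataset when
    classifying many peptides against the same database.
    """
    index = (
        db if isinstance(db, EpitopeSearchIndex) else EpitopeSearchIndex(db, params)
    )
    hits = tuple(index.search(peptide))
    return Prediction(
        query_id=query_id,
        verdict="epitope" if hits else "non-epitope",
        hits=hits,
    )


def residue_profile(
    protein: str, hits: Sequence[UngappedHit]
) -> ResidueProfile:
    """Tally hit coverage per residue and z-score it over the protein.

    ``B[i]`` counts the hits whose query interval covers residue i;
    ``mu`` and ``sigma`` are the mean and population std of B over all
    residues.  When sigma is 0 (uniform coverage, e.g. no hits at all)
    Z is defined as all zeros.
    """
    n = len(protein)
    B = np.zeros(n, dtype=np.int64)
    for h in hits:
        if h.query_start < 1 or h.query_end > n:
            raise ValueError(
                f"hit {h.query_start}-{h.query_end} outside protein of length {n}"
            )
        B[h.query_start - 1 : h.query_end] += 1
    mu = float(B.mean())
    sigma = float(B.std())
    if sigma > 0:
        Z = (B - mu) / sigma
    else:
        Z = np.zeros(n, dtype=float)
    return ResidueProfile(B=B, Z=Z, mu=mu, sigma=sigma)


def _descend(Z: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    """Plateau descent within run [lo, hi]: seed at the leftmost maximum,
    extend outward while the next residue's Z is <= the boundary's Z."""
    seed = lo + int(np.argmax(Z[lo : hi + 1]))
    l = r = seed
    while l - 1 >= lo and Z[l - 1] <= Z[l]:
        l -= 1
    while r + 1 <= hi and Z[r + 1] <= Z[r]:
        r += 1
    return l, r


def _carve(Z: np.ndarray, lo: int, hi: int, min_len: int) -> list[tuple[int, int]]:
    if hi - lo + 1 < min_len:
        return []
    l, r = _descend(Z, lo, hi)
    if r - l + 1 < min_len:
        return []
    out = _carve(Z, lo, l - 1, min_len)
    out.append((l, r))
    out.extend(_carve(Z, r + 1, hi, min_len))
    return out


def extract_cores(
    profile: ResidueProfile,
    protein: str,
    hits: Sequence[UngappedHit] = (),
    min_core_len: int = 8,
    db: EpitopeDataset | None = None,
) -> list[EpitopeCore]:
    """Segment the Z_B profile into non-overlapping epitope cores.

    Operates on maximal runs of residues with B > 0.  Within a run the
    core is seeded at the leftmost Z maximum and extended outward by
    non-increasing descent; segments of >= ``min_core_len`` residues are
    accepted and the procedure recurses on the remainders of the run.
    In the degenerate sigma = 0 case (Z identically zero) each whole run
    of length >= ``min_core_len`` becomes one core.
    """
    B, Z = profile.B, profile.Z
    n = len(B)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if B[i] > 0:
            j = i
            while j + 1 < n and B[j + 1] > 0:
                j += 1
            segments.extend(_carve(Z, i, j, min_core_len))
            i = j + 1
        else:
            i += 1

    neut_by_id = {r.id: r.neutralizing for r in db} if db is not None else {}
    cores: list[EpitopeCore] = []
    for l, r in segments:
        support = tuple(
            h for h in hits if h.query_start <= r + 1 and h.query_end >= l + 1
        )
        best_bit = max((h.bit_score for h in support), default=float("nan"))
        cores.append(
            EpitopeCore(
                start=l + 1,
                end=r + 1,
                peptide=protein[l : r + 1],
                bit_score=best_bit,
                neutralizing_support=any(
                    neut_by_id.get(h.subject_id, False) for h in support
                ),
                supporting_hits=support,
            )
        )
    cores.sort(key=lambda c: c.start)
    return cores


def scan_protein(
    protein: str,
    db: EpitopeDataset,
    params: SearchParams = SearchParams(),
    only_neutralizing: bool = False,
    accessibility_track: Sequence[float] | None = None,
    flexibility_track: Sequence[float] | None = None,
    query_id: str = "query",
) -> Prediction:
    """Scan a protein for epitope cores supported by database hits.

    Pipeline: ungapped hit search -> (optional filter to hits on
    neutralizing-flagged records) -> residue tally and Z_B profile ->
    non-overlapping core extraction.  Per-core accessibility/flexibility
    are arithmetic means of the supplied per-residue tracks over the core
    residues; tracks must have exactly one value per protein residue.
    """
    for name, track in (
        ("accessibility", accessibility_track),
        ("flexibility", flexibility_track),
    ):
        if track is not None and len(track) != len(protein):
            raise ValueError(
                f"{name} track has {len(track)} values for a protein of "
                f"length {len(protein)}"
            )

    index = EpitopeSearchIndex(db, params)
    hits = index.search(protein)
    if only_neutralizing:
        neut = {r.id for r in db if r.neutralizing}
        hits = [h for h in hits if h.subject_id in neut]
    profile = residue_profile(protein, hits)
    cores = extract_cores(
        profile, protein, hits, min_core_len=params.min_length, db=db
    )
    if accessibility_track is not None or flexibility_track is not None:
        annotated = []
        for c in cores:
            acc = (
                float(np.mean(accessibility_track[c.start - 1 : c.end]))
                if accessibility_track is not None
                else None
            )
            flex = (
                float(np.mean(flexibility_track[c.start - 1 : c.end]))
                if flexibility_track is not None
                else None
            )
            annotated.append(
                EpitopeCore(
                    start=c.start,
                    end=c.end,
                    peptide=c.peptide,
                    bit_score=c.bit_score,
                    neutralizing_support=c.neutralizing_support,
                    accessibility=acc,
                    flexibility=flex,
                    supporting_hits=c.supporting_hits,
                )
            )
        cores = annotated
    return Prediction(
        query_id=query_id,
        hits=tuple(hits),
        cores=tuple(cores),
        profile=profile,
    )
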