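"""Protein similarity scoring and per-species best-hit extraction.

The pipeline anchors query sequences to a reference species via their
highest-scoring protein similarity hit.  Scores are optimal
Smith–Waterman local alignment scores with affine gaps (BLOSUM62 by
default), converted to bit scores with the Karlin–Altschul
transformation ``(lambda * S - ln K) / ln 2``.

The score thresholds used throughout the grouping (exclusion of
species-specific sequences, retention of candidates) are interpreted on
this bit-score scale and are configurable everywhere.  Gap costs follow
the BLAST convention: a gap of length ``k`` costs
``gap_open + k * gap_extend``.

E-values are deliberately not computed in-house — they depend on
database composition and size — so operations that need them (the
Markov-clustering comparison) must ingest precomputed tabular hits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinSeq


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring parameters.

    ``gap_open``/``gap_extend`` follow the BLAST convention (gap of
    length k costs ``gap_open + k*gap_extend``).  ``lam`` and ``k`` are
    the gapped Karlin–Altschul constants for BLOSUM62 with 11/1 gaps.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self):
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


@dataclass(frozen=True)
class SimilarityHit:
    """A directed similarity hit (edge of the best-hit graph)."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float | None = None


#: per-(query_species, subject_species) map: query id -> [(subject, bits)...]
@dataclass
class BestHitMap:
    query_species: str
    subject_species: str
    hits: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def best(self, query_id: str) -> tuple[str, float] | None:
        lst = self.hits.get(query_id, [])
        return lst[0] if lst else None

    def co_best(self, query_id: str, tie_epsilon: float) -> list[tuple[str, float]]:
        """All subjects within ``tie_epsilon`` bits of the top hit."""
        lst = self.hits.get(query_id, [])
        if not lst:
            return []
        top = lst[0][1]
        return [(s, b) for s, b in lst if top - b <= tie_epsilon]


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gap position costs open+extend, each further position extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_score(a: ProteinSeq, b: ProteinSeq,
                params: ScoringParams = ScoringParams()) -> SimilarityHit:
    """Optimal Smith–Waterman local score of two proteins, with bit score.

    Characters outside the scoring-matrix alphabet (after normalisation
    to X) raise an error.
    """
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq in (a, b):
        extra = set(seq.residues) - alphabet
        if extra:
            raise ValueError(
                f"{seq.id}: residues {sorted(extra)} absent from "
                f"{params.matrix_name} alphabet"
            )
    raw = int(aligner.score(a.residues, b.residues))
    return SimilarityHit(query_id=a.id, subject_id=b.id, raw_score=raw,
                         bit_score=params.bit_score(raw))


def all_vs_all(seqs_a: list[ProteinSeq], seqs_b: list[ProteinSeq],
               params: ScoringParams = ScoringParams()) -> list[SimilarityHit]:
    """Score every ordered cross pair of two sequence sets.

    When the two lists coincide (same ids), self-pairs are excluded.
    The Smith–Waterman score is symmetric, so each unordered pair is
    aligned once and reported in both directions.
    """
    if not seqs_a or not seqs_b:
        warnings.warn("all_vs_all called with an empty sequence list")
        return []
    same = {s.id for s in seqs_a} == {s.id for s in seqs_b}
    hits: list[SimilarityHit] = []
    if same:
        for i, a in enumerate(seqs_a):
            for b in seqs_a[i + 1:]:
                h = local_score(a, b, params)
                hits.append(h)
                hits.append(SimilarityHit(query_id=b.id, subject_id=a.id,
                                          raw_score=h.raw_score,
                                          bit_score=h.bit_score))
    else:
        for a in seqs_a:
            for b in seqs_b:
                h = local_score(a, b, params)
                hits.append(h)
                hits.append(SimilarityHit(query_id=b.id, subject_id=a.id,
                                          raw_score=h.raw_score,
                                          bit_score=h.bit_score))
    return hits


def best_hits(hits: list[SimilarityHit], species_of: dict[str, str],
              query_species: str, subject_species: str) -> BestHitMap:
    """Collect, per query of one species, its subject hits in another.

    The per-query list is sorted by descending bit score (ties broken by
    subject id for determinism).  Queries of ``query_species`` with no
    hit at all are present with an empty list.
    """
    bh = BestHitMap(query_species=query_species, subject_species=subject_species)
    for qid, sp in species_of.items():
        if sp == query_species:
            bh.hits.setdefault(qid, [])
    for h in hits:
        if (species_of.get(h.query_id) == query_species
                and species_of.get(h.subject_id) == subject_species):
            bh.hits.setdefault(h.query_id, []).append((h.subject_id, h.bit_score))
    for qid in bh.hits:
        bh.hits[qid].sort(key=lambda t: (-t[1], t[0]))
    return bh


def best_hit_maps(hits: list[SimilarityHit], species_of: dict[str, str]
                  ) -> dict[tuple[str, str], BestHitMap]:
    """Best-hit maps for every ordered species pair present in the hits."""
    species = sorted(set(species_of.values()))
    return {
        (qs, ss): best_hits(hits, species_of, qs, ss)
        for qs in species
        for ss in species
        if qs != ss
    }
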