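"""Tandem- and segmental-duplication analyses.

Tandem duplication is defined on gene order: two family genes on the
same chromosome are tandem when no more than ``max_intervening`` other
annotated genes lie between them (rank difference minus one), and the
relation is closed transitively into maximal clusters.  Segmental
duplications are summarised from a precomputed syntenic pair list by
counting pairs whose two sides are both family members.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, SegmentalPair


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    member_ids: tuple[str, ...]  # ordered by rank
    max_gap_used: int

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValueError("a tandem cluster needs at least 2 members")


@dataclass(frozen=True)
class SegmentalSummary:
    n_events: int
    n_family_genes: int


def find_tandem_clusters(models: list[GeneModel], family_ids: set[str] | list[str],
                         max_intervening: int = 10) -> list[TandemCluster]:
    """Chain family genes into maximal tandem clusters.

    Consecutive family genes (in chromosome rank order) belong to the
    same cluster when separated by at most ``max_intervening`` non-family
    genes; the boundary is inclusive ("not more than").  Ranks must come
    from :func:`nacortho.io_formats.read_gene_models`, i.e. count all
    annotated genes of the chromosome.
    """
    family = set(family_ids)
    by_id = {m.gene_id for m in models}
    missing = sorted(family - by_id)
    if missing:
        raise KeyError(f"family ids absent from gene models: {missing}")

    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        if m.gene_id in family:
            by_chrom.setdefault(m.chromosome, []).append(m)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: m.rank)
        current: list[GeneModel] = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            if nxt.rank - prev.rank - 1 <= max_intervening:
                current.append(nxt)
            else:
                if len(current) >= 2:
                    clusters.append(TandemCluster(
                        chromosome=chrom,
                        member_ids=tuple(g.gene_id for g in current),
                        max_gap_used=max_intervening))
                current = [nxt]
        if len(current) >= 2:
            clusters.append(TandemCluster(
                chromosome=chrom,
                member_ids=tuple(g.gene_id for g in current),
                max_gap_used=max_intervening))
    return clusters


def summarize_segmental(pairs: list[SegmentalPair],
                        family_ids: set[str] | list[str],
                        both_sides: bool = True) -> SegmentalSummary:
    """Count duplication events and family genes in a syntenic pair list.

    By default an event requires family genes on *both* sides of the
    pair; ``both_sides=False`` counts pairs with at least one family
    side (sensitivity analysis).  ``n_family_genes`` is the number of
    distinct family genes involved in counted events.
    """
    family = set(family_ids)
    n_events = 0
    involved: set[str] = set()
    for p in pairs:
        in_a, in_b = p.gene_a in family, p.gene_b in family
        hit = (in_a and in_b) if both_sides else (in_a or in_b)
        if hit:
            n_events += 1
            involved.update(g for g, ok in ((p.gene_a, in_a), (p.gene_b, in_b)) if ok)
    return SegmentalSummary(n_events=n_events, n_family_genes=len(involved))
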