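"""Exon/intron architecture classification against the canonical model.

The canonical NAC gene has three CDS exons: the first carries the A and
B subdomains of the DNA-binding domain and ends one nucleotide into a
codon (phase-1 intron), the second carries the C and D subdomains and
ends on a codon boundary (phase-0 intron), and the third holds the E
subdomain and the C-terminal transcription regulatory region (TRR).
Deviations are classified as intron losses (exon mergings), extra
5'-terminal exons upstream of the A-B exon, or extra exons in the TRR.

Subdomain coordinates are an input (1-based protein positions); motif
detection is out of scope.  UTR-only exons are ignored: every count
refers to CDS-bearing exons in transcription order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel

CANONICAL = "canonical"
INTRON1_LOST = "intron1_lost"
INTRON2_LOST = "intron2_lost"
MONOEXONIC = "monoexonic"
NTERM_EXTRA = "nterm_extra"
OTHER = "other"


@dataclass(frozen=True)
class DomainAnnotation:
    """Subdomain coordinates (1-based inclusive protein positions)."""

    protein_id: str
    a: tuple[int, int]
    b: tuple[int, int]
    c: tuple[int, int]
    d: tuple[int, int]
    e: tuple[int, int] | None = None

    def __post_init__(self):
        spans = [self.a, self.b, self.c, self.d] + ([self.e] if self.e else [])
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError(
                    f"{self.protein_id}: subdomains must be ordered and disjoint"
                )


@dataclass(frozen=True)
class StructureClass:
    label: str
    exon_count: int
    nterm_extra_exons: int
    trr_extra_exons: int
    intron_phases: tuple[int, ...]


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron interrupting the CDS.

    Phase after CDS exon *i* is the cumulative CDS length through that
    exon mod 3 (0: between codons; 1: after the first base; 2: after the
    second).  A CDS whose total length is not a multiple of 3 raises
    (pseudogene suspect).
    """
    lengths = model.cds_lengths
    if not lengths:
        raise ValueError(f"{model.gene_id}: no CDS segments")
    if sum(lengths) % 3:
        raise ValueError(
            f"{model.gene_id}: CDS length {sum(lengths)} not divisible by 3"
        )
    phases = []
    cum = 0
    for ln in lengths[:-1]:
        cum += ln
        phases.append(cum % 3)
    return phases


def subdomain_exon_map(model: GeneModel, annotation: DomainAnnotation
                       ) -> dict[str, int]:
    """Assign each subdomain to a CDS exon (1-based index).

    Protein position ``p`` covers CDS nucleotides ``3p-2..3p``; a codon
    belongs to the exon holding its middle nucleotide, and a subdomain to
    the exon holding the majority of its codons (ties to the earlier
    exon).  A subdomain beyond the CDS raises.
    """
    lengths = model.cds_lengths
    if not lengths:
        raise ValueError(f"{model.gene_id}: no CDS segments")
    bounds = []
    cum = 0
    for ln in lengths:
        bounds.append((cum + 1, cum + ln))
        cum += ln

    def exon_of_nt(nt: int) -> int:
        for i, (s, e) in enumerate(bounds, start=1):
            if s <= nt <= e:
                return i
        raise ValueError(f"{model.gene_id}: CDS position {nt} outside CDS")

    out: dict[str, int] = {}
    spans = {"A": annotation.a, "B": annotation.b, "C": annotation.c,
             "D": annotation.d}
    if annotation.e:
        spans["E"] = annotation.e
    for name, (p1, p2) in spans.items():
        counts: dict[int, int] = {}
        for p in range(p1, p2 + 1):
            ex = exon_of_nt(3 * p - 1)  # middle nucleotide of the codon
            counts[ex] = counts.get(ex, 0) + 1
        out[name] = min(sorted(counts), key=lambda ex: (-counts[ex], ex))
    return out


def classify_structure(model: GeneModel, annotation: DomainAnnotation
                       ) -> StructureClass:
    """Classify a gene's architecture against the canonical 3-exon model.

    Decision table (CDS exons only):

    * 1 exon: monoexonic (both introns lost).
    * A-B exon preceded by >=1 exon: nterm_extra, with the count of
      5'-terminal extra exons.
    * 3 exons, phases [1, 0], A-B in exon 1, C-D in exon 2: canonical.
    * 2 exons, A-D all in exon 1: intron1_lost.
    * 2 exons, A-B in exon 1, C-D in exon 2: intron2_lost (C-D merged
      with the TRR exon).
    * anything else: other (never an exception).

    CDS exons after the C-D exon beyond the single canonical TRR exon
    are reported as ``trr_extra_exons`` for every label.
    """
    phases = tuple(intron_phases(model))
    n = len(model.cds_segments)
    sub = subdomain_exon_map(model, annotation)
    ab = max(sub["A"], sub["B"])
    cd = max(sub["C"], sub["D"])
    nterm = ab - 1
    trr_extra = max(0, n - cd - 1)

    if n == 1:
        label = MONOEXONIC
    elif nterm >= 1:
        label = NTERM_EXTRA
    elif n == 3 and phases == (1, 0) and ab == 1 and cd == 2 and trr_extra == 0:
        label = CANONICAL
    elif n == 2 and ab == 1 and cd == 1:
        label = INTRON1_LOST
    elif n == 2 and ab == 1 and cd == 2:
        label = INTRON2_LOST
    else:
        label = OTHER
    return StructureClass(label=label, exon_count=n, nterm_extra_exons=nterm,
                          trr_extra_exons=trr_extra, intron_phases=phases)
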