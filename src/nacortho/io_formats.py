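"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA protein sets with a sidecar species map, a GFF3 subset
(gene/mRNA/exon/CDS) for gene-order and structure analyses, 12-column
tabular similarity-hit files (BLAST ``outfmt 6`` dialect), synteny pair
lists, and the packaged transcription of the published 40-OG table for
the NAC family in *V. vinifera*, *A. thaliana*, *O. sativa* and
*M. acuminata*.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (GFF3 convention).
* Exon and CDS lists are in transcription order: ascending genomic start
  on the plus strand, descending on the minus strand.
* Amino-acid strings are uppercased and any character outside the 20
  standard residues is normalised to ``X``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: id-prefix fallback used for the four study species when no sidecar
#: species map is given.
DEFAULT_PREFIX_SPECIES = (
    ("VvNAC", "Vv"),
    ("ANAC", "At"),
    ("Os", "Os"),
    ("Achr", "Ma"),
)

MONOCOTS = frozenset({"Os", "Ma"})
DICOTS = frozenset({"Vv", "At"})

OG_ID_RE = re.compile(r"^(?:[1-8][a-z]|5c\+MS|[A-Z]{2}\d*)$")


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence, the unit of comparison."""

    id: str
    species: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic location and CDS/exon architecture.

    ``rank`` is the 0-based index of the gene among all genes of its
    chromosome ordered by ascending start; it is filled by
    :func:`read_gene_models` and is the coordinate used by the
    tandem-duplication rule.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    cds_segments: tuple[tuple[int, int], ...] = ()
    rank: int = -1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        for s, e in list(self.exons) + list(self.cds_segments):
            if s > e:
                raise ValueError(f"{self.gene_id}: segment start > end")

    @property
    def cds_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class SegmentalPair:
    """An unordered syntenic gene pair from a collinearity scan."""

    gene_a: str
    gene_b: str
    block_id: str = ""

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class Table1Fixture:
    """The published 40-OG table: (og_id, species, member_id, pseudogene)."""

    rows: list[tuple[str, str, str, bool]] = field(default_factory=list)

    @property
    def og_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for og, *_ in self.rows:
            seen.setdefault(og)
        return list(seen)

    def members(self, og_id: str, species: str | None = None) -> list[str]:
        return [
            m
            for og, sp, m, _ in self.rows
            if og == og_id and (species is None or sp == species)
        ]

    def members_by_og(self) -> dict[str, dict[str, list[str]]]:
        out: dict[str, dict[str, list[str]]] = {}
        for og, sp, m, _ in self.rows:
            out.setdefault(og, {}).setdefault(sp, []).append(m)
        return out

    def species_counts(self, include_pseudogenes: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, sp, _, pseudo in self.rows:
            if pseudo and not include_pseudogenes:
                continue
            counts[sp] = counts.get(sp, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# FASTA


def _normalise_residues(raw: str) -> str:
    up = raw.upper().replace("*", "").replace("-", "")
    return "".join(c if c in STANDARD_AA else "X" for c in up)


def _species_from_id(seq_id: str, species_map: dict[str, str] | None,
                     header_regex: str | None) -> str:
    if species_map is not None:
        if seq_id not in species_map:
            raise KeyError(f"species map has no entry for {seq_id!r}")
        return species_map[seq_id]
    if header_regex is not None:
        m = re.search(header_regex, seq_id)
        if not m:
            raise ValueError(f"header regex did not match {seq_id!r}")
        return m.group(1)
    for prefix, sp in DEFAULT_PREFIX_SPECIES:
        if seq_id.startswith(prefix):
            return sp
    return "unknown"


def read_fasta(path: str | Path, species_map: dict[str, str] | None = None,
               header_regex: str | None = None) -> list[ProteinSeq]:
    """Read a protein FASTA file into :class:`ProteinSeq` records.

    Species are taken from ``species_map`` (a sidecar id→species dict, the
    default route), else extracted with ``header_regex`` (first group),
    else guessed from the id prefixes of the four study species.
    Duplicate ids raise; an empty file returns an empty list with a
    warning.
    """
    seqs: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        seqs.append(
            ProteinSeq(
                id=rec.id,
                species=_species_from_id(rec.id, species_map, header_regex),
                residues=_normalise_residues(str(rec.seq)),
            )
        )
    if not seqs:
        warnings.warn(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[ProteinSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sequence id, species code)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "species"],
                     dtype=str, comment="#")
    return dict(zip(df["id"], df["species"]))


# ---------------------------------------------------------------------------
# GFF3 subset


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 subset (gene/mRNA/exon/CDS) into ranked gene models.

    One :class:`GeneModel` per ``gene`` feature; exon and CDS segments are
    collected from all descendants (transcription order).  ``rank`` is
    assigned per chromosome by ascending gene start and is independent of
    line order in the file.  A CDS segment outside its gene span is an
    error; a gene without exon features is kept with an empty exon list
    and a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exon_set: set[tuple[int, int]] = set()
        cds_set: set[tuple[int, int]] = set()
        for child in db.children(gene.id):
            if child.featuretype == "exon":
                exon_set.add((child.start, child.end))
            elif child.featuretype == "CDS":
                if not (gene.start <= child.start and child.end <= gene.end):
                    raise ValueError(f"CDS outside gene span for {gene.id}")
                cds_set.add((child.start, child.end))
        reverse = gene.strand == "-"
        exons = tuple(sorted(exon_set, reverse=reverse))
        cds = tuple(sorted(cds_set, reverse=reverse))
        if not exons and not cds:
            warnings.warn(f"gene {gene.id} has no exon/CDS features")
        models.append(
            GeneModel(gene_id=gene.id, chromosome=gene.seqid, start=gene.start,
                      end=gene.end, strand=gene.strand, exons=exons,
                      cds_segments=cds)
        )

    # rank per chromosome by ascending start (ties by id for determinism)
    ranked: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda m: (m.start, m.gene_id))
        for rank, m in enumerate(ordered):
            ranked.append(
                GeneModel(gene_id=m.gene_id, chromosome=m.chromosome,
                          start=m.start, end=m.end, strand=m.strand,
                          exons=m.exons, cds_segments=m.cds_segments,
                          rank=rank)
            )
    return ranked


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt 6 dialect)

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_table(path: str | Path):
    """Read a 12-column tabular hit file.

    Returns a list of :class:`nacortho.similarity.SimilarityHit`.  When a
    (query, subject) pair has several HSP lines, the maximum bit score is
    retained (and its e-value kept alongside).  Symmetrisation across the
    two hit directions is a downstream concern.
    """
    from .similarity import SimilarityHit

    best: dict[tuple[str, str], SimilarityHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns"
                )
            try:
                q, s = fields[0], fields[1]
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line") from exc
            key = (q, s)
            if key not in best or bits > best[key].bit_score:
                best[key] = SimilarityHit(
                    query_id=q, subject_id=s,
                    raw_score=0, bit_score=bits, evalue=evalue,
                )
    return list(best.values())


def write_hits_table(hits, path: str | Path) -> None:
    """Write hits as 12-column tabular lines (placeholder HSP columns)."""
    with open(path, "w") as fh:
        for h in hits:
            ev = h.evalue if h.evalue is not None else 0.0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{ev:g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Synteny pairs


def read_synteny_pairs(path: str | Path, col_a: int = 0, col_b: int = 1,
                       block_col: int | None = None,
                       id_regex: str | None = None) -> list[SegmentalPair]:
    """Read a tab-separated synteny pair list (SynMap-style output).

    ``col_a``/``col_b`` select the gene-id columns; ``id_regex`` (first
    group) optionally normalises ids, e.g. stripping a ``GSMUA_`` prefix.
    Pairs are deduplicated irrespective of order; self-pairs are dropped
    with a warning.
    """
    def norm(raw: str) -> str:
        if id_regex is None:
            return raw
        m = re.search(id_regex, raw)
        if not m:
            raise ValueError(f"id {raw!r} does not match normalisation regex")
        return m.group(1)

    pairs: dict[tuple[str, str], SegmentalPair] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                a, b = norm(fields[col_a]), norm(fields[col_b])
            except IndexError as exc:
                raise ValueError(f"{path}:{lineno}: missing id column") from exc
            block = fields[block_col] if block_col is not None else ""
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-pair {a!r} skipped")
                continue
            pair = SegmentalPair(gene_a=a, gene_b=b, block_id=block)
            pairs.setdefault(pair.key, pair)
    return list(pairs.values())


# ---------------------------------------------------------------------------
# Packaged fixtures


def _packaged(name: str) -> Path:
    return Path(resources.files("nacortho").joinpath("data", name))


def read_table1_fixture(path: str | Path | None = None) -> Table1Fixture:
    """Read the packaged transcription of the published 40-OG table.

    Footnotes are encoded in the fixture: putative pseudogenes carry
    ``pseudogene=1`` and the phylogeny-based reassignment of
    Os11g03310.1 to OG 1g is applied.  The merged dicot/monocot row is
    stored as the single OG ``5c+MS``.
    """
    if path is None:
        path = _packaged("table1_ogs.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"og_id": str, "species": str,
                                            "member_id": str})
    fixture = Table1Fixture()
    seen_members: set[str] = set()
    for row in df.itertuples(index=False):
        if not OG_ID_RE.match(row.og_id):
            raise ValueError(f"bad OG id {row.og_id!r}")
        if row.member_id in seen_members:
            raise ValueError(f"member {row.member_id!r} in two OGs")
        seen_members.add(row.member_id)
        fixture.rows.append(
            (row.og_id, row.species, row.member_id, bool(row.pseudogene))
        )
    return fixture


def read_species_inventory(path: str | Path | None = None) -> pd.DataFrame:
    """Read the per-species sequence-inventory bookkeeping table.

    Columns: ``prior_reported`` (members in the source inventories),
    ``removed`` (splice forms, mis-annotations, pseudogenes dropped
    during curation), ``added`` (members recovered during curation), and
    ``divergent_excluded`` (sequences under the similarity exclusion
    threshold).  Derived columns ``candidates`` and ``retained`` hold the
    family inventory before and after threshold filtering.
    """
    if path is None:
        path = _packaged("species_inventory.tsv")
    df = pd.read_csv(path, sep="\t").set_index("species")
    df["candidates"] = df["prior_reported"] - df["removed"] + df["added"]
    df["retained"] = df["candidates"] - df["divergent_excluded"]
    return df


def read_cluster_map(path: str | Path) -> dict[str, int]:
    """Read a TSV mapping reference sequence id → cluster number."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "cluster"],
                     dtype={"id": str, "cluster": int}, comment="#")
    return dict(zip(df["id"], df["cluster"]))
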