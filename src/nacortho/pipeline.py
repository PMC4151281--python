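"""End-to-end orchestration: configuration, the full inference run and
the companion reports, with deterministic TSV outputs."""

from __future__ import annotations

import datetime
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import copy_number, duplication, gene_structure, mcl_compare
from .io_formats import (
    ProteinSeq,
    read_cluster_map,
    read_fasta,
    read_gene_models,
    read_hits_table,
    read_species_map,
    read_synteny_pairs,
)
from .og_inference import (
    AssignmentRecord,
    InferenceParams,
    OrthologousGroup,
    SpeciesProfile,
    infer_groups,
)
from .similarity import ScoringParams, all_vs_all, best_hit_maps


@dataclass
class RunConfig:
    """Configuration of a full inference run.

    Exactly one profile must have the reference role.  ``fasta_paths``
    maps species code -> FASTA path (or supply ``sequences`` directly);
    ``hits_path`` optionally short-circuits in-house scoring with a
    precomputed 12-column tabular hit file.
    """

    profiles: dict[str, SpeciesProfile]
    scoring: ScoringParams = ScoringParams()
    params: InferenceParams = InferenceParams()
    fasta_paths: dict[str, str] = field(default_factory=dict)
    species_map_path: str | None = None
    cluster_map_path: str | None = None
    hits_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    timestamps: bool = True

    def __post_init__(self):
        refs = [p for p in self.profiles.values() if p.role == "reference"]
        if len(refs) != 1:
            raise ValueError("exactly one species profile must be the reference")


def load_sequences(config: RunConfig) -> list[ProteinSeq]:
    species_map = (read_species_map(config.species_map_path)
                   if config.species_map_path else None)
    seqs: list[ProteinSeq] = []
    for sp, path in sorted(config.fasta_paths.items()):
        for s in read_fasta(path, species_map=species_map):
            if species_map is None and s.species == "unknown":
                s = ProteinSeq(id=s.id, species=sp, residues=s.residues)
            seqs.append(s)
    return seqs


def run_full_inference(config: RunConfig,
                       sequences: list[ProteinSeq] | None = None
                       ) -> tuple[list[OrthologousGroup], dict[str, AssignmentRecord]]:
    """Similarity (or hit ingestion) -> thresholds -> anchoring ->
    reference self-grouping -> cross-verification -> lineage-specific
    groups -> nomenclature; writes the OG table, the per-sequence
    assignment table and a run log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if sequences is None:
        sequences = load_sequences(config)
    species_of = {s.id: s.species for s in sequences}
    unknown = sorted(sp for sp in set(species_of.values())
                     if sp not in config.profiles)
    if unknown:
        raise ValueError(f"stage=similarity: no profile for species {unknown}")

    if config.hits_path:
        hits = read_hits_table(config.hits_path)
    else:
        by_sp: dict[str, list[ProteinSeq]] = {}
        for s in sequences:
            by_sp.setdefault(s.species, []).append(s)
        hits = []
        for a, b in itertools.combinations(sorted(by_sp), 2):
            hits.extend(all_vs_all(by_sp[a], by_sp[b], config.scoring))
    maps = best_hit_maps(hits, species_of)

    cluster_map = (read_cluster_map(config.cluster_map_path)
                   if config.cluster_map_path else None)
    groups, records = infer_groups(species_of, maps, config.profiles,
                                   config.params, cluster_map=cluster_map)

    write_og_table(groups, out / "og_table.tsv")
    write_assignments(records, out / "assignments.tsv")
    with open(out / "run_log.txt", "w") as fh:
        if config.timestamps:
            fh.write(f"# run at {datetime.datetime.now().isoformat()}\n")
        fh.write(f"scoring\t{config.scoring}\n")
        fh.write(f"params\t{config.params}\n")
        for sp in sorted(config.profiles):
            fh.write(f"profile\t{config.profiles[sp]}\n")
        fh.write(f"n_sequences\t{len(sequences)}\n")
        fh.write(f"n_groups\t{len(groups)}\n")
    return groups, records


def write_og_table(groups: list[OrthologousGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tspecies\tmember_id\n")
        for g in sorted(groups, key=lambda g: g.og_id):
            for sp in sorted(g.members):
                for m in sorted(g.members[sp]):
                    fh.write(f"{g.og_id}\t{sp}\t{m}\n")


def write_assignments(records: dict[str, AssignmentRecord],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tspecies\tstatus\tog_id\ttie_pending\tevidence\n")
        for sid in sorted(records):
            r = records[sid]
            ev = ";".join(
                f"{sp}:{subj}:{bits:.1f}:{grp or '-'}"
                for sp, (subj, bits, grp) in sorted(r.evidence.items())
            )
            fh.write(f"{r.seq_id}\t{r.species}\t{r.status}\t{r.og_ref}\t"
                     f"{int(r.tie_pending)}\t{ev}\n")


def read_og_table(path: str | Path) -> list[OrthologousGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups: dict[str, OrthologousGroup] = {}
    for row in df.itertuples(index=False):
        og = groups.setdefault(row.og_id, OrthologousGroup(og_id=row.og_id))
        og.add(row.species, row.member_id)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Reports


def run_reports(groups: list[OrthologousGroup], out_dir: str | Path,
                models_paths: dict[str, str] | None = None,
                family_ids: dict[str, set[str]] | None = None,
                synteny_path: str | None = None,
                synteny_species: str | None = None,
                domain_annotations: dict | None = None,
                genome_totals: dict[str, int] | None = None,
                hits=None, max_intervening: int = 10,
                inflations=mcl_compare.DEFAULT_INFLATIONS,
                mcl_weight_mode: str = "bits") -> dict:
    """Duplication, structure, copy-number and clustering reports.

    Every input beyond the OG table is optional; a missing input skips
    the corresponding report with a notice.  Returns the computed
    objects keyed by report name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict = {}

    models_by_species = {}
    if models_paths:
        for sp, path in sorted(models_paths.items()):
            models_by_species[sp] = read_gene_models(path)

    if models_by_species and family_ids:
        rows = []
        for sp, models in models_by_species.items():
            fam = family_ids.get(sp, set())
            if not fam:
                continue
            for i, cl in enumerate(duplication.find_tandem_clusters(
                    models, fam, max_intervening)):
                for m in cl.member_ids:
                    rows.append({"species": sp, "cluster": f"{sp}_t{i}",
                                 "chromosome": cl.chromosome, "member_id": m})
        tandem_df = pd.DataFrame(rows, columns=["species", "cluster",
                                                "chromosome", "member_id"])
        tandem_df.to_csv(out / "tandem_clusters.tsv", sep="\t", index=False)
        produced["tandem"] = tandem_df
    else:
        warnings.warn("tandem report skipped: gene models or family ids missing")

    if synteny_path and family_ids:
        pairs = read_synteny_pairs(synteny_path)
        fam = (family_ids.get(synteny_species, set()) if synteny_species
               else set().union(*family_ids.values()))
        summary = duplication.summarize_segmental(pairs, fam)
        pd.DataFrame([summary.__dict__]).to_csv(
            out / "segmental_summary.tsv", sep="\t", index=False)
        produced["segmental"] = summary
    else:
        warnings.warn("segmental report skipped: synteny pairs missing")

    if models_by_species and domain_annotations:
        rows = []
        for sp, models in models_by_species.items():
            for m in models:
                ann = domain_annotations.get(m.gene_id)
                if ann is None:
                    continue
                sc = gene_structure.classify_structure(m, ann)
                rows.append({"species": sp, "gene_id": m.gene_id,
                             "label": sc.label, "exon_count": sc.exon_count,
                             "nterm_extra": sc.nterm_extra_exons,
                             "trr_extra": sc.trr_extra_exons,
                             "phases": ",".join(map(str, sc.intron_phases))})
        structure_df = pd.DataFrame(rows)
        structure_df.to_csv(out / "structure_classes.tsv", sep="\t", index=False)
        produced["structure"] = structure_df
    else:
        warnings.warn("structure report skipped: domain annotations missing")

    counts = copy_number.build_count_matrix(groups)
    counts.to_csv(out / "count_matrix.tsv", sep="\t")
    produced["counts"] = counts
    if genome_totals:
        ratio_rows = []
        for sp in counts.columns:
            if sp in genome_totals:
                r = copy_number.family_ratio(int(counts[sp].sum()),
                                             genome_totals[sp])
                ratio_rows.append({"species": sp, "n_family": int(counts[sp].sum()),
                                   "n_total": genome_totals[sp],
                                   "ratio": copy_number.round_sig(r, 2)})
        pd.DataFrame(ratio_rows).to_csv(out / "family_ratios.tsv", sep="\t",
                                        index=False)
        produced["ratios"] = ratio_rows
    if counts.shape[1] >= 2 and len(counts) >= 2:
        z = copy_number.zscore_rows(counts)
        z.to_csv(out / "zscores.tsv", sep="\t", float_format="%.4f")
        tree = copy_number.wpgma(copy_number.euclidean_distances(z),
                                 labels=list(z.index))
        (out / "wpgma_tree.nwk").write_text(tree.newick() + "\n")
        produced["zscores"] = z
        produced["tree"] = tree

    if hits is not None:
        graph = mcl_compare.build_graph(hits, weight_mode=mcl_weight_mode)
        sweep = mcl_compare.inflation_sweep(graph, inflations)
        label_of = {m: g.og_id for g in groups for m in g.all_members}
        rows = [{"inflation": infl, "n_clusters": n,
                 "n_nodes": sum(len(c) for c in part.clusters)}
                for infl, n, part in sweep]
        pd.DataFrame(rows).to_csv(out / "mcl_sweep.tsv", sep="\t", index=False)
        produced["mcl_sweep"] = sweep
        produced["mcl_crosstab"] = mcl_compare.cross_tab(sweep[0][2], label_of)
    return produced


def compare_to_reference(records: dict[str, AssignmentRecord],
                         reference: dict[str, str]) -> pd.DataFrame:
    """Compare per-sequence assignments with a reference grouping.

    Agreement means two sequences sharing a reference group also share
    an inferred group membership label.  Returns a per-sequence table
    with an ``agrees`` column; the summary fraction is
    ``df['agrees'].mean()``.  Intended for checking pipeline output
    against the published table when real all-vs-all hit data are
    supplied; disagreements keep their evidence for review.
    """
    ref_ids = sorted(set(reference) & set(records))
    # map inferred og -> majority reference og, then check membership
    pairs = [(records[i].og_ref, reference[i]) for i in ref_ids
             if records[i].status == "assigned"]
    majority: dict[str, str] = {}
    df_pairs = pd.DataFrame(pairs, columns=["inferred", "reference"])
    for og, sub in df_pairs.groupby("inferred"):
        majority[og] = sub["reference"].mode().iloc[0]
    rows = []
    for i in ref_ids:
        rec = records[i]
        agrees = (rec.status == "assigned"
                  and majority.get(rec.og_ref) == reference[i])
        rows.append({"seq_id": i, "status": rec.status,
                     "inferred_og": rec.og_ref, "reference_og": reference[i],
                     "agrees": agrees})
    return pd.DataFrame(rows)
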