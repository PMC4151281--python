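"""Reference-anchored orthologous-group inference.

The algorithm groups the members of a multi-copy gene family across four
species by anchoring every query-species sequence to its highest-scoring
hit in a designated slow-evolving reference species, then verifying each
anchor against the best hits in the remaining species with a 2-of-3
majority rule.  Sequences scoring below a per-species exclusion
threshold against the reference are treated as species-specific
(lineage-restricted or degraded copies) and excluded from the
cross-species groups; sequences whose best hits spread over several
groups with near-identical scores are reported as unassignable rather
than forced into a group.

Species-specific sequences of the non-reference species are then scanned
for reciprocal-best-hit sets spanning at least two species, which become
lineage-specific groups (e.g. a monocot-specific group with no
reference member).

Statuses
--------
assigned
    member of an orthologous group.
species_specific
    best reference score under the exclusion threshold (or no hit).
borderline
    between the exclusion and retention thresholds; reported, kept out
    of the groups.
unassignable
    candidate whose cross-species evidence is contradictory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .similarity import BestHitMap

ASSIGNED = "assigned"
SPECIES_SPECIFIC = "species_specific"
BORDERLINE = "borderline"
UNASSIGNABLE = "unassignable"
CANDIDATE = "candidate"  # internal, pre-verification


@dataclass(frozen=True)
class SpeciesProfile:
    """Role and score thresholds (bits) of one species.

    ``exclusion_threshold``: best-vs-reference bit score below which a
    sequence is considered species-specific.  ``retention_threshold``:
    score at/above which retention in the grouping is certain.  Scores
    falling between the two are reported as borderline.
    """

    species: str
    role: str = "query"  # "reference" | "query"
    exclusion_threshold: float = 170.0
    retention_threshold: float = 250.0

    def __post_init__(self):
        if self.role not in ("reference", "query"):
            raise ValueError(f"bad role {self.role!r}")
        if self.exclusion_threshold > self.retention_threshold:
            raise ValueError("exclusion threshold above retention threshold")


@dataclass(frozen=True)
class InferenceParams:
    tie_epsilon: float = 5.0       # bits within which hits count as co-best
    majority_needed: int = 2       # votes required among the 3 other species
    nonref_min_species: int = 2    # species span for a lineage-specific group

    def __post_init__(self):
        if self.majority_needed < 1:
            raise ValueError("majority_needed must be >= 1")


@dataclass
class AssignmentRecord:
    """The algorithm's verdict for one sequence."""

    seq_id: str
    species: str
    status: str
    og_ref: str = ""
    #: per other species: (best subject, bit score, its provisional group)
    evidence: dict[str, tuple[str, float, str | None]] = field(default_factory=dict)
    tie_pending: bool = False


@dataclass
class OrthologousGroup:
    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    reference_members: list[str] = field(default_factory=list)

    def add(self, species: str, seq_id: str) -> None:
        self.members.setdefault(species, []).append(seq_id)

    @property
    def all_members(self) -> list[str]:
        return [m for mems in self.members.values() for m in mems]

    def n_members(self, species: str | None = None) -> int:
        if species is None:
            return len(self.all_members)
        return len(self.members.get(species, []))


# ---------------------------------------------------------------------------
# Individual rule steps


def filter_by_threshold(best_ref_score: float | None,
                        profile: SpeciesProfile) -> str:
    """Status of a query sequence from its best score vs the reference.

    ``None`` (no reference hit at all) maps to species_specific.
    """
    if best_ref_score is None:
        return SPECIES_SPECIFIC
    if best_ref_score < profile.exclusion_threshold:
        return SPECIES_SPECIFIC
    if best_ref_score >= profile.retention_threshold:
        return CANDIDATE
    return BORDERLINE


def anchor_to_reference(candidates: list[str], to_ref: BestHitMap,
                        params: InferenceParams) -> dict[str, tuple[str, bool]]:
    """Attach each candidate to the provisional group of its top reference hit.

    Returns ``candidate id -> (anchor reference id, tie_pending)``.
    Co-best ties (several reference subjects within ``tie_epsilon`` bits)
    are resolved to the lexicographically smallest reference id and
    flagged; cross-species verification may override them.
    """
    anchors: dict[str, tuple[str, bool]] = {}
    for cand in candidates:
        co = to_ref.co_best(cand, params.tie_epsilon)
        if not co:
            raise ValueError(f"candidate {cand!r} has no reference hit")
        anchor = min(s for s, _ in co)
        anchors[cand] = (anchor, len({s for s, _ in co}) > 1)
    return anchors


def _vote_of_species(co_best: list[tuple[str, float]], min_bits: float,
                     group_of: dict[str, str]) -> tuple[str | None, str]:
    """Reduce one species' co-best hits to a vote.

    Returns ``(group or None, kind)`` with kind in ``vote`` (one group),
    ``tie`` (co-best hits span several groups, contributes no vote) or
    ``absent`` (no qualifying grouped hit).
    """
    qualifying = [(s, b) for s, b in co_best if b >= min_bits]
    groups = {group_of[s] for s, _ in qualifying if s in group_of}
    if not groups:
        return None, "absent"
    if len(groups) == 1:
        return groups.pop(), "vote"
    return None, "tie"


def _tally(votes: list[str], majority_needed: int) -> str | None:
    counts: dict[str, int] = {}
    for g in votes:
        counts[g] = counts.get(g, 0) + 1
    winners = [g for g, c in counts.items() if c >= majority_needed]
    if len(winners) == 1:
        return winners[0]
    return None


def cross_verify(seq_id: str, species: str, anchors: dict[str, tuple[str, bool]],
                 best_maps: dict[tuple[str, str], BestHitMap],
                 group_of: dict[str, str],
                 profiles: dict[str, SpeciesProfile],
                 params: InferenceParams) -> AssignmentRecord:
    """Verify a candidate's anchor against its best hits in the other species.

    The provisional groups of the best hits in the three other species
    (reference included, through the anchor) are tallied; a group backed
    by at least ``majority_needed`` votes wins.  A species whose co-best
    hits span two or more groups casts no vote; two such species, or a
    tally drawn from fewer than two species, or the absence of a
    majority, make the sequence unassignable.
    """
    ref_species = next(p.species for p in profiles.values()
                       if p.role == "reference")
    anchor, tie_pending = anchors[seq_id]
    evidence: dict[str, tuple[str, float, str | None]] = {}
    votes: list[str] = []
    n_tie = 0
    n_cast_species = 0

    # reference vote via the (co-best) anchor(s)
    ref_co = best_maps[(species, ref_species)].co_best(seq_id, params.tie_epsilon)
    ref_groups = {group_of[s] for s, _ in ref_co if s in group_of}
    top_ref = ref_co[0] if ref_co else None
    if top_ref:
        evidence[ref_species] = (top_ref[0], top_ref[1],
                                 group_of.get(anchor))
    if len(ref_groups) == 1:
        votes.append(ref_groups.pop())
        n_cast_species += 1
    elif len(ref_groups) > 1:
        n_tie += 1

    for other in profiles:
        if other in (species, ref_species):
            continue
        bm = best_maps.get((species, other))
        co = bm.co_best(seq_id, params.tie_epsilon) if bm else []
        min_bits = max(profiles[species].exclusion_threshold,
                       profiles[other].exclusion_threshold)
        group, kind = _vote_of_species(co, min_bits, group_of)
        if co:
            top = co[0]
            evidence[other] = (top[0], top[1],
                              group if kind == "vote" else None)
        if kind == "vote":
            votes.append(group)
            n_cast_species += 1
        elif kind == "tie":
            n_tie += 1

    record = AssignmentRecord(seq_id=seq_id, species=species, status=UNASSIGNABLE,
                              evidence=evidence, tie_pending=tie_pending)
    if n_tie >= 2 or n_cast_species < 2:
        return record
    winner = _tally(votes, params.majority_needed)
    if winner is None:
        return record
    record.status = ASSIGNED
    record.og_ref = winner
    return record


def group_reference_sequences(ref_ids: list[str], anchored_refs: set[str],
                              best_maps: dict[tuple[str, str], BestHitMap],
                              anchors: dict[str, tuple[str, bool]],
                              profiles: dict[str, SpeciesProfile],
                              params: InferenceParams
                              ) -> tuple[dict[str, str], dict[str, AssignmentRecord]]:
    """Place reference sequences that anchor no query sequence.

    Such a sequence is merged into the group where its own cross-species
    best hits land (same majority rule as for queries); with no
    cross-species hit above the exclusion thresholds it is reported
    species-specific, and with contradictory votes unassignable.

    Returns ``(group_of_ref, records)`` where ``group_of_ref`` maps every
    grouped reference id to its group key (an anchoring reference id).
    """
    ref_species = next(p.species for p in profiles.values()
                       if p.role == "reference")
    group_of_ref = {r: r for r in anchored_refs}
    records: dict[str, AssignmentRecord] = {}
    anchor_group_of_query = {q: a for q, (a, _) in anchors.items()}

    for rid in sorted(ref_ids):
        if rid in anchored_refs:
            continue
        votes: list[str] = []
        n_tie = 0
        evidence: dict[str, tuple[str, float, str | None]] = {}
        for other, prof in profiles.items():
            if other == ref_species:
                continue
            bm = best_maps.get((ref_species, other))
            co = bm.co_best(rid, params.tie_epsilon) if bm else []
            min_bits = max(profiles[ref_species].exclusion_threshold,
                           prof.exclusion_threshold)
            group, kind = _vote_of_species(co, min_bits, anchor_group_of_query)
            if co:
                evidence[other] = (co[0][0], co[0][1], group)
            if kind == "vote":
                votes.append(group)
            elif kind == "tie":
                n_tie += 1
        if not votes and n_tie == 0:
            records[rid] = AssignmentRecord(rid, ref_species, SPECIES_SPECIFIC,
                                            evidence=evidence)
            continue
        winner = _tally(votes, params.majority_needed) if n_tie < 2 else None
        if winner is None:
            records[rid] = AssignmentRecord(rid, ref_species, UNASSIGNABLE,
                                            evidence=evidence)
        else:
            group_of_ref[rid] = winner
            records[rid] = AssignmentRecord(rid, ref_species, ASSIGNED,
                                            og_ref=winner, evidence=evidence)
    for rid in anchored_refs:
        records[rid] = AssignmentRecord(rid, ref_species, ASSIGNED, og_ref=rid)
    return group_of_ref, records


def detect_nonreference_groups(pool: dict[str, str],
                               best_maps: dict[tuple[str, str], BestHitMap],
                               profiles: dict[str, SpeciesProfile],
                               params: InferenceParams) -> list[set[str]]:
    """Find lineage-specific groups among threshold-excluded sequences.

    ``pool`` maps sequence id -> species for every species-specific
    sequence of the non-reference species.  Sets are seeded by
    reciprocal best hits between pool members of different species whose
    bit scores clear both species' exclusion thresholds; remaining pool
    sequences then join a set when their own best qualifying hit is a
    member (the same one-directional anchoring used against the
    reference).  Sets spanning at least ``nonref_min_species`` species
    are returned.
    """
    parent: dict[str, str] = {s: s for s in pool}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    def qualifying_co_best(qid: str, qsp: str, ssp: str):
        bm = best_maps.get((qsp, ssp))
        if bm is None:
            return []
        min_bits = max(profiles[qsp].exclusion_threshold,
                       profiles[ssp].exclusion_threshold)
        return [(s, b) for s, b in bm.co_best(qid, params.tie_epsilon)
                if b >= min_bits]

    species = sorted({sp for sp in pool.values()})
    # reciprocal best hits seed the sets
    for qid in sorted(pool):
        qsp = pool[qid]
        for ssp in species:
            if ssp == qsp:
                continue
            for sid, _ in qualifying_co_best(qid, qsp, ssp):
                if sid not in pool:
                    continue
                back = {t for t, _ in qualifying_co_best(sid, ssp, qsp)}
                if qid in back:
                    union(qid, sid)

    # one-directional attachment of the remaining orphans
    comp_size: dict[str, int] = {}
    for s in pool:
        comp_size[find(s)] = comp_size.get(find(s), 0) + 1
    for qid in sorted(pool):
        if comp_size[find(qid)] > 1:
            continue
        qsp = pool[qid]
        choices = []
        for ssp in species:
            if ssp == qsp:
                continue
            for sid, bits in qualifying_co_best(qid, qsp, ssp):
                if sid in pool:
                    choices.append((-bits, sid))
        if choices:
            choices.sort()
            union(qid, choices[0][1])

    components: dict[str, set[str]] = {}
    for s in pool:
        components.setdefault(find(s), set()).add(s)
    groups = []
    for comp in components.values():
        if len({pool[s] for s in comp}) >= params.nonref_min_species:
            groups.append(comp)
    groups.sort(key=lambda c: min(c))
    return groups


# ---------------------------------------------------------------------------
# Nomenclature


def _letters(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa ... (spreadsheet-style)."""
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def assign_nomenclature(groups_by_anchor: dict[str, OrthologousGroup],
                        lineage_groups: list[OrthologousGroup],
                        cluster_map: dict[str, int] | None = None,
                        letter_override: dict[str, str] | None = None,
                        lineage_of: dict[str, str] | None = None
                        ) -> list[OrthologousGroup]:
    """Name the groups: cluster number + letter, or a lineage label.

    Reference-containing groups take the cluster number of their
    reference members (all members of one group must map to the same
    cluster) and letters ``a, b, c...`` within each cluster by ascending
    smallest reference id, unless ``letter_override`` maps an anchoring
    reference id to an explicit og id.  Groups without reference members
    are labelled by lineage: ``MS`` (monocot-specific), ``DS``
    (dicot-specific) or ``XS`` (mixed), numbered when repeated.
    """
    from .io_formats import MONOCOTS, DICOTS

    named: list[OrthologousGroup] = []
    by_cluster: dict[int, list[OrthologousGroup]] = {}
    for anchor in sorted(groups_by_anchor):
        og = groups_by_anchor[anchor]
        if cluster_map is None:
            cluster = 1
        else:
            clusters = set()
            for rm in og.reference_members:
                if rm not in cluster_map:
                    raise KeyError(f"reference member {rm!r} missing from cluster map")
                clusters.add(cluster_map[rm])
            if len(clusters) != 1:
                raise ValueError(
                    f"group anchored at {anchor!r} spans clusters {sorted(clusters)}"
                )
            cluster = clusters.pop()
        by_cluster.setdefault(cluster, []).append(og)

    for cluster in sorted(by_cluster):
        ogs = sorted(by_cluster[cluster],
                     key=lambda og: min(og.reference_members))
        for i, og in enumerate(ogs):
            anchor = min(og.reference_members)
            if letter_override and anchor in letter_override:
                og_id = letter_override[anchor]
            else:
                og_id = f"{cluster}{_letters(i)}"
            named.append(replace_id(og, og_id))

    def lineage_label(og: OrthologousGroup) -> str:
        sps = {sp for sp, mems in og.members.items() if mems}
        if lineage_of is not None:
            lineages = {lineage_of.get(sp, "?") for sp in sps}
            if lineages == {"monocot"}:
                return "MS"
            if lineages == {"dicot"}:
                return "DS"
            return "XS"
        if sps <= MONOCOTS:
            return "MS"
        if sps <= DICOTS:
            return "DS"
        return "XS"

    counts: dict[str, int] = {}
    for og in sorted(lineage_groups, key=lambda og: min(og.all_members)):
        label = lineage_label(og)
        counts[label] = counts.get(label, 0) + 1
        og_id = label if counts[label] == 1 else f"{label}{counts[label]}"
        named.append(replace_id(og, og_id))
    return named


def replace_id(og: OrthologousGroup, og_id: str) -> OrthologousGroup:
    return OrthologousGroup(og_id=og_id, members=og.members,
                            reference_members=og.reference_members)


def merge_groups(groups: list[OrthologousGroup], og_x: str, og_y: str,
                 new_id: str) -> list[OrthologousGroup]:
    """Merge two groups under a new id (e.g. the dicot- and
    monocot-specific remnants of one ancestral gene).

    The merge is logged; overlapping members indicate an upstream
    invariant breach and raise.
    """
    by_id = {g.og_id: g for g in groups}
    for og in (og_x, og_y):
        if og not in by_id:
            raise KeyError(f"unknown OG id {og!r}")
    gx, gy = by_id[og_x], by_id[og_y]
    overlap = set(gx.all_members) & set(gy.all_members)
    if overlap:
        raise ValueError(f"groups {og_x} and {og_y} share members {sorted(overlap)}")
    merged = OrthologousGroup(og_id=new_id)
    for g in (gx, gy):
        for sp, mems in g.members.items():
            for m in mems:
                merged.add(sp, m)
        merged.reference_members.extend(g.reference_members)
    warnings.warn(f"merged OGs {og_x} + {og_y} -> {new_id}")
    out = [g for g in groups if g.og_id not in (og_x, og_y)]
    out.append(merged)
    return out


# ---------------------------------------------------------------------------
# Orchestration


def infer_groups(species_of: dict[str, str],
                 best_maps: dict[tuple[str, str], BestHitMap],
                 profiles: dict[str, SpeciesProfile],
                 params: InferenceParams = InferenceParams(),
                 cluster_map: dict[str, int] | None = None,
                 letter_override: dict[str, str] | None = None
                 ) -> tuple[list[OrthologousGroup], dict[str, AssignmentRecord]]:
    """Run the full grouping: filter, anchor, self-group the reference,
    cross-verify, detect lineage-specific groups, and name the result.

    Returns the named groups and one :class:`AssignmentRecord` per input
    sequence (the four statuses partition the input).
    """
    refs = [p for p in profiles.values() if p.role == "reference"]
    if len(refs) != 1:
        raise ValueError("exactly one species must have role=reference")
    ref_sp = refs[0].species
    ref_ids = sorted(i for i, sp in species_of.items() if sp == ref_sp)

    records: dict[str, AssignmentRecord] = {}
    candidates_by_species: dict[str, list[str]] = {}
    for qid in sorted(species_of):
        sp = species_of[qid]
        if sp == ref_sp:
            continue
        bm = best_maps[(sp, ref_sp)]
        top = bm.best(qid)
        status = filter_by_threshold(top[1] if top else None, profiles[sp])
        if status == CANDIDATE:
            candidates_by_species.setdefault(sp, []).append(qid)
        else:
            ev = {ref_sp: (top[0], top[1], None)} if top else {}
            records[qid] = AssignmentRecord(qid, sp, status, evidence=ev)

    anchors: dict[str, tuple[str, bool]] = {}
    for sp, cands in candidates_by_species.items():
        anchors.update(anchor_to_reference(cands, best_maps[(sp, ref_sp)], params))

    anchored_refs = {a for a, _ in anchors.values()}
    group_of_ref, ref_records = group_reference_sequences(
        ref_ids, anchored_refs, best_maps, anchors, profiles, params)
    records.update(ref_records)

    # provisional group of any grouped sequence (queries via their anchor,
    # reference sequences via the self-grouping)
    group_of: dict[str, str] = dict(group_of_ref)
    for q, (a, _) in anchors.items():
        group_of[q] = group_of_ref.get(a, a)

    for sp, cands in sorted(candidates_by_species.items()):
        for qid in cands:
            records[qid] = cross_verify(qid, sp, anchors, best_maps, group_of,
                                        profiles, params)

    # assemble reference-anchored groups from verified assignments
    groups_by_anchor: dict[str, OrthologousGroup] = {}
    for rid in sorted(group_of_ref):
        key = group_of_ref[rid]
        og = groups_by_anchor.setdefault(key, OrthologousGroup(og_id=key))
        og.add(ref_sp, rid)
        og.reference_members.append(rid)
    for qid, rec in sorted(records.items()):
        if rec.status == ASSIGNED and rec.species != ref_sp:
            groups_by_anchor[rec.og_ref].add(rec.species, qid)

    # drop groups that ended up with a lone reference member and no queries
    # only if that reference member was itself merged elsewhere (cannot
    # happen by construction); empty groups are kept out by assembly.

    pool = {qid: rec.species for qid, rec in records.items()
            if rec.status == SPECIES_SPECIFIC and rec.species != ref_sp}
    lineage_sets = detect_nonreference_groups(pool, best_maps, profiles, params)
    lineage_groups: list[OrthologousGroup] = []
    for comp in lineage_sets:
        og = OrthologousGroup(og_id="")
        for sid in sorted(comp):
            og.add(species_of[sid], sid)
        lineage_groups.append(og)

    named = assign_nomenclature(groups_by_anchor, lineage_groups, cluster_map,
                                letter_override)

    # rewrite records with final og ids and lineage-group membership
    final_id: dict[str, str] = {}
    for og in named:
        for m in og.all_members:
            final_id[m] = og.og_id
    for sid, rec in records.items():
        if sid in final_id:
            rec.status = ASSIGNED
            rec.og_ref = final_id[sid]
        elif rec.status == ASSIGNED:  # anchor group dissolved (defensive)
            rec.status = UNASSIGNABLE
            rec.og_ref = ""
    return named, records
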