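"""Core grouping algorithm: threshold filtering, anchoring, majority
cross-verification, reference self-grouping, lineage-specific group
detection, nomenclature — plus equivalence with an independent
enumeration of the rules on small random instances."""

import itertools

import numpy as np
import pytest

from nacortho.og_inference import (
    ASSIGNED,
    BORDERLINE,
    CANDIDATE,
    SPECIES_SPECIFIC,
    UNASSIGNABLE,
    InferenceParams,
    OrthologousGroup,
    SpeciesProfile,
    anchor_to_reference,
    assign_nomenclature,
    cross_verify,
    detect_nonreference_groups,
    filter_by_threshold,
    group_reference_sequences,
    infer_groups,
    merge_groups,
)
from nacortho.similarity import SimilarityHit, best_hit_maps

AT_PROFILE = SpeciesProfile("At", "query", 170.0, 250.0)


def make_maps(scores, species_of):
    """Best-hit maps from a symmetric {(a, b): bits} score dict."""
    hits = []
    for (a, b), bits in scores.items():
        hits.append(SimilarityHit(a, b, 0, float(bits)))
        hits.append(SimilarityHit(b, a, 0, float(bits)))
    return best_hit_maps(hits, species_of)


def flat_profiles(threshold=300.0, ref="Vv", species=("Vv", "At", "Os", "Ma")):
    return {
        sp: SpeciesProfile(sp, "reference" if sp == ref else "query",
                           threshold, threshold)
        for sp in species
    }


class TestThresholdFilter:
    @pytest.mark.parametrize("score,expected", [
        (160.0, SPECIES_SPECIFIC),   # below the exclusion bound
        (251.0, CANDIDATE),          # above the retention bound
        (200.0, BORDERLINE),         # inside the printed gap zone
        (170.0, BORDERLINE),         # exclusion bound itself is not excluded
        (250.0, CANDIDATE),          # retention bound is inclusive
        (None, SPECIES_SPECIFIC),    # no reference hit at all
    ])
    def test_status_zones(self, score, expected):
        assert filter_by_threshold(score, AT_PROFILE) == expected

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            SpeciesProfile("At", "query", 300.0, 200.0)
        with pytest.raises(ValueError):
            SpeciesProfile("At", "queen")


class TestAnchoring:
    def _anchors(self, scores):
        species_of = {"q": "At", "q2": "At", "R1": "Vv", "R2": "Vv"}
        maps = make_maps(scores, species_of)
        cands = sorted({a for (a, _b) in scores} & {"q", "q2"})
        return anchor_to_reference(cands, maps[("At", "Vv")],
                                   InferenceParams())

    def test_clear_best_anchor(self):
        anchors = self._anchors({("q", "R1"): 300, ("q", "R2"): 250})
        assert anchors["q"] == ("R1", False)

    def test_shared_anchor(self):
        anchors = self._anchors({("q", "R1"): 300, ("q2", "R1"): 280})
        assert anchors["q"][0] == anchors["q2"][0] == "R1"

    def test_co_best_tie_resolves_to_smallest_id_and_flags(self):
        anchors = self._anchors({("q", "R1"): 300, ("q", "R2"): 299})
        assert anchors["q"] == ("R1", True)


class TestCrossVerify:
    def _verify(self, scores_q, anchors_extra, group_of):
        species_of = {"q": "At", "R1": "Vv", "R2": "Vv",
                      "o1": "Os", "o2": "Os", "m1": "Ma", "m2": "Ma"}
        maps = make_maps(scores_q, species_of)
        anchors = {"q": ("R1", False), **anchors_extra}
        return cross_verify("q", "At", anchors, maps, group_of,
                            flat_profiles(), InferenceParams())

    def test_two_of_three_majority_assigns(self):
        rec = self._verify(
            {("q", "R1"): 500, ("q", "o1"): 450, ("q", "m1"): 450},
            {"o1": ("R1", False), "m1": ("R2", False)},
            {"R1": "R1", "R2": "R2", "o1": "R1", "m1": "R2"})
        assert (rec.status, rec.og_ref) == (ASSIGNED, "R1")

    def test_three_way_disagreement_unassignable(self):
        rec = self._verify(
            {("q", "R1"): 500, ("q", "o1"): 450, ("q", "m1"): 450},
            {"o1": ("R2", False), "m1": ("R3", False)},
            {"R1": "R1", "R2": "R2", "R3": "R3", "o1": "R2", "m1": "R3"})
        assert rec.status == UNASSIGNABLE

    def test_co_best_spanning_groups_in_two_species_unassignable(self):
        # mirrors reference sequences torn between two sibling groups
        rec = self._verify(
            {("q", "R1"): 500,
             ("q", "o1"): 450, ("q", "o2"): 449,
             ("q", "m1"): 450, ("q", "m2"): 448},
            {"o1": ("R1", False), "o2": ("R2", False),
             "m1": ("R1", False), "m2": ("R2", False)},
            {"R1": "R1", "R2": "R2", "o1": "R1", "o2": "R2",
             "m1": "R1", "m2": "R2"})
        assert rec.status == UNASSIGNABLE

    def test_fewer_than_two_votes_unassignable(self):
        rec = self._verify({("q", "R1"): 500}, {}, {"R1": "R1"})
        assert rec.status == UNASSIGNABLE

    def test_low_scoring_cross_hits_do_not_vote(self):
        # the Os/Ma hits are under the exclusion thresholds: only the
        # reference vote remains, which is not enough on its own
        rec = self._verify(
            {("q", "R1"): 500, ("q", "o1"): 120, ("q", "m1"): 110},
            {"o1": ("R2", False), "m1": ("R2", False)},
            {"R1": "R1", "R2": "R2", "o1": "R2", "m1": "R2"})
        assert rec.status == UNASSIGNABLE


class TestReferenceSelfGrouping:
    def test_unanchored_reference_joins_majority_group(self):
        species_of = {"R1": "Vv", "R2": "Vv", "q1": "At", "o1": "Os",
                      "m1": "Ma"}
        # R2 anchors nobody; its own best hits all live in group(R1)
        scores = {("R2", "q1"): 400, ("R2", "o1"): 400, ("R2", "m1"): 400,
                  ("R1", "q1"): 500, ("R1", "o1"): 500, ("R1", "m1"): 500}
        maps = make_maps(scores, species_of)
        anchors = {"q1": ("R1", False), "o1": ("R1", False),
                   "m1": ("R1", False)}
        group_of, records = group_reference_sequences(
            ["R1", "R2"], {"R1"}, maps, anchors, flat_profiles(),
            InferenceParams())
        assert group_of == {"R1": "R1", "R2": "R1"}
        assert records["R2"].status == ASSIGNED

    def test_reference_without_cross_hits_is_species_specific(self):
        species_of = {"R1": "Vv", "R2": "Vv", "q1": "At"}
        scores = {("R1", "q1"): 500, ("R2", "q1"): 100}
        maps = make_maps(scores, species_of)
        group_of, records = group_reference_sequences(
            ["R1", "R2"], {"R1"}, maps, {"q1": ("R1", False)},
            flat_profiles(), InferenceParams())
        assert records["R2"].status == SPECIES_SPECIFIC
        assert "R2" not in group_of

    def test_reference_torn_between_groups_unassignable(self):
        species_of = {"R1": "Vv", "R2": "Vv", "R3": "Vv",
                      "q1": "At", "o1": "Os", "m1": "Ma"}
        scores = {("R1", "q1"): 500, ("R2", "o1"): 500, ("R2", "m1"): 500,
                  ("R3", "q1"): 400, ("R3", "o1"): 400, ("R3", "m1"): 400}
        maps = make_maps(scores, species_of)
        anchors = {"q1": ("R1", False), "o1": ("R2", False),
                   "m1": ("R2", False)}
        group_of, records = group_reference_sequences(
            ["R1", "R2", "R3"], {"R1", "R2"}, maps, anchors,
            flat_profiles(), InferenceParams())
        # R3's votes: q1 -> group R1, o1/m1 -> group R2: 2-1 majority
        assert group_of["R3"] == "R2"
        # with a 1-1-? split instead, no majority emerges
        scores2 = {("R1", "q1"): 500, ("R2", "o1"): 500,
                   ("R3", "q1"): 400, ("R3", "o1"): 400}
        maps2 = make_maps(scores2, species_of)
        _, records2 = group_reference_sequences(
            ["R1", "R2", "R3"], {"R1", "R2"}, maps2,
            {"q1": ("R1", False), "o1": ("R2", False)},
            flat_profiles(), InferenceParams())
        assert records2["R3"].status == UNASSIGNABLE


class TestNonReferenceGroups:
    def test_monocot_specific_trio_groups(self):
        pool = {"o1": "Os", "m1": "Ma", "m2": "Ma"}
        species_of = {**pool}
        scores = {("o1", "m1"): 400, ("o1", "m2"): 380, ("m1", "m2"): 0}
        maps = make_maps(scores, species_of)
        (grp,) = detect_nonreference_groups(pool, maps, flat_profiles(),
                                            InferenceParams())
        assert grp == {"o1", "m1", "m2"}

    def test_orphan_without_reciprocal_hit_stays_out(self):
        pool = {"o1": "Os", "m1": "Ma", "m2": "Ma", "x1": "At"}
        scores = {("o1", "m1"): 400, ("o1", "m2"): 380,
                  ("x1", "o1"): 100}  # under threshold: no attachment
        maps = make_maps(scores, pool)
        groups = detect_nonreference_groups(pool, maps, flat_profiles(),
                                            InferenceParams())
        assert groups == [{"o1", "m1", "m2"}]

    def test_empty_pool_no_groups(self):
        assert detect_nonreference_groups({}, {}, flat_profiles(),
                                          InferenceParams()) == []


class TestNomenclature:
    def _group(self, anchor, members):
        og = OrthologousGroup(og_id=anchor)
        for sp, ids in members.items():
            for i in ids:
                og.add(sp, i)
        og.reference_members = list(members.get("Vv", []))
        return og

    def test_letters_within_cluster_by_smallest_reference_id(self):
        groups = {
            f"R{i}": self._group(f"R{i}", {"Vv": [f"R{i}"]}) for i in range(8)
        }
        cluster_map = {f"R{i}": 1 for i in range(8)}
        named = assign_nomenclature(groups, [], cluster_map)
        assert [g.og_id for g in named] == [f"1{c}" for c in "abcdefgh"]

    def test_two_clusters_letter_independently(self):
        groups = {"R1": self._group("R1", {"Vv": ["R1"]}),
                  "R2": self._group("R2", {"Vv": ["R2"]}),
                  "R3": self._group("R3", {"Vv": ["R3"]})}
        cluster_map = {"R1": 5, "R2": 5, "R3": 5}
        named = assign_nomenclature(groups, [], cluster_map)
        assert [g.og_id for g in named] == ["5a", "5b", "5c"]

    def test_monocot_specific_group_labelled_ms(self):
        ms = self._group("", {"Os": ["o1"], "Ma": ["m1", "m2"]})
        named = assign_nomenclature({}, [ms])
        assert named[0].og_id == "MS"

    def test_cluster_conflict_raises(self):
        g = self._group("R1", {"Vv": ["R1", "R2"]})
        with pytest.raises(ValueError, match="clusters"):
            assign_nomenclature({"R1": g}, [], {"R1": 1, "R2": 2})

    def test_letter_override(self):
        g = self._group("R1", {"Vv": ["R1"]})
        named = assign_nomenclature({"R1": g}, [], {"R1": 3},
                                    letter_override={"R1": "3e"})
        assert named[0].og_id == "3e"


class TestMerge:
    def _two_groups(self):
        a = OrthologousGroup("5c", members={"Vv": ["R1"], "At": ["q1"]})
        b = OrthologousGroup("MS", members={"Os": ["o1"], "Ma": ["m1", "m2"]})
        return [a, b]

    def test_merge_is_member_union(self):
        merged = merge_groups(self._two_groups(), "5c", "MS", "5c+MS")
        (g,) = merged
        assert g.og_id == "5c+MS"
        assert sorted(g.all_members) == ["R1", "m1", "m2", "o1", "q1"]

    def test_merge_unknown_id_raises(self):
        with pytest.raises(KeyError):
            merge_groups(self._two_groups(), "5c", "nope", "x")

    def test_overlapping_members_raise(self):
        a = OrthologousGroup("A", members={"Vv": ["R1"]})
        b = OrthologousGroup("B", members={"Vv": ["R1"]})
        with pytest.raises(ValueError, match="share members"):
            merge_groups([a, b], "A", "B", "AB")


# ---------------------------------------------------------------------------
# End-to-end on toys


def _toy_instance(scores, species_of, threshold=300.0):
    maps = make_maps(scores, species_of)
    return infer_groups(species_of, maps, flat_profiles(threshold),
                        InferenceParams())


def test_toy8_pipeline_recovers_two_groups(toy8_dataset):
    from nacortho.synthetic_data import run_inference_on_dataset

    groups, records, _ = run_inference_on_dataset(toy8_dataset)
    assert len(groups) == 2
    assert all(r.status == ASSIGNED for r in records.values())
    inferred = {m: g.og_id for g in groups for m in g.all_members}
    truth = toy8_dataset.truth_labels()
    for a, b in itertools.combinations(sorted(truth), 2):
        assert (inferred[a] == inferred[b]) == (truth[a] == truth[b])


def test_three_way_conflicted_query_is_isolated():
    """A query whose three votes disagree ends unassignable without
    disturbing the other assignments."""
    species_of = {"R1": "Vv", "R2": "Vv", "R3": "Vv",
                  "q1": "At", "qX": "At", "o1": "Os", "o2": "Os",
                  "m1": "Ma", "m2": "Ma"}
    scores = {
        ("q1", "R1"): 500, ("o1", "R1"): 500, ("m1", "R1"): 500,
        ("o2", "R2"): 500, ("m2", "R3"): 500,
        ("q1", "o1"): 450, ("q1", "m1"): 450,
        ("o1", "m1"): 450,
        # qX anchors to R1 but its monocot best hits sit in other groups
        ("qX", "R1"): 420, ("qX", "o2"): 460, ("qX", "m2"): 460,
        ("o2", "m2"): 310,
    }
    groups, records = _toy_instance(scores, species_of)
    assert records["qX"].status == UNASSIGNABLE
    assert records["q1"].status == ASSIGNED
    assert records["q1"].og_ref == records["o1"].og_ref == records["m1"].og_ref


def test_partition_and_determinism(default_dataset):
    """Every sequence gets exactly one status and rerunning with
    permuted input order reproduces the identical OG table."""
    from nacortho.synthetic_data import default_sim_profiles
    from nacortho.similarity import all_vs_all

    ds = default_dataset
    hits = []
    for a, b in itertools.combinations(("Vv", "At", "Os", "Ma"), 2):
        hits.extend(all_vs_all(ds.seqs[a], ds.seqs[b]))
    species_of = ds.species_of
    maps = best_hit_maps(hits, species_of)
    profiles = default_sim_profiles(ds.config)
    groups1, records1 = infer_groups(species_of, maps, profiles)

    shuffled = dict(reversed(list(species_of.items())))
    maps2 = best_hit_maps(list(reversed(hits)), shuffled)
    groups2, records2 = infer_groups(shuffled, maps2, profiles)

    assert set(records1) == set(species_of)
    statuses = {ASSIGNED, SPECIES_SPECIFIC, BORDERLINE, UNASSIGNABLE}
    assert {r.status for r in records1.values()} <= statuses
    assert all((r.status == ASSIGNED) == bool(r.og_ref)
               for r in records1.values())

    def table(groups):
        return sorted((g.og_id, sp, tuple(sorted(m)))
                      for g in groups for sp, m in g.members.items())

    assert table(groups1) == table(groups2)
    assert {s: r.status for s, r in records1.items()} == \
           {s: r.status for s, r in records2.items()}


# ---------------------------------------------------------------------------
# Independent enumeration of the rules on small random instances


def enumerate_rules(species_of, scores, threshold, eps=5.0, majority=2):
    """Direct, unoptimised restatement of the grouping rules.

    Returns (status per sequence, partition as a set of frozensets of
    the grouped sequences).  Written independently of the library
    implementation: plain dict scans, no shared helpers.
    """
    def s(a, b):
        return scores.get((a, b), scores.get((b, a), 0.0))

    ref = "Vv"
    by_species = {}
    for sid, sp in species_of.items():
        by_species.setdefault(sp, []).append(sid)

    def co_best(q, sp):
        subj = [(s(q, x), x) for x in by_species.get(sp, [])]
        subj = [t for t in subj if t[0] > 0]
        if not subj:
            return []
        top = max(t[0] for t in subj)
        return sorted(x for sc, x in subj if top - sc <= eps)

    status = {}
    anchor = {}
    for sp, members in by_species.items():
        if sp == ref:
            continue
        for q in members:
            tops = co_best(q, ref)
            best = max((s(q, r) for r in by_species[ref]), default=0.0)
            if not tops or best < threshold:
                status[q] = "species_specific"
            else:
                status[q] = "candidate"
                anchor[q] = min(tops)

    anchored = {anchor[q] for q in anchor}
    group_of_ref = {r: r for r in anchored}
    for r in sorted(by_species[ref]):
        if r in anchored:
            status[r] = "assigned"
            continue
        votes, ties = [], 0
        for sp in by_species:
            if sp == ref:
                continue
            cands = [x for x in co_best(r, sp) if s(r, x) >= threshold]
            gs = {anchor[x] for x in cands if x in anchor}
            if len(gs) == 1:
                votes.append(gs.pop())
            elif len(gs) > 1:
                ties += 1
        counts = {g: votes.count(g) for g in votes}
        winners = [g for g, c in counts.items() if c >= majority]
        if not votes and ties == 0:
            status[r] = "species_specific"
        elif ties >= 2 or len(winners) != 1:
            status[r] = "unassignable"
        else:
            status[r] = "assigned"
            group_of_ref[r] = winners[0]

    member_group = {}
    for q, a in anchor.items():
        member_group[q] = group_of_ref[a]

    final_group = {}
    for q in sorted(anchor):
        sp = species_of[q]
        votes, ties, cast = [], 0, 0
        ref_groups = {group_of_ref[r] for r in co_best(q, ref)
                      if r in group_of_ref}
        if len(ref_groups) == 1:
            votes.append(ref_groups.pop())
            cast += 1
        elif len(ref_groups) > 1:
            ties += 1
        for other in by_species:
            if other in (sp, ref):
                continue
            cands = [x for x in co_best(q, other) if s(q, x) >= threshold]
            gs = {member_group[x] for x in cands if x in member_group}
            if len(gs) == 1:
                votes.append(gs.pop())
                cast += 1
            elif len(gs) > 1:
                ties += 1
        counts = {g: votes.count(g) for g in votes}
        winners = [g for g, c in counts.items() if c >= majority]
        if ties >= 2 or cast < 2 or len(winners) != 1:
            status[q] = "unassignable"
        else:
            status[q] = "assigned"
            final_group[q] = winners[0]

    clusters = {}
    for r, g in group_of_ref.items():
        clusters.setdefault(g, set()).add(r)
    for q, g in final_group.items():
        clusters.setdefault(g, set()).add(q)

    # lineage-specific sets among the excluded non-reference sequences
    pool = sorted(q for q, st in status.items()
                  if st == "species_specific" and species_of[q] != ref)
    parent = {q: q for q in pool}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for q in pool:
        for sp in by_species:
            if sp == species_of[q]:
                continue
            for x in co_best(q, sp):
                if x in pool and s(q, x) >= threshold and \
                        q in co_best(x, species_of[q]):
                    ra, rb = find(q), find(x)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
    comp = {}
    for q in pool:
        comp.setdefault(find(q), set()).add(q)
    for q in pool:
        if len(comp[find(q)]) > 1:
            continue
        choices = []
        for sp in by_species:
            if sp == species_of[q]:
                continue
            for x in co_best(q, sp):
                if x in pool and s(q, x) >= threshold:
                    choices.append((-s(q, x), x))
        if choices:
            choices.sort()
            ra, rb = find(q), find(choices[0][1])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comp = {}
    for q in pool:
        comp.setdefault(find(q), set()).add(q)
    for members in comp.values():
        if len({species_of[m] for m in members}) >= 2:
            clusters[min(members)] = set(members)
            for m in members:
                status[m] = "assigned"

    partition = {frozenset(v) for v in clusters.values()}
    return status, partition


@pytest.mark.parametrize("seed", range(12))
def test_matches_rule_enumeration_on_random_toys(seed):
    rng = np.random.default_rng(seed)
    species_of = {}
    for sp, n in (("Vv", 3), ("At", 3), ("Os", 3), ("Ma", 3)):
        for i in range(n):
            species_of[f"{sp}{i}"] = sp
    ids = sorted(species_of)
    scores = {}
    for a, b in itertools.combinations(ids, 2):
        if species_of[a] == species_of[b]:
            continue
        scores[(a, b)] = float(rng.choice([40, 200, 320, 340, 360, 420, 500]))

    status_exp, partition_exp = enumerate_rules(species_of, scores, 300.0)
    groups, records = _toy_instance(scores, species_of)

    got_status = {sid: rec.status for sid, rec in records.items()}
    exp_status = {sid: ("assigned" if st == "candidate" else st)
                  for sid, st in status_exp.items()}
    assert got_status == exp_status
    got_partition = {frozenset(g.all_members) for g in groups}
    assert got_partition == partition_exp
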