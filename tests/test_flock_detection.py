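import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otuflock.flock_detection import (
    LABEL_DIVERGENT,
    LABEL_FLOCK,
    LABEL_INTRAGENOMIC,
    LABEL_REJECTED,
    TYPE1,
    TYPE2,
    TYPE3,
    TYPE_NONE,
    FlockParams,
    abundance_compatible,
    classify_clade,
    detect_flocks,
    mean_pairwise_divergence,
    type_endemism,
)
from otuflock.io_formats import SequenceRecord, parse_newick
from otuflock.reference_match import DivergenceCache, ReferenceHit, p_distance
from otuflock.synthetic_community import evolve_sequence, plant_flock, random_sequence
from otuflock.tree_ops import enumerate_clades, focal_clades


def brute_force_abundance(reads: dict, params: FlockParams):
    """Subset-enumeration oracle (inputs <= ~15 OTUs)."""
    best = frozenset()
    items = list(reads.items())
    dominant = max(reads.values())
    for r in range(1, len(items) + 1):
        for combo in itertools.combinations(items, r):
            vals = [v for _, v in combo]
            if max(vals) / min(vals) >= params.max_abundance_ratio:
                continue
            if params.require_dominant_in_set and dominant not in vals:
                continue
            if len(combo) > len(best):
                best = frozenset(k for k, _ in combo)
    return best


class TestMeanPairwiseDivergence:
    def test_identical_sequences(self):
        recs = [SequenceRecord(f"s{i}", "ACGT" * 50) for i in range(3)]
        cache = DivergenceCache(recs)
        assert mean_pairwise_divergence({"s0", "s1", "s2"}, cache) == 0.0

    def test_constant_pairwise(self):
        d = {frozenset(p): 0.02 for p in itertools.combinations("abc", 2)}
        src = lambda x, y: d[frozenset((x, y))]
        assert mean_pairwise_divergence({"a", "b", "c"}, src) == pytest.approx(0.02)

    def test_53_tip_fixture_near_target(self, rng):
        anc = random_sequence(380, rng)
        tips = plant_flock(anc, 53, 0.022, rng)
        recs = [SequenceRecord(f"t{i:02d}", s) for i, s in enumerate(tips)]
        cache = DivergenceCache(recs)
        mean = mean_pairwise_divergence({r.id for r in recs}, cache)
        # oracle: brute-force pair scan
        brute = np.mean([p_distance(a, b) for a, b in itertools.combinations(tips, 2)])
        assert mean == pytest.approx(brute)
        assert 0.018 <= mean <= 0.026

    def test_single_id_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_divergence({"a"}, lambda x, y: 0.0)


class TestAbundanceCompatible:
    def test_dominant_plus_trace_fails(self):
        # dominant of 214,236 reads vs satellites under 100 reads
        reads = {"dom": 214236, "s1": 99, "s2": 98, "s3": 97, "s4": 50}
        res = abundance_compatible(reads)
        assert res.passes is False
        assert res.compatible_set == frozenset({"dom"})

    def test_dominant_with_comparable_trace_satellites_fails(self):
        reads = {"dom": 30958, "a": 86, "b": 50, "c": 2, "d": 10, "e": 4, "f": 7}
        assert abundance_compatible(reads).passes is False

    def test_comparable_abundances_pass(self):
        reads = {"a": 100, "b": 50, "c": 30, "d": 2}
        res = abundance_compatible(reads)
        assert res.passes is True
        assert res.compatible_set == frozenset({"a", "b", "c", "d"})  # 100/2 = 50 < 100

    def test_ratio_boundary_strict(self):
        # 100/1 = 100 is NOT < 100
        res = abundance_compatible({"a": 100, "b": 1, "c": 50, "d": 60})
        assert "b" not in res.compatible_set
        assert res.passes is True  # {a, c, d}

    def test_literal_reading_without_dominant(self):
        params = FlockParams(require_dominant_in_set=False)
        reads = {"dom": 214236, "s1": 99, "s2": 98, "s3": 97}
        res = abundance_compatible(reads, params)
        assert res.passes is True
        assert res.compatible_set == frozenset({"s1", "s2", "s3"})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abundance_compatible({})

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            abundance_compatible({"a": 0, "b": 5})

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=9),
           st.booleans())
    def test_equals_brute_force_subsets(self, values, require_dominant):
        reads = {f"o{i}": v for i, v in enumerate(values)}
        params = FlockParams(require_dominant_in_set=require_dominant)
        got = abundance_compatible(reads, params)
        expect = brute_force_abundance(reads, params)
        assert len(got.compatible_set) == len(expect)
        assert got.passes == (len(expect) >= 3)
        # the returned set must itself be valid
        vals = [reads[k] for k in got.compatible_set]
        if vals:
            assert max(vals) / min(vals) < params.max_abundance_ratio
        if require_dominant and got.compatible_set:
            assert max(reads.values()) in {reads[k] for k in got.compatible_set}


def _clade(tip_ids, focal_ids, support=100.0):
    from otuflock.tree_ops import CandidateClade

    return CandidateClade(node=None, support=support, tip_ids=frozenset(tip_ids),
                          focal_tip_ids=frozenset(focal_ids),
                          n_focal=len(set(focal_ids)))


class TestClassifyClade:
    def test_tight_comparable_clade_is_flock(self):
        clade = _clade("abcd", "abcd")
        abund = abundance_compatible({"a": 35, "b": 35, "c": 35, "d": 35})
        call = classify_clade(clade, 0.024, abund)
        assert call.label == LABEL_FLOCK

    def test_divergent_clade(self):
        clade = _clade("abcd", "abcd")
        abund = abundance_compatible({"a": 35, "b": 40, "c": 30, "d": 20})
        assert classify_clade(clade, 0.05, abund).label == LABEL_DIVERGENT

    def test_divergence_boundary_strict(self):
        clade = _clade("abc", "abc")
        abund = abundance_compatible({"a": 10, "b": 10, "c": 10})
        assert classify_clade(clade, 0.03, abund).label == LABEL_DIVERGENT
        assert classify_clade(clade, 0.0299, abund).label == LABEL_FLOCK

    def test_dominant_cloud_is_intragenomic(self):
        clade = _clade(["dom", "s1", "s2", "s3"], ["dom", "s1", "s2", "s3"])
        abund = abundance_compatible({"dom": 214236, "s1": 99, "s2": 98, "s3": 97})
        call = classify_clade(clade, 0.02, abund)
        assert call.label == LABEL_INTRAGENOMIC


class TestDetectFlocks:
    def _fixture(self, seed=11):
        """Hand-built tree: one tight flock, one divergent trio, one cloud."""
        rng = np.random.default_rng(seed)
        anc_f = random_sequence(380, rng)
        flock = plant_flock(anc_f, 4, 0.02, rng)
        anc_d = random_sequence(380, rng)
        divergent = [evolve_sequence(anc_d, 20, rng) for _ in range(3)]  # ~10% apart
        anc_c = random_sequence(380, rng)
        sats = [evolve_sequence(anc_c, 8, rng) for _ in range(3)]
        recs = ([SequenceRecord(f"F{i}", s) for i, s in enumerate(flock)]
                + [SequenceRecord(f"D{i}", s) for i, s in enumerate(divergent)]
                + [SequenceRecord("CDOM", anc_c)]
                + [SequenceRecord(f"CS{i}", s) for i, s in enumerate(sats)])
        reads = {"F0": 30, "F1": 40, "F2": 25, "F3": 33,
                 "D0": 10, "D1": 12, "D2": 9,
                 "CDOM": 50000, "CS0": 5, "CS1": 9, "CS2": 2}
        tree = parse_newick(
            "(((F0,F1)80,(F2,F3)75)99,(D0,D1,D2)95,((CS0,CS1,CS2)70,CDOM)98);")
        return tree, recs, reads

    def test_labels_match_planted_structure(self):
        tree, recs, reads = self._fixture()
        calls = detect_flocks(tree, {r.id for r in recs}, DivergenceCache(recs), reads)
        by_label = {}
        for c in calls:
            by_label.setdefault(c.label, []).append(c)
        assert len(by_label[LABEL_FLOCK]) == 1
        assert by_label[LABEL_FLOCK][0].member_ids == frozenset({"F0", "F1", "F2", "F3"})
        assert len(by_label[LABEL_DIVERGENT]) == 1
        assert by_label[LABEL_DIVERGENT][0].member_ids == frozenset({"D0", "D1", "D2"})
        assert len(by_label[LABEL_INTRAGENOMIC]) == 1
        assert "CDOM" in by_label[LABEL_INTRAGENOMIC][0].member_ids
        # satellite-only subclade is suppressed, not promoted to flock
        rejected_sets = {c.member_ids for c in by_label.get(LABEL_REJECTED, [])}
        assert frozenset({"CS0", "CS1", "CS2"}) in rejected_sets

    def test_no_supported_clades_no_calls(self):
        tree = parse_newick("((A,B),(C,D,E));")
        recs = [SequenceRecord(x, "ACGT" * 95) for x in "ABCDE"]
        calls = detect_flocks(tree, set("ABCDE"), DivergenceCache(recs),
                              {x: 10 for x in "ABCDE"})
        assert calls == []

    def test_nested_flock_collapsed_to_maximal(self, rng):
        anc = random_sequence(380, rng)
        tips = plant_flock(anc, 5, 0.015, rng)
        recs = [SequenceRecord(f"F{i}", s) for i, s in enumerate(tips)]
        reads = {f"F{i}": 20 + i for i in range(5)}
        # inner 3-tip clade also qualifies; only the maximal clade is a flock
        tree = parse_newick("(((F0,F1,F2)88,F3,F4)92,(X,Y)99);")
        calls = detect_flocks(tree, {r.id for r in recs}, DivergenceCache(recs), reads)
        flocks = [c for c in calls if c.label == LABEL_FLOCK]
        assert len(flocks) == 1
        assert flocks[0].member_ids == frozenset(f"F{i}" for i in range(5))
        inner = [c for c in calls if c.clade.tip_ids == frozenset({"F0", "F1", "F2"})]
        assert inner[0].label == LABEL_REJECTED

    def test_every_candidate_gets_exactly_one_call(self):
        tree, recs, reads = self._fixture()
        focal = {r.id for r in recs}
        calls = detect_flocks(tree, focal, DivergenceCache(recs), reads)
        candidates = focal_clades(tree, focal, 60, 3)
        assert len(calls) == len(candidates)
        label_counts = sum(1 for c in calls if c.label in (
            LABEL_FLOCK, LABEL_DIVERGENT, LABEL_INTRAGENOMIC, LABEL_REJECTED))
        assert label_counts == len(candidates)

    def test_min_support_monotonicity(self):
        tree, recs, reads = self._fixture()
        focal = {r.id for r in recs}
        n_prev = None
        for ms in (50, 60, 70, 80, 90, 99):
            n = len(focal_clades(tree, focal, ms, 3))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_max_divergence_monotonicity(self):
        tree, recs, reads = self._fixture()
        focal = {r.id for r in recs}
        cache = DivergenceCache(recs)
        n_prev = None
        for md in (0.005, 0.01, 0.03, 0.08, 0.2):
            params = FlockParams(max_mean_divergence=md)
            n = sum(1 for c in detect_flocks(tree, focal, cache, reads, params)
                    if c.label == LABEL_FLOCK)
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n


class TestTypeEndemism:
    def _flock_call(self, members):
        clade = _clade(members, members)
        from otuflock.flock_detection import FlockCall

        return FlockCall(clade, LABEL_FLOCK, 0.02)

    def test_flock_membership_wins(self):
        call = self._flock_call(["a", "b", "c"])
        tree = parse_newick("((a,b,c)99,(R1,d)95);")
        hit = ReferenceHit("a", "R1", 0.85, 380, 1.0, True)
        res = type_endemism("a", [call], hit, tree, {"R1"})
        assert res.type == TYPE1

    def test_low_identity_is_type2(self):
        tree = parse_newick("((a,b)99,(R1,d)95);")
        hit = ReferenceHit("a", "R1", 0.85, 380, 1.0, True)
        assert type_endemism("a", [], hit, tree, {"R1"}).type == TYPE2

    def test_no_passing_hit_is_type2(self):
        tree = parse_newick("((a,b)99,(R1,d)95);")
        assert type_endemism("a", [], None, tree, {"R1"}).type == TYPE2

    def test_unplaced_is_type3(self):
        tree = parse_newick("(((a,b)50,R1)55,(c,d)95);")
        hit = ReferenceHit("a", "R1", 0.95, 380, 1.0, True)
        assert type_endemism("a", [], hit, tree, {"R1"}).type == TYPE3

    def test_placed_similar_is_none(self):
        tree = parse_newick("(((a,R1)95,b)50,(c,d)95);")
        hit = ReferenceHit("a", "R1", 0.99, 380, 1.0, True)
        assert type_endemism("a", [], hit, tree, {"R1"}).type == TYPE_NONE
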