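"""Direction-aware set algebra: worked examples, brute-force oracle
equivalence, and the cascade's containment/provenance properties."""

import pytest

import dmrcascade as dc
from dmrcascade.intervals import (
    intersect_directed,
    recurrent_consistent,
    subtract_unique,
)

from conftest import random_region_set, truth_regions


def region(chrom, start, end, delta):
    return dc.DMR(
        chrom=chrom,
        start=start,
        end=end,
        delta=delta,
        direction="hyper" if delta > 0 else "hypo",
    )


def rset(name, *regions):
    return dc.DirectedRegionSet(name, regions)


# -- independent all-pairs oracles -----------------------------------------


def brute_intersect(a, b, mode):
    out = []
    for ra in a:
        for rb in b:
            if ra.overlaps(rb):
                same = ra.direction == rb.direction
                if (mode == "same") == same:
                    out.append(ra)
                    break
    return out


def brute_recurrent(units):
    out = []
    for ra in units[0]:
        if all(
            any(ra.overlaps(rb) and ra.direction == rb.direction for rb in u)
            for u in units[1:]
        ):
            out.append(ra)
    return out


# -- classify_direction ----------------------------------------------------


@pytest.mark.parametrize(
    "delta,expected",
    [(+0.3, "hyper"), (-0.3, "hypo"), (0.0, "excluded")],
)
def test_classify_direction(delta, expected):
    assert dc.classify_direction(delta) == expected


def test_classify_direction_rejects_nan():
    with pytest.raises(ValueError):
        dc.classify_direction(float("nan"))


# -- worked examples -------------------------------------------------------


class TestIntersectDirected:
    def test_same_direction_overlap_kept_with_a_coordinates(self):
        a = rset("a", region("chr1", 100, 200, +0.3))
        b = rset("b", region("chr1", 150, 250, +0.3))
        out = intersect_directed(a, b, "same")
        assert [(r.start, r.end, r.direction) for r in out] == [(100, 200, "hyper")]

    def test_opposite_directions_separate_modes(self):
        a = rset("a", region("chr1", 100, 200, +0.3))
        b = rset("b", region("chr1", 150, 250, -0.3))
        assert len(intersect_directed(a, b, "same")) == 0
        out = intersect_directed(a, b, "opposite")
        assert [(r.start, r.end) for r in out] == [(100, 200)]

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        a = rset("a", region("chr1", 100, 200, +0.3))
        b = rset("b", region("chr1", 200, 300, +0.3))
        assert len(intersect_directed(a, b, "same")) == 0

    def test_multiple_b_partners_emit_a_region_once(self):
        a = rset("a", region("chr1", 100, 400, +0.3))
        b = rset(
            "b", region("chr1", 120, 140, +0.2), region("chr1", 300, 350, +0.2)
        )
        assert len(intersect_directed(a, b, "same")) == 1

    def test_matches_brute_force_on_random_sets(self, rng):
        a = random_region_set(rng, 1000, "a")
        b = random_region_set(rng, 1000, "b")
        for mode in ("same", "opposite"):
            got = list(intersect_directed(a, b, mode))
            assert got == sorted(brute_intersect(a, b, mode), key=dc.DMR.sort_key)

    def test_coordinates_depend_only_on_a(self, rng):
        # -wa asymmetry: swapping arguments changes the answer's support
        a = rset("a", region("chr1", 0, 1000, +0.3))
        b = rset("b", region("chr1", 500, 600, +0.3))
        assert [(r.start, r.end) for r in intersect_directed(a, b, "same")] == [
            (0, 1000)
        ]
        assert [(r.start, r.end) for r in intersect_directed(b, a, "same")] == [
            (500, 600)
        ]


class TestSubtractUnique:
    def test_empty_b_is_identity(self):
        a = rset("a", region("chr1", 0, 10, +0.3))
        assert list(subtract_unique(a, rset("b"))) == list(a)

    def test_same_direction_overlap_removed(self):
        a = rset("a", region("chr1", 0, 10, +0.3))
        b = rset("b", region("chr1", 5, 15, +0.3))
        assert len(subtract_unique(a, b)) == 0

    def test_opposite_direction_overlap_retained_but_flagged(self):
        a = rset("a", region("chr1", 0, 10, +0.3))
        b = rset("b", region("chr1", 5, 15, -0.3))
        out = subtract_unique(a, b)
        assert len(out) == 1
        assert len(out.conflicts) == 1

    def test_partitions_a_with_same_direction_intersection(self, rng):
        a = random_region_set(rng, 500, "a")
        b = random_region_set(rng, 500, "b")
        inter = set(intersect_directed(a, b, "same"))
        uniq = set(subtract_unique(a, b))
        assert inter | uniq == set(a)
        assert not inter & uniq


class TestRecurrentConsistent:
    def test_two_units_same_direction(self):
        u1 = rset("u1", region("chr1", 100, 300, +0.3))
        u2 = rset("u2", region("chr1", 150, 350, +0.25))
        out = recurrent_consistent([u1, u2])
        assert [(r.start, r.end, r.direction) for r in out] == [(100, 300, "hyper")]

    def test_direction_conflict_yields_empty_plus_conflict(self):
        u1 = rset("u1", region("chr1", 100, 300, +0.3))
        u2 = rset("u2", region("chr1", 150, 350, -0.25))
        out = recurrent_consistent([u1, u2])
        assert len(out) == 0
        assert len(out.conflicts) == 1

    def test_requires_two_units(self):
        with pytest.raises(ValueError):
            recurrent_consistent([rset("u1")])

    def test_matches_brute_force_three_units(self, rng):
        units = [random_region_set(rng, 300, f"u{i}") for i in range(3)]
        got = list(recurrent_consistent(units))
        assert got == sorted(brute_recurrent(units), key=dc.DMR.sort_key)


# -- operations never alter delta or direction -----------------------------


def test_operations_preserve_region_identity(rng):
    a = random_region_set(rng, 200, "a")
    b = random_region_set(rng, 200, "b")
    original = set(a.regions)
    for rs in (
        intersect_directed(a, b, "same"),
        intersect_directed(a, b, "opposite"),
        subtract_unique(a, b),
        recurrent_consistent([a, b]),
    ):
        assert set(rs.regions) <= original


# -- cascade ---------------------------------------------------------------


def _support(rs):
    return {(r.chrom, r.start, r.end) for r in rs}


class TestCascade:
    def test_containment_chain(self, demo_cohort):
        res = demo_cohort["cascade"]
        assert _support(res["DMR3"]) <= _support(res["DMR1"])
        assert _support(res["DMR6"]) <= _support(res["DMR4"])
        assert _support(res["DMR7"]) <= _support(res["DMR3"])

    def test_only_fully_qualified_regions_reach_dmr7(self, demo_cohort):
        cfg = demo_cohort["config"]
        res = demo_cohort["cascade"]
        truth = [
            dc.DMR(
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                delta=t.effect_size,
                direction=t.direction,
            )
            for t in dc.dmr7_truth(cfg)
        ]
        score = dc.score_recovery(res["DMR7"].regions, truth)
        assert score.recall >= 0.9
        assert score.precision >= 0.9

    def test_shared_treatment_regions_absent_from_dmr6(self, demo_cohort):
        cfg = demo_cohort["config"]
        res = demo_cohort["cascade"]
        shared = [
            dc.DMR(
                chrom=r.chrom, start=r.start, end=r.end,
                delta=r.effect_size, direction=r.direction,
            )
            for r in cfg.planted_dmrs
            if "t821_treatment" in r.contrast
            and "non_t821_treatment" in r.contrast
        ]
        assert shared
        t_hit, _ = dc.match_regions(res["DMR6"].regions, shared)
        assert not any(t_hit)

    def test_missing_cohort_role_is_configuration_error(self, demo_cohort):
        matrix = demo_cohort["matrix"]
        samples = matrix.samples[matrix.samples["group"] != "cellline"]
        with pytest.raises(ValueError, match="cell line"):
            dc.CohortRoles.from_sample_sheet(samples)

    def test_dmr7_hyper_subset_selected(self, demo_cohort):
        res = demo_cohort["cascade"]
        sel = res.dmr7_hyper
        assert all(r.direction == "hyper" for r in sel)
        assert len(sel) == res["DMR7"].n_hyper
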