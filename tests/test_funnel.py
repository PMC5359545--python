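from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_callset
from varfunnel.core import FunctionalClass, ImpactTier
from varfunnel.funnel import (
    FunnelError,
    FunnelReport,
    intersect_gene_list,
    recessive_trio_filter,
    run_funnel,
    select_by_impact,
    subtract_shared,
    trio_sites,
)
from varfunnel.io import GeneList

TRIO = ["sire", "dam", "kid"]
FC = FunctionalClass.MISSENSE


def _cs(rows, samples=TRIO):
    return build_callset(
        [
            ("chr1", pos, "A", "G", gene, FC, dosages)
            for pos, gene, dosages in rows
        ],
        samples,
    )


# ---------------------------------------------------------------------------
# trio_sites


def test_trio_sites_keeps_nonreference_variants():
    cs = _cs([(1, None, [0, 1, 1]), (2, None, [0, 0, 0]), (3, None, [0, 0, 2])])
    out = trio_sites(cs, ("sire", "dam", "kid"))
    assert [k[1] for k in out.keys] == [1, 3]
    assert out.samples == TRIO


def test_trio_sites_counts_match_bruteforce():
    rows = [
        (i, None, dosages)
        for i, dosages in enumerate(
            [
                [0, 0, 0], [1, 0, 0], [0, 0, 0], [0, 2, 0], [0, 0, 0],
                [1, 1, 2], [0, 0, 0], [0, 0, 1], [0, 0, 0], [0, 0, 0],
            ],
            start=1,
        )
    ]
    cs = _cs(rows)
    expected = sum(1 for _, _, d in rows if any(x and x >= 1 for x in d))
    assert expected == 4
    assert len(trio_sites(cs, tuple(TRIO))) == expected


def test_trio_sites_drops_other_samples_and_validates_ids():
    cs = _cs([(1, None, [0, 1, 1, 2])], samples=TRIO + ["extra"])
    out = trio_sites(cs, tuple(TRIO))
    assert out.samples == TRIO
    with pytest.raises(FunnelError):
        trio_sites(cs, ("sire", "dam", "ghost"))
    with pytest.raises(FunnelError):
        trio_sites(cs, ("sire", "sire", "kid"))


# ---------------------------------------------------------------------------
# subtract_shared


def test_subtract_shared_removes_sites_carried_elsewhere():
    target = _cs([(1, None, [1, 1, 2]), (2, None, [0, 1, 1]), (3, None, [1, 0, 0])])
    other = _cs(
        [(2, None, [2]), (4, None, [1])],
        samples=["outgroup"],
    )
    out = subtract_shared(target, other)
    assert [k[1] for k in out.keys] == [1, 3]


def test_subtract_shared_ignores_homref_sites_in_other():
    target = _cs([(1, None, [1, 1, 2])])
    other = _cs([(1, None, [0])], samples=["outgroup"])
    assert subtract_shared(target, other).keys == target.keys


def test_subtract_shared_identity_and_annihilation():
    target = _cs([(1, None, [1, 1, 2]), (2, None, [0, 1, 0])])
    empty = _cs([], samples=["o"])
    assert subtract_shared(target, empty) == target
    assert len(subtract_shared(target, target)) == 0


@settings(derandomize=True, max_examples=100)
@given(
    target_mask=st.lists(st.booleans(), min_size=1, max_size=8),
    other1=st.lists(st.booleans(), min_size=8, max_size=8),
    extra=st.lists(st.booleans(), min_size=8, max_size=8),
)
def test_subtract_shared_idempotent_and_antimonotone(target_mask, other1, extra):
    """Subtracting twice equals subtracting once, and growing the other
    cohort never enlarges the output."""
    positions = range(1, len(target_mask) + 1)
    target = _cs([(p, None, [1, 1, 2]) for p, keep in zip(positions, target_mask) if keep])
    small = _cs(
        [(p, None, [1]) for p, keep in zip(positions, other1) if keep],
        samples=["o"],
    )
    big = _cs(
        [
            (p, None, [1])
            for p, keep1, keep2 in zip(positions, other1, extra)
            if keep1 or keep2
        ],
        samples=["o"],
    )
    once = subtract_shared(target, small)
    assert subtract_shared(once, small) == once
    assert len(subtract_shared(target, big)) <= len(once)


# ---------------------------------------------------------------------------
# recessive_trio_filter


def recessive_oracle(sire, dam, kid):
    """Literal statement of the recessive trio pattern."""
    return kid == 2 and sire == 1 and dam == 1


def test_recessive_trio_filter_matches_bruteforce_over_all_combinations():
    combos = list(product([0, 1, 2], repeat=3))
    cs = _cs([(i, None, list(c)) for i, c in enumerate(combos, start=1)])
    out = recessive_trio_filter(cs, "sire", "dam", "kid")
    expected = [i for i, c in enumerate(combos, start=1) if recessive_oracle(*c)]
    assert [k[1] for k in out.keys] == expected
    assert len(out) == 1  # exactly one of the 27 combinations segregates


def test_recessive_trio_filter_discards_missing_calls():
    cs = _cs([(1, None, [None, 1, 2]), (2, None, [1, 1, None]), (3, None, [1, 1, 2])])
    out = recessive_trio_filter(cs, "sire", "dam", "kid")
    assert [k[1] for k in out.keys] == [3]


def test_recessive_trio_filter_requires_distinct_ids():
    cs = _cs([(1, None, [1, 1, 2])])
    with pytest.raises(FunnelError):
        recessive_trio_filter(cs, "sire", "sire", "kid")


# ---------------------------------------------------------------------------
# impact / gene list


def test_select_by_impact_orders_tiers():
    cs = build_callset(
        [
            ("c", 1, "A", "G", None, FunctionalClass.FRAMESHIFT, [1, 1, 2]),
            ("c", 2, "A", "G", None, FunctionalClass.MISSENSE, [1, 1, 2]),
            ("c", 3, "A", "G", None, FunctionalClass.MODIFIER, [1, 1, 2]),
        ],
        TRIO,
    )
    assert [k[1] for k in select_by_impact(cs, ImpactTier.HIGH).keys] == [1]
    assert [k[1] for k in select_by_impact(cs, ImpactTier.MODERATE).keys] == [1, 2]
    assert select_by_impact(cs, ImpactTier.MODIFIER) == cs


def test_intersect_gene_list():
    cs = _cs([(1, "IQCB1", [1, 1, 2]), (2, None, [1, 1, 2]), (3, "OTHER", [1, 1, 2])])
    out = intersect_gene_list(cs, GeneList(["iqcb1", "CDH23"]))
    assert [k[1] for k in out.keys] == [1]
    assert len(intersect_gene_list(cs, GeneList(["ABC"]))) == 0
    with pytest.raises(FunnelError, match="empty"):
        intersect_gene_list(cs, GeneList([]))


# ---------------------------------------------------------------------------
# run_funnel and reports


def test_run_funnel_on_empty_input_gives_zero_report():
    trio = _cs([])
    other = _cs([], samples=["o"])
    candidates, report = run_funnel(
        trio, other, other, "sire", "dam", "kid", GeneList(["IQCB1"])
    )
    assert len(candidates) == 0
    assert all(report.stage_total(s) == 0 for s in report.stages)


def test_run_funnel_recovers_seeded_causal_variant(default_bundle):
    b = default_bundle
    candidates, report = run_funnel(
        b.trio, b.outgroup, b.panel, *b.trio_ids, b.gene_list
    )
    assert b.truth.causal_key in candidates.keys
    assert report.is_monotone()


def test_funnel_monotonicity_holds_on_simulated_bundles():
    from varfunnel.simulate import SimulationParams, simulate_cohort

    for seed in (0, 1, 2):
        b = simulate_cohort(SimulationParams(seed=seed, n_background=500))
        _, report = run_funnel(b.trio, b.outgroup, b.panel, *b.trio_ids, b.gene_list)
        assert report.is_monotone()
        totals = [report.stage_total(s) for s in report.stages]
        assert totals == sorted(totals, reverse=True)


def test_funnel_report_validation_and_totals():
    counts = {
        "trio": {"frameshift": 5, "missense": 10},
        "species_specific": {"frameshift": 2, "missense": 4},
        "phenotype_segregation": {"frameshift": 1, "missense": 1},
        "gene_list": {"frameshift": 1},
    }
    report = FunnelReport(counts)
    assert report.tier_total("trio", ImpactTier.HIGH) == 5
    assert report.stage_total("trio") == 15
    bad = {**counts, "species_specific": {"frameshift": 9}}
    with pytest.raises(FunnelError):
        FunnelReport(bad)
    # external tallies may legitimately break monotonicity
    loaded = FunnelReport(bad, validate=False)
    assert not loaded.is_monotone()


def test_funnel_report_json_round_trip(tmp_path):
    counts = {"trio": {"missense": 3}, "species_specific": {"missense": 1}}
    report = FunnelReport(counts, stages=("trio", "species_specific"))
    path = tmp_path / "funnel.json"
    report.to_json(path)
    assert FunnelReport.from_json(path) == report
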