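import json
import math
from pathlib import Path

import numpy as np
import pytest

from varfunnel.concordance import VerdictStatus, concordance_screen
from varfunnel.funnel import run_funnel
from varfunnel.simulate import (
    SimulationError,
    SimulationParams,
    TruthRecord,
    simulate_cohort,
    truth_check,
)


def pipeline_survivors(bundle):
    candidates, report = run_funnel(
        bundle.trio,
        bundle.outgroup,
        bundle.panel,
        *bundle.trio_ids,
        bundle.gene_list,
    )
    extended = bundle.extended.subset(keys=candidates.keys)
    verdicts = concordance_screen(extended, bundle.phenotypes)
    survivors = [
        v.variant_key for v in verdicts if v.status is VerdictStatus.RETAINED
    ]
    return survivors, report, verdicts


# ---------------------------------------------------------------------------
# parameters


def test_invalid_parameters_are_rejected():
    with pytest.raises(SimulationError):
        SimulationParams(share_outgroup=1.5)
    with pytest.raises(SimulationError):
        SimulationParams(n_background=-1)
    with pytest.raises(SimulationError):
        SimulationParams(pedigree_template="clan")


def test_decoys_require_an_extended_cohort():
    with pytest.raises(SimulationError, match="decoys"):
        SimulationParams(pedigree_template="trio", n_decoys=1)


# ---------------------------------------------------------------------------
# bundle structure


def test_identical_params_and_seed_give_byte_identical_bundles(tmp_path):
    params = SimulationParams(seed=5, n_background=300)
    dir1, dir2 = tmp_path / "a", tmp_path / "b"
    simulate_cohort(params, out_dir=dir1)
    simulate_cohort(params, out_dir=dir2)
    files = sorted(p.name for p in dir1.iterdir())
    assert files == sorted(p.name for p in dir2.iterdir())
    for name in files:
        assert (dir1 / name).read_bytes() == (dir2 / name).read_bytes()


def test_different_seeds_differ():
    a = simulate_cohort(SimulationParams(seed=1, n_background=100))
    b = simulate_cohort(SimulationParams(seed=2, n_background=100))
    assert a.trio.keys != b.trio.keys


def test_causal_variant_construction(default_bundle):
    b = default_bundle
    causal = b.truth.causal_key
    sire, dam, affected = b.trio_ids
    assert b.trio.alt_count(causal, affected) == 2
    assert b.trio.alt_count(causal, sire) == 1
    assert b.trio.alt_count(causal, dam) == 1
    assert causal not in b.outgroup
    assert causal not in b.panel
    variant = b.trio.variant(causal)
    assert variant.gene == b.params.causal_gene
    assert variant.functional_class == b.params.causal_class
    assert len(variant.ref) - len(variant.alt) == 2  # 2 bp deletion


def test_decoys_pass_the_trio_pattern_but_fail_cohort_concordance(default_bundle):
    b = default_bundle
    sire, dam, affected = b.trio_ids
    for key in b.truth.decoy_keys:
        assert b.trio.alt_count(key, affected) == 2
        assert b.trio.alt_count(key, sire) == 1
        assert b.trio.alt_count(key, dam) == 1
    verdicts = concordance_screen(
        b.extended.subset(keys=list(b.truth.decoy_keys)), b.phenotypes
    )
    assert all(v.status is VerdictStatus.EXCLUDED_GENOTYPE for v in verdicts)


def test_truth_record_round_trips_through_json(default_bundle):
    data = json.loads(json.dumps(default_bundle.truth.to_dict()))
    back = TruthRecord.from_dict(data)
    assert back.causal_key == default_bundle.truth.causal_key
    assert back.decoy_keys == default_bundle.truth.decoy_keys
    assert back.categories == default_bundle.truth.categories


# ---------------------------------------------------------------------------
# recovery


def test_minimal_bundle_funnels_to_exactly_the_causal_variant():
    b = simulate_cohort(
        SimulationParams(seed=3, n_background=0, n_decoys=0, pedigree_template="trio")
    )
    candidates, _ = run_funnel(
        b.trio, b.outgroup, b.panel, *b.trio_ids, b.gene_list
    )
    assert candidates.keys == [b.truth.causal_key]


def test_recovery_on_default_bundle(default_bundle):
    survivors, report, _ = pipeline_survivors(default_bundle)
    result = truth_check(survivors, default_bundle.truth)
    assert result.success
    assert result.false_positives == ()
    assert report.is_monotone()


def test_truth_check_negative_controls(default_bundle):
    truth = default_bundle.truth
    empty = truth_check([], truth)
    assert not empty.causal_recovered and not empty.success
    noisy = truth_check([truth.causal_key, truth.decoy_keys[0]], truth)
    assert noisy.causal_recovered and not noisy.unique
    assert noisy.false_positives == (truth.decoy_keys[0],)
    with pytest.raises(SimulationError, match="bundle id"):
        truth_check([], truth, bundle_id="deadbeef")


def test_causal_shared_with_panel_is_removed_by_subtraction(default_bundle):
    """Negative control: if the causal site were present in the panel, the
    species-specific subtraction would eliminate it."""
    from varfunnel.core import CallSet
    from varfunnel.funnel import subtract_shared

    b = default_bundle
    causal_variant = b.trio.variant(b.truth.causal_key)
    forced_panel = CallSet(
        [causal_variant], ["P1"], np.array([[1]], dtype=np.int8)
    )
    out = subtract_shared(b.trio, forced_panel)
    assert b.truth.causal_key not in out
    survivors = [k for k in out.keys]
    assert truth_check(
        [k for k in survivors if k == b.truth.causal_key], b.truth
    ).causal_recovered is False


# ---------------------------------------------------------------------------
# statistical structure


def test_sharing_fractions_converge_to_parameters():
    """Law of large numbers: observed outgroup/panel sharing within three
    binomial standard deviations of the parameters at n = 10,000."""
    params = SimulationParams(seed=13, n_background=10_000)
    b = simulate_cohort(params)
    background = [
        k for k, cat in b.truth.categories.items() if cat in ("background", "shared")
    ]
    n = len(background)
    outgroup_keys = set(b.outgroup.keys)
    panel_keys = set(b.panel.keys)
    for observed, expected in [
        (sum(k in outgroup_keys for k in background) / n, params.share_outgroup),
        (sum(k in panel_keys for k in background) / n, params.share_panel),
    ]:
        sd = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * sd


def test_outgroup_subtraction_removes_expected_fraction():
    params = SimulationParams(seed=17, n_background=10_000)
    b = simulate_cohort(params)
    from varfunnel.funnel import subtract_shared

    background = [
        k for k, cat in b.truth.categories.items() if cat in ("background", "shared")
    ]
    target = b.trio.subset(keys=background)
    removed = 1 - len(subtract_shared(target, b.outgroup)) / len(target)
    sd = math.sqrt(0.41 * 0.59 / len(target))
    assert abs(removed - params.share_outgroup) <= 3 * sd


def test_no_genotype_phenotype_association_among_background_variants():
    """Permutation check: across the extended cohort, the mean affected vs
    unaffected dosage difference over background variants is not extreme
    (alpha = 0.01) relative to phenotype relabelings."""
    b = simulate_cohort(SimulationParams(seed=23, n_background=1_000, n_decoys=0))
    background = [
        k for k, cat in b.truth.categories.items() if cat in ("background", "shared")
    ]
    ext = b.extended.subset(keys=background)
    matrix = ext.matrix.astype(float)
    affected_mask = np.array(
        [b.phenotypes[s].value == "affected" for s in ext.samples]
    )

    def statistic(mask):
        return abs(
            matrix[:, mask].mean() - matrix[:, ~mask].mean()
        )

    observed = statistic(affected_mask)
    rng = np.random.default_rng(0)
    null = []
    for _ in range(500):
        null.append(statistic(rng.permutation(affected_mask)))
    p_value = (1 + sum(x >= observed for x in null)) / (len(null) + 1)
    assert p_value > 0.01
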