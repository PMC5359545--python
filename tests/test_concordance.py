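import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varfunnel.concordance import (
    OffenderReason,
    VerdictStatus,
    concordance_screen,
    lineage_exclusion,
    recessive_concordance,
)
from varfunnel.core import PhenotypeStatus
from varfunnel.pedigree import PedigreeError

KEY = ("GENEX", 1, "A", "G")

A, U, Q = (
    PhenotypeStatus.AFFECTED,
    PhenotypeStatus.UNAFFECTED,
    PhenotypeStatus.UNKNOWN,
)


def oracle(calls, phenotypes):
    """Literal per-sample application of the two exclusion predicates."""
    informative = any(d is not None for d in calls.values())
    if not informative:
        return VerdictStatus.UNINFORMATIVE
    for sample, dosage in calls.items():
        if dosage is None:
            continue
        pheno = phenotypes.get(sample, Q)
        if pheno is A and dosage != 2:
            return VerdictStatus.EXCLUDED_GENOTYPE
        if pheno is U and dosage == 2:
            return VerdictStatus.EXCLUDED_GENOTYPE
    return VerdictStatus.RETAINED


@settings(derandomize=True, max_examples=300)
@given(
    dosages=st.lists(
        st.sampled_from([None, 0, 1, 2]), min_size=1, max_size=8
    ),
    phenos=st.lists(st.sampled_from([A, U, Q]), min_size=8, max_size=8),
)
def test_recessive_concordance_matches_bruteforce_oracle(dosages, phenos):
    samples = [f"s{i}" for i in range(len(dosages))]
    calls = dict(zip(samples, dosages))
    phenotypes = dict(zip(samples, phenos))
    verdict = recessive_concordance(KEY, calls, phenotypes)
    assert verdict.status is oracle(calls, phenotypes)


@settings(derandomize=True, max_examples=200)
@given(
    dosages=st.lists(st.sampled_from([None, 0, 1, 2]), min_size=1, max_size=6),
    phenos=st.lists(st.sampled_from([A, U, Q]), min_size=6, max_size=6),
)
def test_adding_a_missing_call_never_changes_the_verdict(dosages, phenos):
    samples = [f"s{i}" for i in range(len(dosages))]
    calls = dict(zip(samples, dosages))
    phenotypes = dict(zip(samples, phenos))
    before = recessive_concordance(KEY, calls, phenotypes)
    calls["extra"] = None
    phenotypes["extra"] = A
    after = recessive_concordance(KEY, calls, phenotypes)
    assert before.status is after.status
    assert before.offending_samples == after.offending_samples


def test_affected_heterozygote_excludes_with_named_offender():
    calls = {"235": 1, "247": 2, "205": 1}
    phenotypes = {"235": A, "247": A, "205": U}
    verdict = recessive_concordance(KEY, calls, phenotypes)
    assert verdict.status is VerdictStatus.EXCLUDED_GENOTYPE
    assert verdict.offending_samples == (
        ("235", OffenderReason.AFFECTED_NOT_HOM_ALT),
    )


def test_unaffected_homozygote_excludes():
    verdict = recessive_concordance(
        KEY, {"a": 2, "b": 2}, {"a": A, "b": U}
    )
    assert verdict.status is VerdictStatus.EXCLUDED_GENOTYPE
    assert ("b", OffenderReason.UNAFFECTED_HOM_ALT) in verdict.offending_samples


def test_all_missing_calls_are_uninformative():
    verdict = recessive_concordance(KEY, {"a": None, "b": None}, {"a": A, "b": U})
    assert verdict.status is VerdictStatus.UNINFORMATIVE


def test_sample_without_phenotype_is_ignored_with_warning():
    with pytest.warns(UserWarning, match="no phenotype"):
        verdict = recessive_concordance(KEY, {"a": 2, "ghost": 1}, {"a": A})
    assert verdict.status is VerdictStatus.RETAINED


def test_discordant_homozygous_affecteds_excluded_under_both_orientations(
    missense_panel,
):
    """Two affected cats homozygous for opposite alleles cannot both be
    homozygous-alternate under any orientation."""
    callset, phenotypes = missense_panel
    cngb1 = ("CNGB1", 1, "C", "T")
    calls = callset.row(cngb1)
    flipped = {s: (None if d is None else 2 - d) for s, d in calls.items()}
    assert recessive_concordance(cngb1, calls, phenotypes).status is (
        VerdictStatus.EXCLUDED_GENOTYPE
    )
    assert recessive_concordance(cngb1, flipped, phenotypes).status is (
        VerdictStatus.EXCLUDED_GENOTYPE
    )


def test_screen_reproduces_published_exclusions(missense_panel):
    """Five of the seven missense candidates fail the cohort concordance
    test; the deletion and two missense candidates survive."""
    callset, phenotypes = missense_panel
    verdicts = concordance_screen(callset, phenotypes)
    by_label = {v.variant_key[0]: v for v in verdicts}
    excluded = {l for l, v in by_label.items() if v.status is VerdictStatus.EXCLUDED_GENOTYPE}
    retained = {l for l, v in by_label.items() if v.status is VerdictStatus.RETAINED}
    assert excluded == {"CHD3", "CNGB1", "DTHD1_942", "RBP3", "USH1C"}
    assert retained == {"IQCB1", "CDH23", "DTHD1_144"}


def test_screen_on_single_retained_column(missense_panel):
    callset, phenotypes = missense_panel
    only = callset.subset(keys=[("IQCB1", 1, "WT", "DELCT")])
    verdicts = concordance_screen(only, phenotypes)
    assert len(verdicts) == 1
    assert verdicts[0].status is VerdictStatus.RETAINED


def test_screen_on_empty_callset(missense_panel):
    callset, phenotypes = missense_panel
    assert concordance_screen(callset.subset(keys=[]), phenotypes) == []


# ---------------------------------------------------------------------------
# lineage exclusion


def test_unrelated_carrier_triggers_lineage_exclusion(studbook):
    verdict = lineage_exclusion(
        ("DTHD1_144", 1, "A", "C"), ["223"], studbook, ["235", "247"]
    )
    assert verdict.status is VerdictStatus.EXCLUDED_LINEAGE
    assert verdict.offending_samples == (
        ("223", OffenderReason.UNRELATED_CARRIER),
    )


def test_connected_carrier_is_retained(studbook):
    verdict = lineage_exclusion(KEY, ["205"], studbook, ["235", "247"])
    assert verdict.status is VerdictStatus.RETAINED


def test_empty_carrier_set_is_vacuously_retained(studbook):
    verdict = lineage_exclusion(KEY, [], studbook, ["235", "247"])
    assert verdict.status is VerdictStatus.RETAINED


def test_unknown_carrier_is_an_error(studbook):
    with pytest.raises(PedigreeError, match="999"):
        lineage_exclusion(KEY, ["999"], studbook, ["235"])


def test_full_candidate_narrowing_to_single_gene(missense_panel, studbook):
    """Cohort concordance plus lineage exclusion leave the deletion as the
    sole candidate."""
    callset, phenotypes = missense_panel
    verdicts = concordance_screen(callset, phenotypes)
    survivors = []
    for verdict in verdicts:
        if verdict.status is not VerdictStatus.RETAINED:
            continue
        carriers = [c for c in callset.carriers(verdict.variant_key) if c in studbook]
        refined = lineage_exclusion(
            verdict.variant_key, carriers, studbook, ["235", "247"]
        )
        if refined.status is VerdictStatus.RETAINED:
            survivors.append(verdict.variant_key[0])
    assert survivors == ["IQCB1"]
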