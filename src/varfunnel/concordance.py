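"""Candidate exclusion over an extended genotyped cohort.

Two complementary screens narrow trio-derived candidates once more
individuals are genotyped:

* **Recessive genotype-phenotype concordance** — a candidate is excluded
  when any affected individual is not homozygous alternate, or any
  unaffected individual is homozygous alternate.  Missing calls never
  ground an exclusion; a variant with no non-missing calls is
  uninformative.  Because assay tables often print raw base pairs without
  declaring which allele is the variant, the screen can optionally test
  both allele orientations and exclude only when the genotypes are
  discordant under each consistent choice.

* **Lineage exclusion** — a candidate is deprioritized when its carriers
  occur in pedigree components disconnected from the affected lineage:
  alleles confined to lines that never interbred with the affected one
  cannot explain the disease.  Disconnection in the undirected
  parent-child graph is the testable version of "never interbred".

Genotype exclusion is evaluated before lineage exclusion; verdicts are
advisory and composable.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import CallSet, PhenotypeStatus, VariantKey
from .pedigree import Pedigree, PedigreeError, connected_component

__all__ = [
    "VerdictStatus",
    "OffenderReason",
    "ConcordanceVerdict",
    "recessive_concordance",
    "concordance_screen",
    "lineage_exclusion",
]


class VerdictStatus(str, enum.Enum):
    RETAINED = "retained"
    EXCLUDED_GENOTYPE = "excluded_genotype"
    EXCLUDED_LINEAGE = "excluded_lineage"
    UNINFORMATIVE = "uninformative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class OffenderReason(str, enum.Enum):
    AFFECTED_NOT_HOM_ALT = "affected_not_hom_alt"
    UNAFFECTED_HOM_ALT = "unaffected_hom_alt"
    UNRELATED_CARRIER = "unrelated_carrier"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ConcordanceVerdict:
    """Retained/excluded status of one candidate variant, with the samples
    that ground an exclusion."""

    variant_key: VariantKey
    status: VerdictStatus
    offending_samples: tuple[tuple[str, OffenderReason], ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.status is VerdictStatus.RETAINED and self.offending_samples:
            raise ValueError("a retained verdict cannot carry offending samples")
        if (
            self.status
            in (VerdictStatus.EXCLUDED_GENOTYPE, VerdictStatus.EXCLUDED_LINEAGE)
            and not self.offending_samples
        ):
            raise ValueError("an exclusion verdict needs offending samples")

    def to_dict(self) -> dict:
        return {
            "variant": list(self.variant_key),
            "status": self.status.value,
            "offending_samples": [
                {"sample": s, "reason": r.value} for s, r in self.offending_samples
            ],
            "note": self.note,
        }


def _verdict_for_calls(
    variant_key: VariantKey,
    calls: Mapping[str, int | None],
    phenotypes: Mapping[str, PhenotypeStatus],
    note: str = "",
) -> ConcordanceVerdict:
    offenders: list[tuple[str, OffenderReason]] = []
    informative = False
    for sample, dosage in calls.items():
        if dosage is None:
            continue
        informative = True
        status = phenotypes.get(sample)
        if status is None:
            warnings.warn(
                f"sample {sample!r} has a genotype but no phenotype; treated as unknown",
                stacklevel=3,
            )
            continue
        if status is PhenotypeStatus.AFFECTED and dosage != 2:
            offenders.append((sample, OffenderReason.AFFECTED_NOT_HOM_ALT))
        elif status is PhenotypeStatus.UNAFFECTED and dosage == 2:
            offenders.append((sample, OffenderReason.UNAFFECTED_HOM_ALT))
    if not informative:
        return ConcordanceVerdict(
            variant_key, VerdictStatus.UNINFORMATIVE, note="all calls missing"
        )
    if offenders:
        return ConcordanceVerdict(
            variant_key,
            VerdictStatus.EXCLUDED_GENOTYPE,
            tuple(offenders),
            note=note,
        )
    return ConcordanceVerdict(variant_key, VerdictStatus.RETAINED, note=note)


def recessive_concordance(
    variant_key: VariantKey,
    calls: Mapping[str, int | None],
    phenotypes: Mapping[str, PhenotypeStatus],
) -> ConcordanceVerdict:
    """Test one variant's genotypes against phenotypes under a recessive
    model.

    Excluded iff some affected sample has a non-missing dosage != 2 or some
    unaffected sample has a non-missing dosage == 2.  Samples with unknown
    phenotype are ignored; missing calls are never grounds for exclusion;
    all calls missing yields an uninformative verdict.
    """
    return _verdict_for_calls(variant_key, calls, phenotypes)


def _flip(calls: Mapping[str, int | None]) -> dict[str, int | None]:
    """Swap allele orientation: dosage 0 <-> 2, 1 and missing unchanged."""
    return {s: (None if d is None else 2 - d) for s, d in calls.items()}


def concordance_screen(
    callset: CallSet,
    phenotypes: Mapping[str, PhenotypeStatus],
    *,
    check_both_orientations: bool = True,
) -> list[ConcordanceVerdict]:
    """One recessive-concordance verdict per variant, in input order.

    With ``check_both_orientations`` (the default) a variant excluded under
    the declared allele orientation is re-tested with ref and alt swapped
    and retained if the flipped orientation is concordant; exclusion then
    means discordance under every consistent orientation.  This matches
    screening tables that print raw base pairs without declaring the
    alternate allele.
    """
    verdicts: list[ConcordanceVerdict] = []
    for key in callset.keys:
        calls = callset.row(key)
        verdict = recessive_concordance(key, calls, phenotypes)
        if (
            check_both_orientations
            and verdict.status is VerdictStatus.EXCLUDED_GENOTYPE
        ):
            flipped = _verdict_for_calls(
                key,
                _flip(calls),
                phenotypes,
                note="concordant only with ref/alt orientation swapped",
            )
            if flipped.status is VerdictStatus.RETAINED:
                verdict = flipped
        verdicts.append(verdict)
    return verdicts


def lineage_exclusion(
    variant_key: VariantKey,
    carrier_ids: Iterable[str],
    pedigree: Pedigree,
    affected_ids: Iterable[str],
) -> ConcordanceVerdict:
    """Exclude a candidate whose carriers include individuals with no
    undirected parent-child path to the affected lineage.

    Vacuously retained when the carrier set is empty.  Raises
    :class:`PedigreeError` if a carrier is not in the pedigree.
    """
    carriers = list(carrier_ids)
    for cid in carriers:
        if cid not in pedigree:
            raise PedigreeError(f"carrier {cid!r} not in pedigree")
    component = connected_component(pedigree, affected_ids)
    offenders = tuple(
        (cid, OffenderReason.UNRELATED_CARRIER)
        for cid in carriers
        if cid not in component
    )
    if offenders:
        return ConcordanceVerdict(
            variant_key,
            VerdictStatus.EXCLUDED_LINEAGE,
            offenders,
            note="carrier(s) disconnected from the affected lineage",
        )
    return ConcordanceVerdict(variant_key, VerdictStatus.RETAINED)
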