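"""The five-stage variant prioritization funnel.

Given whole-genome calls for a trio (two unaffected parents, one affected
offspring), an outgroup individual from a sister species, and a panel of
individuals from a closely related species, the cascade retains variants
that are

1. non-reference somewhere in the trio,
2. not shared with the outgroup,
3. not shared with the related-species panel,
4. segregating with the disease under an autosomal recessive model
   (affected homozygous alternate, both parents heterozygous), and
5. located in genes from a curated disease-gene list.

Stage attrition is reported per functional class in a
:class:`FunnelReport` whose columns follow the cascade order; counts are
non-increasing along the stages for every class.  Impact-tier selection is
applied to the final candidate set, while the report keeps all classes so
that lower-impact survivors (e.g. missense candidates) remain visible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core import (
    CallSet,
    FunctionalClass,
    ImpactTier,
    VarFunnelError,
    VariantKey,
    impact_tier_of,
)
from .io import GeneList

__all__ = [
    "FunnelError",
    "STAGES",
    "FunnelReport",
    "trio_sites",
    "subtract_shared",
    "recessive_trio_filter",
    "select_by_impact",
    "intersect_gene_list",
    "run_funnel",
]


class FunnelError(VarFunnelError):
    pass


#: Cascade stage names, in order.
STAGES: tuple[str, ...] = (
    "trio",
    "species_specific",
    "phenotype_segregation",
    "gene_list",
)


class FunnelReport:
    """Per-stage, per-functional-class variant counts.

    Reports computed by :func:`run_funnel` are monotone: for every class the
    counts never increase along the stage order.  Reports loaded from
    external tallies (``validate=False``) may break monotonicity, e.g. when
    the upstream annotator counted transcript effects rather than variants.
    """

    def __init__(
        self,
        counts: Mapping[str, Mapping[FunctionalClass | str, int]],
        stages: Iterable[str] = STAGES,
        *,
        validate: bool = True,
    ) -> None:
        self.stages: tuple[str, ...] = tuple(stages)
        self._counts: dict[str, dict[FunctionalClass, int]] = {}
        for stage in self.stages:
            stage_counts = counts.get(stage, {})
            row: dict[FunctionalClass, int] = {fc: 0 for fc in FunctionalClass}
            for fc, n in stage_counts.items():
                fc = FunctionalClass(fc)
                n = int(n)
                if n < 0:
                    raise FunnelError(f"negative count for {stage}/{fc.value}")
                row[fc] = n
            self._counts[stage] = row
        if validate and not self.is_monotone():
            raise FunnelError(
                "funnel counts increase along the stage order for some class"
            )

    @classmethod
    def from_callsets(cls, staged: Mapping[str, CallSet]) -> "FunnelReport":
        stages = tuple(staged)
        counts = {
            stage: _class_counts(cs) for stage, cs in staged.items()
        }
        return cls(counts, stages=stages)

    def count(self, stage: str, functional_class: FunctionalClass | str) -> int:
        return self._counts[stage][FunctionalClass(functional_class)]

    def stage_total(self, stage: str) -> int:
        return sum(self._counts[stage].values())

    def tier_total(self, stage: str, tier: ImpactTier) -> int:
        return sum(
            n
            for fc, n in self._counts[stage].items()
            if impact_tier_of(fc) is tier
        )

    def is_monotone(self) -> bool:
        for fc in FunctionalClass:
            series = [self._counts[s][fc] for s in self.stages]
            if any(b > a for a, b in zip(series, series[1:])):
                return False
        return True

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "counts": {
                stage: {fc.value: n for fc, n in row.items()}
                for stage, row in self._counts.items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: Mapping, *, validate: bool = False) -> "FunnelReport":
        return cls(data["counts"], stages=data["stages"], validate=validate)

    @classmethod
    def from_json(cls, path: str | Path, *, validate: bool = False) -> "FunnelReport":
        return cls.from_dict(json.loads(Path(path).read_text()), validate=validate)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FunnelReport):
            return NotImplemented
        return self.stages == other.stages and self._counts == other._counts


def _class_counts(callset: CallSet) -> dict[FunctionalClass, int]:
    counts = {fc: 0 for fc in FunctionalClass}
    for v in callset.variants:
        counts[v.functional_class] += 1
    return counts


# ---------------------------------------------------------------------------
# stages


def _require_samples(callset: CallSet, ids: Iterable[str]) -> None:
    missing = [s for s in ids if s not in callset.samples]
    if missing:
        raise FunnelError(f"samples not in call set: {missing}")


def trio_sites(callset: CallSet, trio_ids: tuple[str, str, str]) -> CallSet:
    """Stage 1: keep variants that are non-reference in the trio.

    Retains variants where at least one trio member carries >= 1 alternate
    allele; the output is restricted to the trio's samples.
    """
    if len(set(trio_ids)) != 3:
        raise FunnelError(f"trio ids must be three distinct samples, got {trio_ids}")
    _require_samples(callset, trio_ids)
    trio_cs = callset.subset(samples=list(trio_ids))
    mask = (trio_cs.matrix >= 1).any(axis=1)
    keys = [k for k, keep in zip(trio_cs.keys, mask) if keep]
    return trio_cs.subset(keys=keys)


def subtract_shared(target: CallSet, other: CallSet) -> CallSet:
    """Stages 2-3: remove variants shared with another cohort.

    A variant is *shared* when its canonical key appears in ``other`` with
    at least one sample carrying an alternate allele there.  Sharing is
    key-level, not genotype-level: cross-species subtraction compares site
    lists, as genotype-identity between species is ill-defined.  Idempotent,
    and anti-monotone in ``other``.
    """
    shared: set[VariantKey] = set()
    if len(other) and other.samples:
        mask = (other.matrix >= 1).any(axis=1)
        shared = {k for k, hit in zip(other.keys, mask) if hit}
    keys = [k for k in target.keys if k not in shared]
    return target.subset(keys=keys)


def recessive_trio_filter(
    callset: CallSet, sire: str, dam: str, affected: str
) -> CallSet:
    """Stage 4: autosomal recessive segregation within the trio.

    Retains exactly the variants where the affected offspring is homozygous
    alternate and both parents are heterozygous.  A missing call in any of
    the three disqualifies the variant (conservative; no imputation).
    """
    if len({sire, dam, affected}) != 3:
        raise FunnelError("sire, dam and affected ids must be distinct")
    _require_samples(callset, (sire, dam, affected))
    keys = []
    for key in callset.keys:
        if (
            callset.alt_count(key, affected) == 2
            and callset.alt_count(key, sire) == 1
            and callset.alt_count(key, dam) == 1
        ):
            keys.append(key)
    return callset.subset(keys=keys)


def select_by_impact(callset: CallSet, minimum_tier: ImpactTier) -> CallSet:
    """Keep variants whose impact tier is at least ``minimum_tier``
    (HIGH > MODERATE > LOW > MODIFIER)."""
    keys = [v.key for v in callset.variants if v.impact_tier >= minimum_tier]
    return callset.subset(keys=keys)


def intersect_gene_list(callset: CallSet, genes: GeneList) -> CallSet:
    """Stage 5: keep variants in genes from the disease-gene list.

    Variants without a gene symbol are never retained.  An empty gene list
    is an error: it would silently empty the funnel.
    """
    if len(genes) == 0:
        raise FunnelError("gene list is empty; refusing to empty the funnel")
    keys = [v.key for v in callset.variants if v.gene in genes]
    return callset.subset(keys=keys)


def run_funnel(
    trio_callset: CallSet,
    outgroup_callset: CallSet,
    panel_callset: CallSet,
    sire: str,
    dam: str,
    affected: str,
    genes: GeneList,
    *,
    minimum_tier: ImpactTier = ImpactTier.MODERATE,
) -> tuple[CallSet, FunnelReport]:
    """Compose the five stages in cascade order and tally attrition.

    Returns the final candidate CallSet (survivors of all stages plus the
    impact-tier cut) and a report counting every stage per functional class.
    The report's gene-list column counts all classes that reach it, before
    the tier cut, so moderate-impact candidates stay visible.
    """
    staged: dict[str, CallSet] = {}
    stage1 = trio_sites(trio_callset, (sire, dam, affected))
    staged["trio"] = stage1
    stage2 = subtract_shared(subtract_shared(stage1, outgroup_callset), panel_callset)
    staged["species_specific"] = stage2
    stage3 = recessive_trio_filter(stage2, sire, dam, affected)
    staged["phenotype_segregation"] = stage3
    stage4 = intersect_gene_list(stage3, genes)
    staged["gene_list"] = stage4
    report = FunnelReport.from_callsets(staged)
    candidates = select_by_impact(stage4, minimum_tier)
    return candidates, report
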