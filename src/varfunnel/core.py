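"""Core domain model shared by every pipeline stage.

The unit of analysis is a biallelic variant call observed across a set of
samples.  Variants carry a SnpEff-style *functional class* (what the
alternate allele does to the annotated transcript) from which a four-level
*impact tier* is derived: HIGH (protein-truncating or splice-destroying),
MODERATE (protein-altering), LOW (silent/near-silent coding effects) and
MODIFIER (non-coding or intergenic).  Genotypes are unphased alternate-allele
dosages in {0, 1, 2}; a missing call is distinct from homozygous reference.

Multiallelic records do not exist at this layer: readers decompose them into
one :class:`Variant` per alternate allele before any filtering.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Final, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VarFunnelError",
    "FunctionalClass",
    "ImpactTier",
    "impact_tier_of",
    "Variant",
    "variant_key",
    "VariantKey",
    "MISSING",
    "GenotypeCall",
    "GenotypeCounts",
    "CallSet",
    "PhenotypeStatus",
    "Phenotype",
]


class VarFunnelError(Exception):
    """Base class for all errors raised by this package."""


class FunctionalClass(str, enum.Enum):
    """SnpEff-style annotation class of a variant's most severe effect."""

    STOP_GAIN = "stop_gain"
    START_STOP_LOSS = "start_stop_loss"
    SPLICE_DONOR_ACCEPTOR = "splice_donor_acceptor"
    EXON_DELETION = "exon_deletion"
    FRAMESHIFT = "frameshift"
    RARE_AMINO_ACID = "rare_amino_acid"
    CODON_ALTERATION = "codon_alteration"
    MISSENSE = "missense"
    SPLICE_BRANCH = "splice_branch"
    UTR_DELETION = "utr_deletion"
    LOW_OTHER = "low_other"
    MODIFIER = "modifier"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@enum.unique
class ImpactTier(enum.IntEnum):
    """Severity tier; ordered so that comparisons mean 'at least as severe'."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Total map from functional class to impact tier.  The HIGH tier collects
#: protein-truncating and splice-site-destroying classes, MODERATE the
#: protein-altering ones; ``low_other`` and ``modifier`` are aggregate
#: buckets for everything milder.
_IMPACT_OF: Final[dict[FunctionalClass, ImpactTier]] = {
    FunctionalClass.STOP_GAIN: ImpactTier.HIGH,
    FunctionalClass.START_STOP_LOSS: ImpactTier.HIGH,
    FunctionalClass.SPLICE_DONOR_ACCEPTOR: ImpactTier.HIGH,
    FunctionalClass.EXON_DELETION: ImpactTier.HIGH,
    FunctionalClass.FRAMESHIFT: ImpactTier.HIGH,
    FunctionalClass.RARE_AMINO_ACID: ImpactTier.HIGH,
    FunctionalClass.CODON_ALTERATION: ImpactTier.MODERATE,
    FunctionalClass.MISSENSE: ImpactTier.MODERATE,
    FunctionalClass.SPLICE_BRANCH: ImpactTier.MODERATE,
    FunctionalClass.UTR_DELETION: ImpactTier.MODERATE,
    FunctionalClass.LOW_OTHER: ImpactTier.LOW,
    FunctionalClass.MODIFIER: ImpactTier.MODIFIER,
}


def impact_tier_of(functional_class: FunctionalClass | str) -> ImpactTier:
    """Return the impact tier of a functional class.

    Parameters
    ----------
    functional_class
        One of the twelve taxonomy labels, as enum member or string.

    Raises
    ------
    ValueError
        If the label is unknown; the message lists all valid labels.
    """
    try:
        fc = FunctionalClass(functional_class)
    except ValueError:
        valid = ", ".join(c.value for c in FunctionalClass)
        raise ValueError(
            f"unknown functional class {functional_class!r}; valid labels: {valid}"
        ) from None
    return _IMPACT_OF[fc]


# Alleles are uppercase tokens.  VCF-derived variants use A/C/G/T sequences;
# assay-style genotype tables may use symbolic alleles such as WT or DELCT.
_ALLELE_RE = re.compile(r"^[A-Z]+$")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Variant:
    """A single biallelic site on a named sequence, 1-based coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    functional_class: FunctionalClass = FunctionalClass.LOW_OTHER

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(
                    f"{name} allele {allele!r} is not a non-empty uppercase token"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")
        # accept plain strings for convenience
        object.__setattr__(
            self, "functional_class", FunctionalClass(self.functional_class)
        )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def impact_tier(self) -> ImpactTier:
        return _IMPACT_OF[self.functional_class]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def variant_key(variant: Variant) -> VariantKey:
    """Canonical identity key of a variant: ``(chrom, pos, ref, alt)``.

    Equal variants read from different files yield equal keys; an indel and
    a SNV at the same position are distinct because their allele strings
    differ.
    """
    return variant.key


#: Sentinel for a missing genotype call (distinct from homozygous reference).
MISSING: Final = None


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's unphased alternate-allele dosage at one variant."""

    sample_id: str
    alt_count: int | None  # 0, 1, 2, or None (missing)

    def __post_init__(self) -> None:
        if self.alt_count is not None and self.alt_count not in (0, 1, 2):
            raise ValueError(
                f"alt_count must be 0, 1, 2 or missing; got {self.alt_count!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.alt_count is None


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-variant genotype tally across a cohort."""

    hom_ref: int
    het: int
    hom_alt: int
    missing: int

    @property
    def called(self) -> int:
        return self.hom_ref + self.het + self.hom_alt


class PhenotypeStatus(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Phenotype:
    sample_id: str
    status: PhenotypeStatus


# Internal matrix encoding of a missing call.
_MISSING_CODE: Final[int] = -1


class CallSet:
    """An ordered variants x samples genotype matrix.

    Every (variant, sample) pair holds a call; missing calls are allowed and
    are distinct from homozygous reference.  Variant keys and sample ids are
    unique.  Internally genotypes live in an ``int8`` matrix with -1 coding a
    missing call, which keeps whole-cohort filters cheap.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        samples: Sequence[str],
        matrix: np.ndarray | None = None,
    ) -> None:
        self._variants: list[Variant] = list(variants)
        self._samples: list[str] = list(samples)
        keys = [v.key for v in self._variants]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate variant keys in call set: {sorted(dupes)}")
        if len(set(self._samples)) != len(self._samples):
            raise ValueError("duplicate sample ids in call set")
        if matrix is None:
            matrix = np.full(
                (len(self._variants), len(self._samples)), _MISSING_CODE, dtype=np.int8
            )
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.shape != (len(self._variants), len(self._samples)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(self._variants)} variants x {len(self._samples)} samples"
            )
        bad = ~np.isin(matrix, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype matrix entries must be -1 (missing), 0, 1 or 2")
        self._matrix = matrix
        self._key_index: dict[VariantKey, int] = {k: i for i, k in enumerate(keys)}
        self._sample_index: dict[str, int] = {s: i for i, s in enumerate(self._samples)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        variants: Sequence[Variant],
        samples: Sequence[str],
        calls: Mapping[tuple[VariantKey, str], int | None],
    ) -> "CallSet":
        """Build from a total mapping ``(variant key, sample id) -> dosage``."""
        cs = cls(variants, samples)
        for (key, sample), dosage in calls.items():
            cs.set_alt_count(key, sample, dosage)
        return cs

    # -- basic accessors ---------------------------------------------------

    @property
    def variants(self) -> list[Variant]:
        return list(self._variants)

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    @property
    def keys(self) -> list[VariantKey]:
        return [v.key for v in self._variants]

    @property
    def matrix(self) -> np.ndarray:
        """Genotype matrix view (variants x samples; -1 = missing)."""
        return self._matrix

    def __len__(self) -> int:
        return len(self._variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._key_index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return (
            self._variants == other._variants
            and self._samples == other._samples
            and np.array_equal(self._matrix, other._matrix)
        )

    def variant(self, key: VariantKey) -> Variant:
        return self._variants[self._key_index[key]]

    def alt_count(self, key: VariantKey, sample: str) -> int | None:
        code = int(self._matrix[self._key_index[key], self._sample_index[sample]])
        return None if code == _MISSING_CODE else code

    def call(self, key: VariantKey, sample: str) -> GenotypeCall:
        return GenotypeCall(sample, self.alt_count(key, sample))

    def set_alt_count(self, key: VariantKey, sample: str, dosage: int | None) -> None:
        if dosage is not None and dosage not in (0, 1, 2):
            raise ValueError(f"alt_count must be 0, 1, 2 or missing; got {dosage!r}")
        code = _MISSING_CODE if dosage is None else dosage
        self._matrix[self._key_index[key], self._sample_index[sample]] = code

    def row(self, key: VariantKey) -> dict[str, int | None]:
        """All calls at one variant as ``sample id -> dosage``."""
        codes = self._matrix[self._key_index[key]]
        return {
            s: (None if int(c) == _MISSING_CODE else int(c))
            for s, c in zip(self._samples, codes)
        }

    # -- cohort summaries --------------------------------------------------

    def count_genotypes(self, key: VariantKey) -> GenotypeCounts:
        codes = self._matrix[self._key_index[key]]
        return GenotypeCounts(
            hom_ref=int((codes == 0).sum()),
            het=int((codes == 1).sum()),
            hom_alt=int((codes == 2).sum()),
            missing=int((codes == _MISSING_CODE).sum()),
        )

    def carriers(self, key: VariantKey) -> list[str]:
        """Samples carrying at least one alternate allele at ``key``."""
        codes = self._matrix[self._key_index[key]]
        return [s for s, c in zip(self._samples, codes) if c >= 1]

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        keys: Iterable[VariantKey] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "CallSet":
        """Restrict to the given variant keys and/or samples (order preserved
        as given by the caller)."""
        if keys is None:
            vidx = list(range(len(self._variants)))
        else:
            vidx = []
            for k in keys:
                if k not in self._key_index:
                    raise KeyError(f"variant key {k!r} not in call set")
                vidx.append(self._key_index[k])
        if samples is None:
            sidx = list(range(len(self._samples)))
        else:
            sidx = []
            for s in samples:
                if s not in self._sample_index:
                    raise KeyError(f"sample {s!r} not in call set")
                sidx.append(self._sample_index[s])
        sub = self._matrix[np.ix_(vidx, sidx)] if vidx and sidx else np.full(
            (len(vidx), len(sidx)), _MISSING_CODE, dtype=np.int8
        )
        return CallSet(
            [self._variants[i] for i in vidx],
            [self._samples[i] for i in sidx],
            sub.copy(),
        )
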