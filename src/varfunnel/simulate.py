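"""Synthetic cohort generator with the statistical structure the cascade
assumes, so every stage is exercisable without external data.

A simulated bundle contains

* a trio call set (two carrier parents, one affected offspring) over a
  background of neutral variants plus one seeded causal variant and a
  configurable number of decoys,
* a single-sample outgroup call set sharing a fixed fraction of the
  background (emulating a sister-species genome that removes shared wild
  felid variation),
* a multi-sample related-species panel sharing another fraction,
* a pedigree (plain trio, or an extended studbook-like topology with an
  unrelated wild-type lineage and carrier-cross litters),
* extended-cohort genotypes for every variant, drawn independently of
  phenotype for background variants, and
* a machine-readable truth record labelling every variant.

The causal variant is homozygous alternate in affected individuals,
heterozygous in both parents, absent from outgroup and panel, and annotated
with the requested gene and functional class.  Decoys satisfy the trio
recessive pattern and sit in listed genes, so they survive the funnel, but
their extended-cohort genotypes are seeded discordant (an additional
affected that is not homozygous alternate, or an unaffected homozygote) so
the concordance screen removes them.

Background genotypes follow a per-variant allele frequency drawn uniformly
from [0.05, 0.5] under Hardy-Weinberg proportions; positions are drawn
collision-free on one linear mock chromosome.  Identical parameters and
seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    CallSet,
    FunctionalClass,
    PhenotypeStatus,
    VarFunnelError,
    Variant,
    VariantKey,
)
from .io import GeneList, write_genotype_table, write_ped, write_vcf
from .pedigree import Individual, Pedigree, Sex

__all__ = [
    "SimulationError",
    "SimulationParams",
    "TruthRecord",
    "CohortBundle",
    "RecoveryReport",
    "simulate_cohort",
    "truth_check",
]


class SimulationError(VarFunnelError):
    pass


#: Mock chromosome name and length used for all simulated variants.
_CHROM = "chrS"
_CHROM_LEN = 100_000_000

#: Functional-class frequencies for background variants, shaped like a
#: genome-wide call set: overwhelmingly modifier, some low and missense,
#: a sliver of high-impact classes.
_CLASS_WEIGHTS: dict[FunctionalClass, float] = {
    FunctionalClass.MODIFIER: 0.9900,
    FunctionalClass.LOW_OTHER: 0.0060,
    FunctionalClass.MISSENSE: 0.0030,
    FunctionalClass.CODON_ALTERATION: 0.00030,
    FunctionalClass.FRAMESHIFT: 0.00030,
    FunctionalClass.SPLICE_DONOR_ACCEPTOR: 0.00020,
    FunctionalClass.STOP_GAIN: 0.00010,
    FunctionalClass.START_STOP_LOSS: 0.00010,
}

#: Gene symbols treated as disease-listed inside simulated bundles.
LISTED_GENES: tuple[str, ...] = (
    "IQCB1",
    "CDH23",
    "CNGB1",
    "RBP3",
    "USH1C",
    "DTHD1",
    "CHD3",
    "RASGRF1",
    "CCDC114",
    "CEP290",
    "CRX",
    "AIPL1",
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort.

    ``share_outgroup`` defaults to 0.41: the fraction of variants a single
    sister-species genome removes from a cross-species call set.
    ``share_panel`` is the additional fraction shared with the
    related-species panel.
    """

    seed: int = 0
    n_background: int = 2000
    share_outgroup: float = 0.41
    share_panel: float = 0.80
    n_panel_samples: int = 51
    n_decoys: int = 3
    pedigree_template: str = "extended"  # "trio" | "extended"
    causal_gene: str = "IQCB1"
    causal_class: FunctionalClass = FunctionalClass.FRAMESHIFT

    def __post_init__(self) -> None:
        for name in ("share_outgroup", "share_panel"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {frac}")
        for name in ("n_background", "n_panel_samples", "n_decoys"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.pedigree_template not in ("trio", "extended"):
            raise SimulationError(
                f"pedigree_template must be 'trio' or 'extended', "
                f"got {self.pedigree_template!r}"
            )
        if self.n_decoys > 0 and self.pedigree_template == "trio":
            raise SimulationError(
                "decoys need an extended cohort to reveal discordance; "
                "use pedigree_template='extended' or n_decoys=0"
            )
        object.__setattr__(self, "causal_class", FunctionalClass(self.causal_class))

    def bundle_id(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a simulated bundle."""

    bundle_id: str
    causal_key: VariantKey
    decoy_keys: tuple[VariantKey, ...]
    categories: dict[VariantKey, str]  # background | shared | causal | decoy

    def to_dict(self) -> dict:
        return {
            "bundle_id": self.bundle_id,
            "causal": list(self.causal_key),
            "decoys": [list(k) for k in self.decoy_keys],
            "categories": {
                "|".join(map(str, k)): cat for k, cat in self.categories.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TruthRecord":
        def parse_key(raw: Sequence | str) -> VariantKey:
            parts = raw.split("|") if isinstance(raw, str) else list(raw)
            return (str(parts[0]), int(parts[1]), str(parts[2]), str(parts[3]))

        return cls(
            bundle_id=data["bundle_id"],
            causal_key=parse_key(data["causal"]),
            decoy_keys=tuple(parse_key(k) for k in data["decoys"]),
            categories={
                parse_key(k): cat for k, cat in data["categories"].items()
            },
        )


@dataclass
class CohortBundle:
    """In-memory result of one simulation run."""

    params: SimulationParams
    trio: CallSet
    outgroup: CallSet
    panel: CallSet
    pedigree: Pedigree
    phenotypes: dict[str, PhenotypeStatus]
    extended: CallSet  # extended genotyped cohort, all variants
    truth: TruthRecord
    trio_ids: tuple[str, str, str]  # (sire, dam, affected)

    @property
    def gene_list(self) -> GeneList:
        return GeneList(LISTED_GENES)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as text files; deterministic given params+seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trio_vcf": out / "trio.vcf",
            "outgroup_vcf": out / "outgroup.vcf",
            "panel_vcf": out / "panel.vcf",
            "ped": out / "pedigree.ped",
            "genotypes": out / "genotypes.tsv",
            "genes": out / "genes.txt",
            "truth": out / "truth.json",
        }
        write_vcf(self.trio, paths["trio_vcf"])
        write_vcf(self.outgroup, paths["outgroup_vcf"])
        write_vcf(self.panel, paths["panel_vcf"])
        write_ped(self.pedigree, paths["ped"])
        write_genotype_table(self.extended, self.phenotypes, paths["genotypes"])
        paths["genes"].write_text("\n".join(LISTED_GENES) + "\n")
        paths["truth"].write_text(
            json.dumps(self.truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        return paths


# ---------------------------------------------------------------------------
# pedigree templates

_TRIO_IDS = ("SIRE1", "DAM1", "AFF1")


def _trio_pedigree() -> tuple[Pedigree, dict[str, PhenotypeStatus], list[str]]:
    inds = [
        Individual("SIRE1", sex=Sex.MALE, phenotype=PhenotypeStatus.UNAFFECTED),
        Individual("DAM1", sex=Sex.FEMALE, phenotype=PhenotypeStatus.UNAFFECTED),
        Individual(
            "AFF1",
            sire="SIRE1",
            dam="DAM1",
            sex=Sex.FEMALE,
            phenotype=PhenotypeStatus.AFFECTED,
        ),
    ]
    phenos = {i.id: i.phenotype for i in inds}
    return Pedigree(inds), phenos, [i.id for i in inds]


def _extended_pedigree() -> tuple[Pedigree, dict[str, PhenotypeStatus], list[str]]:
    """Studbook-like topology: a carrier founder pair with two affected and
    three unaffected offspring, an unrelated wild-type lineage, and a cross
    of a carrier into a third line producing ungenotyped litters."""
    U, A = PhenotypeStatus.UNAFFECTED, PhenotypeStatus.AFFECTED
    inds = [
        Individual("SIRE1", sex=Sex.MALE, phenotype=U),
        Individual("DAM1", sex=Sex.FEMALE, phenotype=U),
        Individual("AFF1", "SIRE1", "DAM1", Sex.FEMALE, A),
        Individual("AFF2", "SIRE1", "DAM1", Sex.MALE, A),
        Individual("SIB1", "SIRE1", "DAM1", Sex.FEMALE, U),
        Individual("SIB2", "SIRE1", "DAM1", Sex.MALE, U),
        Individual("SIB3", "SIRE1", "DAM1", Sex.MALE, U),
        # unrelated wild-type lineage
        Individual("OUT1", sex=Sex.MALE, phenotype=U),
        Individual("OUT2", sex=Sex.FEMALE, phenotype=U),
        Individual("UNREL1", "OUT1", "OUT2", Sex.FEMALE, U),
        Individual("UNREL2", "OUT1", "OUT2", Sex.MALE, U),
        # carrier crossed into a third line; litter not yet genotyped
        Individual("OUT3", sex=Sex.MALE, phenotype=U),
        Individual("KID1", "OUT3", "SIB1", Sex.UNKNOWN, PhenotypeStatus.UNKNOWN),
        Individual("KID2", "OUT3", "SIB1", Sex.UNKNOWN, PhenotypeStatus.UNKNOWN),
    ]
    phenos = {i.id: i.phenotype for i in inds}
    genotyped = [
        "SIRE1", "DAM1", "AFF1", "AFF2", "SIB1", "SIB2", "SIB3",
        "OUT1", "OUT2", "UNREL1", "UNREL2", "OUT3",
    ]
    return Pedigree(inds), phenos, genotyped


#: Causal-variant dosages in the extended cohort (Mendelian by construction).
_EXTENDED_CAUSAL_DOSAGE = {
    "SIRE1": 1, "DAM1": 1, "AFF1": 2, "AFF2": 2, "SIB1": 1, "SIB2": 0,
    "SIB3": 1, "OUT1": 0, "OUT2": 0, "UNREL1": 0, "UNREL2": 0, "OUT3": 0,
}


# ---------------------------------------------------------------------------
# simulation


def _hwe_dosages(rng: np.random.Generator, freq: float, n: int) -> np.ndarray:
    return rng.binomial(2, freq, size=n).astype(np.int8)


def simulate_cohort(
    params: SimulationParams, out_dir: str | Path | None = None
) -> CohortBundle:
    """Generate a complete cohort bundle; optionally write it to disk.

    Background variants get independent outgroup/panel membership at the
    configured fractions and Hardy-Weinberg trio and extended-cohort
    genotypes independent of phenotype.  See the module docstring for the
    causal-variant and decoy construction.
    """
    rng = np.random.default_rng(params.seed)
    if params.pedigree_template == "trio":
        pedigree, phenotypes, genotyped = _trio_pedigree()
    else:
        pedigree, phenotypes, genotyped = _extended_pedigree()
    sire, dam, affected = _TRIO_IDS

    n_special = 1 + params.n_decoys
    n_total = params.n_background + n_special
    positions = np.sort(
        rng.choice(_CHROM_LEN, size=n_total, replace=False) + 1
    )
    causal_slot, *decoy_slots = rng.choice(
        n_total, size=n_special, replace=False
    ).tolist()

    bases = np.array(list("ACGT"))
    classes = list(_CLASS_WEIGHTS)
    class_p = np.array(list(_CLASS_WEIGHTS.values()))
    class_p = class_p / class_p.sum()

    variants: list[Variant] = []
    categories: dict[VariantKey, str] = {}
    trio_rows: list[np.ndarray] = []
    ext_rows: list[np.ndarray] = []
    outgroup_member: list[bool] = []
    panel_member: list[bool] = []
    freqs: list[float] = []

    decoy_keys: list[VariantKey] = []
    causal_key: VariantKey | None = None
    n_ext = len(genotyped)

    for slot in range(n_total):
        pos = int(positions[slot])
        if slot == causal_slot:
            # 2 bp deletion in the causal gene
            anchor = str(rng.choice(bases))
            variant = Variant(
                _CHROM,
                pos,
                ref=anchor + "CT",
                alt=anchor,
                gene=params.causal_gene,
                functional_class=params.causal_class,
            )
            causal_key = variant.key
            categories[variant.key] = "causal"
            trio_rows.append(np.array([1, 1, 2], dtype=np.int8))
            ext_rows.append(
                np.array(
                    [_EXTENDED_CAUSAL_DOSAGE.get(s, 0) for s in genotyped],
                    dtype=np.int8,
                )
                if params.pedigree_template == "extended"
                else np.array([1, 1, 2], dtype=np.int8)
            )
            outgroup_member.append(False)
            panel_member.append(False)
            freqs.append(0.0)
            variants.append(variant)
            continue
        if slot in decoy_slots:
            gene = str(
                rng.choice([g for g in LISTED_GENES if g != params.causal_gene])
            )
            ref, alt = rng.choice(bases, size=2, replace=False)
            variant = Variant(
                _CHROM,
                pos,
                ref=str(ref),
                alt=str(alt),
                gene=gene,
                functional_class=FunctionalClass.MISSENSE,
            )
            decoy_keys.append(variant.key)
            categories[variant.key] = "decoy"
            trio_rows.append(np.array([1, 1, 2], dtype=np.int8))
            dosages = {s: int(d) for s, d in zip(
                genotyped, _hwe_dosages(rng, 0.25, n_ext)
            )}
            dosages.update({sire: 1, dam: 1, affected: 2})
            # seed a discordance the trio cannot see
            if rng.random() < 0.5:
                dosages["AFF2"] = int(rng.choice([0, 1]))
            else:
                victim = str(rng.choice(["UNREL1", "UNREL2", "SIB2"]))
                dosages[victim] = 2
                dosages["AFF2"] = 2
            ext_rows.append(
                np.array([dosages[s] for s in genotyped], dtype=np.int8)
            )
            outgroup_member.append(False)
            panel_member.append(False)
            freqs.append(0.0)
            variants.append(variant)
            continue

        # background variant
        ref, alt = rng.choice(bases, size=2, replace=False)
        fclass = classes[int(rng.choice(len(classes), p=class_p))]
        gene = f"GENE{int(rng.integers(1, 5000)):04d}"
        variant = Variant(
            _CHROM, pos, ref=str(ref), alt=str(alt), gene=gene,
            functional_class=fclass,
        )
        freq = float(rng.uniform(0.05, 0.5))
        trio_rows.append(_hwe_dosages(rng, freq, 3))
        ext_rows.append(_hwe_dosages(rng, freq, n_ext))
        in_outgroup = bool(rng.random() < params.share_outgroup)
        in_panel = bool(rng.random() < params.share_panel)
        outgroup_member.append(in_outgroup)
        panel_member.append(in_panel)
        categories[variant.key] = "shared" if (in_outgroup or in_panel) else "background"
        freqs.append(freq)
        variants.append(variant)

    assert causal_key is not None

    trio_cs = CallSet(variants, [sire, dam, affected], np.vstack(trio_rows))

    # outgroup: one sample, carrying the shared variants
    og_keys = [v for v, m in zip(variants, outgroup_member) if m]
    og_matrix = np.full((len(og_keys), 1), 0, dtype=np.int8)
    for i in range(len(og_keys)):
        og_matrix[i, 0] = int(rng.choice([1, 2]))
    outgroup_cs = CallSet(og_keys, ["OUTGROUP1"], og_matrix)

    # panel: HWE genotypes conditioned on at least one carrier
    panel_samples = [f"PANEL{i + 1:02d}" for i in range(params.n_panel_samples)]
    panel_variants = [v for v, m in zip(variants, panel_member) if m]
    panel_freqs = [f for f, m in zip(freqs, panel_member) if m]
    panel_matrix = np.zeros((len(panel_variants), len(panel_samples)), dtype=np.int8)
    for i, freq in enumerate(panel_freqs):
        row = _hwe_dosages(rng, freq, len(panel_samples))
        while len(panel_samples) and not (row >= 1).any():
            row = _hwe_dosages(rng, freq, len(panel_samples))
        panel_matrix[i] = row
    panel_cs = CallSet(panel_variants, panel_samples, panel_matrix)

    extended_cs = CallSet(variants, genotyped, np.vstack(ext_rows))

    truth = TruthRecord(
        bundle_id=params.bundle_id(),
        causal_key=causal_key,
        decoy_keys=tuple(decoy_keys),
        categories=categories,
    )
    bundle = CohortBundle(
        params=params,
        trio=trio_cs,
        outgroup=outgroup_cs,
        panel=panel_cs,
        pedigree=pedigree,
        phenotypes=phenotypes,
        extended=extended_cs,
        truth=truth,
        trio_ids=(sire, dam, affected),
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# recovery check


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of comparing pipeline survivors against the truth record."""

    causal_recovered: bool
    unique: bool
    false_positives: tuple[VariantKey, ...]

    @property
    def success(self) -> bool:
        return self.causal_recovered and self.unique

    def to_dict(self) -> dict:
        return {
            "causal_recovered": self.causal_recovered,
            "unique": self.unique,
            "false_positives": [list(k) for k in self.false_positives],
        }


def truth_check(
    survivor_keys: Iterable[VariantKey],
    truth: TruthRecord,
    *,
    bundle_id: str | None = None,
) -> RecoveryReport:
    """Report whether the causal variant is the unique survivor of
    funnel + concordance, and list false positives.

    ``bundle_id``, when given, must match the truth record's (guards
    against comparing output and truth from different bundles).
    """
    if bundle_id is not None and bundle_id != truth.bundle_id:
        raise SimulationError(
            f"bundle id mismatch: output {bundle_id!r} vs truth {truth.bundle_id!r}"
        )
    survivors = list(survivor_keys)
    recovered = truth.causal_key in survivors
    false_positives = tuple(k for k in survivors if k != truth.causal_key)
    return RecoveryReport(
        causal_recovered=recovered,
        unique=recovered and not false_positives,
        false_positives=false_positives,
    )
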