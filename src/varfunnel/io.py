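"""Readers and writers for the formats the pipeline touches.

* VCF v4.2 (uncompressed text; GT FORMAT required, SnpEff-style ``ANN``
  INFO optional) via cyvcf2, with multiallelic records decomposed into one
  biallelic variant per alternate allele.
* PLINK-style 6-column PED pedigrees.
* TSV genotype tables in the shape of a published cohort screening table:
  one row per sample, one column per assayed variant holding allele-pair
  strings, with the column header declaring each variant's reference and
  alternate allele (``LABEL:ref>alt``) because raw base-pair tables leave
  allele orientation implicit.
* Plain-text gene lists, one symbol per line, compared case-insensitively.

All readers reject malformed input with an error naming the offending
line or cell rather than silently coercing it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from cyvcf2 import VCF

from .core import (
    CallSet,
    FunctionalClass,
    PhenotypeStatus,
    VarFunnelError,
    Variant,
    impact_tier_of,
)
from .pedigree import Individual, Pedigree, PedigreeError, Sex

__all__ = [
    "IoError",
    "VcfParseError",
    "GenotypeTableError",
    "GeneList",
    "PedRecord",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_gene_list",
    "read_genotype_table",
    "write_genotype_table",
]


class IoError(VarFunnelError):
    pass


class VcfParseError(IoError):
    pass


class GenotypeTableError(IoError):
    pass


# ---------------------------------------------------------------------------
# gene lists


class GeneList:
    """A case-normalized set of gene symbols used as an intersection filter."""

    def __init__(self, symbols: Iterable[str]) -> None:
        self._symbols = frozenset(
            s.strip().upper() for s in symbols if s and s.strip()
        )

    def __contains__(self, symbol: str | None) -> bool:
        return symbol is not None and symbol.strip().upper() in self._symbols

    def __len__(self) -> int:
        return len(self._symbols)

    def __iter__(self):
        return iter(sorted(self._symbols))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneList):
            return NotImplemented
        return self._symbols == other._symbols


def read_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list, one symbol per line; ``#`` comments and
    blank lines are ignored; duplicates collapse."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return GeneList(symbols)


# ---------------------------------------------------------------------------
# VCF

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def _parse_ann(ann: str | None) -> tuple[str | None, FunctionalClass]:
    """Parse a ``gene|class[,gene|class...]`` annotation token list.

    When several annotations describe one variant (multiple isoforms), the
    highest-impact one wins.
    """
    if not ann:
        return None, FunctionalClass.LOW_OTHER
    best: tuple[str | None, FunctionalClass] | None = None
    for token in str(ann).split(","):
        parts = token.split("|")
        if len(parts) != 2:
            raise VcfParseError(
                f"malformed ANN token {token!r}; expected 'gene|functional_class'"
            )
        gene = parts[0].strip() or None
        if gene in (".",):
            gene = None
        try:
            fclass = FunctionalClass(parts[1].strip())
        except ValueError as exc:
            raise VcfParseError(f"malformed ANN token {token!r}: {exc}") from None
        if best is None or impact_tier_of(fclass) > impact_tier_of(best[1]):
            best = (gene, fclass)
    assert best is not None
    return best


def read_vcf(path: str | Path) -> CallSet:
    """Read a VCF v4.2 file into a :class:`CallSet`.

    Each record contributes one variant per alternate allele; a sample's
    dosage for that variant is the number of copies of that allele in its
    GT.  A GT containing any missing allele (``./.`` or half-calls) becomes
    a missing call.  Phase is discarded.  Functional class and gene come
    from an ``ANN=gene|class`` INFO field when present, else ``low_other``.

    Raises
    ------
    VcfParseError
        If the file lacks a GT FORMAT declaration or a record cannot be
        parsed (the error names the record).
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfParseError(f"{path}: VCF has no GT FORMAT field declared")
    samples = list(vcf.samples)
    header_lines = vcf.raw_header.count("\n")

    variants: list[Variant] = []
    rows: list[list[int | None]] = []
    record_no = 0
    iterator = iter(vcf)
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(
                f"{path}: malformed record at line ~{header_lines + record_no + 1}: {exc}"
            ) from exc
        record_no += 1
        line_no = header_lines + record_no
        if not _VALID_SEQ.match(rec.REF or ""):
            raise VcfParseError(
                f"{path}: line {line_no}: REF allele {rec.REF!r} is not A/C/G/T"
            )
        if rec.genotypes is None:
            raise VcfParseError(
                f"{path}: line {line_no}: record has no GT genotypes"
            )
        gene, fclass = _parse_ann(rec.INFO.get("ANN"))
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        for alt_index, alt in enumerate(rec.ALT, start=1):
            if not _VALID_SEQ.match(alt or ""):
                raise VcfParseError(
                    f"{path}: line {line_no}: ALT allele {alt!r} is not A/C/G/T"
                )
            variant = Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene=gene,
                functional_class=fclass,
            )
            row: list[int | None] = []
            for gt in gts:
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    row.append(None)
                else:
                    row.append(sum(1 for a in alleles if a == alt_index))
            variants.append(variant)
            rows.append(row)

    cs = CallSet(variants, samples)
    for i, key in enumerate(cs.keys):
        for sample, dosage in zip(samples, rows[i]):
            cs.set_alt_count(key, sample, dosage)
    return cs


_GT_STRINGS = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet as a biallelic VCF v4.2 text file.

    Round-trips losslessly through :func:`read_vcf` for variant keys,
    genotype dosages, genes and functional classes.
    """
    path = Path(path)
    contigs = []
    for v in callset.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation: gene|class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(callset.samples)
        if callset.samples
        else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    )
    for v in callset.variants:
        ann = f"ANN={v.gene or '.'}|{v.functional_class.value}"
        row = callset.row(v.key)
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", ann]
        if callset.samples:
            fields.append("GT")
            fields += [_GT_STRINGS[row[s]] for s in callset.samples]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED


@dataclass(frozen=True)
class PedRecord:
    """One row of a PLINK-style 6-column PED file."""

    family_id: str
    individual_id: str
    sire_id: str  # "0" = founder
    dam_id: str
    sex: str
    phenotype_code: str


_PHENO_CODES = {
    "2": PhenotypeStatus.AFFECTED,
    "1": PhenotypeStatus.UNAFFECTED,
    "0": PhenotypeStatus.UNKNOWN,
    "-9": PhenotypeStatus.UNKNOWN,
}
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}


def read_ped(
    path: str | Path,
    *,
    allow_implicit_founders: bool = False,
    known_genotypes: Mapping[str, int] | None = None,
) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file into a Pedigree.

    Phenotype codes follow PLINK convention: 2 affected, 1 unaffected,
    0 or -9 unknown.  A parent id of ``0`` marks a founder.  Parents that
    appear only in parent columns are an error unless
    ``allow_implicit_founders`` creates them as unknown-phenotype founders.
    ``#`` comment lines are ignored.
    """
    path = Path(path)
    records: list[PedRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise PedigreeError(
                f"{path}: line {lineno}: expected 6 columns, found {len(fields)}"
            )
        rec = PedRecord(*fields)
        if rec.individual_id in (r.individual_id for r in records):
            raise PedigreeError(
                f"{path}: line {lineno}: duplicate individual id {rec.individual_id!r}"
            )
        if rec.sex not in _SEX_CODES:
            raise PedigreeError(
                f"{path}: line {lineno}: invalid sex code {rec.sex!r} (use 0/1/2)"
            )
        if rec.phenotype_code not in _PHENO_CODES:
            raise PedigreeError(
                f"{path}: line {lineno}: invalid phenotype code "
                f"{rec.phenotype_code!r} (use 2/1/0/-9)"
            )
        records.append(rec)

    ids = {r.individual_id for r in records}
    individuals: list[Individual] = []
    implicit: list[str] = []
    for r in records:
        for parent in (r.sire_id, r.dam_id):
            if parent != "0" and parent not in ids:
                if not allow_implicit_founders:
                    raise PedigreeError(
                        f"{path}: parent {parent!r} of {r.individual_id!r} has no "
                        "row of its own (pass allow_implicit_founders to accept)"
                    )
                if parent not in implicit:
                    implicit.append(parent)
    for parent in implicit:
        individuals.append(Individual(id=parent))
    for r in records:
        individuals.append(
            Individual(
                id=r.individual_id,
                sire=None if r.sire_id == "0" else r.sire_id,
                dam=None if r.dam_id == "0" else r.dam_id,
                sex=_SEX_CODES[r.sex],
                phenotype=_PHENO_CODES[r.phenotype_code],
            )
        )
    return Pedigree(individuals, known_genotypes=known_genotypes)


def write_ped(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    """Write a Pedigree as a PLINK-style 6-column PED file."""
    pheno_out = {
        PhenotypeStatus.AFFECTED: "2",
        PhenotypeStatus.UNAFFECTED: "1",
        PhenotypeStatus.UNKNOWN: "0",
    }
    lines = []
    for ind in pedigree.individuals:
        lines.append(
            "\t".join(
                [
                    family_id,
                    ind.id,
                    ind.sire or "0",
                    ind.dam or "0",
                    str(int(ind.sex)),
                    pheno_out[ind.phenotype],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotype tables (screening-assay shape)

_COLUMN_RE = re.compile(r"^(?P<label>[^:]+):(?P<ref>[A-Za-z]+)>(?P<alt>[A-Za-z]+)$")

_PHENO_WORDS = {
    "affected": PhenotypeStatus.AFFECTED,
    "pra-affected": PhenotypeStatus.AFFECTED,
    "normal": PhenotypeStatus.UNAFFECTED,
    "unaffected": PhenotypeStatus.UNAFFECTED,
    "unknown": PhenotypeStatus.UNKNOWN,
    "?": PhenotypeStatus.UNKNOWN,
}

#: Missing-data marker used in screening tables for failed assays.
MISSING_CELL = "/"


def _split_allele_pair(cell: str, ref: str, alt: str) -> tuple[str, str] | None:
    """Split an allele-pair cell like ``AG``, ``wt/delCT`` or ``/``; return
    None for a missing call."""
    cell = cell.strip().replace("*", "")
    if cell == MISSING_CELL or cell == "":
        return None
    if "/" in cell:
        left, right = cell.split("/", 1)
    elif cell.upper() in (ref, alt):
        # a single symbol names a homozygote (studbook shorthand, e.g. "wt")
        left = right = cell
    elif len(cell) == 2:
        left, right = cell[0], cell[1]
    else:
        raise GenotypeTableError(f"cannot split allele pair {cell!r}")
    return left.upper(), right.upper()


def read_genotype_table(
    path: str | Path,
) -> tuple[CallSet, dict[str, PhenotypeStatus]]:
    """Read a TSV screening table into a CallSet plus phenotype labels.

    Expected columns: ``sample``, optionally ``sex``, ``phenotype``, then
    one column per variant named ``LABEL:ref>alt`` (the declaration fixes
    which allele counts as alternate).  Cells hold allele pairs ("AG",
    "wt/delCT"); ``/`` marks a failed assay (missing call).  Table variants
    carry the label as both sequence name and gene symbol, at position 1.

    Raises
    ------
    GenotypeTableError
        For undeclared variant columns or alleles outside {ref, alt}; the
        error names the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(MISSING_CELL)
    df.columns = [c.strip() for c in df.columns]
    if "sample" not in df.columns or "phenotype" not in df.columns:
        raise GenotypeTableError(
            f"{path}: genotype table needs 'sample' and 'phenotype' columns"
        )
    meta_cols = {"sample", "sex", "phenotype"}
    variant_cols = [c for c in df.columns if c not in meta_cols]
    if not variant_cols:
        raise GenotypeTableError(f"{path}: no variant columns found")

    variants: list[Variant] = []
    col_alleles: dict[str, tuple[str, str]] = {}
    for col in variant_cols:
        m = _COLUMN_RE.match(col)
        if not m:
            raise GenotypeTableError(
                f"{path}: column {col!r} does not declare alleles as 'LABEL:ref>alt'"
            )
        label = m.group("label").strip()
        ref = m.group("ref").upper()
        alt = m.group("alt").upper()
        variants.append(
            Variant(
                chrom=label,
                pos=1,
                ref=ref,
                alt=alt,
                gene=label,
                functional_class=FunctionalClass.MISSENSE,
            )
        )
        col_alleles[col] = (ref, alt)

    samples = [str(s).strip() for s in df["sample"]]
    if len(set(samples)) != len(samples):
        raise GenotypeTableError(f"{path}: duplicate sample ids")

    phenotypes: dict[str, PhenotypeStatus] = {}
    for sample, word in zip(samples, df["phenotype"]):
        key = str(word).strip().lower()
        if key not in _PHENO_WORDS:
            raise GenotypeTableError(
                f"{path}: sample {sample!r}: unknown phenotype label {word!r}"
            )
        phenotypes[sample] = _PHENO_WORDS[key]

    cs = CallSet(variants, samples)
    for variant, col in zip(variants, variant_cols):
        ref, alt = col_alleles[col]
        for sample, cell in zip(samples, df[col]):
            try:
                pair = _split_allele_pair(str(cell), ref, alt)
            except GenotypeTableError as exc:
                raise GenotypeTableError(
                    f"{path}: sample {sample!r}, column {col!r}: {exc}"
                ) from None
            if pair is None:
                cs.set_alt_count(variant.key, sample, None)
                continue
            dosage = 0
            for allele in pair:
                if allele == alt:
                    dosage += 1
                elif allele != ref:
                    raise GenotypeTableError(
                        f"{path}: sample {sample!r}, column {col!r}: allele "
                        f"{allele!r} is neither declared ref {ref!r} nor alt {alt!r}"
                    )
            cs.set_alt_count(variant.key, sample, dosage)
    return cs, phenotypes


def write_genotype_table(
    callset: CallSet,
    phenotypes: Mapping[str, PhenotypeStatus],
    path: str | Path,
    *,
    sex: Mapping[str, str] | None = None,
) -> None:
    """Write a CallSet plus phenotypes in the screening-table TSV dialect.

    Genotypes are rendered as ``ref/ref``, ``ref/alt``, ``alt/alt`` pairs
    using each variant's declared alleles; missing calls become ``/``.
    """
    pheno_out = {
        PhenotypeStatus.AFFECTED: "affected",
        PhenotypeStatus.UNAFFECTED: "normal",
        PhenotypeStatus.UNKNOWN: "unknown",
    }
    cols = ["sample"] + (["sex"] if sex else []) + ["phenotype"]
    # column labels must be unique; use gene plus position when needed
    labels = []
    for v in callset.variants:
        label = v.gene or v.chrom
        if any(l.split(":")[0] == label for l in labels):
            label = f"{label}_{v.pos}"
        labels.append(f"{label}:{v.ref}>{v.alt}")
    header = cols + labels
    lines = ["\t".join(header)]
    for sample in callset.samples:
        row = [sample]
        if sex:
            row.append(sex.get(sample, "?"))
        row.append(pheno_out[phenotypes.get(sample, PhenotypeStatus.UNKNOWN)])
        for v in callset.variants:
            dosage = callset.alt_count(v.key, sample)
            if dosage is None:
                row.append(MISSING_CELL)
            else:
                pair = [v.ref, v.ref] if dosage == 0 else (
                    [v.ref, v.alt] if dosage == 1 else [v.alt, v.alt]
                )
                row.append("/".join(pair))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
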