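"""Loaders for the packaged study fixtures.

The fixtures transcribe the published cohort screening tables and studbook
pedigree of the black-footed cat retinal-atrophy study:

* :func:`load_iqcb1_cohort` — the 16-cat direct-sequencing screen of the
  IQCB1 c.1282delCT deletion;
* :func:`load_missense_panel` — the 15-cat assay of the deletion plus the
  seven moderate-impact missense candidates, with per-column allele
  declarations;
* :func:`load_studbook` — the studbook pedigree (a transcription of a
  published figure, so edge-level fidelity is approximate) with the known
  IQCB1 genotypes attached;
* :func:`load_published_funnel` — the published genome-wide filter-cascade
  tallies per stage and functional class;
* :func:`load_retinal_genes` — a synthetic illustrative retinal-disease
  gene list standing in for a user-supplied curated database.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .core import CallSet, PhenotypeStatus
from .funnel import FunnelReport
from .io import GeneList, read_gene_list, read_genotype_table, read_ped
from .pedigree import Pedigree

__all__ = [
    "load_iqcb1_cohort",
    "load_missense_panel",
    "load_studbook",
    "load_published_funnel",
    "load_retinal_genes",
    "IQCB1_KEY",
]

_DATA = files("varfunnel.data")

#: Variant key of the IQCB1 deletion column in both genotype-table fixtures.
IQCB1_KEY = ("IQCB1", 1, "WT", "DELCT")


def load_iqcb1_cohort() -> tuple[CallSet, dict[str, PhenotypeStatus]]:
    """The 16-sample screening cohort, IQCB1 deletion only."""
    with as_file(_DATA / "cohort_iqcb1.tsv") as path:
        return read_genotype_table(path)


def load_missense_panel() -> tuple[CallSet, dict[str, PhenotypeStatus]]:
    """The 15-sample screen of IQCB1 plus seven missense candidates."""
    with as_file(_DATA / "missense_panel.tsv") as path:
        return read_genotype_table(path)


def load_studbook(*, with_genotypes: bool = True) -> Pedigree:
    """The transcribed studbook pedigree; known IQCB1 genotypes attached
    from the screening cohort unless ``with_genotypes`` is False."""
    known = None
    if with_genotypes:
        callset, _ = load_iqcb1_cohort()
        known = {
            sample: dosage
            for sample, dosage in callset.row(IQCB1_KEY).items()
            if dosage is not None
        }
    with as_file(_DATA / "studbook.ped") as path:
        return read_ped(path, known_genotypes=known)


def load_published_funnel() -> FunnelReport:
    """The published per-stage, per-class genome-wide variant tallies.

    Loaded without monotonicity validation: the upstream annotator counted
    transcript effects, and one low-frequency class increases between the
    first two stages.
    """
    with as_file(_DATA / "funnel_counts.json") as path:
        return FunnelReport.from_json(path, validate=False)


def load_retinal_genes() -> GeneList:
    with as_file(_DATA / "retinal_genes.txt") as path:
        return read_gene_list(path)
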