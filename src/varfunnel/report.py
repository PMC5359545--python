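"""Human-readable rendering of funnel reports and concordance verdicts.

Text rendering is presentation-only; JSON is the machine interface and is
never re-parsed by the pipeline.
"""

from __future__ import annotations

from typing import Iterable

from .concordance import ConcordanceVerdict
from .core import FunctionalClass, ImpactTier, impact_tier_of
from .funnel import FunnelReport

__all__ = ["render_funnel", "render_verdicts"]

_STAGE_LABELS = {
    "trio": "WGS trio",
    "species_specific": "Species-specific",
    "phenotype_segregation": "Phenotype segregation",
    "gene_list": "Gene list",
}

_CLASS_LABELS = {
    FunctionalClass.STOP_GAIN: "Stop gain",
    FunctionalClass.START_STOP_LOSS: "Start/Stop loss",
    FunctionalClass.SPLICE_DONOR_ACCEPTOR: "Splice donor/acceptor",
    FunctionalClass.EXON_DELETION: "Exon deletion",
    FunctionalClass.FRAMESHIFT: "Frameshift",
    FunctionalClass.RARE_AMINO_ACID: "Rare amino acid",
    FunctionalClass.CODON_ALTERATION: "Codon alteration",
    FunctionalClass.MISSENSE: "Missense",
    FunctionalClass.SPLICE_BRANCH: "Splice branch",
    FunctionalClass.UTR_DELETION: "5'/3' UTR deletion",
    FunctionalClass.LOW_OTHER: "Low (other)",
    FunctionalClass.MODIFIER: "Modifier",
}


def render_funnel(report: FunnelReport) -> str:
    """Render a funnel report as a text grid.

    Stages are columns, functional classes rows, grouped by impact tier
    with per-tier subtotals; a final line prints the HIGH-impact total of
    the last stage before the gene intersection (the candidate count the
    cascade is read for).
    """
    stages = list(report.stages)
    headers = [_STAGE_LABELS.get(s, s) for s in stages]
    name_w = max(len(l) for l in _CLASS_LABELS.values()) + 2
    col_w = [max(len(h), 12) for h in headers]

    def fmt_row(name: str, values: Iterable) -> str:
        cells = [f"{v:>{w},}" if isinstance(v, int) else f"{v:>{w}}"
                 for v, w in zip(values, col_w)]
        return f"{name:<{name_w}}" + "  ".join(cells)

    lines = [fmt_row("Functional class", headers)]
    lines.append("-" * len(lines[0]))
    for tier in (ImpactTier.HIGH, ImpactTier.MODERATE, ImpactTier.LOW,
                 ImpactTier.MODIFIER):
        tier_classes = [fc for fc in FunctionalClass if impact_tier_of(fc) is tier]
        for fc in tier_classes:
            lines.append(
                fmt_row(_CLASS_LABELS[fc], [report.count(s, fc) for s in stages])
            )
        lines.append(
            fmt_row(
                f"[{tier.name} subtotal]",
                [report.tier_total(s, tier) for s in stages],
            )
        )
        lines.append("")
    segregation_stage = (
        "phenotype_segregation"
        if "phenotype_segregation" in stages
        else stages[-1]
    )
    high_total = report.tier_total(segregation_stage, ImpactTier.HIGH)
    lines.append(
        f"High-impact variants at {_STAGE_LABELS.get(segregation_stage, segregation_stage)}: "
        f"{high_total}"
    )
    return "\n".join(lines)


def render_verdicts(verdicts: Iterable[ConcordanceVerdict]) -> str:
    """One line per candidate: label, status, and offending samples."""
    lines = []
    for v in verdicts:
        label = v.variant_key[0]
        offenders = ", ".join(f"{s} ({r.value})" for s, r in v.offending_samples)
        line = f"{label:<12} {v.status.value}"
        if offenders:
            line += f"  [{offenders}]"
        if v.note:
            line += f"  # {v.note}"
        lines.append(line)
    return "\n".join(lines)
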