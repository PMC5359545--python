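"""Frameshift consequence prediction from coding-sequence nomenclature.

Given a small deletion in HGVS coding notation (``c.<pos>del<bases>``),
predicts the protein-level outcome.  The default convention places the
premature stop at the codon containing the first deleted nucleotide — the
immediate-stop convention ``p.<res><codon>*`` used when the altered coding
sequence is not available — so the stop codon index is ``ceil(pos / 3)``.
When the coding sequence is supplied, the shifted reading frame is instead
translated to the first downstream stop, which can only move the stop at or
beyond the first affected codon.

With the wild-type protein length known, the number of abolished residues
is ``protein_length - stop_codon_index + 1`` (the stop replaces a coded
residue, so the residue at the stop position counts as lost).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .core import VarFunnelError

__all__ = [
    "HgvsError",
    "UnsupportedHgvsError",
    "ProteinConsequence",
    "parse_hgvs_c",
    "codon_index",
    "frameshift_consequence",
]


class HgvsError(VarFunnelError):
    pass


class UnsupportedHgvsError(HgvsError):
    """Notation is recognizable HGVS but outside the supported subset."""


_DEL_RE = re.compile(r"^c\.(?P<pos>\d+)(?:_(?P<end>\d+))?del(?P<what>[ACGTacgt]+|\d*)$")
_OTHER_KINDS = re.compile(r"ins|dup|inv|>|=")

def _translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon, dropping any trailing
    partial codon ('*' marks stops)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def parse_hgvs_c(notation: str) -> tuple[int, str]:
    """Parse a coding-deletion HGVS string such as ``c.1282delCT``.

    Returns the 1-based coding position of the first deleted nucleotide
    and the deleted-base string.  A numeric form ``c.<pos>del<n>`` returns
    ``"N" * n``.  Substitutions, insertions, duplications and inversions
    are recognized but unsupported.
    """
    notation = notation.strip()
    m = _DEL_RE.match(notation)
    if not m:
        if notation.startswith("c.") and _OTHER_KINDS.search(notation):
            raise UnsupportedHgvsError(
                f"{notation!r}: only deletions (c.<pos>del<bases>) are supported"
            )
        raise HgvsError(f"cannot parse HGVS coding notation {notation!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise HgvsError(f"{notation!r}: coding position must be >= 1")
    what = m.group("what")
    if what.isdigit():
        bases = "N" * int(what)
    elif what:
        bases = what.upper()
    else:
        if m.group("end") is None:
            bases = "N"
        else:
            bases = "N" * (int(m.group("end")) - pos + 1)
    if m.group("end") is not None and int(m.group("end")) - pos + 1 != len(bases):
        raise HgvsError(
            f"{notation!r}: range length does not match the deleted bases"
        )
    if not bases:
        raise HgvsError(f"{notation!r}: empty deletion")
    return pos, bases


def codon_index(cds_position: int) -> int:
    """1-based codon number containing a 1-based coding nucleotide:
    ``ceil(cds_position / 3)``."""
    if cds_position < 1:
        raise HgvsError(f"coding position must be >= 1, got {cds_position}")
    return (cds_position + 2) // 3


@dataclass(frozen=True)
class ProteinConsequence:
    """Predicted protein-level outcome of a coding deletion."""

    cds_position: int
    deleted_length: int
    stop_codon_index: int
    residues_lost: int | None
    hgvs_c: str
    hgvs_p: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.hgvs_c} -> {self.hgvs_p}"


def frameshift_consequence(
    cds_position: int,
    deleted: int | str,
    *,
    protein_length: int | None = None,
    cds_sequence: str | None = None,
    protein_sequence: str | None = None,
    allow_in_frame: bool = False,
) -> ProteinConsequence:
    """Predict the truncation caused by a coding deletion.

    Parameters
    ----------
    cds_position
        1-based coding position of the first deleted nucleotide.
    deleted
        The deleted bases (string) or their count.
    protein_length
        Wild-type protein length in residues; enables ``residues_lost``.
    cds_sequence
        Wild-type coding sequence.  When given, the shifted frame is
        translated and the stop is placed at the first downstream stop
        codon instead of the immediate-stop convention.
    protein_sequence
        Wild-type protein sequence; supplies the residue letter for
        ``hgvs_p`` (``p.L428*`` instead of ``p.428*``).
    allow_in_frame
        Permit deletions whose length is a multiple of three (not a true
        frameshift); off by default.
    """
    if isinstance(deleted, str):
        bases = deleted.upper()
        deleted_length = len(bases)
    else:
        bases = None
        deleted_length = int(deleted)
    if deleted_length < 1:
        raise HgvsError("deletion length must be >= 1")
    if deleted_length % 3 == 0 and not allow_in_frame:
        raise HgvsError(
            f"a {deleted_length} nt deletion is in-frame, not a frameshift; "
            "pass allow_in_frame to analyze it anyway"
        )
    first_codon = codon_index(cds_position)
    if protein_length is not None and first_codon > protein_length:
        raise HgvsError(
            f"coding position {cds_position} lies beyond a protein of "
            f"{protein_length} residues"
        )

    stop = first_codon
    if cds_sequence is not None:
        seq = re.sub(r"\s", "", cds_sequence).upper()
        if cds_position > len(seq):
            raise HgvsError(
                f"coding position {cds_position} beyond CDS of length {len(seq)}"
            )
        mutant = seq[: cds_position - 1] + seq[cds_position - 1 + deleted_length :]
        translated = _translate(mutant)
        found = translated.find("*", first_codon - 1)
        if found < 0:
            raise HgvsError(
                "shifted reading frame reaches the end of the CDS without a "
                "stop codon"
            )
        stop = found + 1

    residues_lost = None
    if protein_length is not None:
        residues_lost = protein_length - stop + 1

    if bases is not None and "N" not in bases:
        hgvs_c = f"c.{cds_position}del{bases}"
    else:
        hgvs_c = f"c.{cds_position}del{deleted_length}"

    residue = ""
    if protein_sequence is not None and stop <= len(protein_sequence):
        residue = protein_sequence[stop - 1].upper()
    hgvs_p = f"p.{residue}{stop}*"

    return ProteinConsequence(
        cds_position=cds_position,
        deleted_length=deleted_length,
        stop_codon_index=stop,
        residues_lost=residues_lost,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
    )
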