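"""Deterministic in-silico tryptic digestion.

Classic trypsin specificity: cleave C-terminal to lysine (K) or arginine
(R) unless the following residue is proline (P).  A K/R followed by P is
not a cleavage site and therefore never counts as a missed cleavage.
Coordinates are 1-based inclusive throughout, matching the site notation
used in proteomics reports (e.g. "Ser 67" = position 67).

The engine enumerates every peptide bounded by cleavage sites (or the
protein termini) whose internal missed-cleavage count and length fall
within the requested bounds.  Non-canonical residues X and U are accepted
in sequences but are never cleavage sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ValidationError

# 20 canonical amino acids plus X (unknown) and U (selenocysteine).
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXU")

_HEADER_RE = re.compile(r"^(?P<accession>\S+)(?:\s+(?P<description>.*))?$")


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein sequence.

    Parameters
    ----------
    accession : str
        Unique identifier (e.g. UniProt accession).
    gene : str
        Gene symbol; empty string when unknown.
    description : str
        Free-text header description.
    sequence : str
        Uppercase amino-acid string over the 22-letter alphabet.
    """

    accession: str
    gene: str = ""
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"{self.accession}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located on its parent protein.

    ``start``/``end`` are 1-based inclusive coordinates on the parent;
    ``missed_cleavages`` counts internal (uncut) cleavage sites.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValidationError(
                f"peptide {self.sequence}: span {self.start}-{self.end} "
                "inconsistent with length"
            )

    def covers(self, position: int) -> bool:
        """True if the 1-based protein coordinate lies inside the peptide."""
        return self.start <= position <= self.end


def cleavage_sites(sequence: str) -> list[int]:
    """Tryptic cleavage positions of a sequence.

    Returns the sorted 1-based residue positions p such that trypsin cuts
    between p and p+1: residue p is K or R, residue p+1 exists and is not
    P.  The C-terminus is never listed.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    return [
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in "KR" and sequence[p] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 30,
) -> list[Peptide]:
    """Enumerate tryptic peptides of a protein.

    Every peptide bounded by consecutive-or-skipped cleavage sites (or the
    termini) with ``missed_cleavages <= max_missed_cleavages`` and length
    within ``[min_length, max_length]`` is returned, sorted by
    (start, end).  The initiator methionine is retained: no Met-clipped
    forms are produced unless ``digest_with_met_clipping`` is used.
    """
    if max_missed_cleavages < 0:
        raise ValidationError("max_missed_cleavages must be >= 0")
    if not (1 <= min_length <= max_length):
        raise ValidationError(
            f"invalid length bounds [{min_length}, {max_length}]"
        )
    seq = protein.sequence
    # Boundaries between which peptides run: cut points in 0-based
    # "between residues" coordinates, plus both termini.
    cuts = [0] + cleavage_sites(seq) + [len(seq)]
    out: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, len(cuts)):
            mc = j - i - 1
            if mc > max_missed_cleavages:
                break
            start, end = cuts[i] + 1, cuts[j]
            length = end - start + 1
            if min_length <= length <= max_length:
                out.append(Peptide(seq[start - 1 : end], start, end, mc))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def digest_with_met_clipping(
    protein: ProteinRecord,
    max_missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 30,
) -> list[Peptide]:
    """Digest, additionally emitting Met-clipped forms of N-terminal peptides.

    Off the default path: plain :func:`digest` keeps the initiator
    methionine.  Here, for each peptide starting at position 1 of a
    Met-initiated protein, a second form starting at position 2 is added
    (subject to the same length bounds).
    """
    peps = digest(protein, max_missed_cleavages, min_length, max_length)
    if not protein.sequence.startswith("M"):
        return peps
    extra = []
    seen = {(p.start, p.end) for p in peps}
    for p in digest(protein, max_missed_cleavages, 1, max_length + 1):
        if p.start == 1 and p.end >= 2:
            clipped = Peptide(p.sequence[1:], 2, p.end, p.missed_cleavages)
            if (
                min_length <= len(clipped.sequence) <= max_length
                and (2, p.end) not in seen
            ):
                extra.append(clipped)
                seen.add((2, p.end))
    out = peps + extra
    out.sort(key=lambda p: (p.start, p.end))
    return out


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _gene_from_description(description: str) -> str:
    m = re.search(r"GN=(\S+)", description)
    return m.group(1) if m else ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Headers are ``>accession description``; a ``GN=SYMBOL`` token in the
    description, when present, populates the gene field.  Wrapped and
    unwrapped sequence lines are both accepted.
    """
    from Bio import SeqIO

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(rec.description)
        accession = rec.id
        description = (m.group("description") or "") if m else ""
        if accession in seen:
            raise ValidationError(f"duplicate accession {accession}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                gene=_gene_from_description(description),
                description=description,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def format_fasta(records: Iterable[ProteinRecord]) -> str:
    """Serialize records as FASTA text (unwrapped sequence lines)."""
    chunks = []
    for rec in records:
        header = rec.accession
        if rec.description:
            header += f" {rec.description}"
        chunks.append(f">{header}\n{rec.sequence}\n")
    return "".join(chunks)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    Path(path).write_text(format_fasta(records))
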