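"""Variant-peptide (SAP) database construction and detection patterns.

A single-amino-acid polymorphism (SAP) is applied to its reference
protein, the *mutated* sequence is digested, and every tryptic peptide
that contains the variant position with at most two missed cleavages is
appended to the search database.  Running digestion on the mutated
sequence means cleavage-site gain/loss caused by the substitution
(e.g. R->T removing a site) is handled for free.

Each appended FASTA entry is a peptide-level entry with a traceable
header ``accession|pPOSrefALT|sap`` so downstream protein inference never
conflates variant evidence with the reference protein.  A whole-protein
mode (one mutated full-length entry per variant) is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .digestion import Peptide, ProteinRecord, cleavage_sites, digest, format_fasta
from .errors import ReferenceMismatchError, ValidationError

SAP_TAG = "sap"

#: Default peptide length bounds for variant entries (wider than the
#: reporting default so long variant contexts are not lost).
DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 45
MAX_MISSED_CLEAVAGES = 2


@dataclass(frozen=True)
class SAPVariant:
    """A single amino-acid substitution on a protein.

    ``groups`` lists the sample groups (cell lines) carrying the variant.
    """

    accession: str
    position: int
    ref: str
    alt: str
    gene: str = ""
    groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.accession} p{self.position}: ref == alt ({self.ref})"
            )
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError("ref and alt must be single residues")
        if self.position < 1:
            raise ValidationError("position must be >= 1")
        object.__setattr__(self, "groups", frozenset(self.groups))

    @property
    def tag(self) -> str:
        """Compact variant tag, e.g. ``p12GD`` for G12D."""
        return f"p{self.position}{self.ref}{self.alt}"

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``G12D``."""
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class VariantPeptideEntry:
    """One variant peptide destined for the augmented database."""

    variant: SAPVariant
    peptide: Peptide  # coordinates on the mutated sequence
    header: str
    wt_counterpart: Peptide | None  # on the reference sequence; may be None


def apply_variant(protein: ProteinRecord, variant: SAPVariant) -> ProteinRecord:
    """Return the protein with the substitution applied.

    Raises :class:`ReferenceMismatchError` when the stated reference
    residue disagrees with the sequence (stale SNV table).  X/U residues
    never satisfy a reference check.
    """
    if variant.position > len(protein.sequence):
        raise ReferenceMismatchError(
            f"{protein.accession}: variant position {variant.position} "
            f"beyond sequence length {len(protein.sequence)}"
        )
    observed = protein.sequence[variant.position - 1]
    if observed != variant.ref or observed in "XU":
        raise ReferenceMismatchError(
            f"{protein.accession} p{variant.position}: expected "
            f"{variant.ref}, sequence has {observed}"
        )
    seq = (
        protein.sequence[: variant.position - 1]
        + variant.alt
        + protein.sequence[variant.position :]
    )
    return replace(
        protein,
        accession=f"{protein.accession}|{variant.tag}",
        sequence=seq,
    )


def _wt_counterpart(
    protein: ProteinRecord, variant: SAPVariant, mutated_pep: Peptide
) -> Peptide | None:
    """Reference-sequence counterpart of a variant peptide.

    Prefers the reference peptide with the same boundaries (when the
    substitution did not create/destroy a cleavage site at the window
    edge); otherwise falls back to the fully cleaved (mc=0) reference
    peptide covering the variant coordinate, if one exists.
    """
    ref_peps = digest(
        protein, MAX_MISSED_CLEAVAGES, 1, len(protein.sequence)
    )
    by_span = {(p.start, p.end): p for p in ref_peps}
    same = by_span.get((mutated_pep.start, mutated_pep.end))
    if same is not None:
        return same
    for p in ref_peps:
        if p.missed_cleavages == 0 and p.covers(variant.position):
            return p
    return None


def variant_peptides(
    protein: ProteinRecord,
    variant: SAPVariant,
    min_length: int = DEFAULT_MIN_LEN,
    max_length: int = DEFAULT_MAX_LEN,
) -> list[VariantPeptideEntry]:
    """All tryptic peptides of the mutated sequence containing the variant.

    Exactly the peptides that (a) cover the variant position, (b) carry at
    most two missed cleavages, and (c) satisfy the length bounds.  This is
    the minimal set guaranteeing a search engine configured with <= 2
    missed cleavages can match the variant.
    """
    mutated = apply_variant(protein, variant)
    entries = []
    for pep in digest(mutated, MAX_MISSED_CLEAVAGES, min_length, max_length):
        if not pep.covers(variant.position):
            continue
        header = f"{protein.accession}|{variant.tag}|{SAP_TAG}"
        entries.append(
            VariantPeptideEntry(
                variant=variant,
                peptide=pep,
                header=header,
                wt_counterpart=_wt_counterpart(protein, variant, pep),
            )
        )
    return entries


def build_augmented_fasta(
    proteins: list[ProteinRecord],
    variants: list[SAPVariant],
    min_length: int = DEFAULT_MIN_LEN,
    max_length: int = DEFAULT_MAX_LEN,
    whole_protein: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Append variant entries to a reference database.

    Returns ``(fasta_text, mapping)``: the FASTA holds every reference
    entry unchanged followed by one entry per variant peptide (or one
    mutated full-length entry per variant when ``whole_protein``); the
    mapping table links appended entries to (accession, gene, position,
    ref, alt, peptide sequence, WT counterpart sequence).  Appending zero
    variants returns the reference database serialization unchanged.
    Duplicate peptide sequences arising from distinct variants are kept
    but flagged in the ``duplicated`` column.
    """
    index = {p.accession: p for p in proteins}
    missing = sorted({v.accession for v in variants} - index.keys())
    if missing:
        raise ValidationError(f"unresolvable accessions: {missing}")

    parts = [format_fasta(proteins)]
    rows = []
    for variant in variants:
        protein = index[variant.accession]
        if whole_protein:
            mutated = apply_variant(protein, variant)
            mutated = replace(
                mutated, description=f"{protein.description} {SAP_TAG}".strip()
            )
            parts.append(format_fasta([mutated]))
            rows.append(
                {
                    "entry": mutated.accession,
                    "accession": protein.accession,
                    "gene": variant.gene or protein.gene,
                    "position": variant.position,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "peptide": mutated.sequence,
                    "wt_peptide": "",
                    "start": 1,
                    "end": len(mutated.sequence),
                    "missed_cleavages": -1,
                }
            )
            continue
        for k, entry in enumerate(
            variant_peptides(protein, variant, min_length, max_length)
        ):
            name = f"{entry.header}|{k}"
            parts.append(f">{name}\n{entry.peptide.sequence}\n")
            rows.append(
                {
                    "entry": name,
                    "accession": protein.accession,
                    "gene": variant.gene or protein.gene,
                    "position": variant.position,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "peptide": entry.peptide.sequence,
                    "wt_peptide": (
                        entry.wt_counterpart.sequence
                        if entry.wt_counterpart
                        else ""
                    ),
                    "start": entry.peptide.start,
                    "end": entry.peptide.end,
                    "missed_cleavages": entry.peptide.missed_cleavages,
                }
            )
    mapping = pd.DataFrame(
        rows,
        columns=[
            "entry",
            "accession",
            "gene",
            "position",
            "ref",
            "alt",
            "peptide",
            "wt_peptide",
            "start",
            "end",
            "missed_cleavages",
        ],
    )
    mapping["duplicated"] = mapping.duplicated("peptide", keep=False)
    return "".join(parts), mapping


def read_snv_table(path) -> list[SAPVariant]:
    """Read a DepMap-export-like SNV table.

    Expected TSV columns: accession, gene, position, ref, alt, cell_line.
    One row per (variant, carrier cell line); rows sharing the variant key
    are merged into a single :class:`SAPVariant` with the union of
    carriers.
    """
    from .errors import SchemaError

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"SNV table missing columns: {sorted(missing)}")
    if "cell_line" not in df.columns:
        df["cell_line"] = ""
    if "gene" not in df.columns:
        df["gene"] = ""
    variants = []
    for (acc, pos, ref, alt, gene), sub in df.groupby(
        ["accession", "position", "ref", "alt", "gene"], sort=False
    ):
        groups = frozenset(g for g in sub["cell_line"] if g)
        variants.append(
            SAPVariant(
                accession=acc,
                position=int(pos),
                ref=ref,
                alt=alt,
                gene=gene,
                groups=groups,
            )
        )
    return variants


def sap_detection_pattern(
    observations,
    mapping: pd.DataFrame,
    groups: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean WT/variant detection pattern across cells.

    Parameters
    ----------
    observations : list of PrecursorObservation
        q-value-filtered report rows.
    mapping : DataFrame
        Output of :func:`build_augmented_fasta` (peptide-mode).
    groups : dict
        run_id -> group label for every cell to include (cells absent
        from the report yield all-False columns).

    Returns
    -------
    (pattern, summary) : the boolean peptide x cell matrix, whose rows are
    labelled ``GENE ALT_LABEL (variant)`` / ``GENE ALT_LABEL (wt)``, and a
    per-group detection-fraction summary.
    """
    detected: dict[str, set[str]] = {}
    for obs in observations:
        detected.setdefault(obs.stripped_sequence, set()).add(obs.run_id)

    cells = list(groups)
    rows = {}
    for _, m in mapping.drop_duplicates(["accession", "position", "ref", "alt"]).iterrows():
        label = f"{m['gene'] or m['accession']} {m['ref']}{m['position']}{m['alt']}"
        sub = mapping[
            (mapping["accession"] == m["accession"])
            & (mapping["position"] == m["position"])
            & (mapping["alt"] == m["alt"])
        ]
        var_seqs = set(sub["peptide"])
        wt_seqs = {s for s in sub["wt_peptide"] if s}
        var_cells = set().union(*(detected.get(s, set()) for s in var_seqs))
        wt_cells = (
            set().union(*(detected.get(s, set()) for s in wt_seqs))
            if wt_seqs
            else set()
        )
        rows[f"{label} (variant)"] = [c in var_cells for c in cells]
        rows[f"{label} (wt)"] = [c in wt_cells for c in cells]

    pattern = pd.DataFrame.from_dict(rows, orient="index", columns=cells)
    group_series = pd.Series(groups)
    summary = (
        pattern.T.groupby(group_series).mean().T
        if not pattern.empty
        else pd.DataFrame()
    )
    return pattern, summary
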