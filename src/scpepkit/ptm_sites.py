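"""PTM site mapping to protein coordinates and histone activity scoring.

A modification observed on a peptide is lifted to an absolute protein
coordinate (``protein position = peptide start + position in peptide -
1``) with the residue checked against the reference sequence, yielding
site labels such as ``S67`` or ``K27me3``.  Histone-mark profiles combine
activating marks (K79me/me2, K14ac, K23ac) against repressing marks
(K27me/me2/me3, K79fo) into a per-cell log2 transcriptional-activity
ratio; a higher ratio indicates an overall increase in transcriptional
activity.

Histone coordinates are mature-protein coordinates (initiator methionine
removed), the convention behind labels like H3 K27.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import ProteinRecord
from .errors import ValidationError
from .matrix import QuantMatrix
from .report_ingest import (
    MOD_RESIDUES,
    ParsedModification,
    PrecursorObservation,
    parse_modified_sequence,
)

#: Default H3 mark partition for the activity ratio.
ACTIVATING_MARKS = ("K79me", "K79me2", "K14ac", "K23ac")
REPRESSING_MARKS = ("K27me", "K27me2", "K27me3", "K79fo")

#: Marks that decorate a residue label (Met oxidation is tracked but not
#: suffixed into e.g. phosphosite labels).
_SUFFIXED = {"me", "me2", "me3", "ac", "fo"}


@dataclass(frozen=True)
class ModificationSite:
    """A PTM instance at an absolute protein coordinate."""

    accession: str
    gene: str
    residue: str
    position: int
    mod_type: str

    @property
    def site_label(self) -> str:
        """Field-standard label: ``S67``, ``K27me3``, ``Nt-ac``."""
        if self.mod_type == "nterm-ac":
            return "Nt-ac"
        suffix = self.mod_type if self.mod_type in _SUFFIXED else ""
        return f"{self.residue}{self.position}{suffix}"

    @property
    def key(self) -> str:
        return f"{self.gene or self.accession}:{self.site_label}"


def map_sites(
    stripped_sequence: str,
    parsed_mods: list[ParsedModification],
    protein: ProteinRecord,
    peptide_start: int,
) -> list[ModificationSite]:
    """Lift peptide-level modifications to protein coordinates.

    The peptide must occur at ``peptide_start`` (1-based) in the protein;
    a residue mismatch raises :class:`ValidationError`, signalling isoform
    or coordinate drift.  The mapping is invariant to which enclosing
    peptide (any missed-cleavage state) carries the modification.
    """
    end = peptide_start + len(stripped_sequence) - 1
    if (
        peptide_start < 1
        or end > len(protein.sequence)
        or protein.sequence[peptide_start - 1 : end] != stripped_sequence
    ):
        raise ValidationError(
            f"{protein.accession}: peptide {stripped_sequence!r} does not "
            f"occur at position {peptide_start}"
        )
    sites = []
    for mod in parsed_mods:
        if mod.mod_type == "nterm-ac":
            position = peptide_start
            residue = protein.sequence[position - 1]
        else:
            position = peptide_start + mod.peptide_position - 1
            residue = protein.sequence[position - 1]
            if residue != mod.residue:
                raise ValidationError(
                    f"{protein.accession} p{position}: reference has "
                    f"{residue}, modification reported on {mod.residue}"
                )
        sites.append(
            ModificationSite(
                accession=protein.accession,
                gene=protein.gene,
                residue=residue,
                position=position,
                mod_type=mod.mod_type,
            )
        )
    return sites


def _locate(peptide: str, sequence: str) -> int | None:
    """1-based start of a peptide in a protein; None if absent/ambiguous."""
    first = sequence.find(peptide)
    if first == -1 or sequence.find(peptide, first + 1) != -1:
        return None
    return first + 1


def site_table(
    observations: list[PrecursorObservation],
    proteins: list[ProteinRecord],
) -> tuple[QuantMatrix, pd.Series]:
    """Site x sample log2-intensity table plus detection frequencies.

    Each observation carrying modifications is located on its (single)
    protein and its modifications are mapped to sites; the value is log2
    of the summed intensity of all precursors carrying that site in that
    sample (peptides of different missed-cleavage states pool into one
    row).  The second return value counts, per site, the samples in which
    it was observed.
    """
    index = {p.accession: p for p in proteins}
    rows = []
    meta: dict[str, dict] = {}
    for obs in observations:
        if not obs.is_modified or obs.intensity <= 0 or obs.is_sap:
            continue
        if len(obs.accessions) != 1 or obs.accessions[0] not in index:
            continue
        protein = index[obs.accessions[0]]
        start = _locate(obs.stripped_sequence, protein.sequence)
        if start is None:
            continue
        _, mods = parse_modified_sequence(obs.modified_sequence)
        for site in map_sites(obs.stripped_sequence, mods, protein, start):
            rows.append((site.key, obs.run_id, obs.intensity))
            meta.setdefault(
                site.key,
                {
                    "accession": site.accession,
                    "gene": site.gene,
                    "site_label": site.site_label,
                    "residue": site.residue,
                    "position": site.position,
                    "mod_type": site.mod_type,
                },
            )
    groups = pd.Series(
        {obs.run_id: obs.group for obs in observations}, dtype=object
    )
    if not rows:
        empty = QuantMatrix(
            pd.DataFrame(columns=list(groups.index)), groups
        )
        return empty, pd.Series(dtype=int)
    df = pd.DataFrame(rows, columns=["site", "sample", "intensity"])
    raw = df.pivot_table(
        index="site", columns="sample", values="intensity", aggfunc="sum"
    ).reindex(columns=list(groups.index))
    matrix = QuantMatrix(
        np.log2(raw),
        groups,
        pd.DataFrame.from_dict(meta, orient="index").reindex(raw.index),
    )
    frequencies = matrix.values.notna().sum(axis=1)
    return matrix, frequencies


@dataclass
class HistoneMarkProfile:
    """Per-sample raw-scale intensities of the eight H3 marks."""

    sample_id: str
    marks: dict[str, float] = field(default_factory=dict)  # NaN-free: omit missing

    def __post_init__(self) -> None:
        for name, value in self.marks.items():
            if value < 0:
                raise ValidationError(
                    f"{self.sample_id}: negative intensity for {name}"
                )


def histone_activity_ratio(
    profile: HistoneMarkProfile,
    pseudocount: float = 0.0,
    activating: tuple[str, ...] = ACTIVATING_MARKS,
    repressing: tuple[str, ...] = REPRESSING_MARKS,
) -> float:
    """Log2 ratio of activating over repressing H3 mark intensity.

    ``log2((sum activating + pseudocount) / (sum repressing + pseudocount))``
    on raw (linear) intensities; missing marks contribute zero to their
    sum.  With pseudocount 0 and an empty side the ratio is undefined
    (NaN).  The ratio is scale-invariant at pseudocount 0 and monotone in
    each mark.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    act = sum(profile.marks.get(m, 0.0) for m in activating) + pseudocount
    rep = sum(profile.marks.get(m, 0.0) for m in repressing) + pseudocount
    if act <= 0 or rep <= 0:
        return math.nan
    return math.log2(act / rep)


def default_pseudocount(profile: HistoneMarkProfile) -> float:
    """Half the smallest observed positive mark intensity (0 if none)."""
    positive = [v for v in profile.marks.values() if v > 0]
    return 0.5 * min(positive) if positive else 0.0


def histone_profiles(
    site_matrix: QuantMatrix,
    gene: str = "H3-1",
    marks: tuple[str, ...] = ACTIVATING_MARKS + REPRESSING_MARKS,
) -> list[HistoneMarkProfile]:
    """Extract per-sample H3 mark profiles from a site table."""
    meta = site_matrix.feature_meta
    profiles = []
    for sample in site_matrix.values.columns:
        found = {}
        for key in site_matrix.values.index:
            if meta.loc[key, "gene"] != gene:
                continue
            label = meta.loc[key, "site_label"]
            if label not in marks:
                continue
            value = site_matrix.values.at[key, sample]
            if pd.notna(value):
                found[label] = float(2.0 ** value)
        profiles.append(HistoneMarkProfile(sample_id=sample, marks=found))
    return profiles


def activity_ratio_table(
    site_matrix: QuantMatrix,
    gene: str = "H3-1",
    pseudocount: float | None = None,
    activating: tuple[str, ...] = ACTIVATING_MARKS,
    repressing: tuple[str, ...] = REPRESSING_MARKS,
) -> pd.DataFrame:
    """Per-sample activity ratios for a histone gene.

    ``pseudocount=None`` applies the per-sample default (half the smallest
    observed positive mark); pass 0.0 for the strict ratio.
    """
    rows = []
    for profile in histone_profiles(
        site_matrix, gene, activating + repressing
    ):
        pc = default_pseudocount(profile) if pseudocount is None else pseudocount
        rows.append(
            {
                "sample": profile.sample_id,
                "group": site_matrix.sample_groups.get(
                    profile.sample_id, ""
                ),
                "n_marks": len(profile.marks),
                "activity_ratio": histone_activity_ratio(
                    profile, pc, activating, repressing
                ),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
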