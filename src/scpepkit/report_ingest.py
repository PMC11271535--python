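"""Precursor-report parsing and quantitative matrix assembly.

Reads long-format precursor reports (one row per precursor per run, the
dialect of a DIA-NN-style main report), parses ``(UniMod:N)`` modified
sequences, and rolls rows up into peptide x cell and protein x cell log2
matrices.  Protein quantities use a deterministic top-3 peptide sum;
per-sample median normalization emulates global cross-run normalization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError, VocabularyError
from .matrix import QuantMatrix
from .variant_db import SAP_TAG

logger = logging.getLogger(__name__)

#: UniMod accession -> modification shorthand.
UNIMOD_VOCAB = {
    1: "ac",        # acetyl (protein N-terminus or lysine)
    21: "phospho",  # phospho S/T/Y
    34: "me",       # methyl K
    35: "ox",       # oxidation M
    36: "me2",      # dimethyl K
    37: "me3",      # trimethyl K
    122: "fo",      # formyl K
}

#: Residues each modification may sit on (N-terminal acetyl handled apart).
MOD_RESIDUES = {
    "ac": {"K"},
    "phospho": {"S", "T", "Y"},
    "me": {"K"},
    "ox": {"M"},
    "me2": {"K"},
    "me3": {"K"},
    "fo": {"K"},
    "nterm-ac": {"-"},
}

_TAG_RE = re.compile(r"\(UniMod:(\d+)\)")


@dataclass(frozen=True)
class ParsedModification:
    """One modification within a peptide.

    ``peptide_position`` is 1-based within the stripped sequence; 0
    denotes the peptide N-terminus (residue reported as ``-``).
    """

    peptide_position: int
    mod_type: str
    residue: str


@dataclass(frozen=True)
class PrecursorObservation:
    """One row of a search-engine precursor report."""

    run_id: str
    group: str
    modified_sequence: str
    stripped_sequence: str
    charge: int
    q_value: float
    rt: float
    ion_mobility: float
    intensity: float
    accessions: tuple[str, ...]
    gene: str

    @property
    def is_modified(self) -> bool:
        return self.modified_sequence != self.stripped_sequence

    @property
    def is_sap(self) -> bool:
        return any(SAP_TAG in acc.split("|") for acc in self.accessions)


@dataclass
class ReportDialect:
    """Column map of the long-format report (DIA-NN main-report-like)."""

    run: str = "Run"
    group: str = "Group"
    modified_sequence: str = "Modified.Sequence"
    stripped_sequence: str = "Stripped.Sequence"
    charge: str = "Precursor.Charge"
    q_value: str = "Q.Value"
    rt: str = "RT"
    ion_mobility: str = "IM"
    intensity: str = "Precursor.Quantity"
    protein_ids: str = "Protein.Ids"
    genes: str = "Genes"

    def mandatory(self) -> list[str]:
        return [
            self.run,
            self.modified_sequence,
            self.charge,
            self.q_value,
            self.rt,
            self.ion_mobility,
            self.intensity,
            self.protein_ids,
        ]


def parse_modified_sequence(
    modified_sequence: str,
) -> tuple[str, list[ParsedModification]]:
    """Split a ``(UniMod:N)`` annotated peptide into sequence + mods.

    A tag binds to the residue immediately preceding it; a tag before the
    first residue is the peptide N-terminus (position 0, ``nterm-ac``).
    Re-inserting the tags at the returned positions reproduces the input.
    """
    if modified_sequence.count("(") != modified_sequence.count(")"):
        raise ValidationError(
            f"unbalanced parentheses in {modified_sequence!r}"
        )
    stripped = []
    mods = []
    i = 0
    while i < len(modified_sequence):
        ch = modified_sequence[i]
        if ch == "(":
            m = _TAG_RE.match(modified_sequence, i)
            if not m:
                raise ValidationError(
                    f"unrecognized tag at offset {i} in {modified_sequence!r}"
                )
            unimod = int(m.group(1))
            if unimod not in UNIMOD_VOCAB:
                raise VocabularyError(
                    f"UniMod:{unimod} outside the configured vocabulary"
                )
            pos = len(stripped)
            if pos == 0:
                mod_type, residue = "nterm-ac", "-"
                if UNIMOD_VOCAB[unimod] != "ac":
                    raise VocabularyError(
                        f"UniMod:{unimod} not allowed at the N-terminus"
                    )
            else:
                mod_type, residue = UNIMOD_VOCAB[unimod], stripped[pos - 1]
                if residue not in MOD_RESIDUES[mod_type]:
                    raise VocabularyError(
                        f"{mod_type} on {residue} at position {pos} "
                        f"not in the allowed vocabulary"
                    )
            mods.append(ParsedModification(pos, mod_type, residue))
            i = m.end()
        else:
            stripped.append(ch)
            i += 1
    return "".join(stripped), mods


def strip_sequence(modified_sequence: str) -> str:
    return parse_modified_sequence(modified_sequence)[0]


def format_modified_sequence(
    stripped_sequence: str, mods: list[ParsedModification]
) -> str:
    """Inverse of :func:`parse_modified_sequence`."""
    inverse = {v: k for k, v in UNIMOD_VOCAB.items()}
    inverse["nterm-ac"] = inverse["ac"]
    by_pos: dict[int, list[str]] = {}
    for mod in sorted(mods, key=lambda m: m.peptide_position):
        by_pos.setdefault(mod.peptide_position, []).append(
            f"(UniMod:{inverse[mod.mod_type]})"
        )
    out = ["".join(by_pos.get(0, []))]
    for i, ch in enumerate(stripped_sequence, start=1):
        out.append(ch)
        out.append("".join(by_pos.get(i, [])))
    return "".join(out)


def read_report(
    path: str | Path,
    dialect: ReportDialect | None = None,
    q_threshold: float = 0.01,
) -> list[PrecursorObservation]:
    """Read and q-value-filter a long-format precursor report.

    Rows with ``q_value > q_threshold`` are dropped (and counted in the
    log); malformed rows raise with their row numbers.  A missing
    mandatory column raises :class:`SchemaError` naming the column.
    """
    dialect = dialect or ReportDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    logger.info(
        "read_report: %d rows, columns mapped via %s", len(df), dialect
    )
    return observations_from_frame(df, dialect, q_threshold)


def observations_from_frame(
    df: pd.DataFrame,
    dialect: ReportDialect | None = None,
    q_threshold: float = 0.01,
) -> list[PrecursorObservation]:
    """Validate and q-filter an in-memory report table.

    Same contract as :func:`read_report`, for callers that already hold
    the long-format table (e.g. straight from the simulator).  All
    columns are coerced from their string form.
    """
    dialect = dialect or ReportDialect()
    df = df.astype(str).replace("nan", np.nan)
    df = df.reset_index(drop=True)
    for col in dialect.mandatory():
        if col not in df.columns:
            raise SchemaError(f"report missing mandatory column {col!r}")
    bad_rows: list[tuple[int, str]] = []

    def _flag(mask: pd.Series, message: str) -> None:
        for i in df.index[mask][:5]:
            bad_rows.append((int(i) + 2, message))  # +2: header + 1-based

    # parse each distinct modified sequence once
    stripped_of: dict[str, str] = {}
    bad_seqs: dict[str, str] = {}
    for modseq in df[dialect.modified_sequence].dropna().unique():
        try:
            stripped_of[modseq], _ = parse_modified_sequence(modseq)
        except (ValidationError, TypeError) as exc:
            bad_seqs[modseq] = str(exc)
    if bad_seqs:
        mask = df[dialect.modified_sequence].isin(bad_seqs)
        _flag(mask, "unparseable modified sequence")
    stripped = df[dialect.modified_sequence].map(stripped_of)
    if dialect.stripped_sequence in df.columns:
        stated = df[dialect.stripped_sequence]
        mismatch = stated.notna() & (stated != "") & (stated != stripped)
        _flag(mismatch, "stated stripped sequence inconsistent")
    numeric = {}
    for name, col in (
        ("q", dialect.q_value),
        ("intensity", dialect.intensity),
        ("rt", dialect.rt),
        ("im", dialect.ion_mobility),
        ("charge", dialect.charge),
    ):
        numeric[name] = pd.to_numeric(df[col], errors="coerce")
        _flag(numeric[name].isna(), f"non-numeric {col}")
    _flag(
        (numeric["q"] < 0) | (numeric["q"] > 1), "q-value outside [0,1]"
    )
    _flag(numeric["intensity"] < 0, "negative intensity")
    n_bad = (
        df[dialect.modified_sequence].isin(bad_seqs)
        | stripped.isna()
        | sum(numeric[n].isna() for n in numeric).astype(bool)
        | (numeric["q"] < 0)
        | (numeric["q"] > 1)
        | (numeric["intensity"] < 0)
    )
    if dialect.stripped_sequence in df.columns:
        n_bad |= mismatch
    if n_bad.any():
        preview = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:5])
        raise SchemaError(
            f"{int(n_bad.sum())} malformed report rows ({preview})"
        )

    keep = numeric["q"] <= q_threshold
    n_filtered = int((~keep).sum())
    has_group = dialect.group in df.columns
    has_genes = dialect.genes in df.columns
    groups = (
        df[dialect.group].fillna("") if has_group else pd.Series("", index=df.index)
    )
    genes = (
        df[dialect.genes].fillna("") if has_genes else pd.Series("", index=df.index)
    )
    acc_cache: dict[str, tuple[str, ...]] = {}

    def _split(ids: str) -> tuple[str, ...]:
        if ids not in acc_cache:
            acc_cache[ids] = tuple(a for a in str(ids).split(";") if a)
        return acc_cache[ids]

    observations = [
        PrecursorObservation(
            run_id=run,
            group=group,
            modified_sequence=modseq,
            stripped_sequence=strp,
            charge=int(charge),
            q_value=float(q),
            rt=float(rt),
            ion_mobility=float(im),
            intensity=float(intensity),
            accessions=_split(ids),
            gene=gene,
        )
        for run, group, modseq, strp, charge, q, rt, im, intensity, ids, gene
        in zip(
            df.loc[keep, dialect.run],
            groups[keep],
            df.loc[keep, dialect.modified_sequence],
            stripped[keep],
            numeric["charge"][keep],
            numeric["q"][keep],
            numeric["rt"][keep],
            numeric["im"][keep],
            numeric["intensity"][keep],
            df.loc[keep, dialect.protein_ids],
            genes[keep],
        )
    ]
    logger.info(
        "read_report: kept %d observations, filtered %d at q > %g",
        len(observations),
        n_filtered,
        q_threshold,
    )
    return observations


def _groups_of(observations: list[PrecursorObservation]) -> pd.Series:
    groups: dict[str, str] = {}
    for obs in observations:
        groups.setdefault(obs.run_id, obs.group)
    return pd.Series(groups, dtype=object)


def assemble_peptide_matrix(
    observations: list[PrecursorObservation],
) -> QuantMatrix:
    """Modified-peptide x sample matrix.

    The value is log2 of the summed intensity across charge states of the
    same modified peptide within a run; zero-intensity rows are treated as
    missing.
    """
    rows = [
        (obs.modified_sequence, obs.run_id, obs.intensity)
        for obs in observations
        if obs.intensity > 0
    ]
    if not rows:
        return QuantMatrix(pd.DataFrame(), pd.Series(dtype=object))
    df = pd.DataFrame(rows, columns=["feature", "sample", "intensity"])
    raw = df.pivot_table(
        index="feature", columns="sample", values="intensity", aggfunc="sum"
    )
    groups = _groups_of(observations)
    raw = raw.reindex(columns=list(groups.index))
    meta_rows = {}
    for obs in observations:
        if obs.modified_sequence not in meta_rows:
            meta_rows[obs.modified_sequence] = {
                "stripped_sequence": obs.stripped_sequence,
                "accessions": ";".join(obs.accessions),
                "gene": obs.gene,
                "is_modified": obs.is_modified,
                "is_sap": obs.is_sap,
            }
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return QuantMatrix(np.log2(raw), groups, meta.reindex(raw.index))


def assemble_protein_matrix(peptide_matrix: QuantMatrix) -> QuantMatrix:
    """Protein x sample matrix from a peptide matrix.

    Only unmodified, non-SAP peptides mapping to exactly one accession
    contribute to quantitation (shared peptides count for detection only).
    The protein value per run is log2 of the sum of its top-3 raw peptide
    intensities (all of them when fewer than 3).
    """
    meta = peptide_matrix.feature_meta
    usable = meta.index[
        (~meta["is_modified"])
        & (~meta["is_sap"])
        & (meta["accessions"].str.count(";") == 0)
        & (meta["accessions"] != "")
    ]
    raw = 2.0 ** peptide_matrix.values.loc[usable]
    accession = meta.loc[usable, "accessions"]

    def top3_sum(block: pd.DataFrame) -> pd.Series:
        arr = block.to_numpy()
        if arr.shape[0] > 3:
            arr = -np.sort(-arr, axis=0)[:3]  # NaN sorts last under -sort
        return pd.Series(np.nansum(arr, axis=0), index=block.columns)

    protein_raw = raw.groupby(accession).apply(top3_sum)
    protein_raw = protein_raw.where(protein_raw > 0)
    gene = (
        meta.loc[usable]
        .groupby(accession)["gene"]
        .agg(lambda g: g.iloc[0])
    )
    n_peptides = meta.loc[usable].groupby(accession).size()
    feature_meta = pd.DataFrame(
        {"gene": gene, "n_peptides": n_peptides}
    ).reindex(protein_raw.index)
    return QuantMatrix(
        np.log2(protein_raw), peptide_matrix.sample_groups, feature_meta
    )


def detected_proteins_per_sample(
    observations: list[PrecursorObservation],
) -> pd.DataFrame:
    """Per-sample distinct peptide and protein detection counts."""
    rows = []
    by_run: dict[str, tuple[set, set]] = {}
    for obs in observations:
        peps, prots = by_run.setdefault(obs.run_id, (set(), set()))
        peps.add(obs.stripped_sequence)
        prots.update(a for a in obs.accessions if SAP_TAG not in a.split("|"))
    for run, (peps, prots) in by_run.items():
        rows.append({"sample": run, "n_peptides": len(peps), "n_proteins": len(prots)})
    return pd.DataFrame(rows).set_index("sample")


def normalize_per_sample(matrix: QuantMatrix) -> QuantMatrix:
    """Median-center each sample, preserving the global median.

    The per-sample median of observed log2 values is subtracted and the
    global pre-normalization median added back, so within-sample value
    differences are untouched.  All-missing samples are left unshifted
    with a warning.
    """
    values = matrix.values
    global_median = np.nanmedian(values.to_numpy()) if values.size else 0.0
    sample_medians = values.median(axis=0, skipna=True)
    empty = sample_medians.index[sample_medians.isna()]
    if len(empty):
        logger.warning(
            "normalize_per_sample: %d all-missing samples left unshifted",
            len(empty),
        )
    shift = (global_median - sample_medians).fillna(0.0)
    return QuantMatrix(
        values.add(shift, axis=1), matrix.sample_groups, matrix.feature_meta
    )
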