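"""Ground-truth simulator of single-cell precursor reports.

Emulates the structure of a DIA search-engine main report for a
four-group single-cell design (one normal line, three cancer lines, 50
cells each by default): log2-normal protein abundance with group effects
and per-cell loading offsets, peptide intensity shares drawn once from a
symmetric Dirichlet, logistic abundance-dependent dropout, Gaussian RT /
ion-mobility jitter around fixed per-peptide centers, planted SAP
peptides restricted to carrier groups, planted histone / phosphosite
peptides, uniform q-values for true rows plus a configurable fraction of
decoy rows above the q threshold, and an optional treated condition that
scales selected histone marks (the EZH2-inhibitor design).

Everything flows from a single seed; two runs with the same config are
byte-identical, and every emitted row is traceable to the returned
:class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import ProteinRecord, cleavage_sites, digest
from .errors import ValidationError
from .fixtures import designated_fixtures
from .report_ingest import format_modified_sequence, ParsedModification
from .variant_db import SAPVariant, variant_peptides

# residue sampling weights for random sequences (~11% K+R combined,
# modest P so proline suppression is exercised)
_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWYKR"))
_WEIGHTS = np.array(
    [0.08, 0.02, 0.06, 0.07, 0.04, 0.07, 0.02, 0.05, 0.09, 0.02,
     0.04, 0.05, 0.04, 0.07, 0.05, 0.07, 0.01, 0.04, 0.06, 0.05]
)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()


@dataclass
class GroupSpec:
    name: str
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"group {self.name}: n_cells must be >= 1")


@dataclass
class SimulationConfig:
    """Knobs of the simulator; defaults are the study-like conditions."""

    seed: int = 0
    n_proteins: int = 1000
    protein_length_mean: float = 250.0
    protein_length_sd: float = 60.0
    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("NHC", 50),
            GroupSpec("HuCCT-1", 50),
            GroupSpec("RBE", 50),
            GroupSpec("EGI-1", 50),
        ]
    )
    normal_group: str = "NHC"
    # differential expression planted between cancer groups and the
    # normal group (log2 effect applied in every non-normal group)
    n_de_up: int = 30
    n_de_down: int = 30
    de_effect: float = 2.0
    # per-cancer-line private proteome shifts (distinct proteotypes;
    # ~10% of the proteome differs per line)
    n_line_specific: int = 100
    line_effect: float = 1.2
    # abundance model (log2 scale)
    base_mean: float = 13.0
    base_sd: float = 2.0
    noise_sd: float = 0.4
    cell_offset_sd: float = 0.3
    # housekeeping-flagged proteins: fraction and abundance boost
    housekeeping_fraction: float = 0.13
    housekeeping_boost: float = 1.5
    # logistic dropout on log2 peptide intensity
    dropout_midpoint: float = 10.0
    dropout_slope: float = 1.0
    # chromatography / mobility
    rt_min: float = 5.0
    rt_max: float = 35.0
    rt_jitter_sd: float = 0.6       # minutes
    im_min: float = 0.7
    im_max: float = 1.3
    im_jitter_sd: float = 0.017     # 1/K0
    # quant peptide bounds
    min_peptide_length: int = 7
    max_peptide_length: int = 30
    # planted variant and PTM behaviour
    variant_detect_prob: float = 0.9
    ptm_detect_prob: float = 0.8
    ptm_stoichiometry: float = 0.25
    phospho_detect_prob: float = 0.3
    # histone activity design: activating marks scaled up in "active" cells
    active_cell_fraction: float = 0.5
    active_multiplier: float = 4.0
    # treated-condition mark scaling, e.g. {"treated": {"K27me3": 0.4}}
    treatment_mark_multipliers: dict = field(default_factory=dict)
    # decoy rows above the q threshold
    decoy_fraction: float = 0.05
    q_threshold: float = 0.01

    def validate(self) -> None:
        for prob in (
            self.variant_detect_prob,
            self.ptm_detect_prob,
            self.phospho_detect_prob,
            self.active_cell_fraction,
            self.decoy_fraction,
            self.housekeeping_fraction,
        ):
            if not 0 <= prob <= 1:
                raise ValidationError(f"probability {prob} outside [0, 1]")
        if not 0 < self.ptm_stoichiometry <= 1:
            raise ValidationError("stoichiometry must be in (0, 1]")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate group names")


def nucleus_config(seed: int = 0) -> SimulationConfig:
    """Single-nucleus treatment design: 15 control vs 15 treated nuclei,
    K27me3 scaled to 40% in the treated condition, total H3 untouched."""
    return SimulationConfig(
        seed=seed,
        n_proteins=300,
        groups=[GroupSpec("control", 15), GroupSpec("treated", 15)],
        normal_group="control",
        n_de_up=0,
        n_de_down=0,
        n_line_specific=0,
        active_cell_fraction=0.0,
        treatment_mark_multipliers={"treated": {"K27me3": 0.4}},
    )


#: (gene, site position, residue, mod label, UniMod shorthand) planted on
#: the designated fixtures.  H3 marks cover the activity-ratio vocabulary;
#: NCL sites mirror the printed nucleolin phosphosites.
HISTONE_MARKS = [
    ("H3-1", 14, "K", "K14ac", "ac"),
    ("H3-1", 23, "K", "K23ac", "ac"),
    ("H3-1", 79, "K", "K79me", "me"),
    ("H3-1", 79, "K", "K79me2", "me2"),
    ("H3-1", 27, "K", "K27me", "me"),
    ("H3-1", 27, "K", "K27me2", "me2"),
    ("H3-1", 27, "K", "K27me3", "me3"),
    ("H3-1", 79, "K", "K79fo", "fo"),
]
ACTIVATING_LABELS = {"K79me", "K79me2", "K14ac", "K23ac"}
NCL_PHOSPHOSITES = [
    ("NCL", 67, "S", "S67", "phospho"),
    ("NCL", 76, "T", "T76", "phospho"),
    ("NCL", 121, "T", "T121", "phospho"),
    ("NCL", 563, "S", "S563", "phospho"),
]


@dataclass
class GroundTruth:
    """Everything planted by :func:`simulate_cells`."""

    config: SimulationConfig
    accessions: list[str]
    genes: list[str]
    base_abundance: pd.Series            # log2, per accession
    group_effects: pd.DataFrame          # accession x group, log2
    de_labels: pd.Series                 # up / down / "" per accession
    housekeeping_genes: list[str]
    cell_groups: pd.Series               # run_id -> group
    cell_offsets: pd.Series              # run_id -> log2 offset
    variant_carriers: dict[str, list[str]]   # variant label -> groups
    variant_peptide_seqs: dict[str, str]     # variant label -> peptide
    wt_peptide_seqs: dict[str, str]          # variant label -> WT peptide
    active_cells: list[str]
    rt_centers: pd.Series                # peptide -> minutes
    im_centers: pd.Series                # peptide -> 1/K0
    n_true_rows: int = 0
    n_decoy_rows: int = 0
    mark_events: pd.DataFrame | None = None  # cell x mark detection truth

    def abundance(self, accession: str, group: str) -> float:
        return float(
            self.base_abundance[accession]
            + self.group_effects.at[accession, group]
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=_WEIGHTS))


def generate_reference_db(
    config: SimulationConfig,
) -> list[ProteinRecord]:
    """Random reference proteins plus the four designated fixtures.

    Sequences use residue frequencies with ~11% combined K/R so that
    tryptic peptides of 7-30 residues dominate.  Deterministic for a
    given config seed; ``n_proteins=0`` yields only the fixtures.
    """
    rng = np.random.default_rng(config.seed)
    proteins = []
    lengths = np.clip(
        rng.normal(
            config.protein_length_mean,
            config.protein_length_sd,
            size=config.n_proteins,
        ),
        80,
        800,
    ).astype(int)
    for i in range(config.n_proteins):
        proteins.append(
            ProteinRecord(
                accession=f"SYNP{i + 1:04d}",
                gene=f"GENE{i + 1:04d}",
                description=f"synthetic protein {i + 1} GN=GENE{i + 1:04d}",
                sequence=_random_sequence(rng, lengths[i]),
            )
        )
    return proteins + designated_fixtures()


def generate_variants(
    config: SimulationConfig, proteins: list[ProteinRecord]
) -> list[SAPVariant]:
    """Planted SAP variants with guaranteed-valid reference residues.

    Always includes the KRAS-like G12D (carriers HuCCT-1 and EGI-1 when
    present) and the CCT8-like A488T (carrier RBE when present), plus two
    variants on random proteins, one of which removes a cleavage site
    (R -> T) to exercise window changes.
    """
    rng = np.random.default_rng(config.seed + 1)
    by_acc = {p.accession: p for p in proteins}
    group_names = [g.name for g in config.groups]
    cancer = [g for g in group_names if g != config.normal_group]

    def pick_groups(wanted: list[str]) -> frozenset[str]:
        present = [g for g in wanted if g in group_names]
        return frozenset(present or cancer[:1] or group_names[:1])

    variants = [
        SAPVariant(
            "KRAS_SYN", 12, "G", "D", gene="KRAS",
            groups=pick_groups(["HuCCT-1", "EGI-1"]),
        ),
        SAPVariant(
            "CCT8_SYN", 488, "A", "T", gene="CCT8",
            groups=pick_groups(["RBE"]),
        ),
    ]
    randoms = [p for p in proteins if p.accession.startswith("SYNP")]
    rng.shuffle(randoms)
    # one substitution that removes a cleavage site (R -> T)
    for protein in randoms:
        sites = [
            p for p in cleavage_sites(protein.sequence)
            if protein.sequence[p - 1] == "R" and 10 < p < len(protein) - 10
        ]
        if sites:
            pos = int(sites[len(sites) // 2])
            variants.append(
                SAPVariant(
                    protein.accession, pos, "R", "T", gene=protein.gene,
                    groups=pick_groups(cancer[:1]),
                )
            )
            break
    # one plain substitution away from any site
    for protein in randoms:
        if protein.accession in {v.accession for v in variants}:
            continue
        seq = protein.sequence
        inner = [
            i for i in range(10, len(seq) - 10)
            if seq[i] not in "KRPXU" and seq[i] != "L"
        ]
        if inner:
            pos = inner[len(inner) // 2] + 1
            variants.append(
                SAPVariant(
                    protein.accession, pos, seq[pos - 1], "L",
                    gene=protein.gene, groups=pick_groups(cancer[-1:]),
                )
            )
            break
    for v in variants:
        assert by_acc[v.accession].sequence[v.position - 1] == v.ref
    return variants


def _shortest_site_peptide(protein: ProteinRecord, position: int):
    """Shortest tryptic peptide (mc <= 2, length 4-30) covering a site."""
    candidates = [
        p
        for p in digest(protein, 2, 4, 30)
        if p.covers(position)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (len(p.sequence), p.start))


def _mark_modified_sequence(
    protein: ProteinRecord, position: int, shorthand: str
) -> tuple[str, str]:
    """(modified sequence, stripped sequence) of a planted mark peptide."""
    pep = _shortest_site_peptide(protein, position)
    if pep is None:
        raise ValidationError(
            f"{protein.accession}: no peptide covers position {position}"
        )
    mod = ParsedModification(
        peptide_position=position - pep.start + 1,
        mod_type=shorthand,
        residue=protein.sequence[position - 1],
    )
    return format_modified_sequence(pep.sequence, [mod]), pep.sequence


def simulate_cells(
    config: SimulationConfig,
    proteins: list[ProteinRecord] | None = None,
    variants: list[SAPVariant] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format precursor report with ground truth.

    Returns ``(report, truth)`` where ``report`` is a DataFrame in the
    default :class:`~scpepkit.report_ingest.ReportDialect` column layout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    if proteins is None:
        proteins = generate_reference_db(config)
    if variants is None:
        variants = generate_variants(config, proteins)
    by_acc = {p.accession: p for p in proteins}
    for v in variants:
        if v.accession not in by_acc:
            raise ValidationError(
                f"variant on unknown protein {v.accession}"
            )

    accessions = [p.accession for p in proteins]
    genes = [p.gene for p in proteins]
    n_prot = len(proteins)
    group_names = [g.name for g in config.groups]
    cancer_groups = [g for g in group_names if g != config.normal_group]

    # ---- abundance model -------------------------------------------------
    base = rng.normal(config.base_mean, config.base_sd, size=n_prot)
    hk_flags = rng.random(n_prot) < config.housekeeping_fraction
    base = base + hk_flags * config.housekeeping_boost
    # designated fixtures kept comfortably detectable
    for acc in ("KRAS_SYN", "CCT8_SYN", "H31_SYN", "NCL_SYN"):
        idx = accessions.index(acc)
        base[idx] = max(base[idx], config.base_mean + 1.0)

    effects = pd.DataFrame(
        0.0, index=accessions, columns=group_names
    )
    de_labels = pd.Series("", index=accessions, dtype=object)
    # DE proteins drawn from the upper half of base abundance so that
    # down-regulated proteins stay quantifiable in the cancer groups
    eligible = [
        i for i in np.argsort(-base)
        if accessions[i].startswith("SYNP")
    ]
    n_de = config.n_de_up + config.n_de_down
    if n_de > len(eligible):
        raise ValidationError(
            f"{n_de} DE proteins requested but only {len(eligible)} "
            "random proteins available"
        )
    de_pool = eligible[: max(2 * n_de, n_de)]
    de_idx = rng.choice(len(de_pool), size=n_de, replace=False) if n_de else []
    chosen = [de_pool[i] for i in de_idx]
    for k, i in enumerate(chosen):
        sign = 1.0 if k < config.n_de_up else -1.0
        for g in cancer_groups:
            effects.iloc[i, effects.columns.get_loc(g)] = sign * config.de_effect
        de_labels.iloc[i] = "up" if sign > 0 else "down"
    # line-specific shifts on separate proteins
    remaining = [i for i in eligible if i not in set(chosen)]
    cursor = 0
    for g in cancer_groups:
        for _ in range(config.n_line_specific):
            if cursor >= len(remaining):
                break
            i = remaining[cursor]
            cursor += 1
            effects.iloc[i, effects.columns.get_loc(g)] = (
                config.line_effect if cursor % 2 else -config.line_effect
            )

    # ---- cells -----------------------------------------------------------
    cells, cell_groups = [], []
    for group in config.groups:
        for j in range(group.n_cells):
            cells.append(f"{group.name}_c{j + 1:03d}")
            cell_groups.append(group.name)
    n_cells = len(cells)
    cell_groups = pd.Series(cell_groups, index=cells)
    offsets = pd.Series(
        rng.normal(0.0, config.cell_offset_sd, size=n_cells), index=cells
    )
    group_col = np.array(
        [group_names.index(g) for g in cell_groups], dtype=int
    )

    # protein x cell log2 abundance
    abundance = (
        base[:, None]
        + effects.to_numpy()[:, group_col]
        + offsets.to_numpy()[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_prot, n_cells))
    )

    # ---- peptide table ---------------------------------------------------
    pep_protein_idx: list[int] = []
    pep_seqs: list[str] = []
    pep_shares: list[float] = []
    for i, protein in enumerate(proteins):
        peps = digest(
            protein, 0, config.min_peptide_length, config.max_peptide_length
        )
        if not peps:
            continue
        shares = rng.dirichlet(np.ones(len(peps)))
        for pep, share in zip(peps, shares):
            pep_protein_idx.append(i)
            pep_seqs.append(pep.sequence)
            pep_shares.append(share)
    pep_protein_idx = np.array(pep_protein_idx)
    pep_shares = np.array(pep_shares)
    n_pep = len(pep_seqs)
    # shared peptide sequences (e.g. repeated filler units of the fixture
    # proteins) carry all parent accessions, the way a search engine
    # reports ambiguous precursors; ingest excludes them from protein
    # quantitation while still counting them for detection
    seq_owner_idx: dict[str, set[int]] = {}
    for idx, seq in zip(pep_protein_idx, pep_seqs):
        seq_owner_idx.setdefault(seq, set()).add(int(idx))
    pep_protein_ids = [
        ";".join(sorted(accessions[i] for i in seq_owner_idx[seq]))
        for seq in pep_seqs
    ]
    pep_genes = [
        ";".join(sorted({genes[i] for i in seq_owner_idx[seq]}))
        for seq in pep_seqs
    ]
    rt_centers = rng.uniform(config.rt_min, config.rt_max, size=n_pep)
    im_centers = rng.uniform(config.im_min, config.im_max, size=n_pep)
    charges = rng.choice([2, 3], size=n_pep)

    # ---- detection and emission (vectorized) -----------------------------
    log2_int = abundance[pep_protein_idx, :] + np.log2(pep_shares)[:, None]
    prob = 1.0 / (
        1.0
        + np.exp(
            -(log2_int - config.dropout_midpoint) / config.dropout_slope
        )
    )
    detected = rng.random(size=prob.shape) < prob
    pep_i, cell_i = np.nonzero(detected)

    cells_arr = np.array(cells, dtype=object)
    groups_arr = cell_groups.to_numpy()
    pep_seq_arr = np.array(pep_seqs, dtype=object)
    columns = {
        "Run": cells_arr[cell_i],
        "Group": groups_arr[cell_i],
        "Modified.Sequence": pep_seq_arr[pep_i],
        "Stripped.Sequence": pep_seq_arr[pep_i],
        "Precursor.Charge": charges[pep_i],
        "Q.Value": rng.uniform(0.0, config.q_threshold, size=pep_i.size),
        "RT": rt_centers[pep_i]
        + rng.normal(0.0, config.rt_jitter_sd, size=pep_i.size),
        "IM": im_centers[pep_i]
        + rng.normal(0.0, config.im_jitter_sd, size=pep_i.size),
        "Precursor.Quantity": 2.0 ** log2_int[pep_i, cell_i],
        "Protein.Ids": np.array(pep_protein_ids, dtype=object)[pep_i],
        "Genes": np.array(pep_genes, dtype=object)[pep_i],
    }
    frames = [pd.DataFrame(columns)]
    rt_center_map = dict(zip(pep_seqs, rt_centers))
    im_center_map = dict(zip(pep_seqs, im_centers))

    def _emit(
        run: str,
        modseq: str,
        stripped: str,
        intensity: float,
        protein_id: str,
        gene: str,
        charge: int = 2,
    ) -> dict:
        if stripped not in rt_center_map:
            rt_center_map[stripped] = float(
                rng.uniform(config.rt_min, config.rt_max)
            )
            im_center_map[stripped] = float(
                rng.uniform(config.im_min, config.im_max)
            )
        return {
            "Run": run,
            "Group": cell_groups[run],
            "Modified.Sequence": modseq,
            "Stripped.Sequence": stripped,
            "Precursor.Charge": charge,
            "Q.Value": float(rng.uniform(0.0, config.q_threshold)),
            "RT": rt_center_map[stripped]
            + float(rng.normal(0.0, config.rt_jitter_sd)),
            "IM": im_center_map[stripped]
            + float(rng.normal(0.0, config.im_jitter_sd)),
            "Precursor.Quantity": float(intensity),
            "Protein.Ids": protein_id,
            "Genes": gene,
        }

    # ---- planted variants ------------------------------------------------
    carrier_map: dict[str, list[str]] = {}
    variant_seq: dict[str, str] = {}
    wt_seq: dict[str, str] = {}
    extra_rows: list[dict] = []
    for variant in variants:
        protein = by_acc[variant.accession]
        entries = variant_peptides(protein, variant)
        if not entries:
            continue
        entry = min(entries, key=lambda e: len(e.peptide.sequence))
        label = f"{variant.gene or variant.accession} {variant.label}"
        carrier_map[label] = sorted(variant.groups)
        variant_seq[label] = entry.peptide.sequence
        wt_seq[label] = (
            entry.wt_counterpart.sequence if entry.wt_counterpart else ""
        )
        prot_idx = accessions.index(variant.accession)
        for c, run in enumerate(cells):
            if cell_groups[run] not in variant.groups:
                continue
            if rng.random() >= config.variant_detect_prob:
                continue
            intensity = 2.0 ** (abundance[prot_idx, c] - 2.0)
            extra_rows.append(
                _emit(
                    run,
                    entry.peptide.sequence,
                    entry.peptide.sequence,
                    intensity,
                    f"{variant.accession}|{variant.tag}|sap",
                    variant.gene or protein.gene,
                )
            )

    # ---- planted PTMs ----------------------------------------------------
    active_cells = []
    if config.active_cell_fraction > 0:
        mask = rng.random(n_cells) < config.active_cell_fraction
        active_cells = [cells[c] for c in range(n_cells) if mask[c]]
    active_set = set(active_cells)
    mark_rows = []
    gene_to_acc = {p.gene: p.accession for p in proteins}
    for gene, position, residue, label, shorthand in HISTONE_MARKS:
        protein = by_acc[gene_to_acc[gene]]
        modseq, stripped = _mark_modified_sequence(
            protein, position, shorthand
        )
        prot_idx = accessions.index(protein.accession)
        for c, run in enumerate(cells):
            if rng.random() >= config.ptm_detect_prob:
                mark_rows.append(
                    {"cell": run, "mark": label, "detected": False}
                )
                continue
            stoich = config.ptm_stoichiometry
            if label in ACTIVATING_LABELS and run in active_set:
                stoich *= config.active_multiplier
            mults = config.treatment_mark_multipliers.get(
                cell_groups[run], {}
            )
            stoich *= mults.get(label, 1.0)
            intensity = stoich * 2.0 ** abundance[prot_idx, c]
            extra_rows.append(
                _emit(
                    run, modseq, stripped, intensity,
                    protein.accession, protein.gene,
                )
            )
            mark_rows.append({"cell": run, "mark": label, "detected": True})
    for gene, position, residue, label, shorthand in NCL_PHOSPHOSITES:
        protein = by_acc[gene_to_acc[gene]]
        modseq, stripped = _mark_modified_sequence(
            protein, position, shorthand
        )
        prot_idx = accessions.index(protein.accession)
        for c, run in enumerate(cells):
            if rng.random() >= config.phospho_detect_prob:
                continue
            intensity = config.ptm_stoichiometry * 2.0 ** abundance[
                prot_idx, c
            ]
            extra_rows.append(
                _emit(
                    run, modseq, stripped, intensity,
                    protein.accession, protein.gene,
                )
            )

    if extra_rows:
        frames.append(pd.DataFrame(extra_rows))
    report = pd.concat(frames, ignore_index=True)
    n_true = len(report)

    # ---- decoys above the q threshold ------------------------------------
    n_decoy = int(round(config.decoy_fraction * n_true))
    if n_decoy:
        picks = rng.choice(n_true, size=n_decoy, replace=True)
        decoys = report.iloc[picks].copy().reset_index(drop=True)
        decoys["Q.Value"] = rng.uniform(
            config.q_threshold + 1e-6, 0.5, size=n_decoy
        )
        report = pd.concat([report, decoys], ignore_index=True)

    truth = GroundTruth(
        config=config,
        accessions=accessions,
        genes=genes,
        base_abundance=pd.Series(base, index=accessions),
        group_effects=effects,
        de_labels=de_labels,
        housekeeping_genes=[genes[i] for i in np.nonzero(hk_flags)[0]],
        cell_groups=cell_groups,
        cell_offsets=offsets,
        variant_carriers=carrier_map,
        variant_peptide_seqs=variant_seq,
        wt_peptide_seqs=wt_seq,
        active_cells=active_cells,
        rt_centers=pd.Series(rt_center_map),
        im_centers=pd.Series(im_center_map),
        n_true_rows=n_true,
        n_decoy_rows=n_decoy,
        mark_events=pd.DataFrame(mark_rows) if mark_rows else None,
    )
    return report, truth


def expected_proteins_per_cell(
    config: SimulationConfig, proteins: list[ProteinRecord]
) -> float:
    """Analytic expectation of the per-cell detected-protein count.

    Evaluates the logistic dropout curve at each peptide's expected log2
    intensity (base abundance + log2 share, noise ignored) and combines
    peptides per protein as 1 - prod(1 - p).  The simulator's empirical
    mean should sit near this value.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_prot = len(proteins)
    base = rng.normal(config.base_mean, config.base_sd, size=n_prot)
    hk = rng.random(n_prot) < config.housekeeping_fraction
    base = base + hk * config.housekeeping_boost
    accs = [p.accession for p in proteins]
    for acc in ("KRAS_SYN", "CCT8_SYN", "H31_SYN", "NCL_SYN"):
        if acc in accs:
            i = accs.index(acc)
            base[i] = max(base[i], config.base_mean + 1.0)
    total = 0.0
    for i, protein in enumerate(proteins):
        peps = digest(
            protein, 0, config.min_peptide_length, config.max_peptide_length
        )
        if not peps:
            continue
        shares = rng.dirichlet(np.ones(len(peps)))
        log2_int = base[i] + np.log2(shares)
        p = 1.0 / (
            1.0
            + np.exp(
                -(log2_int - config.dropout_midpoint) / config.dropout_slope
            )
        )
        total += 1.0 - np.prod(1.0 - p)
    return total


def write_report(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a report readable by ``report_ingest.read_report``.

    Values round-trip to 6 significant digits.
    """
    try:
        rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:  # pragma: no cover - environment dependent
        from .errors import IOFailure

        raise IOFailure(str(exc)) from exc


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ground truth as JSON (for manifests/debugging)."""
    payload = {
        "config": asdict(truth.config),
        "de_labels": {
            k: v for k, v in truth.de_labels.items() if v
        },
        "housekeeping_genes": truth.housekeeping_genes,
        "variant_carriers": truth.variant_carriers,
        "variant_peptide_seqs": truth.variant_peptide_seqs,
        "wt_peptide_seqs": truth.wt_peptide_seqs,
        "active_cells": truth.active_cells,
        "cell_groups": truth.cell_groups.to_dict(),
        "n_true_rows": truth.n_true_rows,
        "n_decoy_rows": truth.n_decoy_rows,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_interactome(
    proteins: list[ProteinRecord],
    n_edges: int = 2000,
    kinase_fraction: float = 0.12,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Random BioGRID-style edge list plus a kinase list.

    Kinases get extra hub edges so kinase-anchored subnetworks are
    non-trivial.  Returns ``(edge table, kinase gene list)``.
    """
    rng = np.random.default_rng(seed + 3)
    gene_list = sorted({p.gene for p in proteins if p.gene})
    n = len(gene_list)
    n_kin = max(1, int(kinase_fraction * n))
    kinases = sorted(rng.choice(gene_list, size=n_kin, replace=False))
    kinase_set = set(kinases)
    n_edges = min(n_edges, n * (n - 1) // 2)
    edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(edges) < n_edges // 2 and attempts < 30 * n_edges:
        a, b = rng.choice(n, size=2, replace=False)
        a, b = gene_list[a], gene_list[b]
        edges.add((min(a, b), max(a, b)))
        attempts += 1
    # kinase hub edges fill the remainder (bounded by what exists)
    kinase_pairs = [
        (min(a, b), max(a, b))
        for a in kinases
        for b in gene_list
        if a != b
    ]
    rng.shuffle(kinase_pairs)
    for pair in kinase_pairs:
        if len(edges) >= n_edges:
            break
        edges.add(tuple(pair))
    table = pd.DataFrame(
        sorted(edges),
        columns=[
            "Official Symbol Interactor A",
            "Official Symbol Interactor B",
        ],
    )
    return table, list(kinases)
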