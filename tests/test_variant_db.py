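"""Variant database construction: windowing rule, FASTA assembly,
detection patterns."""

import numpy as np
import pandas as pd
import pytest

from scpepkit.digestion import ProteinRecord
from scpepkit.errors import ReferenceMismatchError, SchemaError, ValidationError
from scpepkit.fixtures import cct8_like, kras_like
from scpepkit.report_ingest import PrecursorObservation
from scpepkit.variant_db import (
    SAPVariant,
    apply_variant,
    build_augmented_fasta,
    read_snv_table,
    sap_detection_pattern,
    variant_peptides,
)

from conftest import brute_force_variant_peptides, random_sequence


def _obs(run, group, stripped, acc="X", intensity=100.0):
    return PrecursorObservation(
        run_id=run, group=group, modified_sequence=stripped,
        stripped_sequence=stripped, charge=2, q_value=0.001,
        rt=10.0, ion_mobility=1.0, intensity=intensity,
        accessions=(acc,), gene="",
    )


class TestApplyVariant:
    def test_single_point_edit(self):
        kras = kras_like()
        mutated = apply_variant(kras, SAPVariant("KRAS_SYN", 12, "G", "D"))
        assert mutated.sequence[11] == "D"
        diffs = [
            i for i, (a, b) in enumerate(zip(kras.sequence, mutated.sequence))
            if a != b
        ]
        assert diffs == [11]
        assert mutated.accession == "KRAS_SYN|p12GD"

    def test_plain_substitution(self, toy_protein):
        mutated = apply_variant(toy_protein, SAPVariant("TOY1", 3, "C", "S"))
        assert mutated.sequence == "AKSKR"

    def test_reference_mismatch_raises(self, toy_protein):
        with pytest.raises(ReferenceMismatchError):
            apply_variant(toy_protein, SAPVariant("TOY1", 3, "A", "S"))

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValidationError):
            SAPVariant("X", 1, "G", "G")


class TestVariantPeptides:
    def test_kras_g12d_emits_printed_peptide(self):
        entries = variant_peptides(
            kras_like(), SAPVariant("KRAS_SYN", 12, "G", "D"), 7, 45
        )
        sequences = {e.peptide.sequence for e in entries}
        assert "LVVVGADGVGK" in sequences
        wt = {
            e.wt_counterpart.sequence
            for e in entries
            if e.peptide.sequence == "LVVVGADGVGK"
        }
        assert wt == {"LVVVGAGGVGK"}

    def test_cct8_a488t_emits_printed_peptide(self):
        entries = variant_peptides(
            cct8_like(), SAPVariant("CCT8_SYN", 488, "A", "T"), 7, 45
        )
        assert "NVGLDIEAEVPTVK" in {e.peptide.sequence for e in entries}

    def test_no_cleavage_sites_whole_sequence(self):
        protein = ProteinRecord(accession="P", sequence="AAACAAA")
        entries = variant_peptides(
            protein, SAPVariant("P", 4, "C", "S"), 1, 30
        )
        assert [e.peptide.sequence for e in entries] == ["AAASAAA"]
        assert entries[0].peptide.missed_cleavages == 0

    def test_every_entry_contains_alt_residue(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, 60)
            protein = ProteinRecord(accession="P", sequence=seq)
            pos = int(rng.integers(1, 61))
            ref = seq[pos - 1]
            alt = "W" if ref != "W" else "G"
            for entry in variant_peptides(
                protein, SAPVariant("P", pos, ref, alt), 1, 60
            ):
                offset = pos - entry.peptide.start
                assert entry.peptide.sequence[offset] == alt
                assert entry.peptide.missed_cleavages <= 2

    def test_matches_brute_force_set(self, rng):
        """Emitted peptide strings equal exhaustive enumeration, including
        substitutions that create or destroy cleavage sites."""
        forced_alts = ["K", "R", "P", "T", "W"]
        for trial in range(20):
            seq = random_sequence(rng, int(rng.integers(20, 70)))
            protein = ProteinRecord(accession="P", sequence=seq)
            pos = int(rng.integers(1, len(seq) + 1))
            ref = seq[pos - 1]
            alt = forced_alts[trial % len(forced_alts)]
            if alt == ref:
                alt = "H" if ref != "H" else "Y"
            got = {
                e.peptide.sequence
                for e in variant_peptides(
                    protein, SAPVariant("P", pos, ref, alt), 1, 70
                )
            }
            assert got == brute_force_variant_peptides(seq, pos, alt, 1, 70)

    def test_site_loss_widens_window(self):
        # R at position 4 is a site; R->T merges the flanking peptides
        protein = ProteinRecord(accession="P", sequence="AAKARAAAKAAR")
        entries = variant_peptides(
            protein, SAPVariant("P", 5, "R", "T"), 1, 30
        )
        assert "ATAAAK" in {e.peptide.sequence for e in entries}


class TestBuildAugmentedFasta:
    def test_zero_variants_is_identity(self, toy_protein):
        from scpepkit.digestion import format_fasta

        text, mapping = build_augmented_fasta([toy_protein], [])
        assert text == format_fasta([toy_protein])
        assert mapping.empty

    def test_kras_mapping_row(self):
        text, mapping = build_augmented_fasta(
            [kras_like()],
            [SAPVariant("KRAS_SYN", 12, "G", "D", gene="KRAS")],
        )
        row = mapping[mapping["peptide"] == "LVVVGADGVGK"]
        assert len(row) == 1
        assert row.iloc[0][["accession", "position", "ref", "alt"]].tolist() \
            == ["KRAS_SYN", 12, "G", "D"]
        assert "LVVVGADGVGK" in text
        assert text.startswith(">KRAS_SYN ")

    def test_appended_count_matches_brute_force(self, rng):
        proteins, variants, expected = [], [], 0
        for i in range(5):
            seq = random_sequence(rng, 50)
            proteins.append(
                ProteinRecord(accession=f"P{i}", sequence=seq)
            )
        for i in range(3):
            seq = proteins[i].sequence
            pos = int(rng.integers(5, 45))
            ref = seq[pos - 1]
            alt = "N" if ref != "N" else "Q"
            variants.append(SAPVariant(f"P{i}", pos, ref, alt))
            mutated = seq[: pos - 1] + alt + seq[pos:]
            from conftest import brute_force_digest

            expected += sum(
                1
                for pep, start, end, mc in brute_force_digest(
                    mutated, 2, 7, 45
                )
                if start <= pos <= end
            )
        _, mapping = build_augmented_fasta(proteins, variants, 7, 45)
        assert len(mapping) == expected

    def test_unknown_accession_reported(self, toy_protein):
        with pytest.raises(ValidationError, match="GHOST"):
            build_augmented_fasta(
                [toy_protein], [SAPVariant("GHOST", 1, "A", "C")]
            )

    def test_whole_protein_mode(self, toy_protein):
        text, mapping = build_augmented_fasta(
            [toy_protein], [SAPVariant("TOY1", 3, "C", "S")],
            whole_protein=True,
        )
        assert "AKSKR" in text
        assert mapping.iloc[0]["peptide"] == "AKSKR"


class TestSnvTable:
    def test_round_trip_merges_carriers(self, tmp_path):
        path = tmp_path / "snv.tsv"
        pd.DataFrame(
            {
                "accession": ["KRAS_SYN", "KRAS_SYN", "CCT8_SYN"],
                "gene": ["KRAS", "KRAS", "CCT8"],
                "position": [12, 12, 488],
                "ref": ["G", "G", "A"],
                "alt": ["D", "D", "T"],
                "cell_line": ["HuCCT-1", "EGI-1", "RBE"],
            }
        ).to_csv(path, sep="\t", index=False)
        variants = read_snv_table(path)
        assert len(variants) == 2
        kras = next(v for v in variants if v.accession == "KRAS_SYN")
        assert kras.groups == frozenset({"HuCCT-1", "EGI-1"})

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "snv.tsv"
        pd.DataFrame({"accession": ["X"], "position": [1]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(SchemaError, match="ref"):
            read_snv_table(path)


class TestDetectionPattern:
    def _mapping(self):
        _, mapping = build_augmented_fasta(
            [kras_like()],
            [SAPVariant("KRAS_SYN", 12, "G", "D", gene="KRAS")],
        )
        return mapping

    def test_carrier_groups_only(self):
        mapping = self._mapping()
        groups = {"c1": "g1", "c2": "g2", "c3": "g3", "c4": "g1"}
        observations = [
            _obs("c1", "g1", "LVVVGADGVGK", "KRAS_SYN|p12GD|sap"),
            _obs("c4", "g1", "LVVVGADGVGK", "KRAS_SYN|p12GD|sap"),
            _obs("c3", "g3", "LVVVGADGVGK", "KRAS_SYN|p12GD|sap"),
            _obs("c2", "g2", "LVVVGAGGVGK", "KRAS_SYN"),
        ]
        pattern, summary = sap_detection_pattern(
            observations, mapping, groups
        )
        variant_row = pattern.loc["KRAS G12D (variant)"]
        assert variant_row[["c1", "c4", "c3"]].all()
        assert not variant_row["c2"]
        assert summary.loc["KRAS G12D (variant)", "g2"] == 0.0
        assert summary.loc["KRAS G12D (wt)", "g2"] == 1.0

    def test_empty_report_all_false(self):
        pattern, _ = sap_detection_pattern(
            [], self._mapping(), {"c1": "g1", "c2": "g2"}
        )
        assert not pattern.to_numpy().any()

    def test_wt_and_variant_co_detection(self):
        groups = {"c1": "g1"}
        observations = [
            _obs("c1", "g1", "LVVVGADGVGK", "KRAS_SYN|p12GD|sap"),
            _obs("c1", "g1", "LVVVGAGGVGK", "KRAS_SYN"),
        ]
        pattern, _ = sap_detection_pattern(
            observations, self._mapping(), groups
        )
        assert pattern.loc["KRAS G12D (variant)", "c1"]
        assert pattern.loc["KRAS G12D (wt)", "c1"]
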