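"""Synthetic designated fixture proteins used by the simulator and tests.

These are constructed stand-ins, not database sequences: each reproduces
only the local tryptic context required for its worked example (variant
peptide windows, histone mark coordinates, phosphosite coordinates) and
is filler elsewhere.  Accessions carry a ``_SYN`` suffix to make the
synthetic provenance explicit.

* KRAS-like — residues 1-17 give the tryptic peptide LVVVGAGGVGK
  (positions 6-16) whose G12D form is LVVVGADGVGK.
* CCT8-like — residues 477-490 give the tryptic peptide NVGLDIEAEVPAVK
  whose A488T form is NVGLDIEAEVPTVK.
* Histone-H3-like — lysines at mature-protein coordinates 14, 23, 27
  and 79, each inside a short tryptic peptide.
* Nucleolin-like — serine/threonine at coordinates 67, 76, 121 and 563,
  each inside a 20-residue tryptic peptide.
"""

from __future__ import annotations

from .digestion import ProteinRecord

# 20-residue tryptic filler unit (ends in K, starts with A so the
# preceding K is a valid cleavage site).
_UNIT = "AEGLNQSVDFHTAGELSVQK"


def kras_like() -> ProteinRecord:
    """Synthetic KRAS-like fixture (G12 context, 97 residues)."""
    seq = "MTEYKLVVVGAGGVGKS" + _UNIT * 4
    assert seq[11] == "G" and seq[4] == "K" and seq[15] == "K"
    return ProteinRecord(
        accession="KRAS_SYN",
        gene="KRAS",
        description="synthetic KRAS-like fixture GN=KRAS",
        sequence=seq,
    )


def cct8_like() -> ProteinRecord:
    """Synthetic CCT8-like fixture (A488 context, 503 residues)."""
    seq = _UNIT * 23 + "AGELSVQDNFHTSETR" + "NVGLDIEAEVPAVK" + "AGELSVQNDTFHK"
    assert len(seq) == 503 and seq[487] == "A" and seq[475] == "R"
    assert seq[476:490] == "NVGLDIEAEVPAVK"
    return ProteinRecord(
        accession="CCT8_SYN",
        gene="CCT8",
        description="synthetic CCT8-like fixture GN=CCT8",
        sequence=seq,
    )


def histone_h3_like() -> ProteinRecord:
    """Synthetic histone-H3-like fixture (mature coords, 136 residues).

    K14 sits in STGGK (10-14), K23 in QLATK (19-23), K27 in KSAPATGGVK
    (27-36) and K79 in EIAQDFK (73-79).
    """
    seq = (
        "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHR"  # 1-40
        "YVATESGALDQFNHEVSTAGLDNFQEAGVTLR"          # 41-72
        "EIAQDFK"                                   # 73-79
        "TDLNAGHEVSQFAEYLVSDGQALNHEFGVTSDLR"        # 80-113
        "QAGNEYVSTLFDHSAGELSVQNR"                   # 114-136
    )
    for pos in (14, 23, 27, 79):
        assert seq[pos - 1] == "K", pos
    return ProteinRecord(
        accession="H31_SYN",
        gene="H3-1",
        description="synthetic histone-H3-like fixture GN=H3-1",
        sequence=seq,
    )


def nucleolin_like() -> ProteinRecord:
    """Synthetic nucleolin-like fixture (S67/T76/T121/S563, 580 residues)."""
    seq = list(_UNIT * 29)
    for pos, residue in ((67, "S"), (76, "T"), (121, "T"), (563, "S")):
        seq[pos - 1] = residue
    seq = "".join(seq)
    return ProteinRecord(
        accession="NCL_SYN",
        gene="NCL",
        description="synthetic nucleolin-like fixture GN=NCL",
        sequence=seq,
    )


def designated_fixtures() -> list[ProteinRecord]:
    """The four fixture proteins bundled into every reference database."""
    return [kras_like(), cct8_like(), histone_h3_like(), nucleolin_like()]
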