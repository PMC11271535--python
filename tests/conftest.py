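"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths: digestion is
re-derived by substring enumeration, BH by an explicit step-up sweep, so
that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from scpepkit.digestion import ProteinRecord

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with elevated K/R/P to exercise cleavage rules."""
    pool = RESIDUES + "KKRRPP"
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=length))


def brute_force_digest(
    sequence: str, max_mc: int, min_len: int, max_len: int
) -> set[tuple[str, int, int, int]]:
    """Enumerate all substrings; keep valid tryptic peptides.

    A substring is a peptide when both boundaries are termini or cleavage
    sites and its internal cleavage-site count is within the budget.
    """
    sites = {
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in "KR" and sequence[p] != "P"
    }
    bounds = {0} | sites | {len(sequence)}
    out = set()
    for s in range(len(sequence)):
        for e in range(s + 1, len(sequence) + 1):
            if s in bounds and e in bounds:
                internal = sum(1 for p in sites if s < p < e)
                if internal <= max_mc and min_len <= e - s <= max_len:
                    out.add((sequence[s:e], s + 1, e, internal))
    return out


def brute_force_variant_peptides(
    sequence: str, position: int, alt: str, min_len: int, max_len: int
) -> set[str]:
    """All variant-containing tryptic peptides of the mutated sequence."""
    mutated = sequence[: position - 1] + alt + sequence[position:]
    return {
        pep
        for pep, start, end, mc in brute_force_digest(
            mutated, 2, min_len, max_len
        )
        if start <= position <= end
    }


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH: sort ascending, q_i = p_i * n / i, enforce monotone
    non-decreasing from the top rank down, cap at 1, restore order."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = min(running_min, 1.0)
    return q


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240719)


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord(accession="TOY1", gene="TOY1", sequence="AKCKR")
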