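"""Physicochemical summaries and per-column conservation statistics.

Molecular weight uses average (isotope-abundance weighted) residue masses
plus one water, the ProtParam convention.  The theoretical isoelectric
point is the bisection root of the Bjellqvist-model net charge (positive
terms: N-terminus, K, R, H; negative: C-terminus, D, E, C, Y); the charge
is strictly decreasing in pH so the root on [0, 14] is unique.
Conservation columns carry residue frequencies, information content
log2(20) - H (bits) and the modal consensus residue, the numbers behind a
sequence logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_scan import AA_ALPHABET

WATER_MASS = 18.0153

#: average residue masses in Daltons (ExPASy ProtParam convention)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Bjellqvist pKa set (ExPASy-compatible), swappable via function arguments
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

MAX_INFORMATION = math.log2(20.0)


@dataclass
class PhyschemRecord:
    gene_id: str
    length: int
    mw: float
    pi: float
    classification: str  # acidic (pi < 7) or basic (pi >= 7)


@dataclass
class ConservationColumn:
    position: int  # 1-based
    frequencies: dict[str, float]
    information: float
    consensus: str


def molecular_weight(protein: str, average_unknown_mass: float | None = None) -> float:
    """Average molecular weight in Daltons (residue masses + one water).

    Non-standard residues raise unless ``average_unknown_mass`` provides a
    stand-in mass (e.g. the mean residue mass for X).
    """
    if not protein:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for a in protein.upper():
        mass = RESIDUE_MASS.get(a)
        if mass is None:
            if average_unknown_mass is None:
                raise ValueError(f"non-standard residue {a!r}")
            mass = average_unknown_mass
        total += mass
    return total


def charge_at_ph(protein: str, ph: float,
                 pka_positive: dict | None = None,
                 pka_negative: dict | None = None) -> float:
    """Net charge of the peptide at the given pH under the Bjellqvist model."""
    pos = pka_positive or PKA_POSITIVE
    neg = pka_negative or PKA_NEGATIVE
    seq = protein.upper()
    charge = 1.0 / (1.0 + 10.0 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (neg["Cterm"] - ph))
    for a in seq:
        if a in pos:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pos[a]))
        elif a in neg:
            charge -= 1.0 / (1.0 + 10.0 ** (neg[a] - ph))
    return charge


def isoelectric_point(protein: str, tolerance: float = 1e-4,
                      pka_positive: dict | None = None,
                      pka_negative: dict | None = None) -> float:
    """pH at which the net charge vanishes (bisection on [0, 14])."""
    if not protein:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = charge_at_ph(protein, mid, pka_positive, pka_negative)
        if abs(c) < tolerance:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem_table(proteins: dict[str, str]) -> pd.DataFrame:
    """MW / pI / acid-base classification for a set of proteins."""
    rows = []
    for gene_id, seq in proteins.items():
        pi = isoelectric_point(seq)
        rows.append(
            PhyschemRecord(
                gene_id=gene_id,
                length=len(seq),
                mw=molecular_weight(seq),
                pi=pi,
                classification="acidic" if pi < 7.0 else "basic",
            )
        )
    return pd.DataFrame(
        [(r.gene_id, r.length, r.mw, r.pi, r.classification) for r in rows],
        columns=["gene_id", "length", "mw", "pi", "classification"],
    )


def conservation_profile(aligned_sequences: list[str]) -> list[ConservationColumn]:
    """Per-column residue frequencies, information content and consensus
    for a gap-free alignment (no pseudocount; ties by alphabetical order)."""
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValueError("aligned sequences must have equal lengths")
    n = len(aligned_sequences)
    columns = []
    for c in range(length):
        residues = [s[c].upper() for s in aligned_sequences]
        freqs: dict[str, float] = {}
        for a in residues:
            freqs[a] = freqs.get(a, 0.0) + 1.0 / n
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        consensus = min(freqs, key=lambda a: (-freqs[a], a))
        columns.append(
            ConservationColumn(
                position=c + 1,
                frequencies=freqs,
                information=MAX_INFORMATION - entropy,
                consensus=consensus,
            )
        )
    return columns


def conservation_table(columns: list[ConservationColumn]) -> pd.DataFrame:
    """Flatten ConservationColumns into a logo-ready table."""
    rows = []
    for col in columns:
        row = {"position": col.position, "consensus": col.consensus,
               "information": col.information}
        for a in AA_ALPHABET:
            row[f"freq_{a}"] = col.frequencies.get(a, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
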