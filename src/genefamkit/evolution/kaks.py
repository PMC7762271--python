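"""Nei-Gojobori Ka/Ks estimation with Jukes-Cantor correction.

Potential synonymous sites per codon are the fractions of the nine
single-nucleotide changes that preserve the encoded amino acid (changes to
stop codons count as nonsynonymous); observed differences are averaged
over all mutational pathways between the two codons, excluding pathways
that pass through a stop codon.  Proportions are corrected for multiple
hits with d = -(3/4) ln(1 - (4/3) p); omega = Ka/Ks < 1 indicates
purifying selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log

from Bio.Data import CodonTable

from .align import PairwiseAlignment

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

JC_SATURATION = 0.75


@dataclass
class DuplicatePair:
    """A duplicated gene pair with its divergence and selection estimates."""

    gene_a: str
    gene_b: str
    identity: float
    n_codons: int
    S: float  # potential synonymous sites
    N: float  # potential nonsynonymous sites
    sd: float  # synonymous differences (pathway-averaged)
    nd: float  # nonsynonymous differences
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    omega: float | None
    selection: str
    cluster: int | None = None


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if CODON_TO_AA[codon] == "*":
        raise ValueError(f"stop codon {codon!r}")
    return codon


@lru_cache(maxsize=None)
def ng_sites(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) sites of one sense codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; s + n = 3 exactly.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA[mutant] == aa:  # stops differ from aa, so nonsyn
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_count_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons.

    All orderings of the differing positions are enumerated (1, 2 or 6
    pathways); pathways passing through a stop codon are excluded and the
    average renormalised over the rest.  sd + nd equals the number of
    differing positions.
    """
    codon_a, codon_b = _check_codon(codon_a), _check_codon(codon_b)
    diffs = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        current = codon_a
        sd = nd = 0.0
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and step < len(order) - 1 and not allow_stops:
                return None
            if CODON_TO_AA[nxt] == CODON_TO_AA[current] and CODON_TO_AA[nxt] != "*":
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    orders = list(itertools.permutations(diffs))
    results = [r for r in (walk(o, False) for o in orders) if r is not None]
    if not results:  # every pathway blocked by a stop: average over all
        results = [walk(o, True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0 or p >= JC_SATURATION:
        raise ValueError(f"proportion {p} outside [0, 0.75)")
    return -0.75 * log(1.0 - (4.0 / 3.0) * p)


def kaks(alignment: PairwiseAlignment, min_codons: int = 10) -> DuplicatePair:
    """Complete a duplicate pair with Nei-Gojobori Ka/Ks estimates.

    The alignment is read in consecutive column triplets; triplets with a
    gap, an ambiguous base or a stop codon in either sequence are dropped
    (complete-codon pairwise deletion).  S and N are averaged over both
    sequences; ps or pn >= 0.75 flags the pair as saturated.
    """
    a, b = alignment.aligned_a.upper(), alignment.aligned_b.upper()
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    usable = len(a) - len(a) % 3
    for i in range(0, usable, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            continue
        n_codons += 1
        s_a += ng_sites(ca)[0]
        s_b += ng_sites(cb)[0]
        d = ng_count_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    if n_codons < min_codons:
        raise ValueError(f"only {n_codons} comparable codons (< {min_codons})")
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0

    base = dict(
        gene_a=alignment.seq_a_id,
        gene_b=alignment.seq_b_id,
        identity=alignment.identity,
        n_codons=n_codons,
        S=S,
        N=N,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
    )
    if ps >= JC_SATURATION or pn >= JC_SATURATION:
        return DuplicatePair(**base, ks=None, ka=None, omega=None, selection="saturated")
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks == 0.0:
        return DuplicatePair(**base, ks=ks, ka=ka, omega=None, selection="undefined")
    omega = ka / ks
    if omega < 1.0:
        selection = "purifying"
    elif omega > 1.0:
        selection = "positive"
    else:
        selection = "neutral"
    return DuplicatePair(**base, ks=ks, ka=ka, omega=omega, selection=selection)
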