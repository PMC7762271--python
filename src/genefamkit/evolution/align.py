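"""Global nucleotide alignment (Needleman-Wunsch with affine gaps) and
duplicate-pair detection by pairwise CDS identity.

A gap of length k costs gap_open + k * gap_extend.  Traceback ties resolve
deterministically: diagonal, then up (gap in the second sequence), then
left.  Identity is matches / aligned columns.  Duplicated gene pairs are
pairs whose identity strictly exceeds the threshold (85% by default, the
classical cutoff for calling recent duplicates); clusters are the
connected components of the retained-pair graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

NEG_INF = -1e30


@dataclass
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _substitution_row(a_char: str, b_arr: np.ndarray, match: float, mismatch: float) -> np.ndarray:
    eq = b_arr == a_char
    if a_char == "N":
        eq = np.zeros_like(eq)
    return np.where(eq, match, mismatch)


def global_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two ACGTN strings under affine gaps."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties must be <= 0")
    n, m = len(a), len(b)
    b_arr = np.frombuffer(b.upper().encode(), dtype="S1").astype("U1")
    a_up = a.upper()

    V = np.empty((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in b (up moves)
    js = np.arange(1, m + 1, dtype=float)
    V[0, 0] = 0.0
    V[0, 1:] = gap_open + gap_extend * js
    E[0, 1:] = V[0, 1:]
    for i in range(1, n + 1):
        V[i, 0] = gap_open + gap_extend * i
        F[i, 0] = V[i, 0]
        subs = _substitution_row(a_up[i - 1], b_arr, match, mismatch)
        Mrow = V[i - 1, :m] + subs
        Frow = np.maximum(F[i - 1, 1:], V[i - 1, 1:] + gap_open) + gap_extend
        F[i, 1:] = Frow
        # E via running max over gap-start candidates (reopening from an
        # E-derived cell never beats extending, since gap_open <= 0)
        base = np.empty(m)
        base[0] = V[i, 0]
        if m > 1:
            base[1:] = np.maximum(Mrow[: m - 1], Frow[: m - 1])
        cand = base + gap_open - gap_extend * np.arange(m)
        E[i, 1:] = gap_extend * js + np.maximum.accumulate(cand)
        V[i, 1:] = np.maximum(np.maximum(Mrow, Frow), E[i, 1:])

    # traceback
    eps = 1e-9
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = n, m, "V"
    while i > 0 or j > 0:
        if state == "V":
            if i > 0 and j > 0:
                s = match if (a_up[i - 1] == b_arr[j - 1] and a_up[i - 1] != "N") else mismatch
                if abs(V[i, j] - (V[i - 1, j - 1] + s)) < eps:
                    out_a.append(a[i - 1])
                    out_b.append(b[j - 1])
                    i, j = i - 1, j - 1
                    continue
            if i > 0 and abs(V[i, j] - F[i, j]) < eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            closes = abs(F[i, j] - (V[i - 1, j] + gap_open + gap_extend)) < eps
            i -= 1
            state = "V" if closes or i == 0 else "F"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            closes = abs(E[i, j] - (V[i, j - 1] + gap_open + gap_extend)) < eps
            j -= 1
            state = "V" if closes or j == 0 else "E"

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return PairwiseAlignment(
        seq_a_id=seq_a_id,
        seq_b_id=seq_b_id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(V[n, m]),
        identity=matches / len(aligned_a),
    )


def find_duplicates(
    cds: dict[str, str],
    identity_threshold: float = 0.85,
    **align_params,
) -> tuple[list[PairwiseAlignment], dict[str, int]]:
    """Align all unordered CDS pairs and retain those with identity
    strictly greater than ``identity_threshold``.

    Returns the retained alignments (sorted by gene ids) and a gene ->
    cluster-id map over the connected components of the retained-pair
    graph (components ordered by their smallest gene id).
    """
    if len(cds) < 2:
        raise ValueError("need at least 2 sequences")
    retained: list[PairwiseAlignment] = []
    graph = nx.Graph()
    for ga, gb in itertools.combinations(sorted(cds), 2):
        aln = global_align(cds[ga], cds[gb], seq_a_id=ga, seq_b_id=gb, **align_params)
        if aln.identity > identity_threshold:
            retained.append(aln)
            graph.add_edge(ga, gb)
    clusters: dict[str, int] = {}
    components = sorted(nx.connected_components(graph), key=min)
    for idx, comp in enumerate(components, start=1):
        for gene in comp:
            clusters[gene] = idx
    return retained, clusters
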