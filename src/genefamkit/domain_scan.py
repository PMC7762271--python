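"""Profile-based protein domain detection.

The AP2/ERF superfamily is defined by possession of the ~60-residue AP2
DNA-binding domain (RAV members add a B3 domain).  This module detects such
domains with a position-specific log-odds profile scored over gap-free
windows, calibrates a bit-score threshold against a shuffled-sequence null
so hits can be reported with E-values, and filters partial or low-quality
hits.  Interop with HMMER3 per-domain tabular output is provided for real
genome-scale runs.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical amino-acid alphabet, alphabetical by one-letter code
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

EULER_GAMMA = 0.57721566490153286


@dataclass
class GumbelCalibration:
    """Extreme-value fit of the null distribution of per-protein maximum
    window scores, used to convert bit scores to E-values.

    ``n_windows`` is the number of score windows in the searches used for
    the fit; E-values for other protein lengths are scaled linearly with
    their window count (per-protein search-space scaling).
    """

    mu: float
    beta: float
    n_windows: int

    def evalue(self, score: float, n_windows: int) -> float:
        """Expected number of hits >= ``score`` in a search with
        ``n_windows`` window placements."""
        return math.exp(-(score - self.mu) / self.beta) * n_windows / self.n_windows

    def threshold(self, target_evalue: float, n_windows: int) -> float:
        """Bit score at which the expected hit count equals ``target_evalue``."""
        if target_evalue <= 0:
            raise ValueError("target_evalue must be > 0")
        return self.mu - self.beta * math.log(
            target_evalue * self.n_windows / n_windows
        )


@dataclass
class DomainProfile:
    """Position-specific scoring model for one domain.

    ``scores[c, a]`` is the log2 odds (bits) of residue ``a`` at column
    ``c`` relative to the background; ``emissions`` are the corresponding
    posterior residue frequencies (pseudocount included), used by the
    synthetic-genome generator to sample domain instances.
    """

    name: str
    scores: np.ndarray  # (length, 20) bits
    emissions: np.ndarray  # (length, 20) frequencies
    background: np.ndarray  # (20,)
    calibration: GumbelCalibration | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != self.emissions.shape or self.scores.shape[1] != 20:
            raise ValueError("profile matrices must be (length, 20)")
        if self.length < 1:
            raise ValueError("profile must have at least 1 column")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.emissions.argmax(axis=1))


@dataclass
class DomainHit:
    """One scored domain occurrence on a protein.

    ``profile_start`` is the first profile column covered by the hit (only
    nonzero for windows truncated at the protein's N-terminal end);
    ``coverage`` is the fraction of profile columns matched by standard
    residues.
    """

    gene_id: str
    profile_name: str
    start: int
    end: int
    score: float
    evalue: float
    coverage: float
    profile_start: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def encode_protein(protein: str) -> np.ndarray:
    """Map residues to alphabet indices; non-standard residues (X, B, Z,
    ...) map to 20 and score as background (0 bits)."""
    return np.fromiter(
        (AA_INDEX.get(a, 20) for a in protein.upper()), dtype=np.int64, count=len(protein)
    )


def build_profile(
    aligned_sequences: Sequence[str],
    pseudocount: float = 1.0,
    name: str = "profile",
    background: np.ndarray | None = None,
) -> DomainProfile:
    """Build a log-odds profile from a gap-free alignment.

    score(c, a) = log2[(count(a, c) + pseudocount * bg(a))
                       / ((n + pseudocount) * bg(a))]
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 aligned sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValueError("aligned sequences must have equal lengths")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    counts = np.zeros((length, 20))
    for seq in aligned_sequences:
        for c, a in enumerate(seq.upper()):
            if a not in AA_INDEX:
                raise ValueError(f"non-standard residue {a!r} at column {c}")
            counts[c, AA_INDEX[a]] += 1.0
    n = float(len(aligned_sequences))
    emissions = (counts + pseudocount * background) / (n + pseudocount)
    scores = np.log2(emissions / background)
    return DomainProfile(
        name=name, scores=scores, emissions=emissions, background=background.copy()
    )


def load_bundled_alignment(filename: str) -> list[tuple[str, str]]:
    """Read a bundled FASTA alignment fixture as (header, sequence) pairs."""
    text = resources.files("genefamkit.data").joinpath(filename).read_text()
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = line[1:].strip()
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records

_BUNDLED_ALIGNMENTS = {
    "AP2": "ap2_domain_synthetic_alignment.fasta",
    "B3": "b3_domain_synthetic_alignment.fasta",
}


def load_bundled_profile(name: str, pseudocount: float = 1.0) -> DomainProfile:
    """Load one of the shipped synthetic domain profiles ("AP2" or "B3")."""
    if name not in _BUNDLED_ALIGNMENTS:
        raise KeyError(f"no bundled profile named {name!r}")
    records = load_bundled_alignment(_BUNDLED_ALIGNMENTS[name])
    return build_profile([s for _, s in records], pseudocount=pseudocount, name=name)


def _window_scores(idx: np.ndarray, profile: DomainProfile) -> np.ndarray:
    """Scores of all full-length window placements (vectorised)."""
    n, m = idx.size, profile.length
    if n < m:
        return np.empty(0)
    # pad the score matrix with a zero column for non-standard residues
    padded = np.concatenate([profile.scores, np.zeros((m, 1))], axis=1)
    out = np.zeros(n - m + 1)
    for c in range(m):
        out += padded[c, idx[c : c + n - m + 1]]
    return out


def _placement_count(n: int, m: int, min_overlap: int) -> int:
    """Number of window placements scored on a protein of length ``n``
    (full windows plus truncations down to ``min_overlap`` columns)."""
    full = max(n - m + 1, 0)
    return full + 2 * max(min(m, n) - min_overlap, 0)


def _all_placement_scores(idx: np.ndarray, profile: DomainProfile,
                          min_overlap: int = 10) -> np.ndarray:
    """Scores of every placement, including end-truncated windows — the
    same search space scan_protein evaluates."""
    n, m = idx.size, profile.length
    padded = np.concatenate([profile.scores, np.zeros((m, 1))], axis=1)
    scores = list(_window_scores(idx, profile))
    for s in range(-(m - min_overlap), min(0, n - min_overlap + 1)):
        c0, c1 = -s, min(m, n - s)
        scores.append(float(padded[np.arange(c0, c1), idx[s + c0 : s + c1]].sum()))
    for s in range(max(0, n - m + 1), n - min_overlap + 1):
        if s <= n - m:
            continue
        c1 = n - s
        scores.append(float(padded[np.arange(0, c1), idx[s : s + c1]].sum()))
    return np.asarray(scores)


def scan_protein(
    protein: str,
    profile: DomainProfile,
    threshold: float,
    gene_id: str = "",
    min_overlap: int = 10,
    calibration: GumbelCalibration | None = None,
) -> list[DomainHit]:
    """All window placements scoring >= ``threshold``, greedily reduced to a
    non-overlapping set (descending score, ties by smaller start).

    Windows truncated at either sequence end are scored over their
    overlapping columns only, which reduces their coverage.  Proteins
    shorter than 10 residues yield an empty result (logged, not an error).
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n, m = len(protein), profile.length
    if n < 10:
        logger.info("protein %s shorter than 10 residues; skipping scan", gene_id)
        return []
    idx = encode_protein(protein)
    padded = np.concatenate([profile.scores, np.zeros((m, 1))], axis=1)
    cal = calibration or profile.calibration

    candidates: list[tuple[float, int, int, int, float, int]] = []

    def add_placement(s: int) -> None:
        c0, c1 = max(0, -s), min(m, n - s)
        cols = np.arange(c0, c1)
        res = idx[s + c0 : s + c1]
        score = float(padded[cols, res].sum())
        if score >= threshold:
            matched = int((res < 20).sum())
            coverage = matched / m
            if coverage > 0:
                candidates.append((score, max(s, 0), min(s + m, n), c0, coverage, s))

    # full windows, vectorised
    if n >= m:
        full = _window_scores(idx, profile)
        standard = (idx < 20).astype(np.int64)
        run = np.convolve(standard, np.ones(m, dtype=np.int64), mode="valid")
        for s in np.nonzero(full >= threshold)[0]:
            cov = run[s] / m
            if cov > 0:
                candidates.append((float(full[s]), int(s), int(s) + m, 0, float(cov), int(s)))
    # truncated windows at both ends
    for s in range(-(m - min_overlap), min(0, n - min_overlap + 1)):
        add_placement(s)
    for s in range(max(0, n - m + 1), n - min_overlap + 1):
        if s <= n - m:
            continue
        add_placement(s)

    # greedy non-overlapping selection
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[DomainHit] = []
    occupied: list[tuple[int, int]] = []
    for score, start, end, c0, coverage, _s in candidates:
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        n_windows = max(1, _placement_count(n, m, min_overlap))
        ev = cal.evalue(score, n_windows) if cal is not None else 0.0
        chosen.append(
            DomainHit(
                gene_id=gene_id,
                profile_name=profile.name,
                start=start,
                end=end,
                score=score,
                evalue=ev,
                coverage=coverage,
                profile_start=c0,
            )
        )
    chosen.sort(key=lambda h: h.start)
    return chosen


def fit_null_calibration(
    profile: DomainProfile,
    n_shuffles: int = 200,
    protein_length: int = 300,
    seed: int = 0,
) -> GumbelCalibration:
    """Fit a Gumbel law (method of moments) to the maxima of full-window
    scores over random background sequences."""
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffled sequences")
    if protein_length < profile.length:
        raise ValueError("protein_length must be >= profile length")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_shuffles)
    for i in range(n_shuffles):
        idx = rng.choice(20, size=protein_length, p=profile.background)
        maxima[i] = _all_placement_scores(idx, profile).max()
    sd = float(maxima.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate (zero-variance) null distribution")
    beta = sd * math.sqrt(6.0) / math.pi
    mu = float(maxima.mean()) - EULER_GAMMA * beta
    return GumbelCalibration(
        mu=mu,
        beta=beta,
        n_windows=_placement_count(protein_length, profile.length, 10),
    )


def calibrate_threshold(
    profile: DomainProfile,
    n_shuffles: int = 200,
    protein_length: int = 300,
    target_evalue: float = 1e-5,
    seed: int = 0,
) -> float:
    """Calibrate the bit-score threshold whose expected false-hit count per
    search of ``protein_length`` equals ``target_evalue``.

    The fitted calibration is attached to ``profile.calibration`` so that
    subsequent scans can report E-values.
    """
    cal = fit_null_calibration(profile, n_shuffles, protein_length, seed)
    profile.calibration = cal
    return cal.threshold(target_evalue, n_windows=cal.n_windows)


def read_domtblout(path) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    Envelope coordinates are converted from 1-based inclusive to 0-based
    half-open; the independent (i-)E-value is used as the hit E-value and
    coverage is the matched fraction of profile (query) columns.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(f"malformed domtblout line {lineno}: too few fields")
            try:
                qlen = int(fields[5])
                ievalue = float(fields[12])
                score = float(fields[13])
                hmm_from, hmm_to = int(fields[15]), int(fields[16])
                env_from, env_to = int(fields[19]), int(fields[20])
            except ValueError as exc:
                raise ValueError(f"malformed domtblout line {lineno}: {exc}") from None
            hits.append(
                DomainHit(
                    gene_id=fields[0],
                    profile_name=fields[3],
                    start=env_from - 1,
                    end=env_to,
                    score=score,
                    evalue=ievalue,
                    coverage=(hmm_to - hmm_from + 1) / qlen,
                    profile_start=hmm_from - 1,
                )
            )
    return hits


def filter_hits(
    hits: Iterable[DomainHit],
    max_evalue: float = 1e-5,
    min_coverage: float = 0.7,
) -> list[DomainHit]:
    """Remove partial or low-quality hits: keep E-value <= ``max_evalue``
    and coverage >= ``min_coverage``; input order is preserved."""
    if max_evalue < 0 or not 0 <= min_coverage <= 1:
        raise ValueError("thresholds out of range")
    return [h for h in hits if h.evalue <= max_evalue and h.coverage >= min_coverage]
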