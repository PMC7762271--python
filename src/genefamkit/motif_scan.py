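"""Repression-motif and promoter cis-element scanning.

Proteins are screened for the short repression/activation motifs known in
the AP2/ERF superfamily ([R/K]LFGV in RAV members; the EAR-type DLN motif
in its strict FDLNLPP and generalised [L/F]DLN[L/F] spellings, reported
separately; the EDLL activation motif).  Promoters are screened for four
stress-related cis-elements (DRE [AG]CCGAC, ABRE TCCACGTCTC, re2f-1
GCGGGAAA, and the GTACGTG ACGT motif) on both strands.  All matches, even
overlapping ones, are reported; coordinates are 0-based half-open and N
never matches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass
class MotifPattern:
    name: str
    pattern: str  # position-restricted residue/base classes, e.g. [RK]LFGV
    alphabet: str  # "protein" | "dna"
    scan_both_strands: bool = False


@dataclass
class MotifHit:
    sequence_id: str
    motif_name: str
    start: int
    end: int
    strand: str  # "+"/"-" for dna, "." for protein
    matched_text: str


#: repression/activation motifs screened on protein sequences
REPRESSION_MOTIFS = [
    MotifPattern("RK-LFGV", "[RK]LFGV", "protein"),
    MotifPattern("FDLNLPP", "FDLNLPP", "protein"),
    MotifPattern("LF-DLN-LF", "[LF]DLN[LF]", "protein"),
    MotifPattern("EDLL", "EDLL", "protein"),
]

#: promoter cis-regulatory elements, scanned on both strands
PROMOTER_ELEMENTS = [
    MotifPattern("DRE", "[AG]CCGAC", "dna", scan_both_strands=True),
    MotifPattern("ABRE", "TCCACGTCTC", "dna", scan_both_strands=True),
    MotifPattern("re2f-1", "GCGGGAAA", "dna", scan_both_strands=True),
    MotifPattern("ACGT-motif", "GTACGTG", "dna", scan_both_strands=True),
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _pattern_length(pattern: str) -> int:
    return len(re.findall(r"\[[^\]]+\]|.", pattern))


def _overlapping_matches(pattern: str, seq: str) -> list[tuple[int, str]]:
    plen = _pattern_length(pattern)
    rx = re.compile(f"(?=({pattern}))")
    return [(m.start(), m.group(1)) for m in rx.finditer(seq) if len(m.group(1)) == plen]


def scan_sequence(
    sequence: str,
    patterns: list[MotifPattern],
    sequence_id: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) pattern matches, sorted by start.

    For DNA patterns with ``scan_both_strands``, minus-strand matches are
    reported in the coordinates of the given sequence with strand "-" and
    the matched text as read on the minus strand.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for pat in patterns:
        for start, text in _overlapping_matches(pat.pattern, seq):
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    motif_name=pat.name,
                    start=start,
                    end=start + len(text),
                    strand="+" if pat.alphabet == "dna" else ".",
                    matched_text=text,
                )
            )
        if pat.alphabet == "dna" and pat.scan_both_strands:
            rc = reverse_complement(seq)
            n = len(seq)
            for start, text in _overlapping_matches(pat.pattern, rc):
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        motif_name=pat.name,
                        start=n - (start + len(text)),
                        end=n - start,
                        strand="-",
                        matched_text=text,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def scan_repression_motifs(protein: str, sequence_id: str = "",
                           patterns: list[MotifPattern] | None = None) -> list[MotifHit]:
    """Screen one protein for the repression/activation motifs."""
    return scan_sequence(protein, patterns or REPRESSION_MOTIFS, sequence_id)


def scan_promoter_elements(promoter: str, sequence_id: str = "",
                           patterns: list[MotifPattern] | None = None) -> list[MotifHit]:
    """Screen one promoter for the cis-regulatory elements, both strands."""
    return scan_sequence(promoter, patterns or PROMOTER_ELEMENTS, sequence_id)


def extract_promoter(genome: dict[str, str], gene, length: int = 1500) -> str:
    """Promoter sequence: the ``length`` bases immediately 5' of the start
    codon, read on the gene's strand.

    ``gene`` needs attributes chromosome, start, end (1-based inclusive)
    and strand.  For minus-strand genes this is the reverse complement of
    the genomic window just 3' of the genomic CDS end.  Windows running
    off a chromosome edge are truncated with a logged warning.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} missing from genome store")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        cds_start0 = gene.start - 1
        lo = cds_start0 - length
        if lo < 0:
            logger.warning("promoter of %s truncated at chromosome start", gene.id)
            lo = 0
        return chrom[lo:cds_start0]
    hi = gene.end + length
    if hi > len(chrom):
        logger.warning("promoter of %s truncated at chromosome end", gene.id)
        hi = len(chrom)
    return reverse_complement(chrom[gene.end:hi])
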