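"""Subfamily assignment, gene naming and chromosome tabulation.

Architecture rules (domain count on the filtered hit set) assign the coarse
subfamily: two AP2 domains -> AP2, AP2 + B3 -> RAV, one AP2 -> ERF clade.
ERF-clade genes are refined to ERF / DREB / DRF / SOLOIST by nearest
labelled reference domain (ungapped column-wise identity against the
shipped reference set).  Genes are then named ``<prefix>-001`` onward in
chromosomal order (chromosome number, then A before B subgenome, then
start coordinate), the convention used for wheat-style 1A-7B karyotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from .domain_scan import DomainHit, DomainProfile, load_bundled_alignment

logger = logging.getLogger(__name__)

#: tetraploid wheat karyotype: chromosomes 1-7 in the A and B subgenomes
CHROMOSOMES = [f"{num}{sub}" for num in range(1, 8) for sub in "AB"]

#: tie-break priority for equal-identity references (highest first)
LABEL_PRIORITY = {"ERF": 0, "DREB": 1, "DRF": 2, "SOLOIST": 3}

SOLOIST_IDENTITY_FLOOR = 0.25


@dataclass
class FamilyRecord:
    """One classified family member."""

    gene_id: str
    subfamily: str
    architecture: list[str] = field(default_factory=list)
    chromosome: str = ""
    start: int = 0
    strand: str = "+"
    assigned_name: str = ""
    linker_length: int | None = None  # AP2 subfamily QC: inter-domain gap


def load_reference_domains(path=None) -> list[tuple[str, str]]:
    """Labelled (label, sequence) reference domains for ERF-clade
    refinement, in file order (the shipped synthetic fixture by default)."""
    if path is None:
        records = load_bundled_alignment("erf_clade_references_synthetic.fasta")
    else:
        from Bio import SeqIO

        records = [(r.description, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    refs = []
    for header, seq in records:
        label = None
        for token in header.split():
            if token.startswith("subfamily="):
                label = token.split("=", 1)[1]
        if label is None:
            raise ValueError(f"reference {header!r} lacks a subfamily= tag")
        refs.append((label, seq))
    return refs


def classify_architecture(hits: list[DomainHit]) -> str:
    """Coarse subfamily from the domain architecture of one gene.

    Returns "AP2", "RAV", "ERF_CLADE" (single AP2 domain, pending
    refinement), "UNCLASSIFIED" (B3 without AP2, warned) or "NONE".
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"hits from multiple genes: {sorted(genes)}")
    ordered = sorted(hits, key=lambda h: h.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError("hits must be non-overlapping")
    n_ap2 = sum(1 for h in hits if h.profile_name.startswith("AP2"))
    n_b3 = sum(1 for h in hits if h.profile_name.startswith("B3"))
    if n_ap2 >= 1 and n_b3 >= 1:
        return "RAV"
    if n_ap2 >= 2:
        return "AP2"
    if n_ap2 == 1:
        return "ERF_CLADE"
    if n_b3 >= 1:
        logger.warning("gene %s has a B3 domain without AP2; UNCLASSIFIED",
                       ordered[0].gene_id if ordered else "?")
        return "UNCLASSIFIED"
    return "NONE"


def refine_erf_clade(
    domain_sequence: str,
    references: list[tuple[str, str]],
    profile_length: int | None = None,
    column_offset: int = 0,
    identity_floor: float = SOLOIST_IDENTITY_FLOOR,
) -> str:
    """Label a single-AP2 domain by its nearest labelled reference.

    ``domain_sequence`` is the hit's residues aligned to profile columns
    starting at ``column_offset`` (nonzero for truncated hits).  The label
    of the reference with highest ungapped column-wise identity wins; ties
    break by ERF > DREB > DRF > SOLOIST then file order.  A best identity
    below ``identity_floor`` falls through to SOLOIST; a domain covering
    less than half the profile is UNCLASSIFIED.
    """
    if not references:
        raise ValueError("reference set is empty")
    ref_len = profile_length if profile_length is not None else len(references[0][1])
    if len(domain_sequence) < 0.5 * ref_len:
        return "UNCLASSIFIED"
    best: tuple[float, int, int] | None = None  # (-identity, priority, order)
    best_label = None
    for order, (label, ref_seq) in enumerate(references):
        segment = ref_seq[column_offset : column_offset + len(domain_sequence)]
        n = min(len(segment), len(domain_sequence))
        if n == 0:
            continue
        matches = sum(a == b for a, b in zip(domain_sequence[:n], segment[:n]))
        identity = matches / n
        key = (-identity, LABEL_PRIORITY.get(label, 99), order)
        if best is None or key < best:
            best, best_label = key, label
    if best is None:
        return "UNCLASSIFIED"
    if -best[0] < identity_floor:
        return "SOLOIST"
    return best_label


def classify_gene(
    gene_id: str,
    hits: list[DomainHit],
    protein: str,
    references: list[tuple[str, str]],
    ap2_profile: DomainProfile,
) -> FamilyRecord:
    """Full classification of one gene from its filtered hits."""
    arch = classify_architecture(hits)
    ordered = sorted(hits, key=lambda h: h.start)
    architecture = [h.profile_name for h in ordered]
    linker = None
    if arch == "AP2":
        ap2_hits = [h for h in ordered if h.profile_name.startswith("AP2")]
        linker = ap2_hits[1].start - ap2_hits[0].end
        subfamily = "AP2"
    elif arch == "ERF_CLADE":
        hit = next(h for h in ordered if h.profile_name.startswith("AP2"))
        subfamily = refine_erf_clade(
            protein[hit.start : hit.end],
            references,
            profile_length=ap2_profile.length,
            column_offset=hit.profile_start,
        )
    else:
        subfamily = arch
    return FamilyRecord(
        gene_id=gene_id,
        subfamily=subfamily,
        architecture=architecture,
        linker_length=linker,
    )


def _chromosome_key(label: str) -> tuple[int, str]:
    if label not in CHROMOSOMES:
        raise ValueError(f"unknown chromosome label {label!r}")
    return int(label[:-1]), label[-1]


def assign_names(records: list[FamilyRecord], prefix: str = "TtAP2/ERF") -> dict[str, str]:
    """Name genes by chromosomal location order.

    Sort key: chromosome number 1-7, subgenome letter A before B, start
    coordinate ascending; names are ``<prefix>-%03d`` in that order.
    """
    seen = set()
    for r in records:
        key = (r.chromosome, r.start, r.gene_id)
        if key in seen:
            raise ValueError(f"duplicate (chromosome, start, gene_id): {key}")
        seen.add(key)
    ordered = sorted(
        records, key=lambda r: (*_chromosome_key(r.chromosome), r.start, r.gene_id)
    )
    naming: dict[str, str] = {}
    for i, r in enumerate(ordered, start=1):
        r.assigned_name = f"{prefix}-{i:03d}"
        naming[r.gene_id] = r.assigned_name
    return naming


def chromosome_distribution(records: list[FamilyRecord]) -> dict:
    """Gene counts per chromosome (zero-filled over all 14 labels) plus
    per-subgenome totals."""
    counts = {label: 0 for label in CHROMOSOMES}
    for r in records:
        if r.chromosome not in counts:
            raise ValueError(f"unknown chromosome label {r.chromosome!r}")
        counts[r.chromosome] += 1
    subgenomes = {
        "A": sum(v for k, v in counts.items() if k.endswith("A")),
        "B": sum(v for k, v in counts.items() if k.endswith("B")),
    }
    return {"per_chromosome": counts, "per_subgenome": subgenomes}
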