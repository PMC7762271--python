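"""Synthetic gene-family genome generator with recorded ground truth.

Emulates the inputs of a genome-wide AP2/ERF-style family survey on a
tetraploid (1A-7B) karyotype: proteins carrying domain instances sampled
from the bundled AP2/B3 profiles in the four architectures (ERF-clade =
one AP2; AP2 = two AP2 domains with a 25-residue linker; RAV = AP2 then
B3; SOLOIST = a divergent single AP2; NONE = background only), CDSs
back-translated with seeded uniform synonymous-codon choice, duplicated
pairs diverged at controlled omega and Ks, chromosome sequences with
planted promoter cis-elements, FPKM matrices with planted tissue-specific
and stress-responsive genes, and replicate-level qPCR Ct tables.  Every
planting is recorded in a truth table so downstream stages are testable
without downloads.

Fixed config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain_scan import AA_ALPHABET, DomainProfile, load_bundled_profile
from .evolution.kaks import BASES, CODON_TO_AA, ng_sites
from .family_classify import CHROMOSOMES
from .motif_scan import reverse_complement
from .subfamilies import subfamily_consensuses

SUBFAMILIES = ("ERF", "DREB", "DRF", "AP2", "RAV", "SOLOIST", "NONE")
ERF_CLADE = ("ERF", "DREB", "DRF")

AP2_LINKER_LENGTH = 25

#: sense codons per amino acid, for seeded uniform back-translation
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic genome.

    Defaults emulate the conditions of a desk-scale family survey: ~60
    genes over chromosomes 1A-7B, purifying-selection duplicate pairs
    (omega < 1) at Ks ~ 0.05 (CDS identity ~ 0.96), five tissues, paired
    1 h / 6 h drought and heat stress columns, and three qPCR replicates.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {
            "ERF": 18, "DREB": 8, "DRF": 5, "AP2": 6, "RAV": 6,
            "SOLOIST": 5, "NONE": 12,
        }
    )
    chromosomes: list[str] = field(default_factory=lambda: list(CHROMOSOMES))
    omega_grid: list[float] = field(default_factory=lambda: [0.1, 0.3, 0.5])
    ks_target: float = 0.05
    n_duplicate_pairs: int = 8
    tissues: list[str] = field(
        default_factory=lambda: ["leaf", "root", "stem", "grain", "spike"]
    )
    stress_conditions: list[str] = field(
        default_factory=lambda: ["drought_1h", "drought_6h", "heat_1h", "heat_6h"]
    )
    seed: int = 0
    # generator knobs
    domain_divergence: float = 0.08  # per-column noise within a subfamily
    flank_range: tuple[int, int] = (25, 60)
    n_tissue_specific_per_tissue: int = 2
    n_stress_up: int = 6
    n_stress_down: int = 4
    n_silent: int = 3
    n_fdlnlpp: int = 2
    n_edll: int = 3
    tissue_fold: float = 20.0
    stress_fold: float = 4.0
    fpkm_noise_sd: float = 0.15  # lognormal sigma, natural-log scale
    ct_noise_sd: float = 0.2  # cycles
    n_qpcr_replicates: int = 3

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("subfamily counts must be >= 0")
        if sum(self.counts.values()) == 0:
            raise ValueError("config requests zero genes")
        unknown = set(self.counts) - set(SUBFAMILIES)
        if unknown:
            raise ValueError(f"unknown subfamilies in counts: {sorted(unknown)}")
        bad = set(self.chromosomes) - set(CHROMOSOMES)
        if bad:
            raise ValueError(f"chromosome labels outside 1A-7B: {sorted(bad)}")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        if self.ks_target <= 0:
            raise ValueError("ks_target must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.flank_range, list):
            cfg.flank_range = tuple(cfg.flank_range)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flank_range"] = list(self.flank_range)
        return d


@dataclass
class GeneModel:
    """One gene: identity, location and sequences (GFF-style 1-based
    inclusive coordinates)."""

    id: str
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    cds: str = ""
    protein: str = ""


@dataclass
class GenomeBundle:
    """Everything one synthetic run produces."""

    genes: list[GeneModel]
    genome: dict[str, str]
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def proteins(self) -> dict[str, str]:
        return {g.id: g.protein for g in self.genes}

    @property
    def cds(self) -> dict[str, str]:
        return {g.id: g.cds for g in self.genes}


# ---------------------------------------------------------------------------
# sequence-level generators


def _sample_from_emissions(profile: DomainProfile, rng: np.random.Generator) -> str:
    idx = [rng.choice(20, p=profile.emissions[c]) for c in range(profile.length)]
    return "".join(AA_ALPHABET[i] for i in idx)


def _sample_subfamily_domain(
    consensus: str, profile: DomainProfile, divergence: float, rng: np.random.Generator
) -> str:
    out = list(consensus)
    for c in range(len(out)):
        if rng.random() < divergence:
            out[c] = AA_ALPHABET[rng.choice(20, p=profile.emissions[c])]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    # uniform background maximises contrast with high-information columns
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein: uniform seeded choice among synonymous codons,
    terminated by a uniform stop codon."""
    codons = []
    for aa in protein:
        options = AA_TO_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def mutate_duplicate(
    cds: str, omega: float, ks_target: float, seed: int
) -> tuple[str, float, float]:
    """Diverge a CDS copy at a controlled omega and synonymous rate.

    Single-nucleotide substitutions are proposed at Poisson intensity
    ``ks_target`` per site; synonymous proposals are accepted at the base
    rate, nonsynonymous at base rate x omega, and proposals creating stop
    codons are rejected.  Returns the mutated CDS and the realized
    (accepted-count) Ka and Ks rates relative to the original sequence's
    Nei-Gojobori site counts, so estimators can be checked against truth.
    """
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError("CDS length must be a positive multiple of 3")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if ks_target < 0:
        raise ValueError("ks_target must be >= 0")
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        if CODON_TO_AA.get(codon) == "*":
            raise ValueError(f"stop codon at codon index {i}")
        if codon not in CODON_TO_AA:
            raise ValueError(f"ambiguous codon {codon!r}")
    S = sum(ng_sites(c)[0] for c in codons)
    N = 3.0 * len(codons) - S

    rng = np.random.default_rng(seed)
    seq = list(cds)
    n_proposals = rng.poisson(len(seq) * ks_target)
    syn_accepted = nonsyn_accepted = 0
    for _ in range(n_proposals):
        pos = int(rng.integers(len(seq)))
        current = seq[pos]
        alternatives = [b for b in BASES if b != current]
        new_base = alternatives[rng.integers(3)]
        cstart = pos - pos % 3
        old_codon = "".join(seq[cstart : cstart + 3])
        new_codon = old_codon[: pos - cstart] + new_base + old_codon[pos - cstart + 1 :]
        if CODON_TO_AA[new_codon] == "*":
            continue
        if CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]:
            seq[pos] = new_base
            syn_accepted += 1
        elif rng.random() < omega:
            seq[pos] = new_base
            nonsyn_accepted += 1
    realized_ks = syn_accepted / S if S > 0 else 0.0
    realized_ka = nonsyn_accepted / N if N > 0 else 0.0
    return "".join(seq), realized_ka, realized_ks


# ---------------------------------------------------------------------------
# genome assembly


def _build_protein(
    subfamily: str,
    profiles: dict[str, DomainProfile],
    consensuses: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Protein sequence plus recorded (profile, start, end) domain spans."""
    lo, hi = config.flank_range
    nterm = int(rng.integers(lo, hi + 1))
    cterm = int(rng.integers(lo, hi + 1))
    ap2 = profiles["AP2"]
    b3 = profiles["B3"]
    positions: list[tuple[str, int, int]] = []
    parts = ["M", _random_protein(nterm, rng)]
    cursor = 1 + nterm

    def add_domain(profile: DomainProfile, seq: str) -> None:
        nonlocal cursor
        positions.append((profile.name, cursor, cursor + len(seq)))
        parts.append(seq)
        cursor += len(seq)

    if subfamily in ERF_CLADE or subfamily == "SOLOIST":
        add_domain(
            ap2,
            _sample_subfamily_domain(
                consensuses[subfamily], ap2, config.domain_divergence, rng
            ),
        )
    elif subfamily == "AP2":
        add_domain(ap2, _sample_from_emissions(ap2, rng))
        parts.append(_random_protein(AP2_LINKER_LENGTH, rng))
        cursor += AP2_LINKER_LENGTH
        add_domain(ap2, _sample_from_emissions(ap2, rng))
    elif subfamily == "RAV":
        add_domain(ap2, _sample_from_emissions(ap2, rng))
        parts.append(_random_protein(10, rng))
        cursor += 10
        add_domain(b3, _sample_from_emissions(b3, rng))
    elif subfamily != "NONE":
        raise ValueError(f"unknown subfamily {subfamily!r}")
    parts.append(_random_protein(cterm, rng))
    return "".join(parts), positions


def _assign_expression_classes(
    gene_ids: list[str], subfamilies: dict[str, str], config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    family = [g for g in gene_ids if subfamilies[g] != "NONE"]
    order = list(family)
    rng.shuffle(order)
    classes = {g: "ubiquitous" for g in gene_ids}
    wanted: list[str] = []
    for tissue in config.tissues:
        wanted.extend([f"tissue_specific:{tissue}"] * config.n_tissue_specific_per_tissue)
    wanted.extend(["stress_up"] * config.n_stress_up)
    wanted.extend(["stress_down"] * config.n_stress_down)
    wanted.extend(["silent"] * config.n_silent)
    for gene, cls in zip(order, wanted):
        classes[gene] = cls
    return classes


def generate_family_genome(config: SimulationConfig) -> GenomeBundle:
    """Generate the full synthetic genome bundle for one configuration."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1000])
    profiles = {"AP2": load_bundled_profile("AP2"), "B3": load_bundled_profile("B3")}
    consensuses = subfamily_consensuses(profiles["AP2"])

    # 1. skeletons in fixed subfamily order
    gene_ids: list[str] = []
    subfam: dict[str, str] = {}
    for family in SUBFAMILIES:
        for _ in range(config.counts.get(family, 0)):
            gid = f"g{len(gene_ids) + 1:03d}"
            gene_ids.append(gid)
            subfam[gid] = family

    # 2. duplicate designation: consecutive same-subfamily ERF-clade genes,
    #    drawn round-robin across subfamilies
    candidates = {
        family: [g for g in gene_ids if subfam[g] == family] for family in ERF_CLADE
    }
    pools = {
        family: [(m[k], m[k + 1]) for k in range(0, len(m) - 1, 2)]
        for family, m in candidates.items()
    }
    dup_pairs: list[tuple[str, str]] = []
    while len(dup_pairs) < config.n_duplicate_pairs and any(pools.values()):
        for family in ERF_CLADE:
            if pools[family] and len(dup_pairs) < config.n_duplicate_pairs:
                dup_pairs.append(pools[family].pop(0))
    dup_involved = {g for pair in dup_pairs for g in pair}

    # 3. proteins with planted domains
    proteins: dict[str, str] = {}
    domain_positions: dict[str, list[tuple[str, int, int]]] = {}
    for gid in gene_ids:
        proteins[gid], domain_positions[gid] = _build_protein(
            subfam[gid], profiles, consensuses, config, rng
        )

    # 4. protein motif planting (never into duplicate pairs, whose
    #    sequences must stay tied to the mutation model)
    planted_motifs: dict[str, list[tuple[str, int]]] = {g: [] for g in gene_ids}

    def plant(gid: str, motif_name: str, text: str) -> None:
        seq = proteins[gid]
        dom_end = max(e for _, _, e in domain_positions[gid])
        span = len(seq) - 1 - dom_end - len(text)
        if span <= 2:
            return
        pos = dom_end + 2 + int(rng.integers(span - 1))
        proteins[gid] = seq[:pos] + text + seq[pos + len(text):]
        planted_motifs[gid].append((motif_name, pos))

    for gid in gene_ids:
        if subfam[gid] == "RAV" and gid not in dup_involved:
            plant(gid, "RK-LFGV", ("R" if rng.random() < 0.5 else "K") + "LFGV")
    erf_free = [g for g in gene_ids if subfam[g] == "ERF" and g not in dup_involved]
    for gid in erf_free[: config.n_fdlnlpp]:
        plant(gid, "FDLNLPP", "FDLNLPP")
    for gid in erf_free[config.n_fdlnlpp : config.n_fdlnlpp + config.n_edll]:
        plant(gid, "EDLL", "EDLL")

    # 5. back-translation, then duplicate divergence
    cds: dict[str, str] = {g: back_translate(proteins[g], rng) for g in gene_ids}
    true_omega: dict[str, float] = {}
    true_ks: dict[str, float] = {}
    partner: dict[str, str] = {}
    for idx, (ga, gb) in enumerate(dup_pairs):
        omega = config.omega_grid[idx % len(config.omega_grid)]
        body, stop = cds[ga][:-3], cds[ga][-3:]
        mutated, _ka, real_ks = mutate_duplicate(
            body, omega, config.ks_target, seed=int(rng.integers(2**31))
        )
        cds[gb] = mutated + stop
        proteins[gb] = str(Seq(mutated).translate())
        domain_positions[gb] = list(domain_positions[ga])
        planted_motifs[gb] = []
        partner[ga], partner[gb] = gb, ga
        true_omega[ga] = true_omega[gb] = omega
        true_ks[ga] = true_ks[gb] = real_ks

    # 6. expression classes (needed before promoter planting)
    classes = _assign_expression_classes(gene_ids, subfam, config, rng)

    # 7. chromosomal placement: sequential layout with >=3.1 kb gaps so
    #    every gene keeps an undisturbed 1.5 kb promoter window
    genes = []
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in config.chromosomes}
    for gid in gene_ids:
        chrom = config.chromosomes[int(rng.integers(len(config.chromosomes)))]
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(id=gid, chromosome=chrom, strand=strand, cds=cds[gid],
                         protein=proteins[gid])
        by_chrom[chrom].append(gene)
        genes.append(gene)
    for chrom, members in by_chrom.items():
        cursor = 2000
        for gene in members:
            gene.start = cursor + 1
            gene.end = gene.start + len(gene.cds) - 1
            cursor = gene.end + int(rng.integers(3100, 4000))

    # 8. chromosome sequences with embedded CDS and promoter elements
    element_texts = [("DRE", None), ("ABRE", "TCCACGTCTC"),
                     ("re2f-1", "GCGGGAAA"), ("ACGT-motif", "GTACGTG")]
    genome: dict[str, str] = {}
    for chrom in config.chromosomes:
        members = by_chrom[chrom]
        length = (members[-1].end + 2000) if members else 2000
        arr = np.frombuffer(
            b"".join(BASES[i].encode() for i in rng.integers(0, 4, size=length)),
            dtype="S1",
        ).copy()
        for gene in members:
            insert = gene.cds if gene.strand == "+" else reverse_complement(gene.cds)
            arr[gene.start - 1 : gene.end] = np.frombuffer(insert.encode(), dtype="S1")
            if classes[gene.id] == "stress_up":
                offsets = [100, 420, 760, 1100]
                for (name, text), base_off in zip(element_texts, offsets):
                    if text is None:  # DRE consensus [AG]CCGAC
                        text = ("A" if rng.random() < 0.5 else "G") + "CCGAC"
                    p = base_off + int(rng.integers(120))
                    if gene.strand == "+":
                        gpos = gene.start - 1 - 1500 + p
                        arr[gpos : gpos + len(text)] = np.frombuffer(
                            text.encode(), dtype="S1"
                        )
                    else:
                        gpos = gene.end + 1500 - p - len(text)
                        arr[gpos : gpos + len(text)] = np.frombuffer(
                            reverse_complement(text).encode(), dtype="S1"
                        )
                    planted_motifs[gene.id].append((name, p))
        genome[chrom] = arr.tobytes().decode()

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_subfamily": [subfam[g] for g in gene_ids],
            "domain_positions": [json.dumps(domain_positions[g]) for g in gene_ids],
            "duplicate_partner": [partner.get(g, "") for g in gene_ids],
            "true_omega": [true_omega.get(g, np.nan) for g in gene_ids],
            "true_ks": [true_ks.get(g, np.nan) for g in gene_ids],
            "planted_motifs": [json.dumps(planted_motifs[g]) for g in gene_ids],
            "expression_class": [classes[g] for g in gene_ids],
        }
    )
    return GenomeBundle(genes=genes, genome=genome, truth=truth, config=config)


# ---------------------------------------------------------------------------
# expression and qPCR generators


def generate_expression(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """FPKM matrix (genes x tissues+conditions) with planted classes."""
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng([config.seed, 2001])
    columns = config.tissues + ["control"] + config.stress_conditions
    jit = lambda: rng.lognormal(mean=0.0, sigma=config.fpkm_noise_sd)
    rows = {}
    for _, rec in truth.iterrows():
        gene, cls = rec["gene_id"], rec["expression_class"]
        if cls == "silent":
            rows[gene] = [0.0] * len(columns)
            continue
        if cls == "ubiquitous":
            base = rng.lognormal(mean=np.log(10.0), sigma=0.4)
            rows[gene] = [base * jit() for _ in columns]
            continue
        if cls.startswith("tissue_specific:"):
            tissue = cls.split(":", 1)[1]
            if tissue not in config.tissues:
                raise ValueError(f"unknown tissue in class {cls!r}")
            base = rng.lognormal(mean=np.log(0.2), sigma=0.2)
            rows[gene] = [
                base * (config.tissue_fold if col == tissue else 1.0) * jit()
                for col in columns
            ]
            continue
        if cls in ("stress_up", "stress_down"):
            base = rng.lognormal(mean=np.log(8.0), sigma=0.5)
            factor = config.stress_fold if cls == "stress_up" else 1.0 / config.stress_fold
            rows[gene] = [
                base * (factor if col in config.stress_conditions else 1.0) * jit()
                for col in columns
            ]
            continue
        raise ValueError(f"unknown expression class {cls!r}")
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    matrix.index.name = "gene_id"
    return matrix


def make_qpcr_table(
    fold_map: dict[tuple[str, str], float],
    control: str = "control",
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    ct_offset: float = 30.0,
    ct_reference: float = 16.0,
) -> pd.DataFrame:
    """Replicate-level Ct table for planted fold changes.

    Ct model: ct_target = offset - log2(expression) + Gaussian noise with
    the reference gene held constant, so a planted log2 fold change f
    gives expected ddCT = -f.
    """
    if not fold_map:
        raise ValueError("no target genes")
    if n_replicates < 3:
        raise ValueError("need >= 3 replicates per condition")
    rng = np.random.default_rng(seed)
    genes = sorted({g for g, _ in fold_map})
    treatments = sorted({t for _, t in fold_map})
    base_ct = {g: ct_offset - float(np.log2(rng.lognormal(np.log(8.0), 0.5)))
               for g in genes}
    rows = []
    for gene in genes:
        for treatment in [control] + [t for t in treatments if t != control]:
            fold = fold_map.get((gene, treatment), 1.0)
            f = float(np.log2(fold))
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    (gene, treatment, rep, base_ct[gene] - f + noise, ct_reference)
                )
    return pd.DataFrame(
        rows, columns=["gene", "treatment", "replicate", "ct_target", "ct_reference"]
    )


def generate_qpcr(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Ct table for the planted stress-responsive genes (three biological
    replicates per treatment; Gaussian Ct noise, reference gene constant)."""
    targets = truth[truth["expression_class"].isin(["stress_up", "stress_down"])]
    if targets.empty:
        raise ValueError("no stress-responsive target genes in truth table")
    fold_map: dict[tuple[str, str], float] = {}
    for _, rec in targets.iterrows():
        fold = (config.stress_fold if rec["expression_class"] == "stress_up"
                else 1.0 / config.stress_fold)
        for treatment in config.stress_conditions:
            fold_map[(rec["gene_id"], treatment)] = fold
    seed = int(np.random.default_rng([config.seed, 2002]).integers(2**31))
    return make_qpcr_table(
        fold_map,
        n_replicates=config.n_qpcr_replicates,
        noise_sd=config.ct_noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file I/O


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tgenefamkit\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            genes.append(
                GeneModel(
                    id=attrs.get("ID", ""),
                    chromosome=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def write_truth(path: Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"duplicate_partner": str})
    for col in ("true_omega", "true_ks"):
        truth[col] = pd.to_numeric(truth[col].replace("", np.nan))
    return truth


def write_genome_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    """Write proteins.faa, cds.fna, genome.fna, genes.gff3, truth.tsv and a
    config echo; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "cds": outdir / "cds.fna",
        "genome": outdir / "genome.fna",
        "gff": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    _write_fasta(paths["proteins"], bundle.proteins)
    _write_fasta(paths["cds"], bundle.cds)
    _write_fasta(paths["genome"], bundle.genome)
    write_gff3(paths["gff"], bundle.genes)
    write_truth(paths["truth"], bundle.truth)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    return paths
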