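"""End-to-end pipeline: simulate/load -> scan -> classify -> props ->
evolve -> motifs -> express, with a machine-readable report and a
checksummed output manifest for determinism checks.

One YAML config drives a run; it contains either a ``simulate`` block
(synthetic genome, the bundled test bed) or an ``inputs`` block naming
protein/CDS FASTA, GFF3 and optional genome/FPKM/qPCR files, plus optional
per-stage parameter blocks (scan, classify, evolve, motifs, express).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domain_scan import calibrate_threshold, filter_hits, load_bundled_profile, scan_protein
from .evolution import assign_clades, bootstrap_support, find_duplicates, kaks
from .expression import (
    ddct,
    filter_unexpressed,
    heatmap_long_format,
    stress_response_calls,
    tissue_specificity,
)
from .family_classify import (
    assign_names,
    chromosome_distribution,
    classify_gene,
    load_reference_domains,
)
from .motif_scan import extract_promoter, scan_promoter_elements, scan_repression_motifs
from .protein_props import conservation_profile, conservation_table, physchem_table
from .synthetic_data import (
    GeneModel,
    SimulationConfig,
    generate_expression,
    generate_family_genome,
    generate_qpcr,
    read_fasta,
    read_gff3,
    write_genome_bundle,
)

logger = logging.getLogger(__name__)

FAMILY_SUBFAMILIES = ("ERF", "DREB", "DRF", "AP2", "RAV", "SOLOIST")

PROTEIN_MOTIF_NAMES = {"RK-LFGV", "FDLNLPP", "LF-DLN-LF", "EDLL"}
PROMOTER_ELEMENT_NAMES = {"DRE", "ABRE", "re2f-1", "ACGT-motif"}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class InputError(ValueError):
    """Missing or invalid pipeline input configuration."""


@dataclass
class PipelineReport:
    seed: int
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    wall_time_s: float = 0.0  # informational only; excluded from manifest

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    report: PipelineReport
    tables: dict
    out_dir: Path
    truth: pd.DataFrame | None = None


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise InputError("pipeline config must be a mapping")
    return config


def _write_tsv(path: Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config, out_dir, seed: int | None = None) -> RunResult:
    """Run every stage in order; any stage failure aborts with a
    stage-named error.  Outputs land under ``out_dir`` with a manifest of
    sha256 checksums (report.json excluded: it carries wall time)."""
    config = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    tables: dict = {}
    outputs: dict[str, Path] = {}

    # ---- inputs ----------------------------------------------------------
    truth = None
    if "simulate" in config:
        sim_conf = dict(config["simulate"] or {})
        if seed is not None:
            sim_conf["seed"] = seed
        sim = SimulationConfig.from_dict(sim_conf)
        run_seed = sim.seed
        try:
            bundle = generate_family_genome(sim)
            fpkm = generate_expression(bundle.truth, sim)
            qpcr = generate_qpcr(bundle.truth, sim)
        except Exception as exc:  # config invalid counts etc.
            raise InputError(str(exc)) from exc
        truth = bundle.truth
        genes = bundle.genes
        genome = bundle.genome
        sim_paths = write_genome_bundle(bundle, out_dir / "simulated")
        fpkm_path = out_dir / "simulated" / "fpkm.tsv"
        _write_tsv(fpkm_path, fpkm, index=True)
        qpcr_path = out_dir / "simulated" / "qpcr.tsv"
        _write_tsv(qpcr_path, qpcr)
        for key, p in {**sim_paths, "fpkm": fpkm_path, "qpcr": qpcr_path}.items():
            outputs[f"simulated/{p.name}"] = p
    elif "inputs" in config:
        inputs = config["inputs"] or {}
        for key in ("proteins", "cds", "gff"):
            if key not in inputs:
                raise InputError(f"inputs block missing required key {key!r}")
        proteins = read_fasta(inputs["proteins"])
        cds = read_fasta(inputs["cds"])
        genes = read_gff3(inputs["gff"])
        for g in genes:
            g.protein = proteins.get(g.id, "")
            g.cds = cds.get(g.id, "")
        genome = read_fasta(inputs["genome"]) if "genome" in inputs else None
        fpkm = (
            pd.read_csv(inputs["fpkm"], sep="\t", index_col=0)
            if "fpkm" in inputs
            else None
        )
        qpcr = pd.read_csv(inputs["qpcr"], sep="\t") if "qpcr" in inputs else None
        run_seed = seed if seed is not None else 0
    else:
        raise InputError("config needs a 'simulate' or an 'inputs' block")

    gene_by_id = {g.id: g for g in genes}

    # ---- scan ------------------------------------------------------------
    scan_conf = config.get("scan", {}) or {}
    try:
        profiles = {"AP2": load_bundled_profile("AP2"), "B3": load_bundled_profile("B3")}
        thresholds = {}
        for name, profile in profiles.items():
            thresholds[name] = calibrate_threshold(
                profile,
                n_shuffles=int(scan_conf.get("n_shuffles", 200)),
                protein_length=int(scan_conf.get("calibration_length", 300)),
                target_evalue=float(scan_conf.get("target_evalue", 1e-5)),
                seed=run_seed + 1,
            )
        all_hits = []
        for g in genes:
            for name, profile in profiles.items():
                all_hits.extend(
                    scan_protein(g.protein, profile, thresholds[name], gene_id=g.id)
                )
        kept = filter_hits(
            all_hits,
            max_evalue=float(scan_conf.get("max_evalue", 1e-5)),
            min_coverage=float(scan_conf.get("min_coverage", 0.7)),
        )
        hits_by_gene: dict[str, list] = {}
        for h in kept:
            hits_by_gene.setdefault(h.gene_id, []).append(h)
        tables["hits"] = pd.DataFrame(
            [
                (h.gene_id, h.profile_name, h.start, h.end, h.score, h.evalue,
                 h.coverage)
                for h in kept
            ],
            columns=["gene_id", "profile", "start", "end", "score", "evalue",
                     "coverage"],
        )
        outputs["hits.tsv"] = out_dir / "hits.tsv"
        _write_tsv(outputs["hits.tsv"], tables["hits"])
    except Exception as exc:
        raise StageError("scan", exc) from exc

    # ---- classify --------------------------------------------------------
    try:
        references = load_reference_domains(
            (config.get("classify", {}) or {}).get("references")
        )
        records = []
        unclassified = []
        for g in genes:
            hits = hits_by_gene.get(g.id, [])
            if not hits:
                continue
            rec = classify_gene(g.id, hits, g.protein, references, profiles["AP2"])
            rec.chromosome, rec.start, rec.strand = g.chromosome, g.start, g.strand
            if rec.subfamily in FAMILY_SUBFAMILIES:
                records.append(rec)
            else:
                unclassified.append(rec)
        prefix = (config.get("classify", {}) or {}).get("prefix", "TtAP2/ERF")
        naming = assign_names(records, prefix=prefix)
        dist = chromosome_distribution(records)
        tables["classification"] = pd.DataFrame(
            [
                (r.gene_id, r.assigned_name, r.subfamily, "+".join(r.architecture),
                 r.chromosome, r.start, r.strand,
                 "" if r.linker_length is None else r.linker_length)
                for r in sorted(records + unclassified, key=lambda r: r.gene_id)
            ],
            columns=["gene_id", "assigned_name", "subfamily", "architecture",
                     "chromosome", "start", "strand", "linker_length"],
        )
        tables["chromosome_counts"] = pd.DataFrame(
            sorted(dist["per_chromosome"].items()), columns=["chromosome", "n_genes"]
        )
        tables["naming"] = naming
        outputs["classification.tsv"] = out_dir / "classification.tsv"
        _write_tsv(outputs["classification.tsv"], tables["classification"])
        outputs["chromosome_counts.tsv"] = out_dir / "chromosome_counts.tsv"
        _write_tsv(outputs["chromosome_counts.tsv"], tables["chromosome_counts"])
    except Exception as exc:
        raise StageError("classify", exc) from exc

    family_ids = [r.gene_id for r in records]

    # ---- props -----------------------------------------------------------
    try:
        tables["physchem"] = physchem_table(
            {gid: gene_by_id[gid].protein for gid in family_ids}
        )
        domain_seqs: dict[str, str] = {}
        for gid in family_ids:
            for h in hits_by_gene.get(gid, []):
                if h.profile_name == "AP2" and h.coverage == 1.0:
                    domain_seqs[gid] = gene_by_id[gid].protein[h.start : h.end]
                    break
        if len(domain_seqs) >= 2:
            cols = conservation_profile(list(domain_seqs.values()))
            tables["conservation"] = conservation_table(cols)
        else:
            tables["conservation"] = pd.DataFrame()
        outputs["physchem.tsv"] = out_dir / "physchem.tsv"
        _write_tsv(outputs["physchem.tsv"], tables["physchem"])
        outputs["conservation_ap2.tsv"] = out_dir / "conservation_ap2.tsv"
        _write_tsv(outputs["conservation_ap2.tsv"], tables["conservation"])
    except Exception as exc:
        raise StageError("props", exc) from exc

    # ---- evolve ----------------------------------------------------------
    evolve_conf = config.get("evolve", {}) or {}
    try:
        family_cds = {gid: gene_by_id[gid].cds for gid in family_ids}
        pairs_df = pd.DataFrame(
            columns=["gene_a", "gene_b", "identity", "ka", "ks", "omega", "selection",
                     "cluster"]
        )
        if len(family_cds) >= 2:
            retained, clusters = find_duplicates(
                family_cds,
                identity_threshold=float(evolve_conf.get("identity_threshold", 0.85)),
            )
            pairs = []
            for aln in retained:
                pair = kaks(aln)
                pair.cluster = clusters.get(pair.gene_a)
                pairs.append(pair)
            pairs_df = pd.DataFrame(
                [
                    (p.gene_a, p.gene_b, p.identity, p.ka, p.ks, p.omega, p.selection,
                     p.cluster)
                    for p in pairs
                ],
                columns=pairs_df.columns,
            )
        tables["duplicates"] = pairs_df

        tree_leaves = dict(domain_seqs)
        ref_labels = {}
        for i, (label, seq) in enumerate(references, start=1):
            leaf = f"REF_{label}_{i}"
            tree_leaves[leaf] = seq
            ref_labels[leaf] = label
        if len(tree_leaves) >= 4:
            tree = bootstrap_support(
                tree_leaves,
                n_replicates=int(evolve_conf.get("bootstrap", 1000)),
                seed=run_seed + 2,
            )
            clades = assign_clades(tree, ref_labels)
            tables["tree"] = tree.newick()
            tables["clades"] = pd.DataFrame(
                sorted(clades.items()), columns=["gene_id", "clade"]
            )
        else:
            tables["tree"] = ""
            tables["clades"] = pd.DataFrame(columns=["gene_id", "clade"])
        outputs["duplicate_pairs.tsv"] = out_dir / "duplicate_pairs.tsv"
        _write_tsv(outputs["duplicate_pairs.tsv"], tables["duplicates"])
        outputs["tree.nwk"] = out_dir / "tree.nwk"
        outputs["tree.nwk"].write_text(tables["tree"] + "\n")
        outputs["clades.tsv"] = out_dir / "clades.tsv"
        _write_tsv(outputs["clades.tsv"], tables["clades"])
    except Exception as exc:
        raise StageError("evolve", exc) from exc

    # ---- motifs ----------------------------------------------------------
    motifs_conf = config.get("motifs", {}) or {}
    try:
        protein_hits = []
        for gid in family_ids:
            protein_hits.extend(scan_repression_motifs(gene_by_id[gid].protein, gid))
        tables["protein_motifs"] = pd.DataFrame(
            [(h.sequence_id, h.motif_name, h.start, h.end, h.matched_text)
             for h in protein_hits],
            columns=["gene_id", "motif", "start", "end", "matched_text"],
        )
        promoter_hits = []
        if genome is not None:
            length = int(motifs_conf.get("promoter_length", 1500))
            for gid in family_ids:
                promoter = extract_promoter(genome, gene_by_id[gid], length=length)
                promoter_hits.extend(scan_promoter_elements(promoter, gid))
        tables["promoter_elements"] = pd.DataFrame(
            [(h.sequence_id, h.motif_name, h.start, h.end, h.strand, h.matched_text)
             for h in promoter_hits],
            columns=["gene_id", "element", "start", "end", "strand", "matched_text"],
        )
        outputs["protein_motifs.tsv"] = out_dir / "protein_motifs.tsv"
        _write_tsv(outputs["protein_motifs.tsv"], tables["protein_motifs"])
        outputs["promoter_elements.tsv"] = out_dir / "promoter_elements.tsv"
        _write_tsv(outputs["promoter_elements.tsv"], tables["promoter_elements"])
    except Exception as exc:
        raise StageError("motifs", exc) from exc

    # ---- express ---------------------------------------------------------
    express_conf = config.get("express", {}) or {}
    try:
        if fpkm is not None:
            family_fpkm = fpkm.loc[[g for g in fpkm.index if g in set(family_ids)]]
            filtered = filter_unexpressed(
                family_fpkm, min_fpkm=float(express_conf.get("min_fpkm", 0.5))
            )
            classes = tissue_specificity(
                filtered,
                tau_threshold=float(express_conf.get("tau_threshold", 0.8)),
                min_peak_fpkm=float(express_conf.get("min_peak_fpkm", 1.0)),
            )
            calls = stress_response_calls(
                filtered,
                log2fc_threshold=float(express_conf.get("log2fc_threshold", 1.0)),
                min_fpkm=float(express_conf.get("min_fpkm", 0.5)),
            )
            tables["expression_classes"] = classes
            tables["stress_calls"] = calls
            tables["heatmap"] = heatmap_long_format(filtered, classes)
            tables["fpkm_filtered"] = filtered
            outputs["expression_classes.tsv"] = out_dir / "expression_classes.tsv"
            _write_tsv(outputs["expression_classes.tsv"], classes, index=True)
            outputs["stress_calls.tsv"] = out_dir / "stress_calls.tsv"
            _write_tsv(outputs["stress_calls.tsv"], calls)
            outputs["heatmap_long.tsv"] = out_dir / "heatmap_long.tsv"
            _write_tsv(outputs["heatmap_long.tsv"], tables["heatmap"])
        if qpcr is not None:
            tables["qpcr_ddct"] = ddct(
                qpcr, control_treatment=express_conf.get("control", "control")
            )
            outputs["qpcr_ddct.tsv"] = out_dir / "qpcr_ddct.tsv"
            _write_tsv(outputs["qpcr_ddct.tsv"], tables["qpcr_ddct"])
    except Exception as exc:
        raise StageError("express", exc) from exc

    # ---- report & manifest ----------------------------------------------
    classification = tables["classification"]
    subfam_tally = classification[
        classification["subfamily"].isin(FAMILY_SUBFAMILIES)
    ]["subfamily"].value_counts().to_dict()
    counts = {
        "n_genes_input": len(genes),
        "n_family_members": len(family_ids),
        "n_unclassified": len(unclassified),
        "n_non_members": len(genes) - len(family_ids) - len(unclassified),
        "subfamily_tally": subfam_tally,
        "n_duplicate_pairs": int(len(tables["duplicates"])),
        "n_saturated_pairs": int(
            (tables["duplicates"]["selection"] == "saturated").sum()
        ),
        "n_purifying_pairs": int(
            (tables["duplicates"]["selection"] == "purifying").sum()
        ),
        "clade_tally": tables["clades"]["clade"].value_counts().to_dict()
        if len(tables["clades"])
        else {},
        "protein_motif_tally": tables["protein_motifs"]["motif"]
        .value_counts()
        .to_dict(),
        "promoter_element_tally": tables["promoter_elements"]["element"]
        .value_counts()
        .to_dict(),
    }
    if "expression_classes" in tables:
        counts["expression_class_tally"] = (
            tables["expression_classes"]["class"].value_counts().to_dict()
        )
    assert sum(subfam_tally.values()) == counts["n_family_members"]

    manifest = {
        rel: hashlib.sha256(path.read_bytes()).hexdigest()
        for rel, path in sorted(outputs.items())
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"files": manifest, "seed": run_seed}, fh, indent=2, sort_keys=True)

    report = PipelineReport(
        seed=run_seed,
        version=__version__,
        config=config,
        counts=counts,
        wall_time_s=round(time.perf_counter() - t0, 3),
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    return RunResult(report=report, tables=tables, out_dir=out_dir, truth=truth)


def validate_report(result: RunResult, truth: pd.DataFrame) -> list[str]:
    """Compare a run's outputs against the generator's truth table.

    Checks subfamily assignments, the duplicate-pair set, planted motif
    positions and expression classes; an empty list means the run
    reproduced every planting.
    """
    discrepancies: list[str] = []
    truth_ids = set(truth["gene_id"])
    classification = result.tables["classification"].set_index("gene_id")
    unknown = set(classification.index) - truth_ids
    if unknown:
        raise ValueError(f"report genes absent from truth: {sorted(unknown)}")

    for _, rec in truth.iterrows():
        gid, expected = rec["gene_id"], rec["true_subfamily"]
        observed = (
            classification.loc[gid, "subfamily"] if gid in classification.index else "NONE"
        )
        if expected == "NONE":
            if observed != "NONE":
                discrepancies.append(f"{gid}: expected non-member, classified {observed}")
        elif observed != expected:
            discrepancies.append(f"{gid}: subfamily {observed} != truth {expected}")

    truth_pairs = {
        frozenset((rec["gene_id"], rec["duplicate_partner"]))
        for _, rec in truth.iterrows()
        if rec["duplicate_partner"]
    }
    found_pairs = {
        frozenset((a, b))
        for a, b in zip(result.tables["duplicates"]["gene_a"],
                        result.tables["duplicates"]["gene_b"])
    }
    for pair in sorted(truth_pairs - found_pairs, key=sorted):
        discrepancies.append(f"duplicate pair missed: {sorted(pair)}")
    for pair in sorted(found_pairs - truth_pairs, key=sorted):
        discrepancies.append(f"spurious duplicate pair: {sorted(pair)}")

    prot_hits = {
        (r.gene_id, r.motif, r.start)
        for r in result.tables["protein_motifs"].itertuples()
    }
    prom_hits = {
        (r.gene_id, r.element, r.start)
        for r in result.tables["promoter_elements"].itertuples()
    }
    for _, rec in truth.iterrows():
        for name, pos in json.loads(rec["planted_motifs"]):
            key = (rec["gene_id"], name, pos)
            if name in PROTEIN_MOTIF_NAMES and key not in prot_hits:
                discrepancies.append(f"planted protein motif missed: {key}")
            if name in PROMOTER_ELEMENT_NAMES and key not in prom_hits:
                discrepancies.append(f"planted promoter element missed: {key}")

    if "expression_classes" in result.tables:
        classes = result.tables["expression_classes"]
        calls = result.tables["stress_calls"]
        family = {g for g in truth_ids
                  if truth.set_index("gene_id").loc[g, "true_subfamily"] != "NONE"}
        for _, rec in truth.iterrows():
            gid, cls = rec["gene_id"], rec["expression_class"]
            if gid not in family:
                continue
            if cls == "silent":
                if gid in classes.index:
                    discrepancies.append(f"{gid}: silent gene not filtered out")
            elif cls in ("ubiquitous",) or cls.startswith("tissue_specific:"):
                observed = classes.loc[gid, "class"] if gid in classes.index else "absent"
                if observed != cls:
                    discrepancies.append(
                        f"{gid}: expression class {observed} != truth {cls}"
                    )
            elif cls in ("stress_up", "stress_down"):
                want = "up" if cls == "stress_up" else "down"
                sub = calls[calls["gene_id"] == gid]
                if sub.empty or not (sub["call"] == want).all():
                    discrepancies.append(f"{gid}: stress calls do not match {cls}")
    return discrepancies
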