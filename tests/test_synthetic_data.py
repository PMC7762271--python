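"""Generator contracts: counts, determinism, architectures, translation
consistency and the controlled-divergence duplicate model."""

import json

import numpy as np
import pytest
from Bio.Seq import Seq

from genefamkit.synthetic_data import (
    SimulationConfig,
    back_translate,
    generate_expression,
    generate_family_genome,
    generate_qpcr,
    mutate_duplicate,
    write_genome_bundle,
)


class TestGenerateFamilyGenome:
    def test_counts_follow_config(self):
        cfg = SimulationConfig(
            counts={"ERF": 5, "AP2": 2, "RAV": 2, "SOLOIST": 1, "NONE": 3},
            n_duplicate_pairs=0, seed=7,
        )
        bundle = generate_family_genome(cfg)
        assert len(bundle.genes) == 13
        truth = bundle.truth
        assert (truth["true_subfamily"] != "NONE").sum() == 10
        domain_positive = truth[truth["true_subfamily"] != "NONE"]
        assert all(
            len(json.loads(p)) >= 1 for p in domain_positive["domain_positions"]
        )

    def test_seed_determinism_byte_identical(self, tmp_path, small_config):
        paths_a = write_genome_bundle(
            generate_family_genome(small_config), tmp_path / "a"
        )
        paths_b = write_genome_bundle(
            generate_family_genome(small_config), tmp_path / "b"
        )
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key

    def test_rav_architecture_ap2_before_b3(self, small_bundle):
        truth = small_bundle.truth
        ravs = truth[truth["true_subfamily"] == "RAV"]
        assert len(ravs) > 0
        for _, rec in ravs.iterrows():
            positions = json.loads(rec["domain_positions"])
            ap2 = [p for p in positions if p[0] == "AP2"]
            b3 = [p for p in positions if p[0] == "B3"]
            assert len(ap2) == 1 and len(b3) == 1
            assert ap2[0][2] <= b3[0][1]  # AP2 strictly upstream of B3

    def test_ap2_architecture_two_domains_with_linker(self, small_bundle):
        truth = small_bundle.truth
        for _, rec in truth[truth["true_subfamily"] == "AP2"].iterrows():
            positions = json.loads(rec["domain_positions"])
            assert [p[0] for p in positions] == ["AP2", "AP2"]
            assert positions[1][1] - positions[0][2] == 25

    def test_translation_consistency(self, small_bundle):
        for gene in small_bundle.genes:
            assert str(Seq(gene.cds).translate(to_stop=True)) == gene.protein

    def test_duplicate_partner_symmetry_and_omega(self, small_bundle):
        truth = small_bundle.truth.set_index("gene_id")
        partnered = truth[truth["duplicate_partner"] != ""]
        assert len(partnered) > 0
        for gid, rec in partnered.iterrows():
            partner = rec["duplicate_partner"]
            assert truth.loc[partner, "duplicate_partner"] == gid
            assert np.isfinite(rec["true_omega"])
        unpartnered = truth[truth["duplicate_partner"] == ""]
        assert unpartnered["true_omega"].isna().all()

    def test_genes_placed_on_valid_nonoverlapping_coordinates(self, small_bundle):
        by_chrom = {}
        for g in small_bundle.genes:
            assert g.chromosome in small_bundle.config.chromosomes
            assert 1 <= g.start <= g.end <= len(small_bundle.genome[g.chromosome])
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            generate_family_genome(
                SimulationConfig(counts={f: 0 for f in ("ERF", "NONE")})
            )

    def test_bad_chromosome_rejected(self):
        with pytest.raises(ValueError):
            generate_family_genome(SimulationConfig(chromosomes=["8C"]))


class TestMutateDuplicate:
    @staticmethod
    def random_cds(n_codons=120, seed=0):
        rng = np.random.default_rng(seed)
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, n_codons))
        return back_translate(protein, rng)[:-3]

    def test_omega_zero_preserves_protein(self):
        cds = self.random_cds()
        mutated, ka, ks = mutate_duplicate(cds, omega=0.0, ks_target=0.4, seed=5)
        assert str(Seq(mutated).translate()) == str(Seq(cds).translate())
        assert ka == 0.0 and ks > 0.0

    def test_ks_target_zero_is_identity(self):
        cds = self.random_cds()
        mutated, ka, ks = mutate_duplicate(cds, omega=0.5, ks_target=0.0, seed=5)
        assert mutated == cds and ka == 0.0 and ks == 0.0

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            mutate_duplicate("ATGTAAGGG", omega=0.5, ks_target=0.1, seed=0)

    def test_no_stops_introduced(self):
        from genefamkit.evolution import CODON_TO_AA

        cds = self.random_cds(300, seed=3)
        mutated, _, _ = mutate_duplicate(cds, omega=1.0, ks_target=0.8, seed=9)
        codons = [mutated[i : i + 3] for i in range(0, len(mutated), 3)]
        assert all(CODON_TO_AA[c] != "*" for c in codons)

    def test_realized_ks_tracks_target(self):
        cds = self.random_cds(300, seed=4)
        realized = [
            mutate_duplicate(cds, omega=0.5, ks_target=0.3, seed=s)[2]
            for s in range(50)
        ]
        assert np.mean(realized) == pytest.approx(0.3, rel=0.1)


class TestGenerateExpression:
    def test_planted_classes_shape_matrix(self, small_bundle, small_config):
        matrix = generate_expression(small_bundle.truth, small_config)
        truth = small_bundle.truth.set_index("gene_id")
        assert set(matrix.index) == set(truth.index)
        for gid, rec in truth.iterrows():
            cls = rec["expression_class"]
            if cls == "silent":
                assert (matrix.loc[gid] == 0).all()
            elif cls.startswith("tissue_specific:"):
                assert matrix.loc[gid].idxmax() == cls.split(":", 1)[1]

    def test_fixed_seed_identical_matrix(self, small_bundle, small_config):
        a = generate_expression(small_bundle.truth, small_config)
        b = generate_expression(small_bundle.truth, small_config)
        assert a.equals(b)

    def test_unknown_class_rejected(self, small_bundle, small_config):
        truth = small_bundle.truth.copy()
        truth.loc[0, "expression_class"] = "bogus"
        with pytest.raises(ValueError):
            generate_expression(truth, small_config)


class TestGenerateQpcr:
    def test_three_replicates_per_condition(self, small_bundle, small_config):
        table = generate_qpcr(small_bundle.truth, small_config)
        sizes = table.groupby(["gene", "treatment"]).size()
        assert (sizes == 3).all()
        assert table["ct_target"].between(0, 45).all()

    def test_targets_are_stress_genes(self, small_bundle, small_config):
        table = generate_qpcr(small_bundle.truth, small_config)
        truth = small_bundle.truth.set_index("gene_id")
        for gene in table["gene"].unique():
            assert truth.loc[gene, "expression_class"] in ("stress_up", "stress_down")
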