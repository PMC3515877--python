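"""Unit tests for the synthetic data generators and their truth ledgers."""

import numpy as np
import pytest

from mapkevo import diversity as div
from mapkevo import io_formats as io
from mapkevo import synthetic_data as sd
from mapkevo._codons import is_stop


class TestSimulationConfig:
    def test_defaults_valid(self):
        sd.SimulationConfig()

    def test_validation(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(theta_site=-1)
        with pytest.raises(ValueError):
            sd.SimulationConfig(omega=-0.1)
        with pytest.raises(ValueError):
            sd.SimulationConfig(kappa=0)
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_accessions=1)


class TestSimulateCodingGene:
    def test_structure(self):
        rec = sd.simulate_coding_gene(50, seed=0)
        assert len(rec.seq) == 150
        assert rec.seq.startswith("ATG")
        codons = [rec.seq[i : i + 3] for i in range(0, 150, 3)]
        assert is_stop(codons[-1])
        assert not any(is_stop(c) for c in codons[:-1])

    def test_deterministic(self):
        assert sd.simulate_coding_gene(50, 3).seq == sd.simulate_coding_gene(50, 3).seq

    def test_different_seeds_differ(self):
        assert sd.simulate_coding_gene(50, 3).seq != sd.simulate_coding_gene(50, 4).seq


class TestEvolveOrthologPair:
    def test_frame_preserved(self):
        base = sd.simulate_coding_gene(100, seed=1).seq
        a, b = sd.evolve_ortholog_pair(base, 0.4, 0.3, 1.0, seed=2)
        for seq in (a, b):
            assert len(seq) == len(base)
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            assert not any(is_stop(c) for c in codons[:-1])
            assert is_stop(codons[-1])

    def test_deterministic(self):
        base = sd.simulate_coding_gene(50, seed=1).seq
        assert sd.evolve_ortholog_pair(base, 0.4, 0.3, 1.0, 5) == (
            sd.evolve_ortholog_pair(base, 0.4, 0.3, 1.0, 5)
        )

    def test_zero_branch_length_identity(self):
        base = sd.simulate_coding_gene(50, seed=1).seq
        assert sd.evolve_ortholog_pair(base, 0.0, 0.3, 1.0, 5) == (base, base)

    def test_omega_zero_keeps_protein(self):
        from mapkevo.ortholog_map import translate_cds

        base = sd.simulate_coding_gene(100, seed=1).seq
        a, b = sd.evolve_ortholog_pair(base, 0.5, 0.0, 1.0, seed=6)
        assert translate_cds(a) == translate_cds(base) == translate_cds(b)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            sd.evolve_ortholog_pair("ATGTAATTTTAA", 0.1, 1.0, 1.0, 0)


class TestSimulatePopulationSample:
    def test_variants_consistent_with_truth(self):
        base = sd.simulate_coding_gene(200, seed=7).seq
        variants, truth = sd.simulate_population_sample(base, 10, 0.02, seed=8)
        by_pos = {t["pos"]: t for t in truth}
        for acc, vs in variants.items():
            for v in vs:
                t = by_pos[v.pos]
                assert v.ref == t["ref"] == base[v.pos - 1]
                assert v.alt == t["alt"]
                assert acc in t["carriers"]

    def test_terminal_stop_untouched(self):
        base = sd.simulate_coding_gene(100, seed=9).seq
        variants, truth = sd.simulate_population_sample(base, 10, 0.1, seed=10)
        stop_positions = {len(base) - 2, len(base) - 1, len(base)}
        assert all(t["pos"] not in stop_positions for t in truth)

    @staticmethod
    def plantable_codon(cds):
        """First internal codon one base change away from a stop codon."""
        from mapkevo._codons import codon_neighbors

        for ci in range(1, len(cds) // 3 - 1):
            codon = cds[3 * ci : 3 * ci + 3]
            for pos in range(3):
                if any(is_stop(nb) for nb in codon_neighbors(codon, pos)):
                    return ci + 1  # 1-based
        raise AssertionError("no plantable codon in test gene")

    def test_stop_injection(self):
        base = sd.simulate_coding_gene(100, seed=11).seq
        target = self.plantable_codon(base)
        variants, truth = sd.simulate_population_sample(
            base, 5, 0.0, seed=12, stop_injections=[("acc002", target)]
        )
        injected = [t for t in truth if t.get("injected") == "premature_stop"]
        assert len(injected) == 1
        assert injected[0]["carriers"] == ["acc002"]
        # applying the variant creates a stop codon at the planted codon
        pseudo = div.apply_variants(base, variants["acc002"], "acc002", "g")
        codon = pseudo.seq[3 * (target - 1) : 3 * target]
        assert is_stop(codon)

    def test_cds_deletion_injection(self):
        base = sd.simulate_coding_gene(100, seed=13).seq
        variants, truth = sd.simulate_population_sample(
            base, 5, 0.0, seed=14, cds_deletions=[("acc001", 10, 2)]
        )
        pseudo = div.apply_variants(base, variants["acc001"], "acc001", "g")
        assert pseudo.seq[9:11] == "--"

    def test_expected_pi_near_theta(self):
        # E[pi] = theta under the neutral infinite-sites model
        theta = 0.02
        pis = []
        for rep in range(30):
            base = sd.simulate_coding_gene(300, seed=500 + rep).seq
            variants, _ = sd.simulate_population_sample(
                base, 12, theta, seed=900 + rep
            )
            rows = [
                div.apply_variants(base, vs, acc, "g").seq
                for acc, vs in variants.items()
            ]
            pis.append(div.nucleotide_diversity(rows).pi)
        assert np.mean(pis) == pytest.approx(theta, rel=0.25)


class TestGenomeBundle:
    def config(self):
        return sd.SimulationConfig(
            seed=5, n_genes=4, n_accessions=6, codons_per_gene=60
        )

    def test_ledger_cds_matches_extraction(self):
        bundle = sd.simulate_genome_bundle(self.config())
        for gene_id, info in bundle.ledger.genes.items():
            model = io.GeneModel(
                gene_id, info["chrom"], info["strand"], info["cds_segments"]
            )
            extracted = div.extract_cds(bundle.chromosomes[info["chrom"]], model)
            assert extracted == info["cds"], gene_id

    def test_both_strands_and_chromosomes_used(self):
        bundle = sd.simulate_genome_bundle(self.config())
        strands = {g["strand"] for g in bundle.ledger.genes.values()}
        chroms = {g["chrom"] for g in bundle.ledger.genes.values()}
        assert strands == {"+", "-"}
        assert chroms == {"Chr1", "Chr2"}

    def test_gff_parses_to_ledger_models(self, tmp_path):
        bundle = sd.simulate_genome_bundle(self.config())
        gff = tmp_path / "x.gff3"
        gff.write_text(bundle.gff3)
        models = {m.gene_id: m for m in io.read_gff3_protein_coding(gff)}
        assert set(models) == set(bundle.ledger.genes)
        for gene_id, info in bundle.ledger.genes.items():
            assert models[gene_id].cds_segments == [
                tuple(s) for s in info["cds_segments"]
            ]
            assert models[gene_id].strand == info["strand"]

    def test_variants_apply_cleanly_and_mutations_land(self):
        bundle = sd.simulate_genome_bundle(self.config())
        pseudo = {}
        for acc, records in bundle.variant_tables.items():
            by_chrom = {}
            for v in records:
                by_chrom.setdefault(v.chrom, []).append(v)
            pseudo[acc] = {
                c: div.apply_variants(seq, by_chrom.get(c, []), acc, c).seq
                for c, seq in bundle.chromosomes.items()
            }
        # every ledgered CDS mutation appears in its carriers' extracted CDS
        for gene_id, muts in bundle.ledger.mutations.items():
            info = bundle.ledger.genes[gene_id]
            model = io.GeneModel(
                gene_id, info["chrom"], info["strand"], info["cds_segments"]
            )
            for mut in muts:
                for acc in mut["carriers"]:
                    cds = div.extract_cds(pseudo[acc][info["chrom"]], model)
                    assert cds[mut["pos"] - 1] == mut["alt"], (gene_id, mut)

    def test_stop_injection_routed_through_bundle(self):
        # find a plantable codon in the first gene of the seed-5 bundle
        probe = sd.simulate_genome_bundle(self.config())
        gene_id = list(probe.ledger.genes)[0]
        target = TestSimulatePopulationSample.plantable_codon(
            probe.ledger.genes[gene_id]["cds"]
        )
        bundle = sd.simulate_genome_bundle(
            self.config(), stop_injections={0: [("acc003", target)]}
        )
        assert bundle.ledger.injected_effects[gene_id][0]["accession"] == "acc003"

    def test_ortholog_records_match_ledger(self):
        bundle = sd.simulate_genome_bundle(self.config())
        for rec in bundle.ortholog_cds:
            gene_id = rec.id.replace("_ort", "")
            assert rec.seq == bundle.ledger.genes[gene_id]["ortholog_cds"]

    def test_write_bundle_round_trip(self, tmp_path):
        bundle = sd.simulate_genome_bundle(self.config())
        out = tmp_path / "bundle"
        sd.write_bundle(bundle, out, config=self.config())
        genome = io.read_fasta(out / "genome.fasta", "dna")
        assert {r.id for r in genome} == {"Chr1", "Chr2"}
        acc = sorted(bundle.variant_tables)[0]
        back = io.read_variant_table(out / "variants" / f"{acc}.tsv", acc)
        assert [(v.chrom, v.pos) for v in back] == [
            (v.chrom, v.pos) for v in bundle.variant_tables[acc]
        ]
        ledger = sd.TruthLedger.from_json((out / "truth.json").read_text())
        assert set(ledger.genes) == set(bundle.ledger.genes)


class TestSimulateProteome:
    def test_counts_and_ids(self):
        prot, ledger, seed_aln = sd.simulate_proteome(4, 10, ("TEY", "TDY"), seed=0)
        assert len(prot) == 14
        assert len(seed_aln) == 8
        assert set(ledger.family_members) == {f"fam{i:03d}" for i in range(4)}

    def test_loop_types_cycle(self):
        _, ledger, _ = sd.simulate_proteome(4, 0, ("TEY", "TDY"), seed=0)
        assert ledger.family_members["fam000"] == "TEY"
        assert ledger.family_members["fam001"] == "TDY"
        assert ledger.family_members["fam002"] == "TEY"

    def test_members_carry_their_motif(self):
        from mapkevo.family_scan import classify_activation_loop

        prot, ledger, _ = sd.simulate_proteome(6, 0, ("TEY", "TDY", "MEY"), seed=1)
        for rec in prot:
            assert classify_activation_loop(rec.seq)[0] == ledger.family_members[rec.id]

    def test_decoys_are_motif_free(self):
        from mapkevo.family_scan import classify_activation_loop

        prot, _, _ = sd.simulate_proteome(0, 40, ("TEY",), seed=2)
        for rec in prot:
            assert classify_activation_loop(rec.seq)[0] == "none"

    def test_bad_loop_type(self):
        with pytest.raises(ValueError, match="loop_types"):
            sd.simulate_proteome(2, 2, ("TTY",))


class TestSimulateExpression:
    def cluster_map(self):
        return {f"g{i}": ("c1" if i < 3 else "c2") for i in range(6)}

    def test_shape_and_ids(self):
        m = sd.simulate_expression(6, 10, self.cluster_map(), seed=0)
        assert m.values.shape == (6, 10)
        assert m.gene_ids == sorted(self.cluster_map())

    def test_within_cluster_correlation_exceeds_between(self):
        m = sd.simulate_expression(6, 40, self.cluster_map(), seed=1)
        corr = np.corrcoef(m.values)
        cm = self.cluster_map()
        within, between = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                (within if cm[m.gene_ids[i]] == cm[m.gene_ids[j]] else between).append(
                    corr[i, j]
                )
        assert min(within) > max(between)

    def test_rho_one_gives_perfect_correlation(self):
        m = sd.simulate_expression(6, 10, self.cluster_map(),
                                   within_cluster_rho=1.0, seed=2)
        corr = np.corrcoef(m.values)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError, match="n_samples"):
            sd.simulate_expression(6, 1, self.cluster_map())
        with pytest.raises(ValueError, match="cover"):
            sd.simulate_expression(7, 10, self.cluster_map())
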