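"""Synthetic genome bundles: construction contracts, determinism, recovery."""

import numpy as np
import pytest

from luxcart import (
    LuxcartInputError,
    PlantedArrangement,
    SyntheticConfig,
    generate_bundle,
    mutate_sequence,
    score_against_truth,
    write_bundle,
)
from luxcart.homolog_detection import classify_proteins
from luxcart.circuit_classification import call_arrangements
from luxcart.synthetic_genomes import load_seed_proteins, read_truth

from conftest import random_config


class TestGenerateBundle:
    def test_minimal_canonical_pair_construction(self):
        cfg = SyntheticConfig(
            n_contigs=1,
            n_background_genes=0,
            planted_arrangements=(PlantedArrangement("canonical_pair"),),
            seed=7,
        )
        bundle = generate_bundle(cfg)
        assert len(bundle.genes) == 2
        (truth,) = bundle.truth
        assert truth.category == "canonical_pair"
        assert len(truth.gene_ids) == 2

    def test_zero_mutation_planted_proteins_equal_seeds(self):
        seeds = load_seed_proteins()
        cfg = SyntheticConfig(
            n_contigs=1,
            n_background_genes=0,
            planted_arrangements=(PlantedArrangement("double_luxR_luxI", "T"),),
            mutation_rate=0.0,
            seed=3,
        )
        bundle = generate_bundle(cfg)
        sequences = {p.sequence for p in bundle.proteins}
        for seed_name in ("luxR_seed_A", "luxR_seed_B", "luxI_seed_A"):
            assert seeds[seed_name] in sequences

    def test_same_seed_byte_identical_different_seed_differs(self, tmp_path):
        cfg = SyntheticConfig(
            n_contigs=2,
            n_background_genes=10,
            planted_arrangements=(PlantedArrangement("luxR_solo"),),
            seed=1,
        )
        p1 = write_bundle(generate_bundle(cfg), tmp_path / "a")
        p2 = write_bundle(generate_bundle(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()
        cfg2 = SyntheticConfig(**{**cfg.__dict__, "seed": 2})
        p3 = write_bundle(generate_bundle(cfg2), tmp_path / "c")
        assert p1["gff"].read_bytes() != p3["gff"].read_bytes()

    def test_truth_covers_each_planted_gene_once(self):
        rng = np.random.default_rng(21)
        bundle = generate_bundle(random_config(rng))
        seen = [gid for t in bundle.truth for gid in t.gene_ids]
        assert len(seen) == len(set(seen))

    def test_contig_capacity_error(self):
        cfg = SyntheticConfig(
            n_contigs=1,
            n_background_genes=0,
            planted_arrangements=(PlantedArrangement("double_luxR_luxI", "T"),),
            contig_length_bp=2000,
            seed=0,
        )
        with pytest.raises(LuxcartInputError, match="capped"):
            generate_bundle(cfg)

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_contigs: 2\nn_background_genes: 4\nseed: 5\n"
            "planted_arrangements:\n  - {category: luxI_solo}\n"
        )
        cfg = SyntheticConfig.from_yaml(path)
        assert cfg.n_contigs == 2
        assert cfg.planted_arrangements[0].category == "luxI_solo"


class TestMutateSequence:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_sequence("MKTWYEAL", 0.0, rng) == "MKTWYEAL"

    def test_length_always_preserved(self):
        rng = np.random.default_rng(1)
        for rate in (0.1, 0.5, 0.9):
            assert len(mutate_sequence("MKTWYEAL" * 10, rate, rng)) == 80

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_substituted_fraction_concentrates_at_rate(self, seed):
        # binomial concentration: 10,000 residues at rate 0.5 -> 0.5 +/- 0.02
        rng = np.random.default_rng(seed)
        seq = "".join(
            np.random.default_rng(7).choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10_000)
        )
        out = mutate_sequence(seq, 0.5, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert abs(frac - 0.5) < 0.02


class TestRoundTrips:
    def test_written_bundle_reparses_identically(self, tmp_path, small_bundle):
        from luxcart import read_domain_hits, read_fasta, read_gff

        cfg, bundle = small_bundle
        paths = write_bundle(bundle, tmp_path)
        genes = read_gff(paths["gff"], genome_id=cfg.genome_id)
        assert tuple(genes) == bundle.genes
        proteins = read_fasta(paths["fasta"])
        assert tuple(sorted(proteins, key=lambda p: p.gene_id)) == bundle.proteins
        hits = read_domain_hits(paths["domtblout"]) + read_domain_hits(paths["interproscan"])
        assert {(h.gene_id, h.signature_id) for h in hits} == {
            (h.gene_id, h.signature_id) for h in bundle.hits
        }
        evalues = {
            (h.gene_id, h.signature_id): h.evalue for h in hits if h.evalue is not None
        }
        for h in bundle.hits:
            if h.evalue is not None:
                assert evalues[(h.gene_id, h.signature_id)] == pytest.approx(
                    h.evalue, rel=1e-2
                )
        assert read_truth(paths["truth"]) == list(bundle.truth)

    def test_planted_truth_recovered_over_random_configs(self):
        """Pipeline recovers planted categories exactly (50 random configs)."""
        rng = np.random.default_rng(2025)
        for _ in range(50):
            cfg = random_config(rng, decoy_rate=0.0)
            bundle = generate_bundle(cfg)
            verdicts = classify_proteins(
                bundle.hits, all_gene_ids=[g.gene_id for g in bundle.genes]
            )
            calls = call_arrangements(bundle.genes, verdicts)
            scores = score_against_truth(bundle.truth, calls)
            assert scores["precision"] == 1.0 and scores["recall"] == 1.0

    def test_decoys_never_authenticated(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            cfg = random_config(rng, decoy_rate=0.5)
            bundle = generate_bundle(cfg)
            planted = {gid for t in bundle.truth for gid in t.gene_ids}
            verdicts = classify_proteins(bundle.hits)
            for gene_id, vlist in verdicts.items():
                if gene_id not in planted:
                    assert not any(
                        v.verdict.startswith("AUTHENTIC") for v in vlist
                    ), f"decoy {gene_id} authenticated"
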