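"""Synthetic-study generator: determinism, truth-table bookkeeping, noise model."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from nephromine.errors import ConfigurationError
from nephromine.orthology import consensus_orthologs
from nephromine.synthio import (
    SimulationConfig,
    generate_identifications,
    generate_ortholog_maps,
    generate_proteome,
    generate_reference_sets,
    simulate_study,
    true_pairing,
    write_study,
)
from nephromine.tiers import venn_partition


class TestConfig:
    def test_zero_proteins_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_proteins=0)

    def test_partition_exceeding_proteome_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_proteins=10, venn_partition=(5, 5, 5, 5))

    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(ortholog_agreement=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_proteins=50, venn_partition=(10, 5, 3, 2))
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestProteome:
    def test_same_seed_identical_different_seed_differs(self):
        cfg1 = SimulationConfig(seed=1, n_proteins=100, venn_partition=(10, 5, 3, 2))
        p1 = generate_proteome(cfg1)
        p2 = generate_proteome(cfg1)
        assert p1 == p2
        cfg2 = SimulationConfig(seed=2, n_proteins=100, venn_partition=(10, 5, 3, 2))
        assert generate_proteome(cfg2) != p1

    def test_sequences_valid_and_unique_accessions(self, small_config):
        prot = generate_proteome(small_config)
        assert len(prot) == small_config.n_proteins
        for seq in prot.values():
            assert set(seq) <= set("ACDEFGHIKLMNPQRSTVWY")
            assert 100 <= len(seq) <= 600


class TestIdentifications:
    def test_truth_table_flag_counts_exact(self):
        cfg = SimulationConfig(seed=5, n_proteins=200, planted_hypoxia_fraction=0.1,
                               planted_rankshift_fraction=0.05, venn_partition=(50, 20, 10, 5))
        _, truth = generate_identifications(generate_proteome(cfg), cfg)
        assert truth["hypoxia_increased"].sum() == 20
        assert truth["rank_shifted"].sum() == 10

    def test_determinism(self, small_config):
        prot = generate_proteome(small_config)
        t1, truth1 = generate_identifications(prot, small_config)
        t2, truth2 = generate_identifications(prot, small_config)
        pd.testing.assert_frame_equal(truth1, truth2)
        for sid in t1:
            pd.testing.assert_frame_equal(t1[sid].records, t2[sid].records)

    def test_unity_fold_change_gives_no_systematic_condition_difference(self):
        cfg = SimulationConfig(seed=9, n_proteins=400, hypoxia_fold_change=1.0,
                               planted_hypoxia_fraction=0.1, planted_rankshift_fraction=0.0,
                               venn_partition=(0, 0, 0, 0))
        tables, truth = generate_identifications(generate_proteome(cfg), cfg)
        planted = set(truth.loc[truth["hypoxia_increased"], "protein_accession"])

        def counts(sample):
            df = tables[sample].records
            return df.loc[df["protein_accession"].isin(planted), "spectral_count"].to_numpy()

        oxy = np.concatenate([counts(f"oxygen_r{r}") for r in range(1, 5)])
        noo = np.concatenate([counts(f"no_oxygen_r{r}") for r in range(1, 5)])
        assert abs(noo.mean() / oxy.mean() - 1.0) < 0.1

    def test_planted_hypoxia_counts_elevated_in_every_rat(self):
        cfg = SimulationConfig(seed=9, n_proteins=400, hypoxia_fold_change=3.0,
                               planted_hypoxia_fraction=0.1, planted_rankshift_fraction=0.0,
                               venn_partition=(0, 0, 0, 0))
        tables, truth = generate_identifications(generate_proteome(cfg), cfg)
        planted = set(truth.loc[truth["hypoxia_increased"], "protein_accession"])
        for r in range(1, 5):
            oxy = tables[f"oxygen_r{r}"].records
            noo = tables[f"no_oxygen_r{r}"].records
            oxy_mean = oxy.loc[oxy["protein_accession"].isin(planted), "spectral_count"].mean()
            noo_mean = noo.loc[noo["protein_accession"].isin(planted), "spectral_count"].mean()
            assert noo_mean > 1.8 * oxy_mean

    def test_rank_shift_planting_elevates_perfusion_baseline(self, small_study):
        # reference counts are drawn at reference_depth_factor x baseline, so
        # the perfusion/reference count ratio for a 30x planted shift is
        # roughly 30 / depth; unplanted proteins sit around 1 / depth
        truth = small_study.truth
        depth = small_study.config.reference_depth_factor
        ref = small_study.identifications["reference_urine"].records.set_index("protein_accession")
        perf = small_study.identifications["oxygen_r1"].records.set_index("protein_accession")

        def ratios(accs):
            return [perf.loc[a, "spectral_count"] / max(1, ref.loc[a, "spectral_count"])
                    for a in accs if a in perf.index and a in ref.index]

        shifted = ratios(truth.loc[truth["rank_shifted"], "protein_accession"])
        normal = ratios(truth.loc[~truth["rank_shifted"], "protein_accession"])
        assert np.median(shifted) > (30 / depth) / 3
        assert np.median(shifted) > 5 * np.median(normal)


class TestOrthologMaps:
    def test_noiseless_limit_reproduces_truth(self):
        cfg = SimulationConfig(seed=4, n_proteins=80, ortholog_agreement=1.0,
                               ortholog_noise=0.0, venn_partition=(20, 10, 5, 5))
        maps = generate_ortholog_maps(generate_proteome(cfg), cfg)
        truth = set(map(tuple, true_pairing(cfg).values))
        for df in maps.values():
            assert set(map(tuple, df.values)) == truth

    def test_zero_agreement_has_no_true_pairs(self):
        cfg = SimulationConfig(seed=4, n_proteins=80, ortholog_agreement=0.0,
                               ortholog_noise=0.0, venn_partition=(20, 10, 5, 5))
        maps = generate_ortholog_maps(generate_proteome(cfg), cfg)
        assert all(df.empty for df in maps.values())

    def test_consensus_recovery_matches_bruteforce_against_truth(self):
        cfg = SimulationConfig(seed=6, n_proteins=500, ortholog_agreement=0.8,
                               ortholog_noise=0.01, venn_partition=(100, 50, 25, 25))
        maps = generate_ortholog_maps(generate_proteome(cfg), cfg)
        consensus = consensus_orthologs(maps, 2)
        got = set(map(tuple, consensus[["rat_protein", "human_gene"]].values))
        # brute-force oracle: count distinct-database votes per pair
        votes = Counter()
        for df in maps.values():
            for pair in set(map(tuple, df.values)):
                votes[pair] += 1
        expect = {pair for pair, v in votes.items() if v >= 2}
        assert got == expect
        truth = set(map(tuple, true_pairing(cfg).values))
        recall = len(got & truth) / len(truth)
        precision = len(got & truth) / len(got)
        assert recall > 0.95 and precision > 0.99


class TestReferenceSets:
    def test_induced_partition_matches_config(self, small_config):
        refsets = generate_reference_sets(small_config)
        pairing = true_pairing(small_config)
        kidney_genes = set(pairing["human_gene"]) & refsets["kidney"].genes
        from nephromine.formats import ReferenceSet
        pooled = ReferenceSet("ue", refsets["urine"].genes | refsets["exosome"].genes)
        part = venn_partition(kidney_genes, pooled, refsets["plasma"])
        b, u, p, n = small_config.venn_partition
        assert (part["both"], part["urine_only"], part["plasma_only"], part["neither"]) == (b, u, p, n)


def test_write_study_round_trips_and_is_deterministic(tmp_path, small_config):
    study = simulate_study(small_config)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_study(study, d1)
    p2 = write_study(simulate_study(small_config), d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
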