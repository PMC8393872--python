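"""The synthetic-data generator: planted structure must be present and
recoverable, null configurations must be clean, outputs deterministic."""

import numpy as np
import pytest

from mirnet import pathways, pulldown, synthetic
from mirnet.synthetic import SimulationConfig


def _small(**kw):
    base = dict(n_genes=200, n_targets=20, utr_length_mean=200, utr_length_sd=40,
                n_hubs=3, hub_extra_degree=40, n_genesets=10, n_enriched_genesets=2,
                geneset_size_range=(5, 20), seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 5},
            {"n_targets": 300},
            {"gc_content": 1.2},
            {"utr_length_mean": 30},
            {"peptides_per_protein_mean": 2},
            {"n_hubs": 500},
            {"geneset_size_range": (10, 900)},
            {"transcript_effect": float("inf")},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            _small(**kw)


class TestUniverse:
    def test_deterministic_fasta_bytes(self, tmp_path):
        cfg = _small()
        for sub in ("a", "b"):
            genes, utrs = synthetic.generate_universe(cfg)
            synthetic.write_fasta(utrs, tmp_path / f"{sub}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_gc_zero_means_only_at(self):
        _, utrs = synthetic.generate_universe(_small(gc_content=0.0))
        assert set("".join(utrs.values())) <= {"A", "T"}

    def test_mean_length_close_to_configured(self):
        cfg = SimulationConfig(n_genes=1000, n_targets=10, utr_length_mean=800, seed=3)
        _, utrs = synthetic.generate_universe(cfg)
        mean_len = np.mean([len(s) for s in utrs.values()])
        assert abs(mean_len - 800) / 800 < 0.05

    def test_minimum_length_enforced(self):
        cfg = _small(utr_length_mean=60, utr_length_sd=50)
        _, utrs = synthetic.generate_universe(cfg)
        assert min(len(s) for s in utrs.values()) >= 50


class TestPlantSeedSites:
    def test_every_target_contains_the_word(self):
        cfg = _small()
        _, utrs = synthetic.generate_universe(cfg)
        planted, truth = synthetic.plant_seed_sites(utrs, cfg)
        assert truth.planted_word == "TCCCCACA"
        for g in truth.target_genes:
            assert planted[g].count(truth.planted_word) >= 1
            assert truth.planted_site_counts[g] >= 1

    def test_no_targets_leaves_utrs_unchanged(self):
        cfg = _small(n_targets=0)
        _, utrs = synthetic.generate_universe(cfg)
        planted, truth = synthetic.plant_seed_sites(utrs, cfg)
        assert planted == utrs
        assert truth.target_genes == []

    def test_non_targets_untouched(self):
        cfg = _small()
        _, utrs = synthetic.generate_universe(cfg)
        planted, truth = synthetic.plant_seed_sites(utrs, cfg)
        for g in set(utrs) - set(truth.target_genes):
            assert planted[g] == utrs[g]

    def test_site_type_option_changes_word(self):
        cfg = _small(site_type="7mer-m8")
        _, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        assert truth.planted_word == "TCCCCAC"


class TestPulldownCounts:
    def test_counts_are_nonnegative_integers(self):
        cfg = _small()
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        counts = synthetic.simulate_pulldown_counts(genes, truth, cfg)
        vals = counts.to_numpy()
        assert (vals >= 0).all()
        assert np.issubdtype(vals.dtype, np.integer)

    def test_null_fold_centres_ratio_at_zero(self):
        cfg = SimulationConfig(n_genes=2000, n_targets=100,
                               pulldown_enrichment_fold=1.0, seed=5)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        counts = synthetic.simulate_pulldown_counts(genes, truth, cfg)
        enr = pulldown.enrichment_ratio(
            pulldown.normalize_counts(pulldown.filter_all_zero(counts)), pseudocount=1
        )
        assert abs(enr["log2_ratio"].mean()) < 0.1

    def test_eightfold_separation_in_log2(self):
        cfg = SimulationConfig(n_genes=2000, n_targets=100,
                               pulldown_enrichment_fold=8.0, seed=7)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        counts = synthetic.simulate_pulldown_counts(genes, truth, cfg)
        enr = pulldown.enrichment_ratio(
            pulldown.normalize_counts(pulldown.filter_all_zero(counts)), pseudocount=1
        )
        is_t = enr.index.isin(truth.target_genes)
        diff = enr.loc[is_t, "log2_ratio"].mean() - enr.loc[~is_t, "log2_ratio"].mean()
        assert abs(diff - 3.0) < 0.3


class TestExpression:
    def test_zero_noise_gives_exact_effects(self):
        cfg = _small(noise_sd=0.0, peptide_noise_sd=0.0, mix_error_sd=0.0,
                     transcript_effect=1.0)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        fc, _ = synthetic.simulate_expression(genes, truth, cfg)
        target_fc = fc.loc[fc["gene"].isin(truth.target_genes), "log2fc"]
        assert np.allclose(target_fc, -1.0)

    def test_noise_free_rollup_recovers_protein_ratio(self):
        from mirnet import expression

        cfg = _small(noise_sd=0.0, peptide_noise_sd=0.0, mix_error_sd=0.0,
                     protein_effect=1.0)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        _, peptides = synthetic.simulate_expression(genes, truth, cfg)
        prot = expression.rollup_protein(expression.scale_normalize(peptides))
        detected_targets = set(prot["protein"]) & set(truth.target_genes)
        vals = prot.set_index("protein").loc[sorted(detected_targets), "log2_ratio"]
        assert np.allclose(vals, -1.0)

    def test_target_recall_matches_normal_tail(self):
        # P(X < -0.5 | mu=-1, sd=0.3) ~ 0.952
        cfg = SimulationConfig(n_genes=4000, n_targets=200, transcript_effect=1.0,
                               noise_sd=0.3, seed=9)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        fc, _ = synthetic.simulate_expression(genes, truth, cfg)
        target_fc = fc.loc[fc["gene"].isin(truth.target_genes), "log2fc"]
        assert (target_fc <= -0.5).mean() > 0.90

    def test_every_protein_has_three_peptides(self):
        cfg = _small(peptides_per_protein_mean=3)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        _, peptides = synthetic.simulate_expression(genes, truth, cfg)
        per_prot = peptides.groupby("protein")["peptide"].nunique()
        assert (per_prot >= 3).all()


class TestNetwork:
    def test_zero_hubs_attachment_one_gives_tree(self):
        cfg = _small(n_hubs=0, network_attachment=1, decoy_edge_fraction=0.0)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        net = synthetic.simulate_network(genes, truth, cfg)
        assert len(net) == len(genes) - 1

    def test_hub_degrees_reach_99th_percentile(self):
        # hubs must stay well under 1% of nodes or the 99th percentile is
        # computed over the hubs themselves
        cfg = _small(n_genes=500, n_targets=40, n_hubs=3)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        net = synthetic.simulate_network(genes, truth, cfg)
        import networkx as nx

        g = nx.from_pandas_edgelist(net, "protein_a", "protein_b")
        degrees = dict(g.degree())
        p99 = np.percentile(list(degrees.values()), 99)
        for hub in truth.hub_genes:
            assert degrees[hub] >= p99

    def test_no_self_loops_or_duplicate_pairs(self):
        cfg = _small()
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        net = synthetic.simulate_network(genes, truth, cfg)
        assert (net["protein_a"] != net["protein_b"]).all()
        pairs = list(zip(net["protein_a"], net["protein_b"]))
        assert len(pairs) == len(set(pairs))

    def test_scores_within_range_and_planted_confident(self):
        cfg = _small()
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        net = synthetic.simulate_network(genes, truth, cfg)
        assert net["combined_score"].between(150, 999).all()
        hub_edges = net.loc[
            net["protein_a"].isin(truth.hub_genes) | net["protein_b"].isin(truth.hub_genes)
        ]
        assert (hub_edges["combined_score"] >= 400).mean() > 0.9


class TestGenesets:
    def test_full_enrichment_fraction_subsets_targets(self):
        cfg = _small(geneset_target_fraction=1.0, geneset_size_range=(5, 15),
                     n_targets=30)
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        coll = synthetic.simulate_genesets(genes, truth, cfg)
        for name in truth.enriched_genesets:
            assert set(coll.sets[name]) <= set(truth.target_genes)

    def test_gmt_round_trip(self, tmp_path):
        cfg = _small()
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        coll = synthetic.simulate_genesets(genes, truth, cfg)
        path = tmp_path / "sets.gmt"
        pathways.write_gmt(coll, path)
        assert pathways.read_gmt(path).sets == coll.sets

    def test_size_range_respected(self):
        cfg = _small()
        genes, utrs = synthetic.generate_universe(cfg)
        _, truth = synthetic.plant_seed_sites(utrs, cfg)
        coll = synthetic.simulate_genesets(genes, truth, cfg)
        lo, hi = cfg.geneset_size_range
        for members in coll.sets.values():
            assert lo <= len(members) <= hi


class TestSimulateAll:
    def test_files_parse_with_module_readers(self, tmp_path, small_config):
        from mirnet import expression, netbuild, seedscan

        synthetic.simulate_all(small_config, outdir=tmp_path)
        utrs = seedscan.read_fasta(tmp_path / "utrs.fasta")
        assert len(utrs) == small_config.n_genes
        counts = pulldown.read_counts(tmp_path / "pulldown_counts.tsv")
        assert len(counts) == small_config.n_genes
        fc = expression.read_fold_changes(tmp_path / "transcriptome.tsv")
        assert len(fc) == small_config.n_genes
        expression.read_peptides(tmp_path / "peptides.tsv")
        netbuild.read_interactions(tmp_path / "network_edges.tsv", score_min=0)
        pathways.read_gmt(tmp_path / "sets.gmt")
        truth = synthetic.GroundTruth.from_json(tmp_path / "truth.json")
        assert len(truth.target_genes) == small_config.n_targets

    def test_fixed_seed_byte_identical_outputs(self, tmp_path, small_config):
        import hashlib

        digests = []
        for sub in ("runA", "runB"):
            out = tmp_path / sub
            synthetic.simulate_all(small_config, outdir=out)
            digests.append({
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
            })
        assert digests[0] == digests[1]
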