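import numpy as np
import pandas as pd
import pytest

import panconet as pc
from panconet.synthetic import true_factor_scores


def _small_config(**kw):
    defaults = dict(n_cohorts=1, genes_per_cohort=150,
                    samples_per_cohort=200, n_normal_samples=0, seed=0)
    defaults.update(kw)
    return pc.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_module_too_small_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _small_config(modules=[pc.ModuleSpec("m", 5)])

    def test_gene_budget_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            _small_config(modules=[pc.ModuleSpec("a", 100),
                                   pc.ModuleSpec("b", 100)])

    def test_censoring_range(self):
        with pytest.raises(ValueError, match="censoring"):
            _small_config(censoring_fraction=1.0)

    def test_child_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            _small_config(modules=[pc.ModuleSpec("m", 30,
                                                 children=(10, 10))])


class TestExpressionGenerator:
    def test_same_seed_bitwise_identical(self):
        cfg = pc.default_config(seed=3)
        a, _ = pc.generate_multi_cohort(cfg)
        b, _ = pc.generate_multi_cohort(pc.default_config(seed=3))
        for label in a:
            assert a[label]["expression"].equals(b[label]["expression"])
            assert a[label]["covariates"].equals(b[label]["covariates"])

    def test_target_correlation_realized(self):
        cfg = _small_config(modules=[pc.ModuleSpec("m", 50, 0.6)])
        cohorts, truth = pc.generate_multi_cohort(cfg)
        expr = cohorts["C1"]["expression"]
        adj = pc.preprocess(expr, cohorts["C1"]["covariates"],
                            apply_log2=False)
        sub = adj.loc[truth.module_genes["m"]]
        R = np.corrcoef(sub)
        mean_abs_r = np.abs(R[np.triu_indices(50, 1)]).mean()
        assert 0.5 <= mean_abs_r <= 0.7

    def test_null_config_has_no_structure(self):
        cfg = _small_config(genes_per_cohort=300, samples_per_cohort=100,
                            modules=[])
        cohorts, _ = pc.generate_multi_cohort(cfg)
        R = np.corrcoef(cohorts["C1"]["expression"])
        frac = (np.abs(R[np.triu_indices(300, 1)]) > 0.5).mean()
        assert frac < 0.01

    def test_shared_modules_reuse_gene_sets(self):
        cfg = pc.default_config(seed=0)
        _, truth = pc.generate_multi_cohort(cfg)
        shared = truth.module_genes["S1"]
        for cohort in ("C1", "C2", "C3"):
            assert all(truth.assignments[cohort][g] == "S1" for g in shared)

    def test_private_module_only_in_its_cohort(self):
        cfg = pc.default_config(seed=0)
        _, truth = pc.generate_multi_cohort(cfg)
        assert truth.module_cohorts["P1"] == ["C1"]
        assert all(g not in truth.assignments["C2"]
                   for g in truth.module_genes["P1"])

    def test_child_layout_creates_nested_leaves(self):
        cfg = _small_config(modules=[pc.ModuleSpec(
            "m", 40, 0.7, children=(20, 20))])
        cohorts, truth = pc.generate_multi_cohort(cfg)
        assert set(truth.module_genes["m.1"]) | set(
            truth.module_genes["m.2"]) == set(truth.module_genes["m"])
        leaf = truth.assignments["C1"][truth.module_genes["m.1"][0]]
        assert leaf == "m.1"
        # within-child correlation exceeds cross-child correlation
        adj = pc.preprocess(cohorts["C1"]["expression"],
                            cohorts["C1"]["covariates"], apply_log2=False)
        z1 = adj.loc[truth.module_genes["m.1"]].to_numpy()
        z2 = adj.loc[truth.module_genes["m.2"]].to_numpy()
        within = np.abs(np.corrcoef(z1)[np.triu_indices(20, 1)]).mean()
        cross = np.abs(np.corrcoef(z1, z2)[:20, 20:]).mean()
        assert within > cross > 0.1

    def test_every_planted_gene_in_exactly_one_leaf(self):
        cfg = pc.default_config(seed=2)
        _, truth = pc.generate_multi_cohort(cfg)
        for cohort, assign in truth.assignments.items():
            planted = [g for mid in truth.module_genes
                       if "." not in mid
                       and cohort in truth.module_cohorts.get(mid, [])
                       for g in truth.module_genes[mid]]
            leaf_ids = {mid for mid in truth.module_genes}
            assert len(planted) == len(set(planted))
            for g in planted:
                if "." in assign[g]:
                    continue
                assert assign[g] in leaf_ids


class TestSurvivalGenerator:
    def _scores(self, cfg, truth, cohorts):
        return true_factor_scores(cohorts["C1"], truth, "C1")

    def test_null_hazard_gives_hr_near_one(self):
        cfg = _small_config(samples_per_cohort=500,
                            modules=[pc.ModuleSpec("m", 30, 0.7)])
        cohorts, truth = pc.generate_multi_cohort(cfg)
        scores = self._scores(cfg, truth, cohorts)
        surv = pc.generate_survival(scores, truth, cfg)
        adj = pc.preprocess(cohorts["C1"]["expression"],
                            cohorts["C1"]["covariates"], apply_log2=False)
        eig = pc.compute_eigengene(set(truth.module_genes["m"]), adj)
        res = pc.cox_fit(pc.median_stratify(eig.scores), surv)
        assert 0.8 <= res.hr <= 1.25

    def test_zero_censoring_all_events(self):
        cfg = _small_config(censoring_fraction=0.0,
                            modules=[pc.ModuleSpec("m", 20, 0.6)])
        cohorts, truth = pc.generate_multi_cohort(cfg)
        surv = pc.generate_survival(self._scores(cfg, truth, cohorts),
                                    truth, cfg)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_censoring_fraction_approximated(self):
        cfg = _small_config(samples_per_cohort=2000, censoring_fraction=0.4,
                            modules=[pc.ModuleSpec("m", 20, 0.6)])
        cohorts, truth = pc.generate_multi_cohort(cfg)
        surv = pc.generate_survival(self._scores(cfg, truth, cohorts),
                                    truth, cfg)
        assert abs((surv["event"] == 0).mean() - 0.4) < 0.05

    def test_empty_samples_rejected(self):
        cfg = _small_config(modules=[pc.ModuleSpec("m", 20, 0.6)])
        _, truth = pc.generate_multi_cohort(cfg)
        with pytest.raises(ValueError, match="empty"):
            pc.generate_survival(pd.DataFrame(), truth, cfg)


class TestMethylationGenerator:
    def _bundle(self):
        cfg = pc.SimulationConfig(
            n_cohorts=1, genes_per_cohort=200, samples_per_cohort=100,
            n_normal_samples=40,
            modules=[pc.ModuleSpec("m", 30, 0.7, meth_coupling=-1),
                     pc.ModuleSpec("u", 20, 0.6)],
            seed=4)
        return pc.generate_all(cfg), cfg

    def test_beta_in_unit_interval(self):
        bundle, _ = self._bundle()
        beta = bundle["cohorts"]["C1"]["beta"]
        assert ((beta >= 0) & (beta <= 1)).all().all()

    def test_coupled_module_anticorrelated(self):
        bundle, _ = self._bundle()
        data = bundle["cohorts"]["C1"]
        truth = bundle["truth"]
        corrs = []
        for g in truth.module_genes["m"]:
            x = data["expression"].loc[g]
            b = data["beta"].loc[f"cg_{g}"]
            corrs.append(np.corrcoef(x, b)[0, 1])
        assert np.mean(corrs) <= -0.3

    def test_uncoupled_gene_uncorrelated(self):
        bundle, _ = self._bundle()
        data = bundle["cohorts"]["C1"]
        truth = bundle["truth"]
        corrs = []
        for g in truth.module_genes["u"]:
            x = data["expression"].loc[g]
            b = data["beta"].loc[f"cg_{g}"]
            corrs.append(np.corrcoef(x, b)[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_probes_inside_promoter_windows(self):
        bundle, _ = self._bundle()
        probes = bundle["cohorts"]["C1"]["probe_annotation"]
        genes = bundle["gene_annotation"]
        mapping = pc.map_promoter_probes(probes, genes)
        mapped = set(zip(mapping["probe"], mapping["gene"]))
        for p, row in probes.iterrows():
            assert (p, row["gene"]) in mapped


class TestAnnotationGenerator:
    def test_assigned_module_genes_inside_their_band(self):
        cfg = pc.default_config(seed=5)
        bands, gene_annot, _ = pc.generate_annotation(cfg)
        _, truth = pc.generate_multi_cohort(cfg)
        band_rows = bands.set_index("name")
        for mid, band in truth.module_cytoband.items():
            if band is None:
                continue
            b = band_rows.loc[band]
            for g in truth.module_genes[mid]:
                row = gene_annot.loc[g]
                assert row["chrom"] == b["chrom"]
                assert b["start"] <= row["tss"] <= b["end"]
                assert row["cytoband"] == band

    def test_at_least_twenty_bands_and_hosting_bands_nonempty(self):
        cfg = pc.default_config(seed=5)
        bands, gene_annot, _ = pc.generate_annotation(cfg)
        assert len(bands) >= 20
        counts = gene_annot["cytoband"].value_counts()
        for band in pc.generate_multi_cohort(cfg)[1].open_bands:
            assert counts.get(band, 0) >= 1

    def test_open_band_signal_elevated(self):
        cfg = pc.default_config(seed=5)
        bands, _, peaks = pc.generate_annotation(cfg)
        _, truth = pc.generate_multi_cohort(cfg)
        sig = pc.cytoband_peak_signal(peaks, bands)
        open_mean = sig[truth.open_bands].mean()
        sample_cols = [c for c in peaks.columns
                       if c not in ("chrom", "start", "end")]
        background = peaks[sample_cols].to_numpy().mean()
        assert open_mean / background > 1.5

    def test_peaks_fixed_width_nonoverlapping(self):
        cfg = pc.default_config(seed=5)
        _, _, peaks = pc.generate_annotation(cfg)
        widths = peaks["end"] - peaks["start"]
        assert widths.nunique() == 1
        by_chrom = peaks.sort_values(["chrom", "start"])
        for _, sub in by_chrom.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:]
                    > sub["end"].to_numpy()[:-1]).all()


class TestTruthSerialization:
    def test_truth_json_round_trip(self, tmp_path):
        cfg = pc.default_config(seed=6)
        _, truth = pc.generate_multi_cohort(cfg)
        truth.to_json(tmp_path / "truth.json")
        back = pc.GroundTruth.from_json(tmp_path / "truth.json")
        assert back.module_genes == {k: sorted(v) for k, v in
                                     truth.module_genes.items()} or \
            back.module_genes == truth.module_genes
        assert back.assignments == truth.assignments
        assert back.module_loghr == truth.module_loghr


def test_null_fixture_network_far_sparser_than_structured(run_dir):
    """With no planted modules the network stage keeps (almost) nothing."""
    rng_cfg = pc.SimulationConfig(n_cohorts=1, genes_per_cohort=400,
                                  samples_per_cohort=120,
                                  n_normal_samples=0, modules=[], seed=9)
    cohorts, _ = pc.generate_multi_cohort(rng_cfg)
    adj = pc.preprocess(cohorts["C1"]["expression"],
                        cohorts["C1"]["covariates"], apply_log2=False)
    try:
        thr = pc.permutation_fdr_threshold(adj, n_perm=10, seed=9)
        null_edges = pc.build_pfn(thr.pairs).number_of_edges()
    except ValueError:
        null_edges = 0
    structured = pd.read_csv(run_dir / "C1.edges.tsv", sep="\t")
    assert null_edges <= 0.01 * len(structured)
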