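"""The synthetic cohort generator: planted structure, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micoprog.editing import gie_evaluate
from micoprog.synthetic import (
    CohortConfig,
    calibrate_skew,
    generate_cohort,
    generate_expression,
    generate_mutation_neoantigen,
    generate_repertoire_pair,
    geometric_clone_probabilities,
    write_cohort,
)
from micoprog.tcr import detect_tumor_enriched, summarize_repertoire


def small_config(**kw):
    defaults = dict(n_samples=40, n_genes=60, n_taxa=20, clone_richness=150,
                    n_templates=6000, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="proportions"):
            small_config(icr_group_proportions=(0.5, 0.4, 0.2)).validate()

    def test_bad_dimensions(self):
        with pytest.raises(ValueError):
            small_config(n_samples=0).validate()

    def test_clone_richness_guard(self):
        with pytest.raises(ValueError, match="richness"):
            small_config(clone_richness=1).validate()

    def test_taxa_budget(self):
        with pytest.raises(ValueError):
            small_config(n_taxa=3, n_risk_taxa=2, n_protective_taxa=2).validate()


class TestExpression:
    def test_null_effect_uniform_pvalues(self):
        # with no planted effect the High-vs-Low comparison of the mean
        # signature expression must yield uniform p-values across replicates
        pvals = []
        for rep in range(200):
            cfg = small_config(icr_effect=0.0, seed=rep)
            expr, truth = generate_expression(cfg)
            score = expr.iloc[:20].mean(axis=0)
            hi = score[truth["true_icr_level"] == "High"]
            lo = score[truth["true_icr_level"] == "Low"]
            pvals.append(stats.ttest_ind(hi, lo).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_shift_per_group(self):
        cfg = small_config(icr_effect=3.0, noise_sd=0.5, n_samples=120, seed=2)
        expr, truth = generate_expression(cfg)
        sig_mean = expr.iloc[:20].mean(axis=0)
        means = sig_mean.groupby(truth["true_icr_level"]).mean()
        assert means["High"] - means["Medium"] == pytest.approx(3.0, abs=0.5)
        assert means["Medium"] - means["Low"] == pytest.approx(3.0, abs=0.5)

    def test_determinism(self):
        cfg = small_config(seed=9)
        a, _ = generate_expression(cfg)
        b, _ = generate_expression(small_config(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestCloneLaw:
    def test_zero_skew_uniform(self):
        p = geometric_clone_probabilities(10, 0.0)
        np.testing.assert_allclose(p, 0.1)

    def test_calibration_monotone_and_accurate(self):
        for target in (0.05, 0.15, 0.3, 0.6):
            skew = calibrate_skew(500, target)
            p = geometric_clone_probabilities(500, skew)
            h = -np.sum(p * np.log2(p))
            assert 1 - h / np.log2(500) == pytest.approx(target, abs=1e-4)

    def test_realized_clonality_within_tolerance(self):
        rng = np.random.default_rng(3)
        cfg = CohortConfig()
        for level, target in cfg.clonality_targets.items():
            tumor, _ = generate_repertoire_pair(cfg, "X", level, rng)
            realized = summarize_repertoire(tumor).clonality
            assert realized == pytest.approx(target, abs=0.05)

    def test_zero_target_near_uniform(self):
        rng = np.random.default_rng(4)
        cfg = small_config(clonality_targets={"Low": 0.0, "Medium": 0.0, "High": 0.0})
        tumor, _ = generate_repertoire_pair(cfg, "X", "Low", rng)
        assert summarize_repertoire(tumor).clonality < 0.05


class TestSpikedClones:
    def test_detection_returns_exactly_the_spikes(self):
        rng = np.random.default_rng(5)
        cfg = CohortConfig()
        for _ in range(5):
            tumor, normal = generate_repertoire_pair(cfg, "S1", "Medium", rng)
            res = detect_tumor_enriched(tumor, normal)
            assert sorted(res.tumor_enriched) == [f"S1_spike{i}" for i in range(5)]

    def test_no_spikes_nothing_enriched(self):
        rng = np.random.default_rng(6)
        cfg = small_config(n_spiked_clones=0)
        tumor, normal = generate_repertoire_pair(cfg, "S1", "Low", rng)
        res = detect_tumor_enriched(tumor, normal)
        assert res.tumor_enriched == []


class TestMutationNeoantigen:
    def test_null_editing_mean_gie_near_one(self):
        cfg = small_config(editing_strength=1.0, n_samples=200, seed=7)
        rng = np.random.default_rng(7)
        _, truth = generate_expression(cfg, rng)
        muts = generate_mutation_neoantigen(cfg, truth, rng)
        gie = [
            gie_evaluate(int(o), int(x)).gie_value
            for x, o in zip(muts["nonsynonymous_count"], muts["observed_neoantigens"])
        ]
        assert np.mean(gie) == pytest.approx(1.0, abs=0.05)

    def test_counts_above_zero_crossing(self):
        cfg = small_config(seed=8, n_samples=300)
        rng = np.random.default_rng(8)
        _, truth = generate_expression(cfg, rng)
        muts = generate_mutation_neoantigen(cfg, truth, rng)
        assert (muts["nonsynonymous_count"] > 26).all()

    def test_editing_recovery(self):
        cfg = CohortConfig(seed=3)
        cohort = generate_cohort(cfg)
        joined = cohort.mutations.join(cohort.truth_samples["true_edited"])
        cutoff = (1 + cfg.editing_strength) / 2
        pred = [
            gie_evaluate(int(r.observed_neoantigens), int(r.nonsynonymous_count),
                         edited_cutoff=cutoff).edited
            for r in joined.itertuples()
        ]
        accuracy = (np.asarray(pred) == joined["true_edited"].to_numpy()).mean()
        assert accuracy >= 0.9


class TestCohortBundle:
    def test_linked_sample_universe(self, small_cohort):
        samples = list(small_cohort.truth_samples.index)
        assert list(small_cohort.expression.columns) == samples
        assert list(small_cohort.abundance.index) == samples
        assert list(small_cohort.survival.index) == samples
        assert list(small_cohort.mutations.index) == samples

    def test_compositional_closure(self, small_cohort):
        np.testing.assert_allclose(small_cohort.abundance.sum(axis=1), 1.0, atol=1e-9)
        assert (small_cohort.abundance.to_numpy() >= 0).all()

    def test_missing_assay_counting(self):
        cfg = small_config(n_samples=50, missing_assay_fractions={"tcr": 0.5}, seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort.repertoires) == 25

    def test_taxa_truth_signs(self, small_cohort):
        signs = small_cohort.truth_taxa
        cfg = small_cohort.config
        assert (signs != 0).sum() == cfg.n_risk_taxa + cfg.n_protective_taxa
        assert (signs == 1).sum() == cfg.n_risk_taxa

    def test_byte_identical_outputs_under_seed(self, tmp_path):
        import hashlib

        def bundle_hash(d):
            h = hashlib.sha256()
            for f in sorted(d.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(f.read_bytes())
            return h.hexdigest()

        cfg_kwargs = dict(n_samples=20, n_genes=40, n_taxa=10, clone_richness=60,
                          n_templates=2000, seed=42)
        a, b = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(CohortConfig(**cfg_kwargs)), a)
        write_cohort(generate_cohort(CohortConfig(**cfg_kwargs)), b)
        assert bundle_hash(a) == bundle_hash(b)

    def test_null_hazard_gives_null_logrank(self):
        # zero hazard coefficients: group comparisons are exchangeable
        from micoprog.survival import logrank_test

        pvals = []
        for rep in range(60):
            cfg = small_config(
                seed=rep,
                hazard_coefficients={"icr": 0.0, "edited": 0.0, "risk_taxon": 0.0,
                                     "protective_taxon": 0.0},
            )
            cohort = generate_cohort(cfg)
            groups = cohort.truth_samples["true_icr_level"]
            _, p = logrank_test(cohort.survival, groups)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
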