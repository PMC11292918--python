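import numpy as np
import pytest

import clogitforest as cf

from conftest import random_dataset


class TestAggregation:
    def test_beta_bar_is_mean_of_tree_betas(self, small_forest):
        betas = [t.beta_hat for t in small_forest.trees]
        assert small_forest.beta_bar == pytest.approx(np.mean(betas))

    def test_degenerate_forest_equals_tree(self, data_b):
        """ntree=1 with the identity sample and mtry=p reproduces a
        directly grown tree."""
        tc = cf.TreeControl(split_eval="fast")
        control = cf.ForestControl(ntree=1, mtry=data_b.p, seed=77, tree=tc)
        model = cf.fit_forest(data_b, control, identity_sample=True)
        rng = np.random.default_rng(
            np.random.SeedSequence(77).spawn(2)[1]
        )
        tree = cf.grow_tree(
            data_b, cf.TreeControl(split_eval="fast", mtry=data_b.p),
            exposure=True, rng=rng,
        )
        np.testing.assert_allclose(
            cf.predict_forest(model, data_b),
            tree.predict(data_b.Z, x=data_b.x),
        )
        assert model.beta_bar == pytest.approx(tree.beta_hat)

    def test_prediction_invariant_to_tree_order(self, small_forest, data_b):
        shuffled = cf.ForestModel(
            trees=list(reversed(small_forest.trees)),
            inbag=list(reversed(small_forest.inbag)),
            control=small_forest.control,
            var_names=small_forest.var_names,
            mtry_used=small_forest.mtry_used,
        )
        np.testing.assert_allclose(
            cf.predict_forest(small_forest, data_b),
            cf.predict_forest(shuffled, data_b),
        )


class TestOOB:
    def test_oob_tree_counts_match_subsample_rate(self, data_b):
        """Under 63.2% subsampling each stratum is OOB for about 36.8%
        of the trees."""
        control = cf.ForestControl(
            ntree=60, mtry=2, seed=5,
            tree=cf.TreeControl(split_eval="fast", max_depth=1),
        )
        model = cf.fit_forest(data_b, control)
        counts = np.zeros(data_b.n)
        for ib in model.inbag:
            counts[ib.oob] += 1
        expected = 60 * (1 - 632 / 1000)
        # binomial standard error for the grand mean
        se = np.sqrt(expected * 0.632 / data_b.n)
        assert abs(counts.mean() - expected) < 4 * se

    def test_root_only_no_exposure_forest_scores_uniform(self):
        rng = np.random.default_rng(31)
        d = random_dataset(rng, n=40, m=4, p=2, exposure=False)
        control = cf.ForestControl(
            ntree=10, mtry=2, seed=1, exposure=False,
            tree=cf.TreeControl(split_eval="fast", min_split_n=10**6),
        )
        model = cf.fit_forest(d, control)
        probs, mean = cf.oob_pred_cond_lik(model, d)
        assert mean == pytest.approx(0.25, abs=1e-12)

    def test_oob_values_are_probabilities(self, small_forest, data_b):
        probs, mean = cf.oob_pred_cond_lik(small_forest, data_b)
        finite = probs[np.isfinite(probs)]
        assert finite.size > 0
        assert np.all((finite > 0) & (finite < 1))
        assert 0 < mean < 1

    def test_oob_detects_signal(self):
        """On tree-structured truth the OOB predictive conditional
        likelihood beats the 1/m null in nearly all replications."""
        wins = 0
        reps = 10
        for r in range(reps):
            study = cf.simulate_study(
                cf.DGPConfig.reduced("B", 5, 5, n_strata=100), seed=800 + r
            )
            model = cf.fit_forest(
                study.data, cf.ForestControl(ntree=25, mtry=3, seed=r)
            )
            _, mean = cf.oob_pred_cond_lik(model, study.data)
            wins += mean > 0.25
        assert wins >= 9


class TestTuneMtry:
    def test_tie_breaks_to_smaller_and_determinism(self, data_b):
        control = cf.ForestControl(ntree=10, seed=3, ntree_tune=5)
        m1 = cf.tune_mtry(data_b, control)
        m2 = cf.tune_mtry(data_b, control)
        assert m1 == m2
        assert 2 <= m1 <= data_b.p

    def test_p2_returns_2(self):
        rng = np.random.default_rng(1)
        d = random_dataset(rng, n=30, m=4, p=2)
        assert cf.tune_mtry(d, cf.ForestControl(seed=0, ntree_tune=3)) == 2


class TestDeterminism:
    def test_serial_equals_parallel(self, data_b):
        base = cf.ForestControl(ntree=8, mtry=3, seed=123,
                                tree=cf.TreeControl(split_eval="fast"))
        from dataclasses import replace
        serial = cf.fit_forest(data_b, replace(base, n_jobs=1))
        parallel = cf.fit_forest(data_b, replace(base, n_jobs=2))
        for t1, t2 in zip(serial.trees, parallel.trees):
            assert t1.history == t2.history
            assert t1.beta_hat == t2.beta_hat
        np.testing.assert_allclose(
            cf.predict_forest(serial, data_b),
            cf.predict_forest(parallel, data_b),
        )

    def test_beta_bar_variance_shrinks_with_ntree(self):
        """Ensemble stability: the seed-to-seed variance of the averaged
        exposure effect decreases as the forest grows."""
        study = cf.simulate_study(
            cf.DGPConfig.reduced("A", 10, 0), seed=55
        )
        var = {}
        for ntree in (5, 50):
            betas = [
                cf.fit_forest(
                    study.data,
                    cf.ForestControl(ntree=ntree, mtry=3, seed=s),
                ).beta_bar
                for s in range(8)
            ]
            var[ntree] = np.var(betas, ddof=1)
        assert var[50] < var[5]


class TestSerialization:
    def test_json_roundtrip_reproduces_predictions(self, small_forest,
                                                   data_b, tmp_path):
        path = tmp_path / "model.json"
        small_forest.to_json(path)
        back = cf.ForestModel.from_json(path)
        np.testing.assert_array_equal(
            cf.predict_forest(back, data_b),
            cf.predict_forest(small_forest, data_b),
        )
        assert back.beta_bar == small_forest.beta_bar

    def test_unknown_schema_rejected(self, small_forest):
        d = small_forest.to_dict()
        d["schema"] = "clogitforest-model-v99"
        with pytest.raises(ValueError, match="schema"):
            cf.ForestModel.from_dict(d)


class TestOffset:
    def test_offset_gamma_excludes_exposure(self, data_a):
        control = cf.ForestControl(ntree=4, mtry=3, seed=2, offset="linear")
        model = cf.fit_forest(data_a, control)
        assert model.offset_gamma.shape == (data_a.p,)
        clr = cf.fit_clr_model(data_a)
        np.testing.assert_allclose(model.offset_gamma, clr.gamma_hat)

    def test_offset_absorbs_linear_structure(self):
        """After the linear fit is absorbed as an offset, splits on
        linear-truth data find far less likelihood improvement: the
        residual the trees see is mostly noise."""
        gains = {"none": [], "linear": []}
        for r in range(6):
            study = cf.simulate_study(
                cf.DGPConfig.reduced("A", 10, 0), seed=600 + r
            )
            for mode in gains:
                model = cf.fit_forest(
                    study.data,
                    cf.ForestControl(ntree=10, mtry=3, seed=r, offset=mode),
                )
                gains[mode].append(np.mean(
                    [t.trace[-1] - t.trace[0] for t in model.trees]
                ))
        assert np.mean(gains["linear"]) < 0.75 * np.mean(gains["none"])
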