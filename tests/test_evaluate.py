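"""Tests for splits, metrics, gap scenarios, preselection and overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gpforward import evaluate as ev
from gpforward import pheno, simulate as sim
from gpforward.exceptions import DesignError, ParameterError
from gpforward.gbm import GbmConfig
from gpforward.linear import EnetConfig, GblupConfig

from conftest import make_panel

FAST_CONFIGS = {
    "gblup": GblupConfig(n_iter=1500, burn_in=500, thin=4),
    "enet": EnetConfig(alpha=0.5, lambda_total=0.05),
    "gbm": GbmConfig(ntree=80, learning_rate=0.1, max_depth=3),
}


class TestForwardSplit:
    def test_partition(self, additive_dataset):
        _, tt = additive_dataset
        ref, val = ev.forward_split(tt, 11, tt.trait_names[0])
        assert len(ref) + len(val) == len(tt.data)
        gens = dict(zip(tt.data["animal_id"], tt.data["generation"]))
        assert all(gens[a] == 11 for a in val)
        assert all(gens[a] != 11 for a in ref)

    def test_validation_size_matches_design(self):
        founders = sim.simulate_founders(50, 1, (0.2, 0.5), seed=70)
        pop = sim.drop_generations(founders, sim.PopulationDesign(), seed=71)
        ds = sim.simulate_trait(pop.panel, sim.TraitArchitecture(n_additive_qtl=10),
                                seed=72, meta=pop.meta)
        tt = pheno.precorrect(ds.traits)
        _, val = ev.forward_split(tt, 11, ds.trait_name)
        assert len(val) == 197  # no missing phenotypes simulated

    def test_absent_generation_errors(self, additive_dataset):
        _, tt = additive_dataset
        with pytest.raises(DesignError):
            ev.forward_split(tt, 99)

    def test_missing_trait_excluded(self, additive_dataset):
        _, tt = additive_dataset
        tt2 = pheno.TraitTable(data=tt.data.copy(), trait_names=tt.trait_names,
                               ystar=tt.ystar)
        trait = tt.trait_names[0]
        drop_id = tt2.data["animal_id"].iloc[0]
        tt2.data.loc[tt2.data["animal_id"] == drop_id, trait] = np.nan
        ref, val = ev.forward_split(tt2, 11, trait)
        assert drop_id not in ref and drop_id not in val


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ev.accuracy(y, y) == pytest.approx(1.0)
        assert ev.rrmse(y, y, 1.0) == 0.0

    def test_affine_invariance_sign(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ev.accuracy(y, -2 * y + 7) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        # hand arithmetic: cov = 0.75, var_x = var_y = 1.25 -> r = 0.6
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([2.0, 1.0, 4.0, 3.0])
        assert ev.accuracy(y, p) == pytest.approx(0.6)

    def test_mean_predictor_rrmse_is_one(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        pred = np.full(50, y.mean())
        assert ev.rrmse(y, pred, float(y.std())) == pytest.approx(1.0)

    def test_rrmse_hand_value(self):
        assert ev.rrmse([0.0, 2.0], [1.0, 1.0], 1.0) == pytest.approx(1.0)

    def test_rrmse_bad_sigma(self):
        with pytest.raises(ParameterError):
            ev.rrmse([0.0, 1.0], [0.0, 1.0], 0.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ParameterError):
            ev.accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bootstrap_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(100)
        p = y + rng.standard_normal(100)
        r = ev.accuracy(y, p)
        boot = ev.bootstrap_ci(y, p, n_boot=500, seed=2)
        assert boot["low"] < r < boot["high"]
        assert boot["sd"] > 0

    def test_bootstrap_determinism(self):
        rng = np.random.default_rng(3)
        y, p = rng.standard_normal(40), rng.standard_normal(40)
        assert ev.bootstrap_ci(y, p, 200, seed=9) == ev.bootstrap_ci(y, p, 200, seed=9)


class TestMetricProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_accuracy_invariant_to_positive_affine_maps(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(20)
        p = y + rng.standard_normal(20)
        base = ev.accuracy(y, p)
        assert ev.accuracy(y, scale * p + shift) == pytest.approx(base, abs=1e-9)

    @given(st.floats(0.1, 20.0), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rrmse_scales_inversely_with_sigma(self, sigma, seed):
        rng = np.random.default_rng(seed)
        y, p = rng.standard_normal(15), rng.standard_normal(15)
        assert ev.rrmse(y, p, sigma) == pytest.approx(ev.rrmse(y, p, 1.0) / sigma)


class TestScenarioQuotas:
    def test_nogap_quota_proportions(self):
        counts = {4: 97, 5: 48, 7: 200, 8: 184, 9: 99}
        spec = ev.ScenarioSpec("NoGAP", (4, 5, 7, 8, 9), sample_size=300)
        quotas = ev.scenario_quotas(spec, counts)
        assert sum(quotas.values()) == 300
        total = sum(counts.values())
        for g, q in quotas.items():
            assert abs(q - 300 * counts[g] / total) <= 1.0  # largest remainder

    def test_gap89_feasible(self):
        counts = {4: 97, 5: 48, 7: 200, 8: 184, 9: 99}
        spec = ev.ScenarioSpec("GAP89", (4, 5, 7), sample_size=300)
        quotas = ev.scenario_quotas(spec, counts)
        assert set(quotas) == {4, 5, 7}
        assert sum(quotas.values()) == 300

    def test_quota_exceeds_pool_errors(self):
        with pytest.raises(DesignError):
            ev.scenario_quotas(
                ev.ScenarioSpec("x", (4, 5), sample_size=300), {4: 10, 5: 10}
            )


class TestGapScenarios:
    @pytest.fixture(scope="class")
    def scenario_run(self, small_population, additive_dataset):
        _, tt = additive_dataset
        scenarios = [
            ev.ScenarioSpec("NoGAP", (4, 5, 7, 8, 9), 11, 120, 3),
            ev.ScenarioSpec("GAP89", (4, 5, 7), 11, 120, 3),
        ]
        reps, summary = ev.run_gap_scenarios(
            small_population.panel, tt, tt.trait_names[0],
            models=("gblup",), scenarios=scenarios,
            configs=FAST_CONFIGS, seed=5,
        )
        return reps, summary

    def test_replicate_counts(self, scenario_run):
        reps, summary = scenario_run
        assert len(reps) == 2 * 3  # scenarios x replicates x 1 model
        assert (summary["n_replicates"] == 3).all()

    def test_gap89_excludes_recent_generations(self, small_population, additive_dataset):
        _, tt = additive_dataset
        spec = ev.ScenarioSpec("GAP89", (4, 5, 7), 11, 120, 2)
        quotas = ev.scenario_quotas(
            spec, {4: 40, 5: 20, 7: 80, 8: 70, 9: 40}
        )
        assert 8 not in quotas and 9 not in quotas

    def test_determinism(self, small_population, additive_dataset):
        _, tt = additive_dataset
        spec = [ev.ScenarioSpec("NoGAP", (4, 5, 7, 8, 9), 11, 100, 2)]
        kw = dict(models=("enet",), scenarios=spec, configs=FAST_CONFIGS, seed=3)
        r1, _ = ev.run_gap_scenarios(small_population.panel, tt, tt.trait_names[0], **kw)
        r2, _ = ev.run_gap_scenarios(small_population.panel, tt, tt.trait_names[0], **kw)
        pd.testing.assert_frame_equal(r1, r2)


class TestPreselect:
    def test_subsets_and_labels(self, small_population, additive_dataset):
        _, tt = additive_dataset
        res = ev.preselect_and_refit(
            small_population.panel, tt, tt.trait_names[0],
            subset_sizes=(20, 10_000), models=("enet", "gbm"),
            configs=FAST_CONFIGS, seed=4,
            importance_config=GbmConfig(ntree=60, learning_rate=0.1, max_depth=3),
        )
        assert set(res["requested_size"]) == {20, 10_000}
        big = res[res["requested_size"] == 10_000]
        assert (big["actual_size"] < 10_000).all()  # capped at nonzero importances
        small = res[res["requested_size"] == 20]
        assert (small["actual_size"] == 20).all()

    def test_informative_subset_beats_random(self, small_population):
        """Top-importance SNPs beat a random subset of the same size for a
        few-QTL trait (mean over repeats)."""
        pop = small_population
        gains = []
        for s in range(3):
            ds = sim.simulate_trait(
                pop.panel,
                sim.TraitArchitecture(n_additive_qtl=10, h2_additive=0.5),
                seed=800 + s, meta=pop.meta,
            )
            tt = pheno.precorrect(ds.traits)
            res = ev.preselect_and_refit(
                pop.panel, tt, ds.trait_name, subset_sizes=(30,),
                models=("gblup",), configs=FAST_CONFIGS, seed=s,
                importance_config=GbmConfig(ntree=100, learning_rate=0.1, max_depth=2),
            )
            top_acc = res["accuracy"].iloc[0]
            # random subset baseline
            rng = np.random.default_rng(8000 + s)
            rand_idx = np.sort(rng.choice(pop.panel.n_snps, 30, replace=False))
            sub = pop.panel.subset(snp_idx=rand_idx)
            p = sub.allele_freq()
            sub = sub.subset(snp_idx=np.flatnonzero((p > 0) & (p < 1)))
            ws = ev._Workspace.build(sub)
            ref, val = ev.forward_split(tt, 11, ds.trait_name)
            pred, _ = ev.fit_and_predict(
                "gblup", tt.ystar_vector(ds.trait_name), ref, val, ws,
                config=FAST_CONFIGS["gblup"], seed=s,
            )
            rand_acc = ev.accuracy(
                tt.ystar_vector(ds.trait_name, val).to_numpy(), pred.to_numpy()
            )
            gains.append(top_acc - rand_acc)
        assert np.mean(gains) > 0

    def test_tiny_subset_errors(self, small_population, additive_dataset):
        _, tt = additive_dataset
        with pytest.raises(ParameterError):
            ev.preselect_and_refit(
                small_population.panel, tt, tt.trait_names[0], subset_sizes=(1,)
            )


class TestTopAnimalOverlap:
    def test_identical_predictions(self):
        p = pd.Series(np.arange(30.0), index=[f"a{i}" for i in range(30)])
        venn = ev.top_animal_overlap({"m1": p, "m2": p.copy()}, k=10)
        assert venn["pair_counts"][("m1", "m2")] == 10
        assert venn["region_counts"] == {("m1", "m2"): 10}

    def test_reversed_rankings_disjoint(self):
        ids = [f"a{i}" for i in range(40)]
        p1 = pd.Series(np.arange(40.0), index=ids)
        p2 = pd.Series(-np.arange(40.0), index=ids)
        venn = ev.top_animal_overlap({"m1": p1, "m2": p2}, k=20)
        assert venn["pair_counts"][("m1", "m2")] == 0

    def test_three_models_match_brute_force(self):
        rng = np.random.default_rng(6)
        ids = [f"a{i}" for i in range(25)]
        preds = {f"m{j}": pd.Series(rng.standard_normal(25), index=ids) for j in range(3)}
        k = 8
        venn = ev.top_animal_overlap(preds, k=k)
        # brute-force region enumeration
        tops = {m: set(sorted(ids, key=lambda a: (-preds[m][a], a))[:k]) for m in preds}
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(preds), r):
                inside = set.intersection(*(tops[m] for m in combo))
                outside = set().union(
                    *(tops[m] for m in preds if m not in combo), set()
                ) if len(combo) < 3 else set()
                exclusive = {a for a in inside
                             if all(a not in tops[m] for m in preds if m not in combo)}
                assert venn["region_counts"].get(tuple(combo), 0) == len(exclusive)
                del inside, outside

    def test_k_too_large_errors(self):
        p = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ParameterError):
            ev.top_animal_overlap({"m": p}, k=5)


class TestSnpRankOverlap:
    def test_self_overlap_is_k(self):
        rng = np.random.default_rng(7)
        panel = make_panel(rng.integers(0, 3, size=(30, 40)).astype(float))
        scores = {"m1": rng.random(40), "m2": rng.random(40)}
        res = ev.snp_rank_overlap(scores, panel, k=15)
        for r in res:
            if r.model_a == r.model_b:
                assert r.overlap == r.k_used_a == 15

    def test_uncorrelated_disjoint_lists(self):
        # orthogonal dosage columns: identity-free overlap must be 0
        d = np.zeros((8, 4))
        d[0, 0] = d[1, 1] = d[2, 2] = d[3, 3] = 2.0
        panel = make_panel(d)
        scores = {"A": np.array([1.0, 0.9, 0.0, 0.0]),
                  "B": np.array([0.0, 0.0, 1.0, 0.9])}
        res = {(r.model_a, r.model_b): r for r in ev.snp_rank_overlap(scores, panel, k=2, r2_threshold=0.9)}
        assert res[("A", "B")].overlap == 0
        assert res[("B", "A")].overlap == 0

    def test_high_ld_counts_as_overlap(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=50).astype(float)
        twin = base.copy()
        twin[0] = 1.0  # one dosage step off -> still r2 > 0.9
        other = rng.integers(0, 3, size=50).astype(float)
        panel = make_panel(np.column_stack([base, twin, other]))
        r2 = np.corrcoef(base, twin)[0, 1] ** 2
        assert r2 > 0.9
        scores = {"A": np.array([1.0, 0.0, 0.0]), "B": np.array([0.0, 1.0, 0.0])}
        res = {(r.model_a, r.model_b): r.overlap
               for r in ev.snp_rank_overlap(scores, panel, k=1)}
        assert res[("A", "B")] == 1 and res[("B", "A")] == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.integers(0, 3, size=(40, 30)).astype(float))
        scores = {"A": rng.random(30), "B": rng.random(30)}
        overlaps = []
        for thr in (0.99, 0.8, 0.5, 0.2):
            res = {(r.model_a, r.model_b): r.overlap
                   for r in ev.snp_rank_overlap(scores, panel, k=10, r2_threshold=thr)}
            overlaps.append(res[("A", "B")])
        assert all(a <= b for a, b in zip(overlaps, overlaps[1:]))

    def test_fewer_scored_snps_labeled(self):
        rng = np.random.default_rng(10)
        panel = make_panel(rng.integers(0, 3, size=(20, 30)).astype(float))
        sparse = np.zeros(30)
        sparse[:5] = rng.random(5)
        res = ev.snp_rank_overlap({"A": sparse, "B": rng.random(30)}, panel, k=10)
        by = {(r.model_a, r.model_b): r for r in res}
        assert by[("A", "B")].k_used_a == 5
        assert by[("A", "A")].overlap == 5


class TestReport:
    def test_roundtrip_and_determinism(self, tmp_path):
        df = pd.DataFrame({"trait": ["t"], "model": ["gblup"], "accuracy": [0.5]})
        out1 = tmp_path / "r1"
        out2 = tmp_path / "r2"
        ev.report({"results": df, "meta": {"seed": 1}}, out1, manifest={"seed": 1})
        ev.report({"results": df, "meta": {"seed": 1}}, out2, manifest={"seed": 1})
        assert (out1 / "results.csv").read_text() == (out2 / "results.csv").read_text()
        assert (out1 / "manifest.json").exists()

    def test_empty_sections_omitted(self, tmp_path):
        df = pd.DataFrame({"a": [1]})
        written = ev.report({"full": df, "empty": pd.DataFrame(), "none": None}, tmp_path)
        assert "empty" not in written and "none" not in written

    def test_nothing_to_report_errors(self, tmp_path):
        with pytest.raises(ParameterError):
            ev.report({}, tmp_path)
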