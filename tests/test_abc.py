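"""ABC machinery: summary statistics, reference tables, model choice."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from botryphylo import diversity
from botryphylo.abc import (
    build_reference_table,
    estimate_parameters,
    model_check,
    posterior_probabilities,
    pre_evaluate,
    scenario_tournament,
    select_by_ci_overlap,
    summary_stats,
    SummaryStatVector,
    TournamentConfig,
)
from botryphylo.coalsim import (
    ParamDraw,
    Population,
    PriorSpec,
    Scenario,
    sample_priors,
    simulate_dataset,
)
from botryphylo.seqio import Alignment, PopulationMap


SINGLE = Scenario("single", [Population("P", "N")], [])
FIXED_HKY = {"mu": (1e-6, 1.000001e-6), "kappa": (2.0, 2.000001),
             "I": (0.0, 1e-9)}
PRIOR_LOW = PriorSpec({"N": (1e2, 1e3), **FIXED_HKY})
PRIOR_HIGH = PriorSpec({"N": (1e4, 1e5), **FIXED_HKY})
CFG_SINGLE = {"P": {"p1": 16}}


def low_scenario():
    return Scenario("low", [Population("P", "N")], [])


def high_scenario():
    return Scenario("high", [Population("P", "N")], [])


@pytest.fixture(scope="module")
def small_table():
    return build_reference_table(
        {"low": low_scenario(), "high": high_scenario()},
        {"low": PRIOR_LOW, "high": PRIOR_HIGH},
        CFG_SINGLE, 400, seed=77, L=300,
    )


class TestSummaryStats:
    def test_monomorphic_dataset(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        pm = PopulationMap({s: "p" for s in "abcd"}, {"p": "R"})
        v = summary_stats((aln, pm)).as_series()
        assert v["R:h"] == 1 and v["R:S"] == 0 and v["R:kbar"] == 0
        assert v["R:D_def"] == 0  # D undefined, imputed

    def test_cross_module_agreement(self, rng):
        from tests.conftest import random_alignment

        aln = random_alignment(rng, 10, 60)
        pm = PopulationMap(
            {aln.ids[i]: ("p1" if i < 5 else "p2") for i in range(10)},
            {"p1": "R1", "p2": "R2"},
        )
        v = summary_stats((aln, pm)).as_series()
        for region, ids in (("R1", aln.ids[:5]), ("R2", aln.ids[5:])):
            sub = aln.subset(ids)
            assert v[f"{region}:S"] == diversity.segregating_sites(sub)
            assert v[f"{region}:kbar"] == pytest.approx(
                diversity.mean_pairwise_differences(sub), abs=1e-12
            )
            assert v[f"{region}:D"] == pytest.approx(
                diversity.tajimas_d(sub)[0], abs=1e-12
            )

    def test_vector_length_constant(self, rng):
        from tests.conftest import random_alignment

        lengths = set()
        for _ in range(5):
            n = int(rng.integers(8, 16))
            aln = random_alignment(rng, n, 40)
            pm = PopulationMap(
                {aln.ids[i]: f"p{i % 3}" for i in range(n)},
                {"p0": "R1", "p1": "R2", "p2": "R3"},
            )
            lengths.add(len(summary_stats((aln, pm)).names))
        assert len(lengths) == 1


class TestReferenceTable:
    def test_balanced_and_deterministic(self):
        kw = dict(
            scenarios={"low": low_scenario(), "high": high_scenario()},
            priors={"low": PRIOR_LOW, "high": PRIOR_HIGH},
            sample_config=CFG_SINGLE, n_per_scenario=10, seed=5, L=200,
        )
        rt1 = build_reference_table(**kw)
        rt2 = build_reference_table(**kw)
        assert rt1.n_rows == 20
        assert (rt1.scenario_ids == "low").sum() == 10
        assert np.array_equal(rt1.stats, rt2.stats)
        pd.testing.assert_frame_equal(rt1.params, rt2.params)

    def test_parameter_marginals_match_prior(self, small_table):
        n_draws = small_table.restrict("low").params["N"].to_numpy()
        stat = kstest((n_draws - 1e2) / (1e3 - 1e2), "uniform")
        assert stat.pvalue > 1e-3


class TestPreEvaluate:
    def test_in_model_observed_rarely_flagged(self, small_table, rng):
        flagged_frac = []
        for rep in range(5):
            d = sample_priors(PRIOR_LOW, rng, "low")
            ds = simulate_dataset(low_scenario(), d, CFG_SINGLE,
                                  seed=int(rng.integers(1, 2**31)), L=300)
            rep_out = pre_evaluate(small_table, summary_stats(ds))
            n_stats = len(small_table.stat_names)
            flagged_frac.append(len(rep_out["flagged"]["low"]) / n_stats)
        assert np.mean(flagged_frac) <= 0.2

    def test_gross_outlier_flagged(self, small_table):
        obs = SummaryStatVector(
            small_table.stat_names,
            small_table.stats.max(axis=0) * 10 + 100,
        )
        rep = pre_evaluate(small_table, obs)
        assert len(rep["flagged"]["low"]) > 0

    def test_pca_reproducible(self, small_table):
        obs = SummaryStatVector(small_table.stat_names,
                                small_table.stats.mean(axis=0))
        a = pre_evaluate(small_table, obs, seed=3)
        b = pre_evaluate(small_table, obs, seed=3)
        assert np.allclose(a["pca_simulated"], b["pca_simulated"])
        assert np.allclose(a["pca_observed"], b["pca_observed"])


class TestModelChoice:
    def test_disjoint_priors_rank_correctly(self, small_table, rng):
        hits = 0
        for rep in range(15):
            d = sample_priors(PRIOR_HIGH, rng, "high")
            ds = simulate_dataset(high_scenario(), d, CFG_SINGLE,
                                  seed=int(rng.integers(1, 2**31)), L=300)
            res = posterior_probabilities(small_table, summary_stats(ds),
                                          retain_frac=0.1, n_boot=0, seed=rep)
            hits += res.probabilities.idxmax() == "high"
        assert hits >= 12

    def test_rejection_and_logistic_agree_on_ranking(self, small_table, rng):
        d = sample_priors(PRIOR_LOW, rng, "low")
        ds = simulate_dataset(low_scenario(), d, CFG_SINGLE, seed=9, L=300)
        res = posterior_probabilities(small_table, summary_stats(ds),
                                      retain_frac=0.2, n_boot=0, seed=1)
        assert res.probabilities.idxmax() == res.rejection.idxmax()

    def test_probabilities_sum_to_one_with_cis(self, small_table, rng):
        d = sample_priors(PRIOR_LOW, rng, "low")
        ds = simulate_dataset(low_scenario(), d, CFG_SINGLE, seed=10, L=300)
        res = posterior_probabilities(small_table, summary_stats(ds),
                                      retain_frac=0.2, n_boot=60, seed=2)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        for s in res.probabilities.index:
            assert res.ci.loc[s, "lo"] <= res.probabilities[s] <= res.ci.loc[s, "hi"]
            assert 0.0 <= res.ci.loc[s, "lo"] <= res.ci.loc[s, "hi"] <= 1.0


class TestParameterEstimation:
    def test_retain_all_unadjusted_recovers_prior(self, small_table):
        rt = small_table.restrict("high")
        obs = SummaryStatVector(rt.stat_names, rt.stats.mean(axis=0))
        est = estimate_parameters(rt, obs, retain_frac=1.0, adjust=False)
        prior_q = np.quantile(rt.params["N"], [0.025, 0.5, 0.975])
        assert est.table.loc["N"].to_numpy() == pytest.approx(prior_q, rel=1e-9)

    def test_quantiles_ordered(self, small_table, rng):
        rt = small_table.restrict("high")
        d = sample_priors(PRIOR_HIGH, rng, "high")
        ds = simulate_dataset(high_scenario(), d, CFG_SINGLE, seed=6, L=300)
        est = estimate_parameters(rt, summary_stats(ds), retain_frac=0.25)
        for _, row in est.table.iterrows():
            assert row["q2.5"] <= row["median"] <= row["q97.5"]


class TestModelCheck:
    def test_deterministic_given_seed(self, small_table, rng):
        rt = small_table.restrict("low")
        d = sample_priors(PRIOR_LOW, rng, "low")
        ds = simulate_dataset(low_scenario(), d, CFG_SINGLE, seed=13, L=300)
        obs = summary_stats(ds)
        est = estimate_parameters(rt, obs, retain_frac=0.25)
        a = model_check(low_scenario(), est.adjusted_draws.abs(), obs,
                        CFG_SINGLE, n_ppc=120, seed=4, L=300)
        b = model_check(low_scenario(), est.adjusted_draws.abs(), obs,
                        CFG_SINGLE, n_ppc=120, seed=4, L=300)
        pd.testing.assert_series_equal(a["tail_prob"], b["tail_prob"])

    def test_gross_misfit_flagged(self, small_table, rng):
        # data from the high-Ne scenario checked against low-Ne posteriors
        rt = small_table.restrict("low")
        d = sample_priors(PRIOR_HIGH, rng, "high")
        ds = simulate_dataset(high_scenario(), d, CFG_SINGLE, seed=14, L=300)
        obs = summary_stats(ds)
        draws = rt.params.iloc[:100]
        rep = model_check(low_scenario(), draws, obs, CFG_SINGLE,
                          n_ppc=120, seed=5, L=300)
        assert len(rep["flagged"]) >= 1


class TestCiOverlapRule:
    def test_single_scenario_trivial(self):
        sel, clean = select_by_ci_overlap({"a": 1.0}, {"a": (0.9, 1.0)})
        assert sel == ["a"] and clean

    def test_clear_winner(self):
        sel, clean = select_by_ci_overlap(
            {"a": 0.9, "b": 0.1}, {"a": (0.85, 0.95), "b": (0.05, 0.15)}
        )
        assert sel == ["a"] and clean

    def test_overlapping_top_pair_selected(self):
        sel, clean = select_by_ci_overlap(
            {"a": 0.45, "b": 0.42, "c": 0.13},
            {"a": (0.40, 0.50), "b": (0.38, 0.47), "c": (0.10, 0.16)},
        )
        assert sorted(sel) == ["a", "b"] and clean

    def test_chained_overlap_flags_unclean(self):
        # b overlaps both the top and the unselected c
        sel, clean = select_by_ci_overlap(
            {"a": 0.5, "b": 0.3, "c": 0.2},
            {"a": (0.45, 0.55), "b": (0.28, 0.46), "c": (0.18, 0.30)},
        )
        assert "a" in sel and not clean


class TestTournament:
    def test_single_set_single_scenario_trivial_winner(self, rng):
        cfg = TournamentConfig(sample_config=CFG_SINGLE, n_per_scenario=30,
                               retain_frac=0.5, n_boot=10, seed=1, L=200)
        d = sample_priors(PRIOR_LOW, rng, "low")
        ds = simulate_dataset(low_scenario(), d, CFG_SINGLE, seed=3, L=200)
        audit = scenario_tournament(
            {"only": {"solo": low_scenario()}}, summary_stats(ds), cfg
        )
        assert audit["winner"] == "solo"
        assert audit["round2"]["selected"] == ["solo"]
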