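"""Coalescent scenario simulation: structural invariants and distributions."""

import numpy as np
import pytest
from scipy.stats import kstest

from botryphylo.coalsim import (
    AdmixtureEvent,
    MergeEvent,
    ParamDraw,
    Population,
    PriorSpec,
    Scenario,
    builtin_scenarios,
    default_priors,
    sample_priors,
    simulate_dataset,
    simulate_genealogy,
    simulate_sequences,
)


@pytest.fixture
def one_pop():
    return Scenario("one", [Population("P", "N")], [])


class TestPriors:
    def test_disjoint_bounds_always_accepted(self, rng):
        ps = PriorSpec(
            {"t2": (0, 1), "t3": (2, 3), "t4": (4, 5)},
            [("t4", ">", "t3"), ("t4", ">", "t2"), ("t3", ">=", "t2")],
        )
        for _ in range(100):
            d = sample_priors(ps, rng)
            assert d.values["t4"] > d.values["t3"] >= d.values["t2"]

    def test_overlapping_bounds_respect_constraints(self, rng):
        ps = PriorSpec(
            {"t2": (0, 1), "t3": (0, 1), "t4": (0, 1)},
            [("t4", ">", "t3"), ("t4", ">", "t2"), ("t3", ">=", "t2")],
        )
        for _ in range(200):
            d = sample_priors(ps, rng)
            assert d.values["t4"] > d.values["t3"] >= d.values["t2"]

    def test_unconstrained_marginal_uniform(self, rng):
        ps = PriorSpec({"N": (100.0, 500.0), "t2": (0, 1), "t3": (0, 1)},
                       [("t3", ">=", "t2")])
        draws = np.array([sample_priors(ps, rng).values["N"] for _ in range(5000)])
        stat = kstest((draws - 100) / 400, "uniform")
        assert stat.pvalue > 1e-3

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec({"N": (5.0, 5.0)})


class TestGenealogy:
    def test_pairwise_coalescence_time_matches_ne(self, one_pop):
        draw = ParamDraw("one", {"N": 1000.0})
        times = []
        for i in range(2000):
            ts = simulate_genealogy(one_pop, draw, {"P": 2}, seed=i + 1)
            t = ts.first()
            times.append(t.time(t.root))
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - 1000.0) < 3 * se

    def test_cross_population_coalescence_after_merge(self):
        sc = Scenario(
            "two",
            [Population("A", "Na"), Population("B", "Nb")],
            [MergeEvent("A", "B", "500")],
        )
        draw = ParamDraw("two", {"Na": 200.0, "Nb": 200.0})
        for i in range(40):
            ts = simulate_genealogy(sc, draw, {"A": 3, "B": 3}, seed=i + 1)
            t = ts.first()
            pop = {u: ts.node(u).population for u in ts.samples()}
            for u in ts.samples():
                for v in ts.samples():
                    if u < v and pop[u] != pop[v]:
                        assert t.tmrca(u, v) > 500

    def test_immediate_merge_reduces_to_single_population(self):
        sc = Scenario(
            "im",
            [Population("A", "Na"), Population("B", "Nb")],
            [MergeEvent("A", "B", "0")],
        )
        draw = ParamDraw("im", {"Na": 100.0, "Nb": 100.0})
        ts = simulate_genealogy(sc, draw, {"A": 1, "B": 1}, seed=1)
        assert ts.num_samples == 2 and ts.first().num_roots == 1

    def test_times_increase_along_root_path(self, one_pop):
        draw = ParamDraw("one", {"N": 300.0})
        ts = simulate_genealogy(one_pop, draw, {"P": 8}, seed=3)
        t = ts.first()
        for u in ts.samples():
            path_times = []
            v = u
            while v != -1:
                path_times.append(t.time(v))
                v = t.parent(v)
            assert path_times == sorted(path_times)
        assert t.num_samples() == 8

    def test_stranded_lineages_rejected(self):
        sc = Scenario(
            "bad",
            [Population("A", "Na"), Population("B", "Nb")],
            [],
        )
        with pytest.raises(ValueError, match="stranded"):
            sc.validate()

    def test_admixture_event_runs(self, rng):
        sc = Scenario(
            "adm",
            [Population("A", "Na"), Population("B", "Nb"),
             Population("C", "Nc")],
            [AdmixtureEvent("C", "A", "B", "ra", "t2"),
             MergeEvent("A", "B", "t3")],
        )
        sc.validate()
        draw = ParamDraw("adm", {"Na": 100.0, "Nb": 100.0, "Nc": 100.0,
                                 "ra": 0.5, "t2": 50.0, "t3": 500.0})
        ts = simulate_genealogy(sc, draw, {"A": 2, "B": 2, "C": 2}, seed=5)
        assert ts.first().num_roots == 1


class TestSequences:
    def test_zero_rate_identical_sequences(self, one_pop):
        draw = ParamDraw("one", {"N": 500.0})
        ts = simulate_genealogy(one_pop, draw, {"P": 6}, seed=2)
        seqs = simulate_sequences(ts, mu=0.0, kappa=2.0, invariant=0.2, seed=9)
        assert len(set(seqs)) == 1

    def test_stationary_frequencies_near_quarter(self, one_pop):
        draw = ParamDraw("one", {"N": 500.0})
        ts = simulate_genealogy(one_pop, draw, {"P": 4}, seed=7, L=4000)
        seqs = simulate_sequences(ts, mu=1e-4, kappa=1.0, invariant=0.0,
                                  L=4000, seed=7)
        counts = np.array([seqs[0].count(b) for b in "ACGT"]) / 4000
        assert np.all(np.abs(counts - 0.25) < 0.05)

    def test_transition_ratio_increases_with_kappa(self, one_pop):
        draw = ParamDraw("one", {"N": 4000.0})

        def tstv(kappa, seed):
            ts = simulate_genealogy(one_pop, draw, {"P": 10}, seed=seed)
            seqs = simulate_sequences(ts, mu=2e-4, kappa=kappa, invariant=0.0,
                                      seed=seed)
            trans = {"AG", "CT"}
            a = b = 0
            for col in zip(*seqs):
                states = sorted(set(col))
                if len(states) == 2:
                    if "".join(states) in trans:
                        a += 1
                    else:
                        b += 1
            return a / max(b, 1)

        ratios = [np.mean([tstv(k, s) for s in range(1, 15)]) for k in (1, 4, 16)]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_segregating_sites_grow_with_mu(self, one_pop):
        from botryphylo.diversity import segregating_sites
        from botryphylo.seqio import Alignment

        draw = ParamDraw("one", {"N": 1000.0})
        means = []
        for mu in (1e-6, 1e-5, 1e-4):
            S = []
            for seed in range(1, 80):
                ts = simulate_genealogy(one_pop, draw, {"P": 6}, seed=seed)
                seqs = simulate_sequences(ts, mu=mu, kappa=2.0, invariant=0.0,
                                          seed=seed)
                aln = Alignment([f"s{i}" for i in range(6)], seqs)
                S.append(segregating_sites(aln))
            means.append(np.mean(S))
        assert means[0] < means[1] < means[2]

    def test_invalid_parameters_rejected(self, one_pop):
        draw = ParamDraw("one", {"N": 100.0})
        ts = simulate_genealogy(one_pop, draw, {"P": 2}, seed=1)
        with pytest.raises(ValueError):
            simulate_sequences(ts, mu=1e-6, kappa=-1.0, invariant=0.0)
        with pytest.raises(ValueError):
            simulate_sequences(ts, mu=1e-6, kappa=2.0, invariant=1.0)


class TestDatasets:
    def test_identical_seed_bitwise_reproducible(self):
        sc = builtin_scenarios("E")["s19"]
        ps = default_priors(sc)
        rng = np.random.default_rng(8)
        draw = sample_priors(ps, rng, "s19")
        cfg = {"ECF": {"p1": 4}, "ECE": {"p2": 4}, "BB": {"p3": 4},
               "Med": {"p4": 4}}
        a = simulate_dataset(sc, draw, cfg, seed=123)
        b = simulate_dataset(sc, draw, cfg, seed=123)
        assert a.alignment.seqs == b.alignment.seqs
        assert a.popmap.sample_to_pop == b.popmap.sample_to_pop

    def test_popmap_matches_sample_config(self):
        sc = builtin_scenarios("E")["s19"]
        ps = default_priors(sc)
        rng = np.random.default_rng(8)
        draw = sample_priors(ps, rng, "s19")
        cfg = {"ECF": {"p1": 3, "p2": 5}, "ECE": {"p3": 2}, "BB": {"p4": 1},
               "Med": {"p5": 4}}
        ds = simulate_dataset(sc, draw, cfg, seed=4)
        assert ds.alignment.n == 15
        assert ds.popmap.population_sizes() == {"p1": 3, "p2": 5, "p3": 2,
                                                "p4": 1, "p5": 4}


class TestScenarioLibrary:
    def test_library_sizes(self):
        assert len(builtin_scenarios("A")) >= 4
        assert len(builtin_scenarios("E")) >= 4

    def test_unknown_clade_rejected(self):
        with pytest.raises(ValueError):
            builtin_scenarios("Z")

    def test_clade_e_origin_scenario_topology(self):
        s19 = builtin_scenarios("E")["s19"]
        assert len(s19.sampled_populations) == 4
        ghosts = [p for p in s19.populations if not p.sampled]
        assert len(ghosts) == 1
        merges = {(e.daughter, e.parent): e.time for e in s19.events
                  if isinstance(e, MergeEvent)}
        # FR <- ghost <- EN <- {Med, Biscay}
        assert merges[("Med", "ECE")] == "t2"
        assert merges[("BB", "ECE")] == "t2"
        assert merges[("ECE", "ghost")] == "t3"
        assert merges[("ghost", "ECF")] == "t4"

    def test_all_scenarios_simulate(self):
        for clade, cfg in (
            ("A", {"Med": {"m": 2}, "NEA": {"e": 2}, "NWA": {"w": 2},
                   "Pac": {"p": 2}}),
            ("E", {"ECF": {"f": 2}, "ECE": {"e": 2}, "BB": {"b": 2},
                   "Med": {"m": 2}}),
        ):
            for sid, sc in builtin_scenarios(clade).items():
                ps = default_priors(sc)
                rng = np.random.default_rng(1)
                draw = sample_priors(ps, rng, sid)
                ds = simulate_dataset(sc, draw, cfg, seed=11)
                assert ds.alignment.n == 8
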