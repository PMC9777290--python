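import numpy as np
import pytest

from gecip import cascade_sim as cs


@pytest.fixture(scope="module")
def plain_model() -> cs.CascadeModel:
    topo = cs.plain_topology()
    rates = {r["rate"]: 0.05 for r in topo["reactions"]}
    return cs.build_cascade(topo, kpar=rates)


@pytest.fixture(scope="module")
def responsive_model() -> cs.CascadeModel:
    """Strong activation, weak deactivation: provably crosses the threshold."""
    topo = cs.plain_topology()
    return cs.build_cascade(topo, kpar=cs.fit_example_rates(topo))


TWO_STATE = {
    "proteins": {"A": ["A0", "A1"]},
    "reactions": [
        {"substrate": "A0", "product": "A1", "modifier": "signal", "rate": "k1"},
        {"substrate": "A1", "product": "A0", "rate": "k2"},
    ],
    "outputs": ["A1"],
    "rates": {"k1": 0.3, "k2": 0.7},
}


class TestBuildCascade:
    def test_plain_cascade_structure(self, plain_model):
        assert plain_model.n_species == 9
        traj = cs.simulate(plain_model, signal=0.0)
        assert np.max(traj.of("T2")) == pytest.approx(0.0, abs=1e-9)

    def test_interaction_matrix_conserves_each_protein(self, plain_model):
        mat = plain_model.interaction_matrix()
        assert set(np.unique(mat)) <= {-1, 0, 1}
        # per reaction: one consumed, one produced, same protein => zero sum
        np.testing.assert_array_equal(mat.sum(axis=0), np.zeros(mat.shape[1]))

    def test_cross_protein_reaction_rejected_naming_it(self):
        topo = cs.plain_topology()
        topo["reactions"].append(
            {"substrate": "R0", "product": "K1", "rate": "k_bad"}
        )
        topo["rates"] = {r["rate"]: 0.05 for r in topo["reactions"]}
        with pytest.raises(cs.TopologyError, match="R0->K1"):
            cs.build_cascade(topo)

    def test_negative_rate_rejected(self):
        topo = cs.plain_topology()
        rates = {r["rate"]: 0.05 for r in topo["reactions"]}
        rates["k_aR1"] = -1.0
        with pytest.raises(cs.TopologyError, match="k_aR1"):
            cs.build_cascade(topo, kpar=rates)

    def test_feedback_loop_builds_and_conserves(self):
        model = cs.build_cascade(cs.normal_topology())
        traj = cs.simulate(model, signal=1.0)
        cs.check_conservation(model, traj)

    def test_two_cascades_with_crosstalk_have_18_species(self):
        topo = cs.crosstalk_topology()
        rates = {r["rate"]: 0.05 for r in topo["reactions"]}
        model = cs.build_cascade(topo, kpar=rates)
        assert model.n_species == 18

    def test_topology_yaml_round_trip(self, tmp_path):
        topo = cs.normal_topology()
        path = tmp_path / "t.yaml"
        cs.save_topology(topo, path)
        assert cs.load_topology(path) == topo


class TestSimulate:
    def test_zero_rates_freeze_the_system(self):
        topo = cs.plain_topology()
        model = cs.build_cascade(
            topo, kpar={r["rate"]: 0.0 for r in topo["reactions"]},
            verify_inactive=False,
        )
        traj = cs.simulate(model, signal=10.0)
        np.testing.assert_allclose(traj.y, np.broadcast_to(traj.y[0], traj.y.shape), atol=1e-12)

    def test_zero_signal_keeps_cascade_inactive(self, responsive_model):
        traj = cs.simulate(responsive_model, signal=0.0)
        assert np.max(traj.of("T2")) < 1e-9

    def test_two_state_equilibrium_matches_closed_form(self):
        model = cs.build_cascade(TWO_STATE)
        for signal in (0.1, 1.0, 5.0):
            traj = cs.simulate(model, signal, t_end=400.0)
            frac = traj.of("A1")[-1] / model.pool
            expected = 0.3 * signal / (0.3 * signal + 0.7)
            assert frac == pytest.approx(expected, abs=1e-4)

    def test_mass_conserved_along_trajectories(self, responsive_model):
        for signal in cs.SIGNALS:
            traj = cs.simulate(responsive_model, signal)
            cs.check_conservation(responsive_model, traj, rtol=1e-6)

    def test_negative_signal_rejected(self, plain_model):
        with pytest.raises(ValueError):
            cs.simulate(plain_model, signal=-1.0)


class TestFitness:
    def test_always_crossing_cascade_scores_one(self, responsive_model):
        res = cs.fitness(responsive_model)
        assert res.F == 1.0
        np.testing.assert_array_equal(res.ffactor1, np.ones(6))
        np.testing.assert_array_equal(res.ffactor2, np.zeros(6))

    def test_single_cascade_factor_is_one_per_crossing_signal(self, plain_model):
        res = cs.fitness(plain_model)
        assert set(np.unique(res.ffactor1)) <= {0.0, 1.0}
        assert res.F == pytest.approx(res.ffactor1.sum() / 6)

    def test_crosstalk_mode_awards_half_per_cascade(self):
        topo = cs.crosstalk_topology()
        rates = {}
        for r in topo["reactions"]:
            rid = r["rate"]
            if rid.startswith("C1_"):
                rates[rid] = 5.0 if r.get("modifier") else 0.1
            else:
                rates[rid] = 1e-6  # cascade 2 never responds
        rates["k_ct"] = 1e-6
        model = cs.build_cascade(topo, kpar=rates)
        res = cs.fitness(model)
        assert set(np.unique(res.ffactor1)) <= {0.0, 0.5}
        np.testing.assert_array_equal(res.ffactor2, np.zeros(6))
        assert 0 < res.F <= 0.5

    def test_flat_output_scores_zero(self, plain_model):
        topo = cs.plain_topology()
        model = cs.build_cascade(
            topo, kpar={r["rate"]: 0.0 for r in topo["reactions"]},
            verify_inactive=False,
        )
        assert cs.fitness(model).F == 0.0

    def test_threshold_decisions_robust_to_tighter_tolerances(self, plain_model, responsive_model):
        for model in (plain_model, responsive_model):
            base = cs.fitness(model, cs.FitnessSpec())
            tight = cs.fitness(model, cs.FitnessSpec(rtol=5e-7, atol=5e-10))
            assert base.F == tight.F

    def test_population_fitness_agrees_with_per_model_fitness(self, plain_model):
        rng = np.random.default_rng(0)
        K = rng.uniform(0.001, 0.1, size=(8, len(plain_model.rate_ids)))
        pop = cs.population_fitness(plain_model, K)
        for i in range(K.shape[0]):
            single = cs.fitness(
                plain_model.with_kpar(dict(zip(plain_model.rate_ids, K[i])))
            )
            assert pop[i] == pytest.approx(single.F)


class TestEvolve:
    CFG = dict(population=20, survivors=5, copies_per_survivor=4)

    def test_population_bookkeeping_single_generation(self):
        cfg = cs.EvolutionConfig(**self.CFG, generations=1, seed=0)
        run = cs.evolve(cs.plain_topology(), cfg)
        assert run.final_population.shape[0] == 20
        assert len(run.best_per_generation) == 2

    def test_same_seed_reproduces_fitness_trajectory(self):
        cfg = cs.EvolutionConfig(**self.CFG, generations=4, seed=11)
        a = cs.evolve(cs.plain_topology(), cfg)
        b = cs.evolve(cs.plain_topology(), cfg)
        np.testing.assert_array_equal(a.best_per_generation, b.best_per_generation)
        np.testing.assert_array_equal(a.final_population, b.final_population)

    def test_best_fitness_never_decreases(self):
        cfg = cs.EvolutionConfig(**self.CFG, generations=8, seed=2)
        run = cs.evolve(cs.plain_topology(), cfg)
        assert np.all(np.diff(run.best_per_generation) >= 0)

    def test_mutation_respects_bounds(self):
        cfg = cs.EvolutionConfig(**self.CFG, generations=3, seed=5)
        run = cs.evolve(cs.plain_topology(), cfg)
        lo, hi = cfg.kpar_bounds
        init_lo, _ = cfg.kpar_init_range
        assert run.final_population.min() >= min(lo, init_lo)
        assert run.final_population.max() <= hi

    def test_mismatched_population_config_rejected(self):
        with pytest.raises(ValueError):
            cs.EvolutionConfig(population=10, survivors=3, copies_per_survivor=4)


class TestCompare:
    def test_feedback_gives_transient_lesion_gives_sustained(self):
        normal = cs.build_cascade(cs.normal_topology())
        cancer = cs.build_cascade(cs.cancer_topology())
        report = cs.compare_normal_vs_cancer(normal, cancer, signals=(1.0,))
        assert report["base"][1.0] == cs.TRANSIENT
        assert report["perturbed"][1.0] == cs.SUSTAINED

    def test_zero_signal_yields_no_label(self):
        normal = cs.build_cascade(cs.normal_topology())
        report = cs.compare_normal_vs_cancer(normal, normal, signals=(0.0,))
        assert report["base"][0.0] == cs.NO_RESPONSE
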