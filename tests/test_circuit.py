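import numpy as np
import pandas as pd
import pytest

import oracles
from mirhub import circuit
from mirhub.circuit import (BooleanNetwork, BooleanRule, GeneParams,
                            attractors, bestfit_boolean, binarize,
                            binarize_runs, build_default_circuit, run_case,
                            simulate, simulate_switch)


class TestModel:
    def test_default_species(self, default_model):
        assert set(default_model.genes) == set(circuit.SPECIES)
        assert circuit.INPUTS == ("iptg",)

    def test_strong_repressor_leaves_only_leak(self, default_model):
        # LacR far above the output operator Kd: promoter activity ~ alpha0
        gp = default_model.genes["mir520c"]
        activity = gp.alpha0 + gp.alpha * gp.hill(1000.0)
        assert activity == pytest.approx(gp.alpha0, rel=0.01)

    def test_invalid_overrides_rejected(self):
        with pytest.raises(ValueError):
            build_default_circuit({"gfp": {"delta": -1.0}})
        with pytest.raises(ValueError):
            build_default_circuit({"nosuch": {"alpha": 1.0}})


class TestSimulate:
    def test_unrepressed_gene_reaches_alpha_over_delta(self):
        """A gene with no active repressor settles at alpha/delta to 0.1%."""
        model = build_default_circuit()
        traj = simulate(model, t_end=40, n_points=50, iptg=100.0)
        gp = model.genes["gfp"]
        lacr = float(traj.data["lacR"].iloc[-1])
        expected = (gp.alpha0 + gp.alpha * gp.hill(lacr)) / gp.delta
        assert float(traj.data["gfp"].iloc[-1]) == pytest.approx(expected, rel=1e-3)

    def test_hundred_point_grid(self, default_model):
        traj = simulate(default_model, n_points=100)
        assert len(traj) == 100
        assert np.all(np.diff(traj.time) > 0)

    def test_all_zero_rates_stay_at_zero(self):
        dead = {s: {"alpha": 0.0, "alpha0": 0.0} for s in circuit.SPECIES}
        traj = simulate(build_default_circuit(dead), t_end=10, n_points=20)
        assert np.allclose(traj.data[list(circuit.SPECIES)], 0.0)

    def test_nonnegative_concentrations(self, case_runs):
        for traj, _ in case_runs.values():
            assert (traj.data[list(circuit.SPECIES)] >= 0).all().all()

    def test_steady_state_is_algebraic_fixed_point(self, default_model):
        """ODE steady state satisfies the rate equations to 0.1%."""
        for iptg in (0.0, 100.0):
            ss = circuit.steady_state(default_model, iptg=iptg)
            lac_free = ss["lacR"]
            g = default_model.genes
            checks = {
                "repressor1": g["repressor1"].alpha0 + g["repressor1"].alpha * g["repressor1"].hill(lac_free),
                "repressor2": g["repressor2"].alpha0 + g["repressor2"].alpha * g["repressor2"].hill(ss["repressor1"]),
                "mir520c": g["mir520c"].alpha0 + g["mir520c"].alpha * g["mir520c"].hill(lac_free),
                "gfp": g["gfp"].alpha0 + g["gfp"].alpha * g["gfp"].hill(lac_free),
            }
            for s, production in checks.items():
                assert ss[s] == pytest.approx(production / g[s].delta, rel=1e-3)

    def test_gfp_nondecreasing_in_iptg(self, default_model):
        """ON/OFF monotonicity: steady GFP never drops as IPTG rises."""
        levels = [0.0, 0.5, 1.0, 3.0, 10.0, 100.0]
        gfps = [circuit.steady_state(default_model, iptg=i)["gfp"] for i in levels]
        assert all(b >= a - 1e-6 for a, b in zip(gfps, gfps[1:]))


class TestCases:
    def test_off_case_labels_off_at_leak_level(self, case_runs, default_model):
        traj, label = case_runs["off"]
        assert label == "OFF"
        gp = default_model.genes["gfp"]
        assert traj.metadata["steady_gfp"] < 0.1 * gp.alpha / gp.delta

    def test_on_case_co_switches_mir_and_gfp(self, case_runs):
        traj, label = case_runs["on"]
        assert label == "ON"
        assert float(traj.data["mir520c"].iloc[-1]) > 25
        assert float(traj.data["gfp"].iloc[-1]) > 25

    def test_inverted_thresholds_rejected(self, default_model):
        with pytest.raises(ValueError):
            run_case(default_model, "off_case1", theta_low=0.6, theta_high=0.5)


class TestBinarize:
    def test_monotone_rise_splits_into_blocks(self):
        df = pd.DataFrame({"x": np.linspace(0, 10, 20)})
        b = binarize(df)["x"].to_numpy()
        assert sorted(b) == list(b) and b[0] == 0 and b[-1] == 1

    def test_constant_zero_species_all_zero(self):
        df = pd.DataFrame({"x": np.zeros(10), "y": np.linspace(0, 1, 10)})
        assert (binarize(df)["x"] == 0).all()

    def test_oscillation_matches_threshold_crossings(self):
        t = np.linspace(0, 4 * np.pi, 200)
        x = np.sin(t)
        b = binarize(pd.DataFrame({"x": x}))["x"].to_numpy()
        assert np.array_equal(b, (x > 0.0).astype(int))

    def test_joint_runs_share_thresholds(self, case_runs):
        off_b, on_b = binarize_runs([case_runs["off"][0], case_runs["on"][0]])
        # miR stays below the shared threshold for the whole OFF run
        assert (off_b["mir520c"] == 0).all()
        assert on_b["mir520c"].iloc[-1] == 1


class TestBestFitBoolean:
    def test_recovers_not_gate(self):
        df = pd.DataFrame({"x1": [0, 1, 0, 1, 1, 0], "x2": [1, 1, 0, 1, 0, 0]})
        bn = bestfit_boolean(df, max_inputs=2)
        assert bn.rules["x2"] == BooleanRule(inputs=("x1",), table=(1, 0))

    def test_constant_variable_gets_empty_input_constant_rule(self):
        df = pd.DataFrame({"x1": [0, 1, 0, 1], "x2": [1, 1, 1, 1]})
        bn = bestfit_boolean(df)
        assert bn.rules["x2"].inputs == ()
        assert bn.rules["x2"].table == (1,)

    def test_conflicting_transitions_resolved_by_majority(self):
        # input state x1=0 maps to 1 twice and to 0 once -> majority 1
        df = pd.DataFrame({"x1": [0, 0, 0, 0], "x2": [0, 1, 1, 0]})
        bn = bestfit_boolean(df, max_inputs=1)
        rule = bn.rules["x2"]
        assert rule.inputs == ()            # constant-1 already optimal (1 mismatch)
        assert rule.table == (1,)

    def test_zero_mismatch_when_generated_by_boolean_network(self):
        rng = np.random.default_rng(4)
        # x3(t+1) = x1 AND x2; drive x1,x2 through all four combinations
        states = rng.integers(0, 2, size=(40, 2))
        x3 = np.zeros(40, dtype=int)
        x3[1:] = states[:-1, 0] & states[:-1, 1]
        df = pd.DataFrame({"x1": states[:, 0], "x2": states[:, 1], "x3": x3})
        bn = bestfit_boolean(df, max_inputs=2)
        assert bn.rules["x3"].inputs == ("x1", "x2")
        assert bn.rules["x3"].table == (0, 0, 0, 1)


class TestAttractors:
    def bn(self, rules, variables, externals=()):
        return BooleanNetwork(variables=tuple(variables), externals=tuple(externals),
                              rules=rules)

    def test_not_gate_two_cycle(self):
        bn = self.bn({"x": BooleanRule(("x",), (1, 0))}, ["x"])
        out = attractors(bn)
        assert len(out) == 1 and out[0].length == 2 and out[0].basin == 2

    def test_identity_map_four_fixed_points(self):
        bn = self.bn({"a": BooleanRule(("a",), (0, 1)),
                      "b": BooleanRule(("b",), (0, 1))}, ["a", "b"])
        out = attractors(bn)
        assert len(out) == 4 and all(a.length == 1 and a.basin == 1 for a in out)

    def test_matches_bruteforce_enumeration_on_random_networks(self):
        """Attractor sets and basins equal the plain 2^n state-space loop."""
        rng = np.random.default_rng(8)
        for trial in range(30):
            n = int(rng.integers(2, 11))
            names = [f"v{i}" for i in range(n)]
            rules = {}
            for v in names:
                k = int(rng.integers(0, min(3, n) + 1))
                ins = tuple(rng.choice(names, size=k, replace=False))
                table = tuple(int(x) for x in rng.integers(0, 2, size=2 ** k))
                rules[v] = BooleanRule(ins, table)
            bn = self.bn(rules, names)
            got = attractors(bn)

            idx = {v: i for i, v in enumerate(names)}

            def update(bits, rules=rules, names=names, idx=idx):
                state = dict(zip(names, bits))
                return tuple(rules[v].evaluate(state) for v in names)

            want = oracles.boolean_attractors(update, n)
            assert len(got) == len(want)
            got_map = {frozenset(a.states): a.basin for a in got}
            assert got_map == {cyc: basin for cyc, basin in want.items()}

    def test_unfrozen_external_input_rejected(self):
        bn = self.bn({"x": BooleanRule(("u",), (0, 1))}, ["x"], externals=["u"])
        with pytest.raises(ValueError):
            attractors(bn)

    def test_basins_cover_state_space(self, default_model):
        per = circuit.two_condition_attractors(default_model)
        for attrs in per.values():
            assert sum(a.basin for a in attrs) == 2 ** len(circuit.SPECIES)


class TestTwoConditionChain:
    def test_exactly_two_attractors_off_and_on(self, default_model):
        """The full validation chain finds bistability: one OFF attractor
        with LacR active and miR/GFP silent, one ON attractor with both
        output genes high."""
        per = circuit.two_condition_attractors(default_model)
        assert len(per[0]) == 1 and len(per[1]) == 1
        species = circuit.SPECIES
        off_state = dict(zip(species, per[0][0].states[0]))
        on_state = dict(zip(species, per[1][0].states[0]))
        assert off_state["lacR"] == 1
        assert off_state["mir520c"] == 0 and off_state["gfp"] == 0
        assert on_state["mir520c"] == 1 and on_state["gfp"] == 1
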