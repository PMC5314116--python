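import numpy as np
import pytest
import scipy.stats as sps

import tastecircuit as tc
from tastecircuit.graphs import GraphError


class TestSemTimeseries:
    def test_same_seed_is_bit_identical(self):
        spec = tc.SimulationSpec.default_circuit(n_subjects=3, n_timepoints=50, seed=1)
        a, _ = tc.generate_sem_timeseries(spec)
        b, _ = tc.generate_sem_timeseries(spec)
        for (sa, ma), (sb, mb) in zip(a.subjects, b.subjects):
            assert sa == sb
            assert np.array_equal(ma, mb)

    def test_empirical_covariance_matches_closed_form(self):
        spec = tc.SimulationSpec.default_circuit(n_subjects=1, n_timepoints=50_000,
                                                 seed=2)
        data, _ = tc.generate_sem_timeseries(spec)
        emp = np.cov(data.subjects[0][1].T, bias=True)
        want = spec.implied_covariance()
        # 2% relative, with an absolute floor for near-zero entries
        assert np.allclose(emp, want, rtol=0.02, atol=0.02 * np.abs(want).max())

    @pytest.mark.parametrize("family,sign", [("gaussian", 0), ("uniform", -1),
                                             ("laplace", 1)])
    def test_noise_family_controls_kurtosis_sign(self, family, sign):
        spec = tc.SimulationSpec.default_circuit(
            n_subjects=1, n_timepoints=20_000, seed=3, noise_family=family)
        data, _ = tc.generate_sem_timeseries(spec)
        # exogenous root column is pure noise
        root = spec.region_labels.index("thalamus")
        k = sps.kurtosis(data.subjects[0][1][:, root])
        if sign == 0:
            assert abs(k) < 0.15
        else:
            assert np.sign(k) == sign

    def test_cyclic_coefficients_rejected(self):
        b = np.zeros((2, 2))
        b[0, 1] = b[1, 0] = 0.5
        with pytest.raises(GraphError):
            tc.SimulationSpec(("x", "y"), b)

    def test_reversed_edge_spec(self):
        spec = tc.SimulationSpec.default_circuit()
        rev = spec.with_reversed_edge("hypothalamus", "ventral_striatum")
        i = spec.region_labels.index("hypothalamus")
        j = spec.region_labels.index("ventral_striatum")
        assert rev.coefficients[j, i] == spec.coefficients[i, j]
        assert rev.coefficients[i, j] == 0
        with pytest.raises(GraphError):
            spec.with_reversed_edge("thalamus", "hypothalamus")  # no such edge

    def test_spec_json_round_trip(self):
        spec = tc.SimulationSpec.default_circuit(n_subjects=4, seed=11)
        again = tc.SimulationSpec.from_json(spec.to_json())
        assert again.region_labels == spec.region_labels
        assert np.array_equal(again.coefficients, spec.coefficients)
        assert (again.n_subjects, again.seed) == (4, 11)


class TestTaskSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_trial_composition_invariants(self, seed):
        sched = tc.generate_task_schedule(seed)
        c = sched.counts()
        assert sum(n for (cs, _), n in c.items() if cs == "sucrose") == 100
        assert sum(n for (cs, _), n in c.items() if cs == "null") == 100
        assert sum(n for (cs, _), n in c.items() if cs == "saliva") == 80
        assert c[("sucrose", "sucrose")] == 80  # 80% contingency
        assert c[("sucrose", "none")] == 20
        assert c[("null", "none")] == 80
        assert c[("null", "sucrose")] == 20
        assert c[("saliva", "saliva")] == 80
        assert sched.trials[:10] == [("sucrose", "sucrose")] * 10

    def test_schedule_is_seeded_shuffle(self):
        a = tc.generate_task_schedule(5)
        b = tc.generate_task_schedule(5)
        c = tc.generate_task_schedule(6)
        assert a.trials == b.trials
        assert a.trials != c.trials
        assert sorted(a.trials) == sorted(c.trials)  # same composition


class TestStreamlineGenerator:
    def test_same_seed_identical_dataset(self, thalamus_taxonomy):
        a = tc.generate_streamline_dataset(thalamus_taxonomy, {"CW": 2}, seed=9)
        b = tc.generate_streamline_dataset(thalamus_taxonomy, {"CW": 2}, seed=9)
        for sid in a["CW"]:
            for key in a["CW"][sid]:
                assert a["CW"][sid][key].counts == b["CW"][sid][key].counts

    def test_null_group_effect_gives_uniform_p_values(self, thalamus_taxonomy):
        """Two identical groups: per-replicate t-test p on one tract ~ Uniform."""
        ps = []
        for rep in range(300):
            data = tc.generate_streamline_dataset(
                thalamus_taxonomy, {"g1": 5, "g2": 5}, seed=50_000 + rep)
            strengths = {}
            for group in data:
                vals = []
                for sid in data[group]:
                    measures = tc.build_pathway_table(data[group][sid],
                                                      thalamus_taxonomy)
                    vals.append(measures[0].connection_strength)
                strengths[group] = vals
            ps.append(sps.ttest_ind(strengths["g1"], strengths["g2"]).pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_injected_effect_detected_with_power(self, thalamus_taxonomy):
        """+50% on one tract, 25 subjects/group: adjusted model power > 0.8."""
        tract = tc.enumerate_tracts(thalamus_taxonomy)[0]
        effect = {"g2": {tract.key(): 1.5}}
        hits, reps = 0, 60
        for rep in range(reps):
            data = tc.generate_streamline_dataset(
                thalamus_taxonomy, {"g1": 25, "g2": 25}, seed=60_000 + rep,
                group_effects=effect)
            values, groups = [], []
            for group in data:
                for sid in data[group]:
                    m = tc.build_pathway_table(data[group][sid], thalamus_taxonomy)
                    values.append(m[0].connection_strength)
                    groups.append(group)
            res = tc.adjusted_group_model(values, groups)["group"]
            hits += res.p_value < 0.05
        assert hits / reps > 0.8


class TestBehavioralGenerator:
    def test_moments_match_targets_exactly(self, behavioral_targets):
        table = tc.generate_behavioral_table([behavioral_targets["age_years"]], seed=3)
        cw = table[(table.group == "CW") & (table.variable == "age_years")]["value"]
        assert cw.mean() == pytest.approx(24.39, abs=1e-9)
        assert cw.std(ddof=1) == pytest.approx(3.49, abs=1e-9)
        assert len(cw) == 26

    def test_round_trip_reproduces_target_f(self, behavioral_targets):
        target = behavioral_targets["body_mass_index"]
        table = tc.generate_behavioral_table([target], seed=4)
        sub = table[table.variable == "body_mass_index"]
        summary = tc.summary_from_values("body_mass_index", sub["value"], sub["group"])
        got = tc.anova_from_summary(summary).statistic
        want = tc.anova_from_summary(target).statistic
        assert got == pytest.approx(want, rel=1e-9)

    def test_same_seed_identical_table(self, behavioral_targets):
        t = [behavioral_targets["trait_anxiety"]]
        a = tc.generate_behavioral_table(t, seed=5)
        b = tc.generate_behavioral_table(t, seed=5)
        assert a.equals(b)

    def test_tiny_group_rejected(self):
        with pytest.raises(Exception):
            tc.GroupSummary("v", [tc.GroupMoments("a", 0, 1, 1),
                                  tc.GroupMoments("b", 0, 1, 5)])
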