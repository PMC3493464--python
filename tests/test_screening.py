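"""Validity criteria, ensemble screening, and the Q/Q' statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lignindesign.scaffold import Design, enumerate_crosstalk_patterns, enumerate_designs
from lignindesign.scenarios import ScenarioEntry, ScenarioSet, generate_synthetic_scenario
from lignindesign.screening import (
    DesignEnsemble,
    ValidityCriteria,
    design_seed_sequence,
    evaluate_instantiation,
    quadrant_data,
    screen_all,
    screen_design,
    summarize_metabolite,
)
from lignindesign.steady_state import derive_ssystem, normalize_instance, solve_steady_state


def make_scenario_set(rho=0.5, obs_ccoaomt=0.5, obs_comt=0.2):
    return ScenarioSet(
        rho_wt=rho,
        rho_provenance="synthetic",
        entries=[
            ScenarioEntry("CCoAOMT-down", {"CCoAOMT": 0.24},
                          observed_sg=obs_ccoaomt, provenance="synthetic"),
            ScenarioEntry("COMT-down", {"COMT": 0.1},
                          observed_sg=obs_comt, provenance="synthetic"),
            ScenarioEntry("ccr1-KO", {"CCR1": 0.05},
                          direction="down", provenance="synthetic"),
            ScenarioEntry("ccr2-KO", {"CCR2": 0.05},
                          hierarchical_multipliers={"CCR1": 1.5, "CCoAOMT": 1.5},
                          direction="up", provenance="synthetic"),
        ],
    )


def predictions(ccoaomt=0.5, comt=0.2, ccr1=0.25, ccr2=0.75):
    return {"CCoAOMT-down": ccoaomt, "COMT-down": comt,
            "ccr1-KO": ccr1, "ccr2-KO": ccr2}


class TestEvaluateInstantiation:
    def setup_method(self):
        self.sset = make_scenario_set()
        self.crit = ValidityCriteria()

    def test_exact_predictions_with_clear_margins_are_valid(self):
        assert evaluate_instantiation(predictions(), self.sset, self.crit) == "valid"

    def test_mse_arithmetic_on_alfalfa_lines(self):
        # errors (0.05, 0.05): MSE = 0.0025 < 0.01 -> quantitative pass
        sset = make_scenario_set(obs_ccoaomt=0.50, obs_comt=0.20)
        verdict = evaluate_instantiation(
            predictions(ccoaomt=0.45, comt=0.25), sset, self.crit
        )
        assert verdict == "valid"

    def test_prediction_inside_five_percent_strip_is_invalid(self):
        # ccr1 at 0.96*rho: treated as essentially wild-type, so no decrease
        verdict = evaluate_instantiation(
            predictions(ccr1=0.96 * 0.5), self.sset, self.crit
        )
        assert verdict == "invalid"

    def test_relaxed_only_band(self):
        # 15% relative error on both lines: MSE fails, 25% rule passes
        sset = make_scenario_set(obs_ccoaomt=1.0, obs_comt=1.0)
        verdict = evaluate_instantiation(
            predictions(ccoaomt=1.15, comt=1.15), sset, self.crit
        )
        assert verdict == "valid_relaxed_only"

    def test_ill_behaved_prediction_dominates(self):
        assert evaluate_instantiation(
            predictions(ccoaomt=None), self.sset, self.crit
        ) == "ill_behaved"
        assert evaluate_instantiation(
            predictions(ccr2=float("nan")), self.sset, self.crit
        ) == "ill_behaved"

    def test_missing_scenario_prediction_raises(self):
        p = predictions()
        del p["ccr2-KO"]
        with pytest.raises(KeyError):
            evaluate_instantiation(p, self.sset, self.crit)

    @given(
        scale=st.floats(0.5, 2.0),
        margin=st.floats(0.01, 0.04),
    )
    def test_tightening_thresholds_never_upgrades_verdict(self, scale, margin):
        order = {"valid": 2, "valid_relaxed_only": 1, "invalid": 0}
        p = predictions(ccoaomt=0.45 * scale, comt=0.22 * scale)
        loose = ValidityCriteria()
        tight = ValidityCriteria(
            mse_threshold=loose.mse_threshold / 4,
            qual_margin=loose.qual_margin + margin,
            relaxed_pct=loose.relaxed_pct / 2,
        )
        v_loose = evaluate_instantiation(p, self.sset, loose)
        v_tight = evaluate_instantiation(p, self.sset, tight)
        assert order[v_tight] <= order[v_loose]


@pytest.fixture(scope="module")
def recovery_setup(design_a_m2m5):
    rng = np.random.default_rng(np.random.SeedSequence([42]))
    sset = generate_synthetic_scenario(design_a_m2m5, rng)
    result = screen_design(design_a_m2m5, sset, n=4000, seed=7)
    return design_a_m2m5, sset, result


class TestScreenDesign:
    def test_zero_ensemble_size_rejected(self, design_a_m2m5, scenario_set):
        with pytest.raises(ValueError):
            screen_design(design_a_m2m5, scenario_set, n=0, seed=1)

    def test_counts_are_consistent(self, recovery_setup):
        _, _, res = recovery_setup
        assert 0 <= res.Q <= res.Q_prime <= res.n_behaved <= res.n_sampled
        assert len(res.valid_records) == res.Q

    def test_same_seed_reproduces_q_and_records(self, recovery_setup):
        design, sset, res = recovery_setup
        res2 = screen_design(design, sset, n=4000, seed=7)
        assert res2.Q == res.Q and res2.Q_prime == res.Q_prime
        pd.testing.assert_frame_equal(res2.valid_records, res.valid_records)

    def test_seed_stream_is_design_specific(self, by_label):
        d1 = Design(by_label["A"], frozenset({"M1"}))
        d2 = Design(by_label["A"], frozenset({"M2"}))
        assert design_seed_sequence(5, d1).entropy != design_seed_sequence(5, d2).entropy
        assert (design_seed_sequence(5, d1).entropy
                == design_seed_sequence(5, d1).entropy)

    def test_singleton_ensemble_with_planted_valid_parameterization(self, by_label):
        # observations copied from the single instantiation's own predictions
        # must validate it: Q = 1 at n = 1
        design = Design(by_label["A"], frozenset({"M2", "M5"}))
        template = make_scenario_set()
        ens = DesignEnsemble(design, template.rho_wt)
        rng = np.random.default_rng(design_seed_sequence(11, design))
        sols = ens.run(template, 1, rng)
        preds = {name: float(s.sg[0]) for name, s in sols.items()}
        assert all(s.behaved[0] for s in sols.values())
        rho = template.rho_wt
        # decisive directions (outside the 5% strip) for both knockouts
        for name in ("ccr1-KO", "ccr2-KO"):
            assert abs(preds[name] / rho - 1.0) > 0.05
        planted = ScenarioSet(
            rho_wt=rho,
            rho_provenance="synthetic",
            entries=[
                ScenarioEntry(e.name, dict(e.enzyme_multipliers),
                              dict(e.hierarchical_multipliers),
                              observed_sg=preds[e.name] if e.is_quantitative else None,
                              direction=None if e.is_quantitative
                              else ("down" if preds[e.name] < rho else "up"),
                              provenance="synthetic")
                for e in template.entries
            ],
        )
        res = screen_design(design, planted, n=1, seed=11)
        assert res.Q == 1

    def test_vectorized_verdicts_match_reference_evaluator(self, recovery_setup):
        design, sset, _ = recovery_setup
        n = 300
        ens = DesignEnsemble(design, sset.rho_wt)
        rng = np.random.default_rng(design_seed_sequence(7, design))
        F, f_dep = ens.sample(n, rng)
        sols = {}
        for entry in sset.entries:
            mult = entry.to_perturbation().multipliers(
                ens.model.enzymes, hierarchical=design.hierarchical
            )
            sols[entry.name] = ens.solve(F, f_dep, mult)
        model = ens.model
        for i in range(n):
            # scalar reference path: rebuild the instance and its solutions
            orders = {
                (model.terms[ti].reaction, model.dependent_vars[vi]): f_dep[i, ti, vi]
                for (ti, vi, _lo, _hi) in ens.pairs
            }
            inst = normalize_instance(model, F[i], orders)
            ssys = derive_ssystem(inst)
            preds = {}
            for entry in sset.entries:
                sol = solve_steady_state(
                    ssys, entry.to_perturbation(),
                    hierarchical=design.hierarchical, rho_wt=sset.rho_wt,
                )
                preds[entry.name] = sol.sg_ratio if sol.ok else None
            verdict = evaluate_instantiation(preds, sset)
            batch_behaved = all(s.behaved[i] for s in sols.values())
            if verdict == "ill_behaved":
                assert not batch_behaved
            else:
                assert batch_behaved
                for entry in sset.entries:
                    assert sols[entry.name].sg[i] == pytest.approx(
                        preds[entry.name], rel=1e-9
                    )


class TestScreenAll:
    def test_matrix_shape_and_design_count(self, configs, scenario_set):
        designs = enumerate_designs(
            configs, enumerate_crosstalk_patterns("activation")
        )
        q, filled, _ = screen_all(designs, scenario_set, n=50, seed=3)
        assert q.shape == (2, 19)
        assert set(q.columns) == {c.label for c in configs}
        assert ((q > 0) == filled).all().all()

    def test_impossible_margin_empties_the_matrix(self, configs, scenario_set):
        designs = enumerate_designs(configs[:5], [frozenset({"M2", "M5"})])
        crit = ValidityCriteria(qual_margin=1e6)
        q, filled, _ = screen_all(designs, scenario_set, n=200, seed=3, criteria=crit)
        assert int(q.to_numpy().sum()) == 0
        assert not filled.to_numpy().any()

    def test_relaxing_criteria_never_unfills_a_circle(self, recovery_setup):
        design, sset, res = recovery_setup
        strict = ValidityCriteria()
        relaxed_q = screen_design(design, sset, n=4000, seed=7, criteria=strict)
        assert relaxed_q.Q_prime >= relaxed_q.Q
        tighter = ValidityCriteria(mse_threshold=0.001, qual_margin=0.1)
        res_tight = screen_design(design, sset, n=4000, seed=7, criteria=tighter)
        assert res_tight.Q <= res.Q


class TestQuadrantData:
    def test_northwest_flag_matches_qualitative_clauses(self, by_label, scenario_set):
        design = Design(by_label["A"], frozenset({"M2", "M5"}))
        df = quadrant_data(design, scenario_set, n=500, seed=1)
        rho = scenario_set.rho_wt
        expected = (
            df.behaved
            & (df["sg_ccr1-KO"] < 0.95 * rho)
            & (df["sg_ccr2-KO"] > 1.05 * rho)
        )
        assert (df.northwest == expected).all()


class TestSummaries:
    def test_median_and_iqr_of_constant_records(self):
        df = pd.DataFrame({"y_ccr2-KO_X2": [0.0, 0.0, 0.0]})
        out = summarize_metabolite(df, "X2", "ccr2-KO")
        assert out == {"median": 1.0, "iqr": 0.0}

    def test_median_of_log_levels(self):
        df = pd.DataFrame({"y_ccr2-KO_X2": np.log([2.0, 4.0, 8.0])})
        assert summarize_metabolite(df, "X2", "ccr2-KO")["median"] == pytest.approx(4.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_metabolite(pd.DataFrame(), "X2", "ccr2-KO")

    def test_ccr2_knockout_raises_caffeyl_aldehyde_in_valid_models(self, recovery_setup):
        _design, _sset, res = recovery_setup
        assert res.Q > 0
        out = summarize_metabolite(res.valid_records, "X2", "ccr2-KO")
        assert out["median"] > 1.0
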