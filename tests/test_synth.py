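"""Generator ground truth: traces, budget-consistent chemistry, biology."""

import numpy as np
import pytest

from biocathode.budget import build_donor_budget
from biocathode.compounds import DEFAULT_REGISTRY
from biocathode.constants import FARADAY
from biocathode.datatypes import ReactorRecord
from biocathode.electrochem import fold_increase, integrate_current
from biocathode.synth import (
    SCENARIO_PRESETS,
    Scenario,
    generate_biology,
    generate_chemistry,
    generate_experiment,
    generate_trace,
)


def record(rid="SYN-test-0", inoculum="LC2", acceptor="CO2"):
    return ReactorRecord(rid, inoculum, 30.0, 7.0, acceptor)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestGenerateTrace:
    def test_abiotic_noiseless_fold_is_one(self):
        scenario = SCENARIO_PRESETS["abiotic"].noiseless()
        trace = generate_trace(scenario, record(), rng())
        ratio, _ = fold_increase(trace)
        assert ratio == pytest.approx(1.0)

    def test_cathode_draw_equals_integrated_coulombs(self):
        scenario = SCENARIO_PRESETS["electrotroph"].noiseless()
        trace = generate_trace(scenario, record(), rng())
        assert integrate_current(trace) == pytest.approx(
            scenario.donor_draws_C["cathode"], rel=1e-12
        )

    def test_plateau_to_baseline_sets_fold_limit(self):
        # late midpoint + fast rate: the logistic is a step to the plateau,
        # so j_max/j_1h approaches 1 + plateau/baseline
        base = 1e-4
        draw_bio = 5 * base * 518_400.0 / 2  # plateau 5x baseline over half the run
        scenario = Scenario(
            label="electrotroph",
            baseline_current_A=base,
            logistic_midpoint_s=259_200.0,
            logistic_rate_per_s=1e-2,
            donor_draws_C={"cathode": base * 518_400.0 + draw_bio},
            product_profile={"acetic acid": 1.0},
            efficiency=1.0,
        ).noiseless()
        trace = generate_trace(scenario, record(), rng())
        ratio, t_at = fold_increase(trace)
        assert ratio == pytest.approx(6.0, rel=0.01)
        assert 2.5 * 86_400 <= t_at <= 3.5 * 86_400

    def test_fixed_seed_reproducible(self):
        scenario = SCENARIO_PRESETS["electrotroph"]
        a = generate_trace(scenario, record(), rng(7))
        b = generate_trace(scenario, record(), rng(7))
        assert np.array_equal(a.current_A, b.current_A)

    def test_draw_below_baseline_charge_errors(self):
        scenario = Scenario(
            label="electrotroph",
            baseline_current_A=1e-3,
            donor_draws_C={"cathode": 10.0},
            product_profile={"acetic acid": 1.0},
        )
        with pytest.raises(ValueError, match="baseline charge"):
            generate_trace(scenario, record(), rng())


class TestGenerateChemistry:
    def test_acetate_delta_inverts_ce_formula(self):
        # cathode draw 200 C, acetate only, efficiency 1:
        # delta = 200 / (F * 8 * 0.25) = 1.036 mM
        scenario = Scenario(
            label="electrotroph",
            baseline_current_A=1e-5,
            donor_draws_C={"cathode": 200.0},
            product_profile={"acetic acid": 1.0},
            efficiency=1.0,
        ).noiseless()
        series, _ = generate_chemistry(scenario, record(), rng())
        acetate = next(m for m in series if m.compound_name == "acetic acid")
        assert acetate.delta_mM == pytest.approx(
            200.0 / (FARADAY * 8 * 0.25) * 1000, rel=1e-12
        )
        assert acetate.delta_mM == pytest.approx(1.036, abs=0.001)

    def test_abiotic_chemistry_unchanged(self):
        scenario = SCENARIO_PRESETS["abiotic"].noiseless()
        series, cod = generate_chemistry(scenario, record(acceptor="SO4"), rng())
        assert all(m.delta_mM == 0.0 for m in series)
        assert cod.cod_initial_gO2_per_L == cod.cod_final_gO2_per_L

    def test_product_coulombs_equal_efficiency_times_draws(self):
        scenario = Scenario(
            label="electro_fermenter",
            donor_draws_C={"cathode": 100.0, "yeast_extract": 100.0},
            product_profile={"acetic acid": 0.5, "butyric acid": 0.5},
            efficiency=0.7,
        ).noiseless()
        series, _ = generate_chemistry(scenario, record(), rng())
        q = sum(
            FARADAY * DEFAULT_REGISTRY[m.compound_name].ne * m.delta_mM / 1000 * 0.25
            for m in series
            if m.delta_mM > 0
        )
        assert q == pytest.approx(0.7 * 200.0, rel=1e-12)

    def test_thiosulfate_draw_realized_stoichiometrically(self):
        scenario = Scenario(
            label="electro_fermenter",
            donor_draws_C={"cathode": 100.0, "thiosulfate": 965.0},
            product_profile={"acetic acid": 1.0},
            efficiency=0.5,
        ).noiseless()
        series, _ = generate_chemistry(scenario, record(acceptor="SO4"), rng())
        thio = next(m for m in series if m.compound_name == "thiosulfate")
        sulfate = next(m for m in series if m.compound_name == "sulfate")
        assert sulfate.delta_mM == pytest.approx(-2 * thio.delta_mM, rel=1e-9)
        assert -thio.delta_mM / 1000 * 0.25 * 8 * FARADAY == pytest.approx(965.0)

    def test_infeasible_formate_draw_errors(self):
        scenario = Scenario(
            label="methylotroph",
            donor_draws_C={"formate": 5000.0},  # would need > 20 mM formate
            product_profile={"acetic acid": 1.0},
        )
        with pytest.raises(ValueError, match="more than the initial"):
            generate_chemistry(scenario, record(inoculum="BJ", acceptor="HCOO"), rng())


class TestGenerateBiology:
    def test_multinomial_counts_near_expectation(self):
        scenario = Scenario(
            label="fermenter",
            donor_draws_C={"yeast_extract": 100.0},
            product_profile={"acetic acid": 1.0},
            taxon_profile={"A": 0.5, "B": 0.5},
            amplicon_depth=100_000,
        )
        _, _, sample, _ = generate_biology(scenario, record(), rng(3))
        sigma = np.sqrt(100_000 * 0.25)
        assert abs(sample["A"] - 50_000) < 3 * sigma
        assert sample.sum() == 100_000

    def test_abiotic_blank_levels(self):
        scenario = SCENARIO_PRESETS["abiotic"]
        qpcr, biofilm, _, _ = generate_biology(scenario, record(), rng())
        assert biofilm.score == 0
        assert qpcr.bacterial_copies_per_cm2 < 1e6

    def test_seeded_reproducibility(self):
        scenario = SCENARIO_PRESETS["electrotroph"]
        a = generate_biology(scenario, record(), rng(11))
        b = generate_biology(scenario, record(), rng(11))
        assert a[0] == b[0]
        assert a[2].equals(b[2])


class TestGenerateExperiment:
    def test_default_mix_one_bundle_per_label(self):
        ds = generate_experiment(master_seed=5)
        assert len(ds.bundles) == 5
        assert len(ds.truth) == 5
        assert set(ds.truth["label"]) == set(SCENARIO_PRESETS)
        assert ds.amplicons.counts.shape[1] == 5

    def test_same_master_seed_identical(self):
        a = generate_experiment(master_seed=9)
        b = generate_experiment(master_seed=9)
        for x, y in zip(a.bundles, b.bundles):
            assert np.array_equal(x.trace.current_A, y.trace.current_A)
            assert x.cod == y.cod and x.qpcr == y.qpcr
        assert a.amplicons.counts.equals(b.amplicons.counts)

    def test_streams_depend_only_on_seed_and_reactor_id(self):
        from biocathode.synth import generate_reactor

        rec_a = record("SYN-a")
        rec_b = record("SYN-b")
        scenario = SCENARIO_PRESETS["electrotroph"]
        # generating b before a must not change a's stream
        b1, _, _ = generate_reactor(scenario, rec_b, master_seed=4)
        a1, _, _ = generate_reactor(scenario, rec_a, master_seed=4)
        a2, _, _ = generate_reactor(scenario, rec_a, master_seed=4)
        b2, _, _ = generate_reactor(scenario, rec_b, master_seed=4)
        assert np.array_equal(a1.trace.current_A, a2.trace.current_A)
        assert np.array_equal(b1.trace.current_A, b2.trace.current_A)
        assert not np.array_equal(a1.trace.current_A, b1.trace.current_A)

    def test_products_never_exceed_donors(self):
        # conservation by construction at efficiency <= 1
        ds = generate_experiment(master_seed=2)
        for _, row in ds.truth.iterrows():
            donors = (
                row.q_cathode_C + row.q_formate_C
                + row.q_thiosulfate_C + row.q_yeast_extract_C
            )
            assert row.q_products_C <= donors + 1e-9

    def test_noiseless_classification_recovery(self):
        mix = [s.noiseless() for s in SCENARIO_PRESETS.values()]
        ds = generate_experiment(mix, master_seed=13)
        for bundle, (_, truth) in zip(ds.bundles, ds.truth.iterrows()):
            summary_q = integrate_current(bundle.trace)
            budget = build_donor_budget(
                bundle.record, summary_q, bundle.metabolite_deltas_mM(), bundle.cod
            )
            assert budget.classification == truth.expected_classification
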