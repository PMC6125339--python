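import math

import numpy as np
import pytest

from b2bsample.qoi_data import QOITable, load_qoi_table
from b2bsample.synthetic_model import (
    DEFAULT_SEED,
    N_PARAMS,
    PARAMETER_NAMES,
    ConfigurationError,
    ParameterVector,
    _directions,
    calibrate_defaults,
    coefficient_box,
    default_config,
    effective_coefficients,
    eval_qoi,
    lp_feasibility_oracle,
    make_config,
    solve_for_coefficients,
)
from b2bsample.mopac import (
    MopacEvaluationFailed,
    MopacParseError,
    MopacTemplateError,
    mopac_parse_output,
    mopac_write_input,
    parse_own_deck,
)


def test_parameter_registry():
    assert len(PARAMETER_NAMES) == N_PARAMS == 27
    assert PARAMETER_NAMES[0] == "USS_H" and PARAMETER_NAMES[-1] == "XFAC_C"


def test_parameter_vector_validation(cfg):
    pv = ParameterVector(cfg.x_nom)
    assert pv["USS_H"] == pytest.approx(cfg.x_nom[0])
    with pytest.raises(ValueError):
        ParameterVector(np.ones(26))
    with pytest.raises(ValueError):
        ParameterVector(np.r_[np.ones(26), np.nan])
    renamed = {**pv.as_dict()}
    renamed["USS_X"] = renamed.pop("USS_H")
    with pytest.raises(ValueError):
        ParameterVector(renamed)


def test_coefficients_vanish_at_nominal(cfg):
    alpha, beta, gamma = effective_coefficients(cfg.x_nom, cfg)
    assert (alpha, beta, gamma) == pytest.approx((-12.3, -4.928, 0.0), abs=1e-12)


def test_eval_qoi_nominal_values(cfg):
    assert eval_qoi(cfg.x_nom, 1, cfg) == pytest.approx(-12.3, abs=1e-12)
    assert eval_qoi(cfg.x_nom, 8, cfg) == pytest.approx(-12.3 + 7 * -4.928, abs=1e-12)
    with pytest.raises(ValueError):
        eval_qoi(cfg.x_nom, 0, cfg)


def test_basis_identity_m2_minus_m1(cfg, rng):
    # algebraic identity of the basis: M_2 - M_1 = beta - gamma / 2
    for _ in range(20):
        x = cfg.x_nom + cfg.delta_ref * rng.uniform(-1, 1, N_PARAMS)
        _, beta, gamma = effective_coefficients(x, cfg)
        lhs = eval_qoi(x, 2, cfg) - eval_qoi(x, 1, cfg)
        assert lhs == pytest.approx(beta - gamma / 2, abs=1e-10)


def test_size_extensivity_limit(cfg, rng):
    # M_{n+1} - M_n -> beta; at n = 20 the deviation is exactly |gamma| / 420
    for _ in range(10):
        x = cfg.x_nom + cfg.delta_ref * rng.uniform(-1, 1, N_PARAMS)
        _, beta, gamma = effective_coefficients(x, cfg)
        dev = abs((eval_qoi(x, 21, cfg) - eval_qoi(x, 20, cfg)) - beta)
        assert dev <= abs(gamma) / 420 + 1e-12
    dev_nom = abs((eval_qoi(cfg.x_nom, 21, cfg) - eval_qoi(cfg.x_nom, 20, cfg)) - -4.928)
    assert dev_nom < 1e-12


def test_exact_fit_coefficients_small_alkanes(table, cfg):
    # independent oracle: solve the 3x3 linear system M_n = value_n, n = 1..3
    A = np.array([[1.0, n - 1.0, 1.0 / n - 1.0] for n in (1, 2, 3)])
    y = np.array([table[n].value for n in (1, 2, 3)])
    coeffs = np.linalg.solve(A, y)
    assert coeffs == pytest.approx((-17.81, -6.435, -8.37), abs=1e-9)
    # and those coefficients indeed reproduce the basis predictions
    assert A @ coeffs == pytest.approx(y, abs=1e-12)


class TestLPOracle:
    def generous_box(self):
        return {"alpha": (-40.0, 10.0), "beta": (-10.0, 0.0), "gamma": (-30.0, 30.0)}

    def test_3_to_8_feasible_by_line_fit(self, table):
        # a pure line fit to rows 3..8 already sits within every uncertainty
        ns = np.arange(3, 9)
        y = np.array([table[n].value for n in ns])
        slope, intercept = np.polyfit(ns - 1.0, y, 1)
        resid = np.abs(intercept + slope * (ns - 1.0) - y)
        unc = np.array([table[n].uncertainty for n in ns])
        assert resid.max() < 0.05 and np.all(resid < unc)
        verdict = lp_feasibility_oracle(table, range(3, 9), self.generous_box())
        assert verdict.feasible

    def test_1_to_8_infeasible_even_generous(self, table):
        assert not lp_feasibility_oracle(table, range(1, 9), self.generous_box()).feasible

    @pytest.mark.parametrize("e", range(1, 9))
    def test_single_index_feasible(self, table, e):
        assert lp_feasibility_oracle(table, [e], self.generous_box()).feasible

    def test_unbounded_box_rejected(self, table):
        box = {"alpha": (-np.inf, 0.0), "beta": (-10, 0), "gamma": (-1, 1)}
        with pytest.raises(ValueError):
            lp_feasibility_oracle(table, [4], box)

    def test_structural_verdicts_default_config(self, table, cfg):
        box = coefficient_box(cfg)
        assert not lp_feasibility_oracle(table, range(1, 9), box).feasible
        assert not lp_feasibility_oracle(table, range(2, 9), box).feasible
        verdict = lp_feasibility_oracle(table, range(3, 9), box)
        assert verdict.feasible and verdict.witness is not None

    def test_witness_maps_back_to_parameter_space(self, table, cfg):
        verdict = lp_feasibility_oracle(table, range(3, 9), coefficient_box(cfg),
                                        interior=True)
        x = solve_for_coefficients(verdict.witness, cfg)
        got = effective_coefficients(x, cfg)
        assert got == pytest.approx(verdict.witness, abs=1e-8)
        for e in range(3, 9):
            assert table[e].contains(eval_qoi(x, e, cfg))


def test_sampled_feasibility_never_contradicts_oracle(model, table, cfg, rng):
    """Soundness: any sampled member of F_I implies the LP for I is feasible."""
    box = coefficient_box(cfg)
    Z = rng.uniform(-1, 1, size=(3000, N_PARAMS))
    X = cfg.x_nom + Z * cfg.delta_ref
    Q = model.evaluate_many(X, table.indices)
    mask = np.column_stack([(Q[:, j] >= table[e].L) & (Q[:, j] <= table[e].U)
                            for j, e in enumerate(table.indices)])
    for a in range(1, 9):
        for b in range(a, 9):
            cols = [table.indices.index(e) for e in range(a, b + 1)]
            if mask[:, cols].all(axis=1).any():
                assert lp_feasibility_oracle(table, range(a, b + 1), box).feasible


class TestCalibrateDefaults:
    def test_coverage_and_offsets(self, table):
        cfg = calibrate_defaults()
        box = coefficient_box(cfg)
        assert box["alpha"][0] <= -20.3 + 1e-9 and box["alpha"][1] >= -4.3 - 1e-9
        assert box["beta"][0] <= -7.0 and box["beta"][1] >= -2.5
        assert box["gamma"][0] <= -0.02 + 1e-12 and box["gamma"][1] >= 0.02 - 1e-12
        for n in range(3, 9):
            offset = abs(eval_qoi(cfg.x_nom, n, cfg) - table[n].value)
            assert 2.5 <= offset <= 3.5

    def test_stated_defaults(self, cfg):
        assert cfg.eps == 0.5
        assert np.sum(np.abs(cfg.omega)) == pytest.approx(3 * math.pi, rel=1e-12)

    def test_deterministic(self):
        a, b = calibrate_defaults(seed=77), calibrate_defaults(seed=77)
        assert np.array_equal(a.w_alpha, b.w_alpha)
        assert np.array_equal(a.omega, b.omega)

    def test_shipped_csv_matches_regeneration(self, cfg):
        regen = _directions(DEFAULT_SEED)
        for key, val in regen.items():
            assert np.array_equal(np.asarray(getattr(cfg, key), dtype=float), val), key


def test_nominal_objective_for_pentane_hexane(model, table, cfg):
    # squared residual of the nominal against pentane/hexane reported values
    obj = sum((model.evaluate(cfg.x_nom, e) - table[e].value) ** 2 for e in (5, 6))
    assert obj == pytest.approx(17.57, abs=0.01)


class TestMopacAdapter:
    def test_deck_contains_every_name_once(self, cfg):
        deck = mopac_write_input(ParameterVector(cfg.x_nom))
        for name in PARAMETER_NAMES:
            assert deck.count(f"{name}=") == 1

    def test_round_trip_bit_exact(self, cfg, rng):
        x = cfg.x_nom + rng.standard_normal(N_PARAMS) * 1e-3
        deck = mopac_write_input(ParameterVector(x))
        values = parse_own_deck(deck)
        assert np.array_equal(np.array([values[n] for n in PARAMETER_NAMES]), x)

    def test_renamed_parameter_rejected(self, cfg):
        bad = ParameterVector(cfg.x_nom).as_dict()
        bad["USS_X"] = bad.pop("USS_H")
        with pytest.raises(MopacTemplateError):
            mopac_write_input(bad)

    def test_parse_final_heat(self):
        text = "...\n FINAL HEAT OF FORMATION = -30.10 KCAL/MOL\n...\n"
        assert mopac_parse_output(text) == pytest.approx(-30.10)

    def test_truncated_output(self):
        with pytest.raises(MopacParseError):
            mopac_parse_output("SCF cycles ...\n(no final line)")

    def test_failure_marker(self):
        with pytest.raises(MopacEvaluationFailed):
            mopac_parse_output("UNABLE TO ACHIEVE SELF-CONSISTENCE\n")
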