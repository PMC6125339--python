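import numpy as np
import pytest

from b2bsample.feasibility import (
    SampleBatch,
    apply_bounds,
    batch_from_csv,
    batch_to_csv,
    consistency_verdict,
    convexity_check,
    count_at_least,
    evaluate_batch,
    feasible_subset,
    find_nonconvex_pair,
    ga_search,
    longest_consecutive_feasible,
    segment_scan,
)
from b2bsample.qoi_data import QOIBound, QOITable, relax_bounds
from b2bsample.synthetic_model import N_PARAMS, coefficient_box, lp_feasibility_oracle


def _mask_batch(mask, indices=None):
    """A toy masked batch from a boolean matrix."""
    mask = np.asarray(mask, dtype=bool)
    n, m = mask.shape
    indices = tuple(indices) if indices else tuple(range(1, m + 1))
    return SampleBatch(
        params=np.zeros((n, N_PARAMS)),
        qoi_indices=indices,
        qois=np.zeros((n, m)),
        ok=np.ones(n, dtype=bool),
        mask=mask,
        mask_indices=indices,
    )


class _Scalar1DModel:
    """Evaluates f(x[0]) regardless of molecule index."""

    def __init__(self, fn):
        self.fn = fn

    def evaluate(self, x, n):
        return float(self.fn(np.asarray(x)[0]))


class TestEvaluateBatch:
    def test_nominal_row_matches_curve(self, model, cfg):
        batch = evaluate_batch(model, cfg.x_nom[None, :], range(1, 9))
        assert batch.column(8)[0] == pytest.approx(-46.796, abs=1e-12)
        assert batch.column(1)[0] == pytest.approx(-12.3, abs=1e-12)

    def test_chunking_is_invisible(self, model, rng):
        X = model.cfg.x_nom + model.cfg.delta_ref * rng.uniform(-1, 1, (50, N_PARAMS))
        whole = evaluate_batch(model, X, range(1, 9))
        chunked = evaluate_batch(model, X, range(1, 9), chunk_size=7)
        assert np.array_equal(whole.qois, chunked.qois)

    def test_empty_index_list(self, model, cfg):
        with pytest.raises(ValueError):
            evaluate_batch(model, cfg.x_nom[None, :], [])

    def test_failed_rows_flagged_and_excluded(self, table):
        class Flaky:
            def evaluate(self, x, n):
                if x[0] > 0:
                    raise RuntimeError("boom")
                return table[n].value  # exactly feasible

        X = np.zeros((4, N_PARAMS))
        X[1, 0] = X[3, 0] = 1.0
        batch = apply_bounds(evaluate_batch(Flaky(), X, table.indices), table)
        assert np.array_equal(batch.ok, [True, False, True, False])
        assert count_at_least(batch, 1) == 2


class TestApplyBounds:
    def test_closed_interval_boundaries(self, table):
        b = table[4]
        qois = np.array([[b.L], [b.value], [b.U], [b.U + 1e-12], [b.L - 1e-12]])
        batch = SampleBatch(np.zeros((5, N_PARAMS)), (4,), qois, np.ones(5, bool))
        masked = apply_bounds(batch, QOITable([b]))
        assert masked.mask[:, 0].tolist() == [True, True, True, False, False]

    def test_missing_column_named(self, table):
        batch = SampleBatch(np.zeros((1, N_PARAMS)), (4,), np.zeros((1, 1)), np.ones(1, bool))
        with pytest.raises(KeyError, match="1"):
            apply_bounds(batch, table)

    def test_mask_deterministic(self, witness_batch, table):
        again = apply_bounds(witness_batch, table)
        assert np.array_equal(again.mask, witness_batch.mask)


class TestFeasibleSubset:
    def test_conjunction(self):
        batch = _mask_batch([[1, 1], [1, 0], [0, 1]])
        assert feasible_subset(batch, [1, 2]).n_members == 1
        assert feasible_subset(batch, [1]).n_members == 2

    def test_monotone_in_subset(self, rng):
        mask = rng.random((50, 5)) < 0.6
        batch = _mask_batch(mask)
        for _ in range(20):
            I = set(rng.choice(5, size=rng.integers(1, 5), replace=False) + 1)
            extra = int(rng.integers(1, 6))
            bigger = feasible_subset(batch, I | {extra})
            assert bigger.n_members <= feasible_subset(batch, I).n_members
            assert set(bigger.members) <= set(feasible_subset(batch, I).members)

    def test_empty_subset_invalid(self):
        with pytest.raises(ValueError):
            feasible_subset(_mask_batch([[1]]), [])


class TestCountCascade:
    def test_toy_counts(self):
        batch = _mask_batch([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
        counts = [count_at_least(batch, m) for m in (1, 2, 3)]
        assert counts == [2, 1, 0]

    def test_non_increasing_and_anchor(self, rng):
        mask = rng.random((200, 8)) < 0.3
        batch = _mask_batch(mask)
        counts = [count_at_least(batch, m) for m in range(1, 9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == 200 - int(np.sum(~mask.any(axis=1)))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            count_at_least(_mask_batch([[1, 0]]), 3)


class TestLongestConsecutive:
    def test_covers_3_to_8_but_not_2_to_8(self, table):
        mask = np.zeros((3, 8), dtype=bool)
        mask[0, 2:8] = True      # feasible for 3..8
        mask[1, 0:4] = True      # feasible for 1..4
        mask[2, 1] = True        # feasible for 2 only
        batch = _mask_batch(mask, indices=range(1, 9))
        best = longest_consecutive_feasible(batch, table)
        assert best.indices == tuple(range(3, 9))

    def test_all_true_row_gives_full_range(self, table):
        batch = _mask_batch(np.ones((1, 8), dtype=bool), indices=range(1, 9))
        assert longest_consecutive_feasible(batch, table).indices == table.indices

    def test_tie_breaks_to_smallest_start(self, table):
        mask = np.zeros((2, 8), dtype=bool)
        mask[0, 0:3] = True      # 1..3
        mask[1, 4:7] = True      # 5..7
        batch = _mask_batch(mask, indices=range(1, 9))
        assert longest_consecutive_feasible(batch, table).indices == (1, 2, 3)

    def test_no_feasible_rows(self, table):
        batch = _mask_batch(np.zeros((2, 8), dtype=bool), indices=range(1, 9))
        assert longest_consecutive_feasible(batch, table) is None


class TestConsistencyVerdict:
    def test_witness_gives_evidence(self):
        batch = _mask_batch([[1, 1], [0, 1]])
        v = consistency_verdict(batch, [1, 2])
        assert v.evidence_of_consistency and v.n_members == 1

    def test_empty_is_sample_limited(self):
        batch = _mask_batch([[1, 0], [0, 1]])
        v = consistency_verdict(batch, [1, 2])
        assert not v.evidence_of_consistency
        assert "does not prove" in v.note

    def test_full_subset_no_evidence_matches_oracle(self, witness_batch, table, cfg):
        v = consistency_verdict(witness_batch, table.indices)
        assert v.label == "no_evidence"
        assert not lp_feasibility_oracle(table, table.indices, coefficient_box(cfg)).feasible


class TestGASearch:
    def test_finds_feasible_subset(self, model, table, design_box):
        res = ga_search(model, table, range(3, 9), design_box, budget=20000, seed=7)
        assert res.violation <= 0.0 and res.feasible

    def test_infeasible_subset_stays_violated(self, model, table, design_box):
        res = ga_search(model, table, range(1, 9), design_box, budget=6000, seed=7)
        assert res.violation > 0.0 and not res.feasible

    def test_budget_one_returns_single_candidate(self, model, table, design_box):
        res = ga_search(model, table, [4], design_box, budget=1, seed=3)
        assert res.n_evals == 1

    def test_deterministic(self, model, table, design_box):
        a = ga_search(model, table, [4, 5], design_box, budget=500, seed=9)
        b = ga_search(model, table, [4, 5], design_box, budget=500, seed=9)
        assert np.array_equal(a.x, b.x) and a.violation == b.violation


class TestSegmentScan:
    toy_table = QOITable([QOIBound(1, 0.125, 0.125)])  # bounds [0, 0.25]

    def _endpoints(self):
        x1 = np.zeros(N_PARAMS)
        x2 = np.zeros(N_PARAMS)
        x2[0] = 1.0
        return x1, x2

    def test_parabola_windows_and_crossings(self):
        model = _Scalar1DModel(lambda u: (2 * u - 1) ** 2)
        x1, x2 = self._endpoints()
        scan = segment_scan(model, x1, x2, 1, self.toy_table, step=1e-3)
        feas_t = scan.t[scan.feasible]
        assert feas_t.min() == pytest.approx(0.25, abs=2e-3)
        assert feas_t.max() == pytest.approx(0.75, abs=2e-3)
        assert sorted(scan.crossings) == pytest.approx([0.25, 0.75], abs=1e-5)

    def test_affine_model_fully_feasible(self):
        model = _Scalar1DModel(lambda u: 0.1 + 0.05 * u)
        x1, x2 = self._endpoints()
        scan = segment_scan(model, x1, x2, 1, self.toy_table)
        assert scan.feasible.all()
        assert convexity_check(scan) == "convex_consistent"

    def test_extended_scan_finds_second_window(self):
        # (2t-1)^2 in [0.81, 1.21]  <=>  t in [-0.05, 0.05] u [0.95, 1.05]
        table = QOITable([QOIBound(1, 1.01, 0.20)])
        model = _Scalar1DModel(lambda u: (2 * u - 1) ** 2)
        x1, x2 = self._endpoints()
        scan = segment_scan(model, x1, x2, 1, table, t_lo=-0.2, t_hi=1.2, step=1e-3)
        feas_t = scan.t[scan.feasible]
        assert feas_t.min() == pytest.approx(-0.05, abs=2e-3)
        assert feas_t.max() == pytest.approx(1.05, abs=2e-3)
        assert len(scan.crossings) == 4
        assert sorted(scan.crossings) == pytest.approx([-0.05, 0.05, 0.95, 1.05], abs=1e-5)

    def test_interior_gap_is_non_convex(self):
        table = QOITable([QOIBound(1, 1.01, 0.20)])
        model = _Scalar1DModel(lambda u: (2 * u - 1) ** 2)
        x1, x2 = self._endpoints()
        scan = segment_scan(model, x1, x2, 1, table, step=1e-3)
        assert convexity_check(scan) == "non_convex"

    def test_infeasible_endpoint_rejected(self):
        model = _Scalar1DModel(lambda u: (2 * u - 1) ** 2)
        x1, x2 = self._endpoints()
        scan = segment_scan(model, x1, x2, 1, self.toy_table)  # endpoints at 1.0
        with pytest.raises(ValueError):
            convexity_check(scan)


def test_synthetic_feasible_set_is_non_convex(model, table):
    """Two sampled-feasible points for hexane with an infeasible midpoint."""
    x1, x2 = find_nonconvex_pair(model, table, n=6, seed=123)
    for x in (x1, x2):
        assert table[6].contains(model.evaluate(x, 6))
    scan = segment_scan(model, x1, x2, 6, table)
    assert convexity_check(scan) == "non_convex"


def test_relaxed_bounds_nest_members(witness_batch, table):
    relaxed_batch = apply_bounds(witness_batch, relax_bounds(table, 1.0))
    assert np.all(witness_batch.mask <= relaxed_batch.mask)
    for I in ([3, 4], [3, 4, 5, 6, 7, 8], [6]):
        tight = set(feasible_subset(witness_batch, I).members)
        loose = set(feasible_subset(relaxed_batch, I).members)
        assert tight <= loose


def test_batch_csv_round_trip(tmp_path, witness_batch):
    paths = batch_to_csv(witness_batch, tmp_path, "t")
    again = batch_from_csv(tmp_path, "t")
    assert np.array_equal(again.params, witness_batch.params)
    assert np.array_equal(again.qois, witness_batch.qois)
    assert np.array_equal(again.mask, witness_batch.mask)
    assert again.qoi_indices == witness_batch.qoi_indices
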