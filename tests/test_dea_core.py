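"""Unit and property tests for the BCC envelopment solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dea_oracles import grid_radial_score, oracle_radial_score, random_instance
from icudea.dea_core import (
    DEADataError,
    DEADataset,
    back_transform_targets,
    evaluate_all,
    invert_variables,
    reference_counts,
    solve_input_oriented,
    solve_output_oriented,
)


def make_dataset(X, Y, inverted_in=None, inverted_out=None):
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    m, n = X.shape
    s = Y.shape[0]
    return DEADataset(
        dmu_ids=tuple(f"d{j}" for j in range(n)),
        X=X,
        Y=Y,
        input_labels=tuple(f"in{i}" for i in range(m)),
        output_labels=tuple(f"out{r}" for r in range(s)),
        inverted_inputs=tuple(inverted_in or [False] * m),
        inverted_outputs=tuple(inverted_out or [False] * s),
    )


#: the worked 3-DMU instance: one input, one output, VRS frontier A--B
WORKED_X = np.array([[2.0, 4.0, 3.0]])
WORKED_Y = np.array([[2.0, 4.0, 2.0]])


class TestInvertVariables:
    def test_reciprocal_and_fixed_point(self):
        np.testing.assert_allclose(invert_variables([1.0], True), [1.0])
        np.testing.assert_allclose(invert_variables([0.5, 2.0], True), [2.0, 0.5])
        np.testing.assert_allclose(invert_variables([0.5, 2.0], False), [0.5, 2.0])

    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=8))
    def test_involution(self, values):
        twice = invert_variables(invert_variables(values, True), True)
        np.testing.assert_allclose(twice, values, rtol=1e-12)

    def test_nonpositive_rejected_naming_dmu(self):
        with pytest.raises(DEADataError, match="smr.*ICU_2"):
            invert_variables([1.0, 0.0], True, label="smr", dmu_ids=["ICU_1", "ICU_2"])


class TestDatasetValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(DEADataError, match="duplicate"):
            DEADataset(("a", "a"), np.ones((1, 2)), np.ones((1, 2)),
                       ("x",), ("y",), (False,), (False,))

    def test_zero_entry_rejected_with_location(self):
        with pytest.raises(DEADataError, match="'in0'.*'d1'"):
            make_dataset([[1.0, 0.0]], [[1.0, 1.0]])

    def test_from_dataframe_applies_inversion(self):
        import pandas as pd

        df = pd.DataFrame({"dmu": ["a", "b"], "x": [1.0, 2.0], "smr": [0.5, 2.0]})
        ds = DEADataset.from_dataframe(
            df, dmu_column="dmu", input_columns=["x"], output_columns=["smr"],
            inverted=["smr"],
        )
        np.testing.assert_allclose(ds.Y[0], [2.0, 0.5])
        assert ds.inverted_outputs == (True,)


class TestWorkedInstance:
    def test_single_dmu_is_self_efficient(self):
        ds = make_dataset([[3.0]], [[2.0]])
        for solve in (solve_input_oriented, solve_output_oriented):
            r = solve(ds, 0)
            assert r.score == pytest.approx(1.0, abs=1e-9)
            assert r.lambdas == pytest.approx({"d0": 1.0})
            assert np.all(r.input_slacks < 1e-9) and np.all(r.output_slacks < 1e-9)

    def test_input_oriented_score_and_peers(self):
        ds = make_dataset(WORKED_X, WORKED_Y)
        r = solve_input_oriented(ds, 2)
        assert r.score == pytest.approx(2.0 / 3.0, abs=1e-6)
        assert set(r.lambdas) == {"d0"}
        assert not r.efficient

    def test_output_oriented_score(self):
        ds = make_dataset(WORKED_X, WORKED_Y)
        r = solve_output_oriented(ds, 2)
        assert r.score == pytest.approx(1.5, abs=1e-6)

    def test_evaluate_all_order_and_scores(self):
        ds = make_dataset(WORKED_X, WORKED_Y)
        results = evaluate_all(ds, "input")
        assert [r.dmu_id for r in results] == ["d0", "d1", "d2"]
        np.testing.assert_allclose(
            [r.score for r in results], [1.0, 1.0, 2.0 / 3.0], atol=1e-6
        )

    def test_reference_counts_worked_instance(self):
        ds = make_dataset(WORKED_X, WORKED_Y)
        counts = reference_counts(evaluate_all(ds, "input"))
        assert counts == {"d0": 1, "d1": 0, "d2": 0}

    def test_all_identical_dmus_all_efficient_zero_counts(self):
        ds = make_dataset([[2.0] * 4], [[3.0] * 4])
        results = evaluate_all(ds, "input")
        assert all(r.efficient for r in results)
        assert set(reference_counts(results).values()) == {0}

    def test_weak_efficiency_flagged(self):
        # d1 matches d0's input but produces half the output: radial score 1
        # with a pure output slack
        ds = make_dataset([[2.0, 2.0]], [[2.0, 1.0]])
        r = solve_input_oriented(ds, 1)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.efficient and r.weakly_efficient
        assert r.output_slacks[0] == pytest.approx(1.0, abs=1e-6)


class TestOracleAgreement:
    def test_matches_independent_simplex_and_grid(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(1, 3))
            s = int(rng.integers(1, 4 - m))
            X, Y = random_instance(rng, n, m, s)
            ds = make_dataset(X, Y)
            for orientation in ("input", "output"):
                for j, r in enumerate(evaluate_all(ds, orientation)):
                    exact = oracle_radial_score(X, Y, j, orientation)
                    assert r.score == pytest.approx(exact, abs=1e-6)
                    if n <= 3:
                        approx = grid_radial_score(X, Y, j, orientation)
                        assert r.score == pytest.approx(approx, abs=5e-3)

    def test_strict_minimum_input_dmu_is_efficient(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, Y = random_instance(rng, 5, 2, 1)
            j = int(np.argmin(X[0]))
            X[0, j] *= 0.5  # make the minimum strict
            r = solve_input_oriented(make_dataset(X, Y), j)
            assert r.score == pytest.approx(1.0, abs=1e-9)


class TestInvariants:
    def test_units_invariance(self):
        rng = np.random.default_rng(11)
        X, Y = random_instance(rng, 5, 2, 1)
        base = [r.score for r in evaluate_all(make_dataset(X, Y), "input")]
        X2 = X * np.array([[10.0], [0.01]])
        Y2 = Y * 1000.0
        scaled = [r.score for r in evaluate_all(make_dataset(X2, Y2), "input")]
        np.testing.assert_allclose(base, scaled, atol=1e-7)

    def test_score_bounds_and_convexity(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(2, 7))
            X, Y = random_instance(rng, n, 2, 1)
            ds = make_dataset(X, Y)
            for orientation, lo, hi in (("input", 0.0, 1.0), ("output", 1.0, np.inf)):
                for r in evaluate_all(ds, orientation):
                    assert lo < r.score <= hi + 1e-9 if orientation == "input" else r.score >= lo - 1e-9
                    assert sum(r.lambdas.values()) == pytest.approx(1.0, abs=1e-7)

    def test_dominated_dmu_never_efficient(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X, Y = random_instance(rng, 4, 2, 1)
            X[:, 3] = X[:, 0] * 1.3  # strictly worse than DMU 0 everywhere
            Y[:, 3] = Y[:, 0] / 1.3
            ds = make_dataset(X, Y)
            for orientation in ("input", "output"):
                assert not evaluate_all(ds, orientation)[3].efficient

    def test_appending_dmu_never_increases_input_scores(self):
        rng = np.random.default_rng(14)
        for _ in range(8):
            X, Y = random_instance(rng, 4, 2, 1)
            before = [r.score for r in evaluate_all(make_dataset(X, Y), "input")]
            Xn = np.hstack([X, rng.uniform(1, 5, size=(2, 1))])
            Yn = np.hstack([Y, rng.uniform(1, 5, size=(1, 1))])
            after = [r.score for r in evaluate_all(make_dataset(Xn, Yn), "input")][:4]
            assert all(a <= b + 1e-7 for a, b in zip(after, before))

    def test_frontier_membership_is_orientation_free(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X, Y = random_instance(rng, 5, 2, 1)
            ds = make_dataset(X, Y)
            for r_in, r_out in zip(evaluate_all(ds, "input"), evaluate_all(ds, "output")):
                if r_in.efficient and not r_in.weakly_efficient:
                    assert r_out.efficient


class TestTargets:
    def test_back_transform_reciprocal_and_identity(self):
        ds = make_dataset([[2.0, 3.0]], [[0.5, 0.8]], inverted_out=[True])
        r = solve_input_oriented(ds, 1)
        r = back_transform_targets(r, ds)
        t_model = r.targets_model_scale
        t_orig = r.targets_original_scale
        assert t_orig["in0"] == pytest.approx(t_model["in0"])
        assert t_orig["out0"] == pytest.approx(1.0 / t_model["out0"])

    def test_projection_lands_on_frontier(self):
        rng = np.random.default_rng(16)
        for _ in range(8):
            X, Y = random_instance(rng, 5, 2, 1)
            ds = make_dataset(X, Y)
            for orientation in ("input", "output"):
                for j, r in enumerate(evaluate_all(ds, orientation)):
                    if r.efficient:
                        continue
                    X2, Y2 = X.copy(), Y.copy()
                    X2[:, j] = [r.targets_model_scale[l] for l in ds.input_labels]
                    Y2[:, j] = [r.targets_model_scale[l] for l in ds.output_labels]
                    solve = (
                        solve_input_oriented if orientation == "input" else solve_output_oriented
                    )
                    assert solve(make_dataset(X2, Y2), j).score == pytest.approx(
                        1.0, abs=1e-6
                    )

    def test_targets_equal_peer_combination(self):
        ds = make_dataset(WORKED_X, WORKED_Y)
        r = solve_input_oriented(ds, 2)
        lam = np.array([r.lambdas.get(d, 0.0) for d in ds.dmu_ids])
        np.testing.assert_allclose(
            [r.targets_model_scale["in0"]], WORKED_X @ lam, atol=1e-9
        )
        np.testing.assert_allclose(
            [r.targets_model_scale["out0"]], WORKED_Y @ lam, atol=1e-9
        )
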