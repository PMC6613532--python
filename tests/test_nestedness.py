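import numpy as np
import pytest
from scipy.optimize import brentq

from macronull import (
    IncidenceMatrix,
    br_discrepancy,
    gen_nested,
    nestedness_null_test,
    nodf,
    temperature,
)
from macronull.nestedness import _draw_fixed_equiprobable, _isocline_exponent

from .conftest import random_matrix

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def nodf_oracle(values):
    """Explicit double loop over ordered row and column pairs."""

    def axis_pairs(v):
        fills = v.sum(axis=1)
        contribs = []
        n = v.shape[0]
        for i in range(n):
            for j in range(n):
                if i < j:
                    hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
                    if fills[hi] > fills[lo] and fills[lo] > 0:
                        shared = int((v[hi] & v[lo]).sum())
                        contribs.append(100.0 * shared / fills[lo])
                    else:
                        contribs.append(0.0)
        return contribs

    rows = axis_pairs(values)
    cols = axis_pairs(values.T)
    total = (sum(rows) + sum(cols)) / (len(rows) + len(cols))
    return total, float(np.mean(rows)), float(np.mean(cols))


def br_oracle(values):
    """Direct count of absences in each row's leftmost-r_i window after
    sorting columns by decreasing totals."""
    order = sorted(
        range(values.shape[1]), key=lambda j: (-values[:, j].sum(), j)
    )
    v = values[:, order]
    misplaced = 0
    for row in v:
        r = int(row.sum())
        misplaced += sum(1 for x in row[:r] if x == 0)
    return misplaced


def temperature_oracle(values):
    """Re-derive U by an explicit per-cell loop: pack, scan each row for
    out-of-order cells, solve each diagonal's isocline crossing with
    brentq, and sum squared relative distances."""
    packed = values[np.argsort(-values.sum(axis=1), kind="stable")]
    packed = packed[:, np.argsort(-packed.sum(axis=0), kind="stable")]
    n_rows, n_cols = packed.shape
    a = _isocline_exponent(float(packed.mean()))
    u_sum = 0.0
    for i in range(n_rows):
        row = packed[i]
        ones = [j for j in range(n_cols) if row[j] == 1]
        zeros = [j for j in range(n_cols) if row[j] == 0]
        first_absence = zeros[0] if zeros else n_cols
        last_presence = ones[-1] if ones else -1
        for j in range(n_cols):
            breaks_order = (row[j] == 1 and j > first_absence) or (
                row[j] == 0 and j < last_presence
            )
            if not breaks_order:
                continue
            x = (j + 0.5) / n_cols
            y = (i + 0.5) / n_rows
            c = y - x
            t_star = brentq(
                lambda t: t**a + (t + c) ** a - 1.0,
                max(0.0, -c),
                min(1.0, 1.0 - c),
                xtol=1e-13,
            )
            # only score cells on the wrong side of the isocline
            if (row[j] == 1 and x > t_star) or (row[j] == 0 and x < t_star):
                u_sum += (abs(x - t_star) / (1.0 - abs(c))) ** 2
    u = u_sum / (n_rows * n_cols)
    return min(100.0, 100.0 * u / 0.04145)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


class TestNodf:
    def test_perfect_triangular_is_100(self, triangular4):
        total, rows, cols = nodf(triangular4)
        assert total == rows == cols == 100.0

    def test_identical_rows_contribute_zero(self):
        v = np.tile([1, 1, 0, 0], (3, 1))
        m = IncidenceMatrix(v, list("abc"))
        _, rows, _ = nodf(m)
        assert rows == 0.0  # no pair has decreasing fill

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        m = random_matrix(5, 5, fill=0.45, seed=seed)
        assert nodf(m) == pytest.approx(nodf_oracle(m.values))

    @pytest.mark.parametrize("seed", [10, 11])
    def test_invariant_to_permutation(self, seed):
        m = random_matrix(7, 6, fill=0.4, seed=seed)
        rng = np.random.default_rng(seed)
        perm = m.values[rng.permutation(7)][:, rng.permutation(6)]
        assert nodf(m) == pytest.approx(
            nodf(IncidenceMatrix(perm, m.row_labels))
        )

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            nodf(IncidenceMatrix(np.array([[1]]), ["a"]))


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------


class TestTemperature:
    def test_perfectly_nested_is_zero(self, triangular4):
        assert temperature(triangular4) == 0.0

    def test_prefix_runs_any_fills_are_zero(self):
        m = gen_nested(12, 9, rho=1.0, seed=0)
        assert temperature(m) == 0.0

    def test_checkerboard_near_scale_maximum(self):
        v = (np.indices((8, 8)).sum(axis=0) % 2).astype(np.int8)
        m = IncidenceMatrix(v, [f"s{i}" for i in range(8)])
        assert temperature(m) > 50.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_summation_oracle(self, seed):
        m = random_matrix(5, 5, fill=0.5, seed=100 + seed)
        assert temperature(m) == pytest.approx(
            temperature_oracle(m.values), abs=1e-6
        )

    def test_isocline_area_matches_fill(self):
        from scipy.integrate import quad

        for fill in (0.2, 0.5, 0.8):
            a = _isocline_exponent(fill)
            area, _ = quad(lambda x: (1 - x**a) ** (1 / a), 0, 1)
            assert area == pytest.approx(fill, abs=1e-6)

    def test_degenerate_matrices_rejected(self):
        ones = IncidenceMatrix(np.ones((3, 3), dtype=int), list("abc"))
        with pytest.raises(ValueError, match="undefined"):
            temperature(ones)


# ---------------------------------------------------------------------------
# BR discrepancy
# ---------------------------------------------------------------------------


class TestBrDiscrepancy:
    def test_perfectly_packed_is_zero(self, triangular4):
        assert br_discrepancy(triangular4) == 0

    def test_single_misplaced_presence(self):
        # packed 2x2 (tied column totals stay in order): the second row's
        # single presence sits outside its leftmost-1 window
        m = IncidenceMatrix(np.array([[1, 0], [0, 1]]), ["a", "b"])
        assert br_discrepancy(m) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        m = random_matrix(6, 6, fill=0.4, seed=200 + seed)
        assert br_discrepancy(m) == br_oracle(m.values)


# ---------------------------------------------------------------------------
# null-model test
# ---------------------------------------------------------------------------


class TestNullTest:
    def test_perfect_nesting_significant_nodf(self, triangular4):
        big = gen_nested(10, 10, rho=1.0, seed=0, fill=0.4)
        res = nestedness_null_test(
            big, metric="NODF_total", n_iter=1000, seed=1
        )
        assert res.p_value <= 0.01
        assert res.observed > res.null_mean

    def test_fixed_equiprobable_preserves_row_sums(self):
        m = random_matrix(10, 8, fill=0.35, seed=7)
        rng = np.random.default_rng(0)
        for _ in range(20):
            draw = _draw_fixed_equiprobable(m.values, rng)
            assert np.array_equal(draw.sum(axis=1), m.row_sums)
            # column sums are free to vary

    def test_direction_consistency_on_nested_data(self):
        """Nested signal shows as T below and NODF above the null mean."""
        m = gen_nested(20, 12, rho=0.85, seed=3)
        res_t = nestedness_null_test(m, metric="T", n_iter=200, seed=5)
        res_n = nestedness_null_test(m, metric="NODF_total", n_iter=200, seed=5)
        assert res_t.observed < res_t.null_mean
        assert res_n.observed > res_n.null_mean

    def test_ci_brackets_null_mean_and_p_positive(self):
        m = random_matrix(8, 8, fill=0.4, seed=9)
        res = nestedness_null_test(m, metric="BR", n_iter=200, seed=2)
        lo, hi = res.null_ci95
        assert lo <= res.null_mean <= hi
        assert 0 < res.p_value <= 1

    def test_equiprobable_null_preserves_total_fill(self):
        m = random_matrix(6, 6, fill=0.5, seed=3)
        res = nestedness_null_test(
            m, metric="NODF_total", null_model="equiprobable-equiprobable",
            n_iter=150, seed=4,
        )
        assert np.isfinite(res.null_mean)

    def test_unknown_inputs_rejected(self, triangular4):
        with pytest.raises(ValueError, match="metric"):
            nestedness_null_test(triangular4, metric="WNODF", n_iter=100)
        with pytest.raises(ValueError, match="null model"):
            nestedness_null_test(triangular4, null_model="swap", n_iter=100)
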