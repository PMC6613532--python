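"""Nestedness metrics (NODF, matrix temperature T, BR discrepancy) and
Monte Carlo null-model tests.

A presence-absence matrix is nested when species-poor assemblages are
subsets of species-rich ones -- the signature of source-sink dynamics
and selective extinction/colonization.  Three classic metrics are
provided.  NODF (0-100, higher = more nested) averages, over every pair
of rows and of columns with strictly decreasing fill, the percentage of
the poorer line's presences shared with the richer one.  Matrix
temperature T (0-100, lower = more nested) measures how far
"unexpected" presences and absences sit from the isocline of perfect
order in the packed matrix.  BR discrepancy counts the presences that
would have to move to pack each row maximally given its total.

Significance comes from null ensembles; the default null keeps each
species' number of occupied bands fixed while letting it fall on any
band with equal probability (fixed rows, equiprobable columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .core_io import IncidenceMatrix

__all__ = [
    "NestednessResult",
    "nodf",
    "temperature",
    "br_discrepancy",
    "nestedness_null_test",
    "METRICS",
    "NULL_MODELS",
]

METRICS = ("NODF_total", "NODF_rows", "NODF_cols", "T", "BR")
NULL_MODELS = ("fixed-equiprobable", "fixed-fixed", "equiprobable-equiprobable")

# Maximal expected mean squared relative distance used to put matrix
# temperature on a 0-100 scale (the classic calculator's constant).
_U_MAX = 0.04145


@dataclass(frozen=True)
class NestednessResult:
    metric: str
    observed: float
    null_mean: float
    null_ci95: tuple[float, float]
    p_value: float
    n_iter: int
    null_model: str
    seed: int


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


def _nodf_axis_sum(values: np.ndarray) -> tuple[float, int]:
    """Sum of paired nestedness over ordered row pairs + pair count."""
    f = values.sum(axis=1).astype(float)
    n = values.shape[0]
    if n < 2:
        return 0.0, 0
    overlap = (values @ values.T).astype(float)
    fi = f[:, None]
    fj = f[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            (fi > fj) & (fj > 0), 100.0 * overlap / np.where(fj > 0, fj, 1), 0.0
        )
    total = float(contrib.sum())  # each unordered pair contributes once
    return total, n * (n - 1) // 2


def _nodf_values(values: np.ndarray) -> tuple[float, float, float]:
    rs, nr = _nodf_axis_sum(values)
    cs, nc = _nodf_axis_sum(values.T)
    rows = rs / nr if nr else float("nan")
    cols = cs / nc if nc else float("nan")
    total = (rs + cs) / (nr + nc) if (nr + nc) else float("nan")
    return total, rows, cols


def nodf(m: IncidenceMatrix) -> tuple[float, float, float]:
    """NODF (total, rows, cols) of a binary matrix.

    Invariant to row/column permutation: only marginal fills and pairwise
    overlaps enter, with equal-fill pairs contributing zero.
    """
    if m.shape[0] < 2 and m.shape[1] < 2:
        raise ValueError("NODF needs at least 2 rows or 2 columns")
    return _nodf_values(m.values)


# ---------------------------------------------------------------------------
# Matrix temperature
# ---------------------------------------------------------------------------


def _isocline_exponent(fill: float) -> float:
    """Exponent a of the superellipse isocline x**a + y**a = 1 (x right,
    y down, unit square) whose presence region {x**a + y**a <= 1} has
    area equal to the matrix fill."""

    def area(a: float) -> float:
        # Gamma(1+1/a)^2 / Gamma(1+2/a), the superellipse quadrant area
        return float(np.exp(2 * gammaln(1 + 1 / a) - gammaln(1 + 2 / a)))

    return brentq(lambda a: area(a) - fill, 1e-3, 1e3, xtol=1e-10)


def _diagonal_crossing(c: np.ndarray, a: float) -> np.ndarray:
    """For diagonals {(t, t+c)} through the unit square, the parameter t
    where the diagonal crosses the isocline, by vectorized bisection
    (the crossing function is strictly increasing in t)."""
    t_lo = np.maximum(0.0, -c)
    t_hi = np.minimum(1.0, 1.0 - c)
    for _ in range(60):
        t_mid = 0.5 * (t_lo + t_hi)
        g = t_mid**a + (t_mid + c) ** a - 1.0
        high = g > 0
        t_hi = np.where(high, t_mid, t_hi)
        t_lo = np.where(high, t_lo, t_mid)
    return 0.5 * (t_lo + t_hi)


def _row_disorder_cells(values: np.ndarray) -> np.ndarray:
    """Boolean mask of cells of a packed matrix that break row order.

    Scanning each row left to right, presences after the row's first
    absence and absences before the row's last presence break perfect
    order.  A perfectly nested packed matrix (every row a prefix run)
    has none, so its temperature is exactly zero.
    """
    n = values.shape[1]
    present = values > 0
    has_absence = ~present
    first_absence = np.where(
        has_absence.any(axis=1), has_absence.argmax(axis=1), n
    )
    rev_last = present[:, ::-1].argmax(axis=1)
    last_presence = np.where(present.any(axis=1), n - 1 - rev_last, -1)
    j = np.arange(n)[None, :]
    unexpected_presence = present & (j > first_absence[:, None])
    unexpected_absence = ~present & (j < last_presence[:, None])
    return unexpected_presence | unexpected_absence


def _temperature_values(values: np.ndarray) -> float:
    n_rows, n_cols = values.shape
    fill = values.mean()
    if fill in (0.0, 1.0):
        raise ValueError("temperature undefined for all-ones/all-zeros matrix")
    # score against the packed matrix
    packed = values[np.argsort(-values.sum(axis=1), kind="stable")]
    packed = packed[:, np.argsort(-packed.sum(axis=0), kind="stable")]
    mask = _row_disorder_cells(packed)
    if not mask.any():
        return 0.0
    i, jdx = np.nonzero(mask)
    x = (jdx + 0.5) / n_cols
    y = (i + 0.5) / n_rows
    c = y - x
    a = _isocline_exponent(float(fill))
    t_cross = _diagonal_crossing(c, a)
    # unexpected = out of row order AND on the wrong side of the
    # isocline: a presence in the absence region or vice versa
    present = packed[i, jdx] == 1
    wrong_side = np.where(present, x > t_cross, x < t_cross)
    d_rel = np.abs(x - t_cross) / (1.0 - np.abs(c))
    u = float((d_rel[wrong_side] ** 2).sum()) / (n_rows * n_cols)
    return float(min(100.0, 100.0 * u / _U_MAX))


def temperature(m: IncidenceMatrix) -> float:
    """Matrix temperature T in [0, 100]; 0 for perfectly nested packed
    matrices, large for checkerboard-like (anti-nested) matrices.

    Unexpected cells of the packed matrix -- cells that break row order
    (a presence after the row's first absence, an absence before its
    last presence) and lie on the wrong side of the matched-fill
    isocline of perfect order -- are scored by their squared relative
    distance from the isocline, measured along the cell's diagonal; the
    mean over all cells is scaled by the classic normalization constant.
    """
    return _temperature_values(m.values)


# ---------------------------------------------------------------------------
# BR discrepancy
# ---------------------------------------------------------------------------


def _br_values(values: np.ndarray) -> int:
    col_order = np.argsort(-values.sum(axis=0), kind="stable")
    v = values[:, col_order]
    r = v.sum(axis=1)
    n = v.shape[1]
    j = np.arange(n)[None, :]
    prefix = j < r[:, None]
    return int((prefix & (v == 0)).sum())


def br_discrepancy(m: IncidenceMatrix) -> int:
    """Discrepancy: with columns packed by decreasing totals, the number
    of absences among the leftmost r_i cells of each row -- presences
    that would have to shift left to reach maximal packing."""
    return _br_values(m.values)


# ---------------------------------------------------------------------------
# Null-model test
# ---------------------------------------------------------------------------


def _metric_fn(metric: str):
    if metric == "NODF_total":
        return lambda v: _nodf_values(v)[0]
    if metric == "NODF_rows":
        return lambda v: _nodf_values(v)[1]
    if metric == "NODF_cols":
        return lambda v: _nodf_values(v)[2]
    if metric == "T":
        return _temperature_values
    if metric == "BR":
        return lambda v: float(_br_values(v))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _draw_fixed_equiprobable(
    values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Redraw each row as a uniform random subset of columns of the same
    row total (species occurrence frequencies conserved; per-band
    richness free to vary equiprobably)."""
    r = values.sum(axis=1)
    u = rng.random(values.shape)
    ranks = u.argsort(axis=1).argsort(axis=1)
    return (ranks < r[:, None]).astype(np.int8)


def _draw_equiprobable(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flat = values.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(values.shape)


def nestedness_null_test(
    m: IncidenceMatrix,
    metric: str = "NODF_total",
    null_model: str = "fixed-equiprobable",
    n_iter: int = 1000,
    seed: int = 0,
) -> NestednessResult:
    """Monte Carlo significance of a nestedness metric.

    One-tailed in the nested direction: NODF high = nested, so
    p = P(null >= observed); T and BR low = nested, so
    p = P(null <= observed).  The add-one correction keeps p > 0.
    Reports the null mean and 2.5/97.5 percentile interval.
    """
    if null_model not in NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is very small; p-values will be coarse")
    fn = _metric_fn(metric)
    observed = fn(m.values)
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_iter)
    if null_model == "fixed-fixed":
        from .cooccurrence import sim9_swap_chain

        for k, null_m in enumerate(
            sim9_swap_chain(m, n_iter=n_iter, seed=seed)
        ):
            null_vals[k] = fn(null_m)
    else:
        draw = (
            _draw_fixed_equiprobable
            if null_model == "fixed-equiprobable"
            else _draw_equiprobable
        )
        for k in range(n_iter):
            null_vals[k] = fn(draw(m.values, rng))
    if metric.startswith("NODF"):
        exceed = null_vals >= observed - 1e-12
    else:  # T and BR: low = nested
        exceed = null_vals <= observed + 1e-12
    p = (1.0 + int(exceed.sum())) / (1.0 + n_iter)
    lo, hi = np.percentile(null_vals, [2.5, 97.5])
    return NestednessResult(
        metric=metric,
        observed=float(observed),
        null_mean=float(null_vals.mean()),
        null_ci95=(float(lo), float(hi)),
        p_value=float(p),
        n_iter=n_iter,
        null_model=null_model,
        seed=seed,
    )
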