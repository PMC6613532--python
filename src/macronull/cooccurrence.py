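"""Checkerboard C-score and the SIM9 fixed-fixed sequential-swap null.

For a species pair with row totals r_i, r_j sharing S sites, the
checkerboard unit CU = (r_i - S)(r_j - S) counts mutually exclusive site
pairs; the C-score is the mean CU over all species pairs.  Segregated
(competitively structured) communities show a C-score above the null
expectation, aggregated ones below it.

The SIM9 null preserves both row and column sums.  It is sampled by a
Markov chain that repeatedly picks a random pair of rows and pair of
columns and, when the 2x2 submatrix is a checkerboard, swaps its
diagonal.  Counting attempted (not only successful) swaps makes the
transition kernel symmetric, so the stationary distribution is uniform
over the fixed-fixed ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_io import IncidenceMatrix

__all__ = [
    "CooccurrenceResult",
    "c_score",
    "sim9_swap_chain",
    "cooccurrence_test",
]


@dataclass(frozen=True)
class CooccurrenceResult:
    observed_cscore: float
    null_mean: float
    null_variance: float
    ses: float
    p_lower: float
    p_upper: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int


def _c_score_values(values: np.ndarray) -> float:
    n_sp = values.shape[0]
    if n_sp < 2:
        raise ValueError("C-score needs at least 2 species")
    r = values.sum(axis=1).astype(float)
    shared = (values @ values.T).astype(float)
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(n_sp, k=1)
    return float(cu[iu].mean())


def c_score(m: IncidenceMatrix) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    return _c_score_values(m.values)


def _has_checkerboard(values: np.ndarray) -> bool:
    """Whether any 2x2 checkerboard submatrix exists (chain can move)."""
    shared = values @ values.T
    r = values.sum(axis=1)
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    np.fill_diagonal(cu, 0)
    return bool((cu > 0).any())


def sim9_swap_chain(
    m: IncidenceMatrix,
    n_iter: int = 5000,
    burn_in: int = 30_000,
    thin: int = 10,
    seed: int = 0,
) -> Iterator[np.ndarray]:
    """Stream ``n_iter`` matrices from the fixed-fixed null ensemble.

    After ``burn_in`` attempted swaps, one state is emitted every
    ``thin`` attempted swaps (rejected attempts count, so the chain
    length is deterministic).  Every emitted matrix has exactly the
    input's row and column sums.  Yields int8 arrays (copies).
    """
    values = m.values.astype(np.int8).copy()
    n_rows, n_cols = values.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("SIM9 needs at least a 2x2 matrix")
    if not _has_checkerboard(values):
        warnings.warn(
            "matrix has no swappable 2x2 checkerboard: the fixed-fixed "
            "ensemble collapses to the observed matrix"
        )
        for _ in range(n_iter):
            yield values.copy()
        return
    rng = np.random.default_rng(seed)
    total_attempts = burn_in + n_iter * thin
    chunk = 65536
    emitted = 0
    attempt = 0
    while emitted < n_iter:
        k = min(chunk, total_attempts - attempt)
        rows = rng.integers(0, n_rows, size=(k, 2))
        cols = rng.integers(0, n_cols, size=(k, 2))
        for t in range(k):
            i1, i2 = rows[t]
            j1, j2 = cols[t]
            if i1 != i2 and j1 != j2:
                a = values[i1, j1]
                if (
                    a == values[i2, j2]
                    and values[i1, j2] == values[i2, j1]
                    and a != values[i1, j2]
                ):
                    values[i1, j1] = values[i2, j2] = 1 - a
                    values[i1, j2] = values[i2, j1] = a
            attempt += 1
            if attempt > burn_in and (attempt - burn_in) % thin == 0:
                yield values.copy()
                emitted += 1
                if emitted >= n_iter:
                    return


def cooccurrence_test(
    m: IncidenceMatrix,
    n_iter: int = 5000,
    burn_in: int = 30_000,
    thin: int = 10,
    seed: int = 0,
) -> CooccurrenceResult:
    """C-score against the SIM9 fixed-fixed null.

    Reports the standardized effect size (observed minus null mean in
    null standard deviations) and both tail probabilities with the
    add-one correction: ``p_upper`` small = segregation (high C-score),
    ``p_lower`` small = aggregation.
    """
    observed = _c_score_values(m.values)
    null_vals = np.fromiter(
        (_c_score_values(v) for v in sim9_swap_chain(m, n_iter, burn_in, thin, seed)),
        dtype=float,
        count=n_iter,
    )
    mean = float(null_vals.mean())
    var = float(null_vals.var(ddof=1)) if n_iter > 1 else 0.0
    ses = (observed - mean) / np.sqrt(var) if var > 0 else float("nan")
    p_upper = (1.0 + int((null_vals >= observed - 1e-12).sum())) / (1.0 + n_iter)
    p_lower = (1.0 + int((null_vals <= observed + 1e-12).sum())) / (1.0 + n_iter)
    return CooccurrenceResult(
        observed_cscore=float(observed),
        null_mean=mean,
        null_variance=var,
        ses=float(ses),
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
    )
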