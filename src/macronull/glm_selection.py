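"""Poisson GLMs of per-band richness on environmental predictors, with
AICc-based single-predictor ranking and bidirectional stepwise selection.

Counts of species per latitudinal band are modelled with a log link,
y_k ~ Poisson(exp(b0 + x_k . b)).  Predictors are z-score standardized
before fitting by default, so coefficients are comparable across
variables with wildly different units (degrees Celsius to square
kilometres).  Model comparison uses the small-sample Akaike criterion
AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); fit quality is summarized by both
the McFadden and Nagelkerke likelihood pseudo-R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "aicc",
    "pseudo_r2",
    "fit_poisson",
    "rank_single_predictors",
    "stepwise_aicc",
]


@dataclass(frozen=True)
class ModelFit:
    predictors: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    pseudo_r2_mcfadden: float
    pseudo_r2_nagelkerke: float
    conf_int: pd.DataFrame = field(repr=False, default=None)  # type: ignore
    delta_aicc: float = 0.0

    def with_delta(self, best_aicc: float) -> "ModelFit":
        from dataclasses import replace

        return replace(self, delta_aicc=self.aicc - best_aicc)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def pseudo_r2(loglik: float, loglik_null: float, n: int) -> tuple[float, float]:
    """(McFadden, Nagelkerke) likelihood pseudo-R2 of a fit against the
    intercept-only model."""
    mcfadden = 1.0 - loglik / loglik_null
    num = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik))
    den = 1.0 - np.exp((2.0 / n) * loglik_null)
    nagelkerke = num / den if den != 0 else float("nan")
    return float(mcfadden), float(nagelkerke)


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0)
    if (sd == 0).any():
        zero = list(X.columns[sd == 0])
        raise ValueError(f"constant predictor column(s): {zero}")
    return (X - X.mean()) / sd


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("richness must be non-negative integer counts")
    return y.astype(float)


def fit_poisson(
    y,
    X: pd.DataFrame | None = None,
    standardize: bool = True,
    loglik_null: float | None = None,
) -> ModelFit:
    """Maximum-likelihood Poisson log-link fit via IRLS.

    The reported log-likelihood is the full Poisson likelihood including
    the log(y!) term.  ``X`` may be None or empty for the intercept-only
    model.  ``loglik_null`` lets callers share the null fit when
    computing pseudo-R2 across many models.
    """
    y = _check_counts(y)
    n = len(y)
    if X is None or X.shape[1] == 0:
        names: tuple[str, ...] = ()
        design = pd.DataFrame(index=pd.RangeIndex(n))
    else:
        if len(X) != n:
            raise ValueError("y and X length mismatch")
        names = tuple(X.columns)
        design = _standardize(X) if standardize else X.copy()
        cond = np.linalg.cond(np.column_stack([np.ones(n), design.to_numpy()]))
        if cond > 1e8:
            warnings.warn(
                f"design matrix is ill-conditioned (cond={cond:.3g}); "
                "coefficients may be unstable"
            )
    k = len(names) + 1
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 (n={n}, k={k})")
    design = sm.add_constant(design.reset_index(drop=True), has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge")
    if loglik_null is None:
        if names:
            null_fit = fit_poisson(y, None)
            loglik_null = null_fit.loglik
        else:
            loglik_null = float(res.llf)
    mcf, nag = pseudo_r2(float(res.llf), loglik_null, n)
    return ModelFit(
        predictors=names,
        coefficients=res.params.rename({"const": "intercept"}),
        std_errors=res.bse.rename({"const": "intercept"}),
        z_values=res.tvalues.rename({"const": "intercept"}),
        p_values=res.pvalues.rename({"const": "intercept"}),
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        pseudo_r2_mcfadden=mcf,
        pseudo_r2_nagelkerke=nag,
        conf_int=res.conf_int().rename(index={"const": "intercept"}),
    )


def rank_single_predictors(
    y, table: pd.DataFrame, standardize: bool = True
) -> list[ModelFit]:
    """One single-predictor model per covariate column, sorted by AICc
    (ties broken by column order); delta-AICc is relative to the best."""
    null_ll = fit_poisson(y, None).loglik
    fits = [
        fit_poisson(y, table[[c]], standardize=standardize, loglik_null=null_ll)
        for c in table.columns
    ]
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    return [f.with_delta(best) for f in fits]


def stepwise_aicc(
    y,
    table: pd.DataFrame,
    scope: list[str] | None = None,
    standardize: bool = True,
) -> ModelFit:
    """Bidirectional stepwise AICc minimization starting from the full
    candidate model.

    At each step every single-predictor drop and add is evaluated; the
    move with the largest AICc improvement is taken, until no move
    improves.  Candidates are scanned in sorted name order, so the result
    does not depend on the column order of ``table``.
    """
    scope = sorted(scope if scope is not None else list(table.columns))
    unknown = [c for c in scope if c not in table.columns]
    if unknown:
        raise ValueError(f"scope names not in table: {unknown}")
    null_ll = fit_poisson(y, None).loglik

    def fit_set(names: tuple[str, ...]) -> ModelFit:
        X = table[list(names)] if names else None
        return fit_poisson(y, X, standardize=standardize, loglik_null=null_ll)

    current = tuple(scope)
    cache: dict[tuple[str, ...], ModelFit] = {}

    def fit_cached(names: tuple[str, ...]) -> ModelFit:
        if names not in cache:
            cache[names] = fit_set(names)
        return cache[names]

    best_fit = fit_cached(current)
    while True:
        moves: list[tuple[str, ...]] = []
        for c in current:  # drops
            moves.append(tuple(x for x in current if x != c))
        for c in scope:  # adds
            if c not in current:
                moves.append(tuple(sorted(current + (c,))))
        improved = None
        for cand in moves:
            f = fit_cached(cand)
            if f.aicc < best_fit.aicc - 1e-9:
                if improved is None or f.aicc < improved.aicc:
                    improved = f
        if improved is None:
            return best_fit
        best_fit = improved
        current = improved.predictors
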