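"""Driver selection: OLS model search by small-sample AICc.

Which litter traits (or microbial taxa) drive priming is decided by
fitting ordinary-least-squares models for every candidate predictor
subset (or by stepwise search for larger panels) and retaining the model
with the lowest corrected Akaike information criterion,

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

where k counts the regression coefficients, the intercept and the
residual variance.  Exhaustive search removes path-dependence and doubles
as the oracle for the stepwise strategies on small candidate sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

STRATEGIES = ("exhaustive", "forward", "backward", "bidirectional")

#: Candidate counts up to this size are searched exhaustively by default.
EXHAUSTIVE_LIMIT = 12


@dataclass(frozen=True)
class RegressionModel:
    """A fitted OLS model and its selection statistics."""

    response: str
    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    rss: float
    r_squared: float
    p_value: float            # overall F-test
    aicc: float
    n: int
    k: int                    # parameters: coefficients + intercept + variance
    coef_se: tuple[float, ...] = ()

    def coefficient(self, name: str) -> float:
        return self.coefficients[self.predictors.index(name)]

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory (1−alpha) confidence interval for one coefficient."""
        from scipy import stats

        i = self.predictors.index(name)
        df = self.n - (len(self.predictors) + 1)
        t = stats.t.ppf(1 - alpha / 2, df)
        return (
            self.coefficients[i] - t * self.coef_se[i],
            self.coefficients[i] + t * self.coef_se[i],
        )


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample AIC: n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1).

    ``k`` is the total parameter count (coefficients + intercept +
    residual variance).  Returns +inf when n − k − 1 ≤ 0 (the correction
    blows up) and −inf for an exactly zero RSS.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if n - k - 1 <= 0:
        return math.inf
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_ols(
    y: Sequence[float],
    X: pd.DataFrame | None,
    response: str = "y",
    standardize: bool = False,
) -> RegressionModel:
    """OLS fit with intercept; X=None or empty fits the intercept-only model.

    ``standardize`` z-scores the predictors first (coefficients then per
    SD of predictor).  A singular design raises, naming the columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=range(n))
    if len(X) != n:
        raise ValidationError("y and X have different lengths")
    names = tuple(X.columns)
    if n <= len(names) + 1:
        raise ValidationError(f"need n > k: n={n}, predictors={len(names)}")
    Xv = X.astype(float)
    if standardize and names:
        Xv = (Xv - Xv.mean()) / Xv.std(ddof=1)
    design = sm.add_constant(Xv, has_constant="add")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        raise ValidationError(
            f"singular design matrix; check for collinear columns among {list(names)}"
        )
    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    k = len(names) + 2  # coefficients + intercept + residual variance
    coefs = tuple(float(fit.params[c]) for c in names)
    ses = tuple(float(fit.bse[c]) for c in names)
    r2 = float(fit.rsquared) if names else 0.0
    p = float(fit.f_pvalue) if names else math.nan
    return RegressionModel(
        response=response,
        predictors=names,
        coefficients=coefs,
        intercept=float(fit.params["const"]),
        rss=rss,
        r_squared=r2,
        p_value=p,
        aicc=aicc(rss, n, k),
        n=n,
        k=k,
        coef_se=ses,
    )


def _fit_subset(y, X, subset, response, standardize):
    return fit_ols(y, X[list(subset)], response=response, standardize=standardize)


def _better(a: RegressionModel, b: RegressionModel) -> bool:
    """a strictly better than b: lower AICc, ties to fewer predictors then names."""
    ka, kb = (a.aicc, len(a.predictors), a.predictors), (
        b.aicc,
        len(b.predictors),
        b.predictors,
    )
    return ka < kb


def select_model(
    y: Sequence[float],
    candidates: pd.DataFrame,
    strategy: str = "exhaustive",
    response: str = "y",
    standardize: bool = False,
) -> RegressionModel:
    """Lowest-AICc model over subsets of the candidate predictors.

    ``exhaustive`` enumerates every subset (candidate count capped at 20);
    ``forward``/``backward``/``bidirectional`` are stepwise searches that
    add/drop one predictor at a time while AICc improves.  Ties break to
    fewer predictors, then lexicographic predictor names.  With no
    candidates the intercept-only model is returned.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"strategy must be one of {STRATEGIES}")
    names = sorted(candidates.columns)
    if not names:
        return fit_ols(y, None, response=response)
    if strategy == "exhaustive":
        if len(names) > 20:
            raise ValidationError("exhaustive search capped at 20 candidates")
        best = fit_ols(y, None, response=response)
        for size in range(1, len(names) + 1):
            for subset in itertools.combinations(names, size):
                try:
                    m = _fit_subset(y, candidates, subset, response, standardize)
                except ValidationError:
                    continue  # unidentifiable subset (singular or n <= k)
                if _better(m, best):
                    best = m
        return best

    current: tuple[str, ...] = tuple(names) if strategy == "backward" else ()
    best = _fit_subset(y, candidates, current, response, standardize)
    allow_add = strategy in ("forward", "bidirectional")
    allow_drop = strategy in ("backward", "bidirectional")
    while True:
        moves: list[RegressionModel] = []
        if allow_add:
            for name in names:
                if name not in best.predictors:
                    try:
                        moves.append(
                            _fit_subset(
                                y, candidates,
                                tuple(sorted(best.predictors + (name,))),
                                response, standardize,
                            )
                        )
                    except ValidationError:
                        continue
        if allow_drop:
            for name in best.predictors:
                moves.append(
                    _fit_subset(
                        y, candidates,
                        tuple(p for p in best.predictors if p != name),
                        response, standardize,
                    )
                )
        improved = False
        for m in moves:
            if _better(m, best):
                best, improved = m, True
        if not improved:
            return best


def models_to_frame(models: Sequence[RegressionModel]) -> pd.DataFrame:
    """Tidy table of retained models (one row per model)."""
    return pd.DataFrame(
        [
            {
                "response": m.response,
                "predictors": "+".join(m.predictors) if m.predictors else "(intercept)",
                "coefficients": ";".join(f"{c:.6g}" for c in m.coefficients),
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "p_value": m.p_value,
                "aicc": m.aicc,
                "n": m.n,
                "k": m.k,
            }
            for m in models
        ]
    )
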