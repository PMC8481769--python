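"""Community statistics: alpha diversity, Bray–Curtis, aggregation, Spearman screen.

Alpha-diversity metrics (observed richness and bias-corrected Chao1) are
delegated to scikit-bio, Bray–Curtis dissimilarity to scipy, and the
Spearman correlation screen to scipy.stats — each wrapped with the
validation and tie/flag semantics this pipeline needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import sobs as _skbio_sobs

from .errors import ValidationError


@dataclass(frozen=True)
class AbundanceTable:
    """Sample × taxon abundance matrix with per-taxon level labels.

    ``data`` is samples × taxa; ``levels`` labels each taxon with its
    taxonomic rank (e.g. ``phylum`` for bacteria, ``class`` for fungi).
    ``relative`` states whether rows are proportions (sum to 1) or counts.
    """

    data: pd.DataFrame
    levels: pd.Series
    relative: bool

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("abundance table has negative entries")
        if set(self.levels.index) != set(self.data.columns):
            raise ValidationError("level labels do not match taxon columns")
        if self.relative:
            sums = self.data.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = sums.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValidationError(f"relative rows do not sum to 1: {bad}")

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "count") -> "AbundanceTable":
        """Build from a long table: sample_id, taxon_id, level, <value_col>."""
        required = {"sample_id", "taxon_id", "level", value_col}
        if not required.issubset(df.columns):
            raise ValidationError(f"long abundance table needs columns {sorted(required)}")
        wide = df.pivot_table(
            index="sample_id", columns="taxon_id", values=value_col,
            aggfunc="sum", fill_value=0.0,
        )
        levels = df.drop_duplicates("taxon_id").set_index("taxon_id")["level"]
        relative = value_col != "count" and bool(
            np.allclose(wide.sum(axis=1), 1.0, atol=1e-6)
        )
        return cls(wide, levels.reindex(wide.columns), relative)

    def to_relative(self) -> "AbundanceTable":
        if self.relative:
            return self
        sums = self.data.sum(axis=1)
        if (sums == 0).any():
            raise ValidationError("cannot normalize a sample with zero total count")
        return AbundanceTable(self.data.div(sums, axis=0), self.levels, relative=True)


def observed_species(count_row: Sequence[float]) -> int:
    """Number of taxa present (count > 0) in one sample's count vector."""
    arr = np.asarray(count_row, dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("observed_species needs counts, not relative abundances")
    return int(_skbio_sobs(arr.astype(int)))


def chao1(count_row: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1)/(2(F2+1)).

    F1 and F2 are the numbers of singleton and doubleton taxa; counts
    must be integers.
    """
    arr = np.asarray(count_row, dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("chao1 requires integer counts")
    return float(_skbio_chao1(arr.astype(int), bias_corrected=True))


def bray_curtis(row_a: Sequence[float], row_b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity 1 − 2Σmin(a,b)/Σ(a+b), in [0, 1]."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rows must cover the same taxon set")
    if a.sum() == 0 and b.sum() == 0:
        raise ValidationError("Bray–Curtis undefined for two all-zero rows")
    return float(braycurtis(a, b))


def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between all samples."""
    ids = table.data.index
    n = len(ids)
    out = np.zeros((n, n))
    vals = table.data.values
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def aggregate_taxa(
    table: AbundanceTable,
    level: str,
    display_threshold: float = 0.01,
    treatment_of: pd.Series | None = None,
    other_label: str = "other",
) -> AbundanceTable:
    """Keep taxa of one rank; pool rare taxa into an ``other`` bucket.

    A taxon is kept when its treatment-mean relative abundance exceeds
    ``display_threshold`` in at least one treatment (with no treatment
    mapping, the overall mean is used).  Pooling conserves total
    abundance exactly: the pooled mass appears under ``other_label``.
    """
    if level not in set(table.levels):
        raise ValidationError(f"unknown taxonomy level {level!r}")
    rel = table.to_relative()
    cols = [c for c in rel.data.columns if table.levels[c] == level]
    sub = rel.data[cols]
    # renormalize within the level so the filter applies to within-level shares
    totals = sub.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError(f"some samples have no {level}-level abundance")
    shares = sub.div(totals, axis=0)
    if treatment_of is not None:
        means = shares.groupby(treatment_of.reindex(shares.index)).mean()
        keep = [c for c in cols if (means[c] > display_threshold).any()]
    else:
        keep = [c for c in cols if shares[c].mean() > display_threshold]
    pooled = shares.drop(columns=keep).sum(axis=1)
    out = shares[keep].copy()
    if display_threshold > 0 or len(keep) < len(cols):
        out[other_label] = pooled
    levels = pd.Series(level, index=out.columns)
    return AbundanceTable(out, levels, relative=True)


@dataclass(frozen=True)
class CorrelationScreen:
    """One response × predictor Spearman cell of the correlation screen."""

    response: str
    predictor: str
    rho: float
    p_value: float
    n: int
    flag: str = ""


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool = False, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Two-sided p via the t approximation; ``exact=True`` switches to a
    permutation p-value (for very small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan, math.nan
    if exact:
        res = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=np.random.default_rng(seed),
        )
        rho = float(stats.spearmanr(x, y).statistic)
        return rho, float(res.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_screen(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    exact: bool = False,
) -> list[CorrelationScreen]:
    """Spearman rho/p for every response × predictor pair across jars.

    Rows are matched on the shared index (jar ids); incomplete pairs are
    dropped per cell.  Constant predictors yield a flagged row with
    undefined rho.
    """
    rows: list[CorrelationScreen] = []
    for resp in responses.columns:
        for pred in predictors.columns:
            joined = pd.concat(
                [responses[resp], predictors[pred]], axis=1, join="inner"
            ).dropna()
            n = len(joined)
            if n < 3:
                rows.append(CorrelationScreen(resp, pred, math.nan, math.nan, n, "too_few_pairs"))
                continue
            y, x = joined.iloc[:, 0].values, joined.iloc[:, 1].values
            if np.unique(x).size == 1:
                rows.append(CorrelationScreen(resp, pred, math.nan, math.nan, n, "constant_predictor"))
                continue
            rho, p = spearman(x, y, exact=exact)
            rows.append(CorrelationScreen(resp, pred, rho, p, n))
    return rows


def screen_to_frame(rows: Sequence[CorrelationScreen]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "response": r.response,
                "predictor": r.predictor,
                "rho": r.rho,
                "p_value": r.p_value,
                "n": r.n,
                "flag": r.flag,
            }
            for r in rows
        ]
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the screen reports raw p by default)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
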