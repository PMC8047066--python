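"""Nonparametric screening of features against the binary indexes.

Each of the 19 features is compared between the two groups defined by
each binary index with a two-sided Mann-Whitney U test, yielding a
19 x 8 significance matrix.  Small samples use tie-aware exact
enumeration of all group labelings; larger samples use the normal
approximation with tie and continuity corrections.  Raw p-values are
starred (* p<=0.05, ** p<=0.01, *** p<=0.001) without multiplicity
correction; a Benjamini-Hochberg adjusted column is emitted alongside
for reference but does not drive the stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES
from .indexes import INDEX_NAMES

#: Largest number of labelings the exact path will enumerate.
EXACT_ENUMERATION_CAP = 200_000


def stars_for(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class MWResult:
    """One Mann-Whitney comparison: U of group A, two-sided p, sizes."""

    U: float
    p_two_sided: float
    n0: int
    n1: int

    @property
    def stars(self) -> str:
        return stars_for(self.p_two_sided)


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _exact_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every assignment of n_a pooled
    observations to group A, computing U from midranks each time."""
    ranks = sst.rankdata(pooled)
    n = len(pooled)
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        u = _u_from_ranks(ranks[list(idx)], n_a)
        hits += abs(u - mu) >= dev - 1e-12
        total += 1
    return hits / total


def mann_whitney(group_a, group_b, mode: str = "auto") -> MWResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``mode='auto'`` enumerates exactly when the smaller group has at
    most 8 observations and the number of labelings is tractable
    (<= 2e5); otherwise the normal approximation with midranks, tie
    correction and continuity correction is used.  Constant pooled data
    gives p = 1 by symmetry.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    u_a = _u_from_ranks(ranks[: a.size], a.size)

    if np.ptp(pooled) == 0.0:
        return MWResult(u_a, 1.0, a.size, b.size)

    small = min(a.size, b.size)
    use_exact = mode == "exact" or (
        mode == "auto"
        and small <= 8
        and comb(a.size + b.size, small) <= EXACT_ENUMERATION_CAP
    )
    if use_exact:
        p = _exact_p(pooled, a.size, u_a)
    else:
        p = float(
            sst.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return MWResult(u_a, min(p, 1.0), a.size, b.size)


def significance_matrix(
    cohort: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    indexes: tuple[str, ...] = INDEX_NAMES,
    mode: str = "auto",
) -> pd.DataFrame:
    """Tidy feature x index screening table.

    For every (feature, index) pair, rows with a missing feature value
    are dropped and the remaining values are split by the binary index.
    Columns: feature, index, U, n0, n1, p, stars, p_bh, testable.  An
    index with a single class in the (non-missing) rows is flagged
    untestable (p = NaN).
    """
    records = []
    for idx in indexes:
        labels = cohort[idx].to_numpy()
        for feat in features:
            vals = cohort[feat].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            v, l = vals[ok], labels[ok]
            if len(np.unique(l)) < 2:
                records.append(
                    dict(feature=feat, index=idx, U=np.nan, n0=int((l == 0).sum()),
                         n1=int((l == 1).sum()), p=np.nan, stars="", testable=False)
                )
                continue
            res = mann_whitney(v[l == 0], v[l == 1], mode=mode)
            records.append(
                dict(feature=feat, index=idx, U=res.U, n0=res.n0, n1=res.n1,
                     p=res.p_two_sided, stars=res.stars, testable=True)
            )
    out = pd.DataFrame(records)
    out["p_bh"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def format_significance_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy screening table into the printed layout: one row
    per feature, one column per index, cells like ``0.004**`` with p
    floored at 0.001."""

    def cell(row):
        if not row["testable"]:
            return "n/a"
        p = max(row["p"], 0.001)
        return f"{p:.3f}{row['stars']}"

    tidy = tidy.assign(cell=tidy.apply(cell, axis=1))
    wide = tidy.pivot(index="feature", columns="index", values="cell")
    return wide.reindex(index=pd.unique(tidy["feature"]), columns=pd.unique(tidy["index"]))
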