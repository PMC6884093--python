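"""Inferential surface: group comparisons, correlations and FDR control.

Each analysis family (one per reported table/grid) is adjusted separately
with Benjamini-Hochberg; significance is declared at adjusted p < 0.05.
Severity associations use Spearman only (the severity scales are
right-skewed); cross-compartment cluster correlations use Pearson.
Pairwise-complete observations are used throughout and the per-pair N is
reported, since missingness differs cell by cell.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    family: str
    var1: str
    var2: str
    method: str                   # pearson | spearman | t-test | anova
    estimate: float
    n: int
    p: float
    p_adj: float | None = None
    undefined: bool = False


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family, r.var1, r.var2, r.method, r.estimate, r.n, r.p, r.p_adj,
          r.undefined) for r in results],
        columns=["family", "var1", "var2", "method", "estimate", "n", "p",
                 "p_adj", "undefined"])


# ----------------------------------------------------------------------
def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_families(results: list[AssociationResult]) -> list[AssociationResult]:
    """Fill adjusted p within each family; undefined results are excluded."""
    out = list(results)
    for fam in sorted({r.family for r in results}):
        idx = [i for i, r in enumerate(out)
               if r.family == fam and not r.undefined and np.isfinite(r.p)]
        skipped = [r for r in out if r.family == fam and r.undefined]
        for r in skipped:
            log.warning("family %s: pair (%s, %s) undefined (N < 3), "
                        "excluded from FDR", fam, r.var1, r.var2)
        if idx:
            adj = fdr_adjust([out[i].p for i in idx])
            for i, a in zip(idx, adj):
                out[i] = replace(out[i], p_adj=float(a))
    return out


# ----------------------------------------------------------------------
@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho (average ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    perms = _perm_matrix(len(x))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    rho_perm = (ryc[perms] @ rxc) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def _correlate_pair(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        if len(x) <= 9:
            return _spearman_exact(x, y)
        r, p = stats.spearmanr(x, y)  # t approximation, average ranks
        return float(r), float(p)
    raise AssociationError(f"unknown method {method!r}")


def correlate(x: pd.DataFrame, y: pd.DataFrame, method: str, family: str,
              adjust: bool = True) -> list[AssociationResult]:
    """Correlate every column of ``x`` with every column of ``y``.

    Estimates use pairwise-complete rows; N is that row count; pairs with
    N < 3 are flagged undefined and excluded from the FDR family.
    """
    if method not in ("pearson", "spearman"):
        raise AssociationError(f"unknown method {method!r}")
    xa, ya = x.align(y, join="inner", axis=0)
    results = []
    for cx in x.columns:
        for cy in y.columns:
            pair = pd.concat([xa[cx], ya[cy]], axis=1).dropna()
            n = len(pair)
            if n < 3:
                results.append(AssociationResult(family, str(cx), str(cy), method,
                                                 np.nan, n, np.nan, undefined=True))
                continue
            r, p = _correlate_pair(pair.iloc[:, 0].to_numpy(dtype=float),
                                   pair.iloc[:, 1].to_numpy(dtype=float), method)
            results.append(AssociationResult(family, str(cx), str(cy), method,
                                             r, n, p))
    return adjust_families(results) if adjust else results


# ----------------------------------------------------------------------
def compare_groups(values: pd.DataFrame, grouping: pd.Series, design: str,
                   family: str, adjust: bool = True) -> list[AssociationResult]:
    """Compare each column of ``values`` across groups.

    ``design='anova'`` runs the diagnosis F-test from the one-way linear
    model (used for marker residuals); ``design='ttest'`` runs the
    equal-variance unpaired t-test (used for two-group cluster scores).
    The estimate is the second-minus-first group mean difference when
    exactly two groups are present.
    """
    if design not in ("anova", "ttest"):
        raise AssociationError(f"unknown design {design!r}")
    g = grouping.loc[values.index]
    levels = sorted(g.dropna().unique().astype(str))
    if len(levels) < 2:
        raise AssociationError("need at least 2 groups")
    results = []
    for c in values.columns:
        col = values[c]
        samples, empty = [], []
        for lvl in levels:
            s = col[g.astype(str) == lvl].dropna().to_numpy(dtype=float)
            if len(s) < 2:
                empty.append(lvl)
            samples.append(s)
        if empty:
            raise AssociationError(
                f"variable {c!r}: groups with <2 non-missing values: {empty}")
        n = int(sum(len(s) for s in samples))
        est = float(samples[1].mean() - samples[0].mean()) if len(levels) == 2 else np.nan
        if design == "ttest":
            if len(levels) != 2:
                raise AssociationError("t-test requires exactly 2 groups")
            t, p = stats.ttest_ind(samples[1], samples[0], equal_var=True)
        else:
            f, p = stats.f_oneway(*samples)
        label = " vs ".join(levels)
        results.append(AssociationResult(
            family, str(c), label, "t-test" if design == "ttest" else "anova",
            est, n, float(p)))
    return adjust_families(results) if adjust else results
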