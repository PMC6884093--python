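"""Per-biomarker covariate adjustment by linear-model residualisation.

For each analyte the Z score is modelled as

    Z ~ diagnosis + race + age + sex + covariate-by-covariate interactions

and a covariate term is retained iff its type-II ANOVA p-value (model
comparison respecting marginality, full-model MSE denominator) is below
the selection alpha.  The reduced model — always keeping diagnosis — is
refit, and the fitted covariate effects, and only those, are subtracted:

    residual = Z - (fitted covariate terms)
             = intercept + fitted diagnosis term + OLS error   (identity)

so the diagnosis signal survives adjustment by construction.  The design
engine is plain numpy least squares: the pipeline refits 16 analytes over
hundreds of simulated cohorts in calibration runs, so fits must be cheap.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COVARIATES = ("age", "sex", "race")


class AdjustmentError(ValueError):
    pass


class RankDeficiencyError(AdjustmentError):
    def __init__(self, analyte: str, term: str):
        self.analyte, self.term = analyte, term
        super().__init__(f"rank-deficient design for analyte {analyte!r} at term {term!r}")


# ----------------------------------------------------------------------
@dataclass
class Design:
    """Encoded model blocks shared by every analyte fit."""

    blocks: dict[str, pd.DataFrame]            # term -> columns (float, NaN ok)
    parents: dict[str, tuple[str, ...]]        # interaction -> its main effects
    candidate_terms: list[str]                 # selection candidates, in order
    index: pd.Index
    _arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def array(self, term: str) -> np.ndarray:
        arr = self._arrays.get(term)
        if arr is None:
            arr = self._arrays[term] = self.blocks[term].to_numpy(dtype=float)
        return arr

    def term_array(self, term: str, columns: list[str]) -> np.ndarray:
        full = self.array(term)
        if list(self.blocks[term].columns) == columns:
            return full
        idx = [list(self.blocks[term].columns).index(c) for c in columns]
        return full[:, idx]


def _encode_categorical(col: pd.Series, name: str, min_category: int) -> pd.DataFrame:
    """Reference-coded dummies; reference = largest level, rare levels pooled."""
    s = col.astype(object)
    counts = s.dropna().value_counts()
    rare = [lvl for lvl, n in counts.items() if n < min_category]
    if rare and len(counts) > 2:
        s = s.where(~s.isin(rare), other="Other")
        counts = s.dropna().value_counts()
    ref = counts.idxmax() if len(counts) else None
    out = {}
    for lvl in sorted(counts.index.astype(str)):
        if lvl == str(ref):
            continue
        vals = (s.astype(str) == lvl).astype(float)
        vals[s.isna()] = np.nan
        out[f"{name}[{lvl}]"] = vals
    return pd.DataFrame(out, index=col.index)


def encode_design(covariates: pd.DataFrame, diagnosis: pd.Series,
                  covariate_names=DEFAULT_COVARIATES, interactions: bool = True,
                  min_category: int = 5) -> Design:
    """Build intercept, diagnosis and candidate covariate blocks."""
    idx = diagnosis.index
    blocks: dict[str, pd.DataFrame] = {
        "Intercept": pd.DataFrame({"Intercept": np.ones(len(idx))}, index=idx)}
    d = diagnosis.astype(object)
    counts = d.dropna().value_counts()
    ref = "HD" if "HD" in counts.index else (counts.idxmax() if len(counts) else None)
    dcols = {}
    for lvl in sorted(counts.index.astype(str)):
        if lvl == str(ref):
            continue
        vals = (d.astype(str) == lvl).astype(float)
        vals[d.isna()] = np.nan
        dcols[f"diagnosis[{lvl}]"] = vals
    blocks["diagnosis"] = pd.DataFrame(dcols, index=idx)

    mains = [c for c in covariate_names if c in covariates.columns]
    for name in mains:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            centered = col.astype(float) - col.astype(float).mean()
            blocks[name] = pd.DataFrame({name: centered}, index=idx)
        else:
            blocks[name] = _encode_categorical(col, name, min_category)
    parents: dict[str, tuple[str, ...]] = {}
    candidates = list(mains)
    if interactions:
        for a, b in itertools.combinations(mains, 2):
            cols = {}
            for ca in blocks[a].columns:
                for cb in blocks[b].columns:
                    cols[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]
            term = f"{a}:{b}"
            blocks[term] = pd.DataFrame(cols, index=idx)
            parents[term] = (a, b)
            candidates.append(term)
    return Design(blocks, parents, candidates, idx)


# ----------------------------------------------------------------------
@dataclass
class AnalyteAdjustment:
    analyte: str
    candidate_pvalues: dict[str, float]
    selected: list[str]
    coef: dict[str, np.ndarray]          # term -> coefficients (reduced model)
    columns: dict[str, list[str]]        # term -> column labels kept in the fit
    dropped: list[str]                   # terms dropped (constant/empty on rows)
    n_used: int
    rows: np.ndarray                     # boolean mask of rows used in the fit


@dataclass
class AdjustmentModel:
    design: Design
    analytes: dict[str, AnalyteAdjustment] = field(default_factory=dict)
    alpha: float = 0.05

    def selection_frame(self) -> pd.DataFrame:
        rows = []
        for a, e in self.analytes.items():
            for t, p in e.candidate_pvalues.items():
                rows.append((a, t, p, t in e.selected))
        return pd.DataFrame(rows, columns=["analyte", "term", "p", "selected"])


@dataclass
class ResidualMatrix:
    """Subjects x analytes covariate-adjusted Z-score residuals."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "ResidualMatrix":
        return ResidualMatrix(self.data.copy(), dict(self.provenance))


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def _fit_one(design: Design, analyte: str, z: np.ndarray, alpha: float
             ) -> AnalyteAdjustment:
    base_terms = ["Intercept", "diagnosis"]
    cand = list(design.candidate_terms)
    finite = np.isfinite(z)
    for t in base_terms + cand:
        arr = design.array(t)
        if arr.shape[1]:
            finite &= np.isfinite(arr).all(axis=1)
    rows = finite
    n = int(rows.sum())

    # drop columns that are constant on the analysed rows
    cols: dict[str, list[str]] = {}
    dropped: list[str] = []
    for t in base_terms + cand:
        blk = design.blocks[t]
        arr = design.array(t)[rows]
        keep = [c for k, c in enumerate(blk.columns)
                if t == "Intercept" or np.ptp(arr[:, k]) > 0]
        cols[t] = keep
        if t not in base_terms and not keep:
            dropped.append(t)
    cand = [t for t in cand if t not in dropped]

    def mat(terms):
        parts = []
        for t in terms:
            if cols[t]:
                parts.append(design.term_array(t, cols[t])[rows])
        return np.hstack(parts) if parts else np.ones((n, 0))

    full_terms = base_terms + cand
    X_full = mat(full_terms)
    p_full = X_full.shape[1]
    if n <= p_full + 5:
        raise AdjustmentError(
            f"analyte {analyte!r}: {n} complete cases for {p_full} parameters")
    if np.linalg.matrix_rank(X_full) < p_full:
        # walk the terms to name the offender
        rank = 0
        acc: list[str] = []
        for t in full_terms:
            acc.append(t)
            Xa = mat(acc)
            r_new = np.linalg.matrix_rank(Xa)
            if r_new < rank + len(cols[t]):
                raise RankDeficiencyError(analyte, t)
            rank = r_new
        raise RankDeficiencyError(analyte, "unknown")

    y = z[rows]
    _, rss_full = _rss(X_full, y)
    df_resid = n - p_full
    mse = rss_full / df_resid

    pvals: dict[str, float] = {}
    for t in cand:
        containing = [u for u in cand if t in design.parents.get(u, ())]
        excluded = set([t] + containing)
        reduced = [u for u in full_terms if u not in excluded]
        _, rss0 = _rss(mat(reduced), y)
        _, rss1 = _rss(mat(reduced + [t]), y)
        q = len(cols[t])
        F = ((rss0 - rss1) / q) / mse if mse > 0 else np.inf
        pvals[t] = float(stats.f.sf(max(F, 0.0), q, df_resid))

    selected = [t for t in cand if pvals[t] < alpha]
    for t in list(selected):  # marginality: interactions bring their parents
        for parent in design.parents.get(t, ()):
            if parent not in selected and parent in cand:
                selected.append(parent)
    selected = [t for t in cand if t in selected]  # restore canonical order

    red_terms = base_terms + selected
    X_red = mat(red_terms)
    beta, _ = _rss(X_red, y)
    coef: dict[str, np.ndarray] = {}
    off = 0
    for t in red_terms:
        k = len(cols[t])
        coef[t] = beta[off:off + k]
        off += k
    return AnalyteAdjustment(analyte, pvals, selected, coef, cols, dropped, n, rows)


def fit_adjustment(z: pd.DataFrame, covariates: pd.DataFrame, diagnosis: pd.Series,
                   covariate_names=DEFAULT_COVARIATES, alpha: float = 0.05,
                   interactions: bool = True, min_category: int = 5
                   ) -> AdjustmentModel:
    """Fit and reduce the per-analyte adjustment models.

    ``z``, ``covariates`` and ``diagnosis`` must share an index (one row
    per subject).  Raises :class:`RankDeficiencyError` naming analyte and
    term when the encoded design is singular.
    """
    if not (z.index.equals(covariates.index) and z.index.equals(diagnosis.index)):
        raise AdjustmentError("z, covariates and diagnosis must share an index")
    design = encode_design(covariates, diagnosis, covariate_names, interactions,
                           min_category)
    model = AdjustmentModel(design=design, alpha=alpha)
    for a in z.columns:
        model.analytes[a] = _fit_one(design, a, z[a].to_numpy(dtype=float), alpha)
    return model


def residualize(z: pd.DataFrame, model: AdjustmentModel) -> ResidualMatrix:
    """Subtract the fitted covariate effects (never the diagnosis term).

    A subject's residual is missing where Z is missing or where a covariate
    used by that analyte's reduced model is missing.
    """
    design = model.design
    out = {}
    for a in z.columns:
        e = model.analytes.get(a)
        if e is None:
            raise AdjustmentError(f"analyte {a!r} was not fitted")
        zv = z[a].to_numpy(dtype=float)
        resid = np.full(zv.shape, np.nan)
        ok = np.isfinite(zv)
        cov_part = np.zeros(zv.shape)
        for t in e.selected:
            blk = design.term_array(t, e.columns[t])
            ok &= np.isfinite(blk).all(axis=1)
            cov_part = cov_part + blk @ e.coef[t]
        resid[ok] = zv[ok] - cov_part[ok]
        out[a] = resid
    prov = {"alpha": model.alpha,
            "terms": {a: list(e.selected) for a, e in model.analytes.items()}}
    return ResidualMatrix(pd.DataFrame(out, index=z.index), prov)


def fitted_parts(model: AdjustmentModel, z: pd.DataFrame, analyte: str) -> dict:
    """Decompose the reduced fit on its own rows (test/diagnostic contract).

    Returns arrays on the fit rows: ``base`` (intercept + diagnosis part),
    ``covariate`` (sum of selected covariate terms), ``error`` (OLS error),
    plus the row mask — so that residual == base + error can be verified.
    """
    e = model.analytes[analyte]
    rows = e.rows
    y = z[analyte].to_numpy(dtype=float)[rows]
    base = np.zeros(rows.sum())
    covp = np.zeros(rows.sum())
    for t, beta in e.coef.items():
        blk = model.design.term_array(t, e.columns[t])[rows]
        part = blk @ beta
        if t in ("Intercept", "diagnosis"):
            base += part
        else:
            covp += part
    return {"rows": rows, "base": base, "covariate": covp,
            "error": y - base - covp, "y": y}
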