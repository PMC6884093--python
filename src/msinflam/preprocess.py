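"""Visit screening, per-subject summarisation and Box-Cox standardisation.

Repeated measurements are screened with the one-way random-effects
intraclass correlation (ICC): visits are exchangeable replicates, so the
one-way variant (absolute agreement, no visit fixed structure) is the
right estimand.  All visits are then averaged per subject regardless of
ICC — low-stability analytes are flagged, not excluded — severity scores
are carried forward from the most recent non-missing visit, and each
analyte is Box-Cox transformed (profile-likelihood lambda on a fixed grid)
and converted to a Z score on the pooled sample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import boxcox as _boxcox

from .panel import BiomarkerSpec, panel_map

log = logging.getLogger(__name__)

SEVERITY_COLS = ("msss", "armss", "msdss")


class ICCUndefinedError(ValueError):
    pass


class DuplicateVisitError(ValueError):
    pass


class StandardizationError(ValueError):
    pass


@dataclass
class ICCResult:
    icc: float
    n_subjects: int
    n_observations: int
    ms_between: float
    ms_within: float
    k0: float


def compute_icc(values, subjects) -> ICCResult:
    """One-way random-effects ICC for an unbalanced repeated-measures design.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with the standard unbalanced
    k0 = (N - sum(n_i^2)/N) / (a - 1).  The estimate may be negative and is
    reported unclipped.  Missing values are dropped first.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(subjects)
    ok = np.isfinite(v)
    v, s = v[ok], s[ok]
    if v.size == 0:
        raise ICCUndefinedError("no non-missing observations")
    uniq, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    a, N = uniq.size, v.size
    if a < 2:
        raise ICCUndefinedError("need at least 2 subjects")
    if N - a < 1:
        raise ICCUndefinedError("need at least one subject with >= 2 visits")
    grand = v.mean()
    group_sum = np.bincount(inv, weights=v)
    group_mean = group_sum / counts
    ssb = float(np.sum(counts * (group_mean - grand) ** 2))
    ssw = float(np.sum((v - group_mean[inv]) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    k0 = (N - np.sum(counts ** 2) / N) / (a - 1)
    denom = msb + (k0 - 1.0) * msw
    icc = (msb - msw) / denom if denom != 0 else np.nan
    return ICCResult(float(icc), int(a), int(N), msb, msw, float(k0))


def summarize_subjects(visits: pd.DataFrame,
                       panel: list[BiomarkerSpec] | None = None,
                       severity_cols=SEVERITY_COLS,
                       icc_flag_threshold: float = 0.8,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse the visit table to one row per subject.

    Biomarkers are averaged over all non-missing visits (unconditionally;
    the ICC report only flags analytes at or below ``icc_flag_threshold``).
    Severity scores take the chronologically last non-missing value.
    Returns ``(summary, icc_report)``.
    """
    pm = panel_map(panel)
    analytes = [c for c in visits.columns if c in pm]
    dup = visits.duplicated(subset=["subject_id", "visit_index"])
    if dup.any():
        keys = visits.loc[dup, ["subject_id", "visit_index"]].values.tolist()
        raise DuplicateVisitError(f"duplicate (subject, visit) keys: {keys[:5]}")
    df = visits.sort_values(["subject_id", "visit_index"], kind="mergesort")

    g = df.groupby("subject_id", sort=True)
    summary = g.agg(diagnosis=("diagnosis", "first")).copy()
    for c in ("sex", "race"):
        if c in df.columns:
            summary[c] = g[c].first()
    if "age" in df.columns:
        summary["age"] = g["age"].mean()
    summary["n_visits"] = g.size()
    for a in analytes:
        summary[a] = g[a].mean()
        summary[f"{a}__n"] = g[a].count()
    for s in severity_cols:
        if s in df.columns:
            summary[s] = g[s].last()  # last non-missing per subject (visit-sorted)

    rows = []
    for a in analytes:
        try:
            r = compute_icc(df[a], df["subject_id"])
            flagged = not (r.icc > icc_flag_threshold)
            rows.append((a, r.icc, r.n_subjects, r.n_observations, flagged))
            if flagged:
                log.warning("analyte %s has ICC %.3f <= %.2f (flagged, still averaged)",
                            a, r.icc, icc_flag_threshold)
        except ICCUndefinedError as exc:
            rows.append((a, np.nan, 0, 0, True))
            log.warning("ICC undefined for %s: %s", a, exc)
    icc_report = pd.DataFrame(
        rows, columns=["analyte", "icc", "n_subjects", "n_observations", "flagged"])
    return summary, icc_report


# ----------------------------------------------------------------------
def boxcox_loglike_grid(x: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood on a grid of exponents (x > 0)."""
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    n = x.size
    logx = np.log(x)
    slog = logx.sum()
    out = np.empty(lam.size)
    nz = lam != 0
    if nz.any():
        y = (np.exp(np.outer(logx, lam[nz])) - 1.0) / lam[nz]
        out[nz] = (lam[nz] - 1.0) * slog - 0.5 * n * np.log(y.var(axis=0))
    if (~nz).any():
        out[~nz] = -slog - 0.5 * n * np.log(logx.var())
    return out


@dataclass
class TransformRecord:
    lambda_: float
    shift: float
    mean: float
    sd: float


@dataclass
class TransformModel:
    """Per-analyte Box-Cox and Z-scoring parameters, reusable on new data."""

    records: dict[str, TransformRecord] = field(default_factory=dict)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for a, r in self.records.items():
            x = df[a].to_numpy(dtype=float)
            z = np.full(x.shape, np.nan)
            ok = np.isfinite(x)
            z[ok] = (_boxcox(x[ok] + r.shift, r.lambda_) - r.mean) / r.sd
            out[a] = z
        return pd.DataFrame(out, index=df.index)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, r.lambda_, r.shift, r.mean, r.sd) for a, r in self.records.items()],
            columns=["analyte", "lambda", "shift", "mean", "sd"])


def standardize(summary: pd.DataFrame,
                analytes: list[str] | None = None,
                lambda_range: tuple[float, float] = (-3.0, 3.0),
                lambda_step: float = 0.01,
                fixed_lambdas: dict[str, float] | None = None,
                ) -> tuple[TransformModel, pd.DataFrame]:
    """Box-Cox transform and Z-score each analyte on the pooled sample.

    A positivity shift of ``1 - min(x)`` is applied when min(x) <= 0 (ESR
    and CRP can legitimately be zero).  Lambda maximises the profile
    log-likelihood on the grid unless overridden via ``fixed_lambdas``.
    Z scores use the n-1 standard deviation; missing cells stay missing.
    """
    if analytes is None:
        analytes = [c for c in summary.columns if c in panel_map()]
    lo, hi = lambda_range
    grid = np.round(np.arange(lo, hi + lambda_step / 2, lambda_step), 10)
    model = TransformModel()
    zcols = {}
    for a in analytes:
        x = summary[a].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xs = x[ok]
        if xs.size < 3:
            raise StandardizationError(f"analyte {a!r} has fewer than 3 values")
        if np.ptp(xs) == 0:
            raise StandardizationError(f"analyte {a!r} has zero variance")
        shift = 0.0 if xs.min() > 0 else 1.0 - xs.min()
        xp = xs + shift
        if fixed_lambdas is not None and a in fixed_lambdas:
            lam = float(fixed_lambdas[a])
        else:
            lam = float(grid[int(np.argmax(boxcox_loglike_grid(xp, grid)))])
        tv = _boxcox(xp, lam)
        mu = float(tv.mean())
        sd = float(tv.std(ddof=1))
        if not sd > 0:
            raise StandardizationError(f"analyte {a!r} degenerate after transform")
        z = np.full(x.shape, np.nan)
        z[ok] = (tv - mu) / sd
        model.records[a] = TransformRecord(lam, shift, mu, sd)
        zcols[a] = z
    return model, pd.DataFrame(zcols, index=summary.index)
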