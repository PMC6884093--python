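"""Synthetic cohort generator with a known latent-factor structure.

The generator emulates the statistical anatomy of a cross-sectional
neuroimmunology cohort: per-subject latent inflammation factors shared by
cluster-mates, diagnosis-group shifts, age/sex/race confounding, repeated
visits with a controlled intraclass correlation, right-skewed marginals
(induced by an inverse Box-Cox map so the pipeline's Box-Cox step has
something real to undo), completely-at-random missingness, and severity
scores coupled to the latent CSF factors.  Every generated cohort comes
with the ground truth needed for recovery testing.

Model for analyte j of subject i at visit t, on the latent (pre-skew) scale:

    y_ijt = fixed_ij + s_ij + e_ijt
    s_ij  = sign_j * L_j * F_{i,c(j)} + sqrt(1 - L_j^2) * u_ij

with F and u standard normal, ``fixed`` the diagnosis shift plus
standardized-covariate effects, and sign_j = -1 for negative APRs.  The
stable part ``s`` has unit variance; the visit-noise variance is solved
analytically from the variance partition (including the exactly computed
fixed-effect variance) so that the one-way ICC of y equals ``icc_target``
in expectation — the target is never tuned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import inv_boxcox

from .panel import BiomarkerSpec, default_panel, panel_map, FROZEN_CLUSTER_LAYOUT

DIAGNOSES = ("HD", "RRMS", "PPMS", "SPMS")
#: aliases usable in diagnosis_effects keys
GROUP_ALIASES: dict[str, tuple[str, ...]] = {
    "MS": ("RRMS", "PPMS", "SPMS"),
    "PMS": ("PPMS", "SPMS"),
}
SEVERITY_COLS = ("msss", "armss", "msdss")
COVARIATE_KEYS = ("age", "sex_male", "race_black", "race_other")
RACE_LEVELS = ("White", "Black", "Other")

ID_COLS = ("subject_id", "diagnosis", "visit_index", "age", "sex", "race")


class SyntheticConfigError(ValueError):
    """Invalid generator configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation giving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class LatentCluster:
    name: str
    compartment: str
    loadings: dict[str, float]


def default_latent_clusters() -> list[LatentCluster]:
    """One latent factor per published cluster, loading 0.8 everywhere."""
    pm = panel_map()
    out = []
    for name, compartment, members in FROZEN_CLUSTER_LAYOUT:
        out.append(LatentCluster(name, compartment, {m: 0.8 for m in members}))
        for m in members:
            assert m in pm
    return out


def default_diagnosis_effects() -> dict[tuple[str, str], float]:
    """Observed-scale group shifts (in latent-SD units) vs healthy donors.

    Chosen to mirror the qualitative published picture: elevated ferritin
    and CSF inflammation in MS, reduced negative APRs, larger CSF shifts in
    progressive disease.
    """
    return {
        ("ferritin", "MS"): 0.35,
        ("transferrin", "MS"): -0.30,
        ("serum_albumin", "PMS"): -0.30,
        ("CSF cluster 1", "RRMS"): 0.25,
        ("CSF cluster 1", "PMS"): 0.45,
        ("CSF cluster 2", "MS"): 0.70,
        ("csf_scd27", "MS"): 0.70,
    }


def default_covariate_effects() -> dict[tuple[str, str], float]:
    """Slopes in SD-per-covariate-SD; on by default so adjustment has work."""
    return {
        ("esr", "age"): 0.30,
        ("esr", "sex_male"): -0.20,
        ("crp", "age"): 0.20,
        ("ferritin", "age"): 0.25,
        ("ferritin", "sex_male"): 0.30,
        ("wbc", "race_black"): -0.30,
        ("csf_chi3l1", "age"): 0.35,
        ("csf_albumin", "age"): 0.25,
        ("csf_albumin", "sex_male"): 0.20,
    }


def default_skew_lambdas() -> dict[str, float]:
    """Inverse-Box-Cox exponents; lambda<1 induces right skew."""
    lam = {name: 0.5 for name in panel_map()}
    lam.update({"crp": 0.0, "ferritin": 0.0, "esr": 0.2, "csf_scd27": 0.25,
                "igg_index": 0.25, "csf_sbcma": 0.3})
    return lam


@dataclass
class SyntheticConfig:
    """Full description of a synthetic study; defaults are the study design."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HD": 51, "RRMS": 118, "PPMS": 87, "SPMS": 86})
    visits_min: int = 1
    visits_max: int = 8
    latent_clusters: list[LatentCluster] = field(default_factory=default_latent_clusters)
    diagnosis_effects: dict[tuple[str, str], float] = field(
        default_factory=default_diagnosis_effects)
    covariate_effects: dict[tuple[str, str], float] = field(
        default_factory=default_covariate_effects)
    icc_target: float = 0.9
    skew_lambdas: dict[str, float] | None = field(default_factory=default_skew_lambdas)
    skew_offset: float = 4.0
    missing_rate: float = 0.10
    severity_missing_rate: float = 0.20
    #: Spearman-scale coupling of latent factors to every severity score
    severity_coupling: dict[str, float] = field(
        default_factory=lambda: {"CSF cluster 2": 0.25})
    severity_visit_sd: float = 0.1
    age_by_diagnosis: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HD": (39.4, 14.4), "RRMS": (42.3, 11.5),
                                 "PPMS": (55.3, 10.0), "SPMS": (55.3, 10.0)})
    sex_male_freq: dict[str, float] = field(
        default_factory=lambda: {"HD": 0.51, "RRMS": 0.36, "PPMS": 0.47, "SPMS": 0.47})
    race_freq: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "HD": {"White": 0.42, "Black": 0.42, "Other": 0.16},
            "RRMS": {"White": 0.69, "Black": 0.26, "Other": 0.05},
            "PPMS": {"White": 0.80, "Black": 0.14, "Other": 0.06},
            "SPMS": {"White": 0.80, "Black": 0.14, "Other": 0.06},
        })
    panel: list[BiomarkerSpec] = field(default_factory=default_panel)
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for d, n in self.group_sizes.items():
            if d not in DIAGNOSES:
                raise SyntheticConfigError("group_sizes", f"unknown diagnosis {d!r}")
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise SyntheticConfigError("group_sizes", f"size for {d} must be >= 0")
        if sum(self.group_sizes.values()) < 1:
            raise SyntheticConfigError("group_sizes", "cohort is empty")
        if not (1 <= self.visits_min <= self.visits_max):
            raise SyntheticConfigError("visits_min", "need 1 <= visits_min <= visits_max")
        if not (0.0 < self.icc_target <= 1.0):
            raise SyntheticConfigError("icc_target", "must be in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SyntheticConfigError("missing_rate", "must be in [0, 1)")
        if not (0.0 <= self.severity_missing_rate < 1.0):
            raise SyntheticConfigError("severity_missing_rate", "must be in [0, 1)")
        pm = panel_map(self.panel)
        seen: dict[str, str] = {}
        for cl in self.latent_clusters:
            for m, load in cl.loadings.items():
                if m not in pm:
                    raise SyntheticConfigError("latent_clusters",
                                               f"unknown analyte {m!r} in {cl.name}")
                if m in seen:
                    raise SyntheticConfigError(
                        "latent_clusters",
                        f"analyte {m!r} in both {seen[m]!r} and {cl.name!r}")
                if not (0.0 <= load <= 1.0):
                    raise SyntheticConfigError("latent_clusters",
                                               f"loading for {m} must be in [0, 1]")
                seen[m] = cl.name
        cluster_names = {cl.name for cl in self.latent_clusters}
        for (target, diag) in self.diagnosis_effects:
            if target not in pm and target not in cluster_names:
                raise SyntheticConfigError("diagnosis_effects",
                                           f"unknown target {target!r}")
            if diag not in DIAGNOSES and diag not in GROUP_ALIASES:
                raise SyntheticConfigError("diagnosis_effects",
                                           f"unknown diagnosis {diag!r}")
        for (analyte, cov) in self.covariate_effects:
            if analyte not in pm:
                raise SyntheticConfigError("covariate_effects",
                                           f"unknown analyte {analyte!r}")
            if cov not in COVARIATE_KEYS:
                raise SyntheticConfigError("covariate_effects",
                                           f"unknown covariate {cov!r}")
        for fac in self.severity_coupling:
            if fac not in cluster_names:
                raise SyntheticConfigError("severity_coupling",
                                           f"unknown latent factor {fac!r}")
        if self.skew_lambdas is not None:
            for a, lam in self.skew_lambdas.items():
                if a not in pm:
                    raise SyntheticConfigError("skew_lambdas", f"unknown analyte {a!r}")
                if lam < 0:
                    raise SyntheticConfigError("skew_lambdas",
                                               "negative exponents are not supported")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["latent_clusters"] = [
            {"name": c.name, "compartment": c.compartment, "loadings": dict(c.loadings)}
            for c in self.latent_clusters]
        d["diagnosis_effects"] = [
            {"target": t, "diagnosis": g, "shift": v}
            for (t, g), v in sorted(self.diagnosis_effects.items())]
        d["covariate_effects"] = [
            {"analyte": a, "covariate": c, "slope": v}
            for (a, c), v in sorted(self.covariate_effects.items())]
        d["age_by_diagnosis"] = {k: list(v) for k, v in self.age_by_diagnosis.items()}
        d["panel"] = [asdict(s) for s in self.panel]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "latent_clusters" in d:
            d["latent_clusters"] = [LatentCluster(**c) for c in d["latent_clusters"]]
        if "diagnosis_effects" in d and isinstance(d["diagnosis_effects"], list):
            d["diagnosis_effects"] = {
                (e["target"], e["diagnosis"]): e["shift"] for e in d["diagnosis_effects"]}
        if "covariate_effects" in d and isinstance(d["covariate_effects"], list):
            d["covariate_effects"] = {
                (e["analyte"], e["covariate"]): e["slope"] for e in d["covariate_effects"]}
        if "age_by_diagnosis" in d:
            d["age_by_diagnosis"] = {k: tuple(v) for k, v in d["age_by_diagnosis"].items()}
        if "panel" in d:
            d["panel"] = [BiomarkerSpec(**s) for s in d["panel"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def analyte_names(self) -> list[str]:
        return [s.name for s in self.panel]

    def partition(self) -> dict[str, str]:
        """analyte -> latent cluster name (singletons get their own factor)."""
        out: dict[str, str] = {}
        for cl in self.latent_clusters:
            for m in cl.loadings:
                out[m] = cl.name
        for a in self.analyte_names():
            out.setdefault(a, a)  # unlisted analyte = its own singleton factor
        return out

    def resolved_diagnosis_effects(self) -> dict[tuple[str, str], float]:
        """Expand cluster targets and MS/PMS aliases to (analyte, diagnosis)."""
        members: dict[str, tuple[str, ...]] = {
            cl.name: tuple(cl.loadings) for cl in self.latent_clusters}
        out: dict[tuple[str, str], float] = {}
        for (target, diag), shift in self.diagnosis_effects.items():
            analytes = members.get(target, (target,))
            diags = GROUP_ALIASES.get(diag, (diag,))
            for a in analytes:
                for d in diags:
                    out[(a, d)] = out.get((a, d), 0.0) + shift
        return out


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline's answers."""

    factors: pd.DataFrame                       # subjects x latent factors
    partition: dict[str, str]                   # analyte -> factor name
    diagnosis_effects: dict[tuple[str, str], float]
    covariate_effects: dict[tuple[str, str], float]
    severity_coupling_spearman: dict[str, float]
    severity_coupling_pearson: dict[str, float]
    icc_target: float
    fixed_effect_variance: dict[str, float]
    visit_noise_sd: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "partition": self.partition,
            "diagnosis_effects": [
                {"analyte": a, "diagnosis": d, "shift": v}
                for (a, d), v in sorted(self.diagnosis_effects.items())],
            "covariate_effects": [
                {"analyte": a, "covariate": c, "slope": v}
                for (a, c), v in sorted(self.covariate_effects.items())],
            "severity_coupling_spearman": self.severity_coupling_spearman,
            "severity_coupling_pearson": self.severity_coupling_pearson,
            "icc_target": self.icc_target,
            "fixed_effect_variance": self.fixed_effect_variance,
            "visit_noise_sd": self.visit_noise_sd,
            "factors": {
                "subjects": list(self.factors.index),
                "columns": list(self.factors.columns),
                "values": self.factors.round(10).values.tolist(),
            },
        }


# ----------------------------------------------------------------------
def _pooled_covariate_moments(cfg: SyntheticConfig, weights: dict[str, float]):
    """Pooled mean/SD of each covariate across the configured mixture."""
    mu_age = sum(w * cfg.age_by_diagnosis[d][0] for d, w in weights.items())
    var_age = sum(
        w * (cfg.age_by_diagnosis[d][1] ** 2 + cfg.age_by_diagnosis[d][0] ** 2)
        for d, w in weights.items()) - mu_age ** 2
    p_male = sum(w * cfg.sex_male_freq[d] for d, w in weights.items())
    q_black = sum(w * cfg.race_freq[d]["Black"] for d, w in weights.items())
    q_other = sum(w * cfg.race_freq[d]["Other"] for d, w in weights.items())

    def _bsd(p):  # SD of a Bernoulli indicator; guard degenerate frequencies
        v = p * (1.0 - p)
        return math.sqrt(v) if v > 0 else 1.0

    return {
        "age": (mu_age, math.sqrt(var_age) if var_age > 0 else 1.0),
        "sex_male": (p_male, _bsd(p_male)),
        "race_black": (q_black, _bsd(q_black)),
        "race_other": (q_other, _bsd(q_other)),
    }


def _fixed_effect_variance(cfg: SyntheticConfig, weights, moments,
                           diag_fx: dict[tuple[str, str], float]) -> dict[str, float]:
    """Exact population variance of the fixed-effect part, per analyte.

    Enumerates diagnosis x sex x race cells (age is normal within cell), so
    confounding between diagnosis and the covariates is accounted for.
    """
    mu_age, sd_age = moments["age"]
    out: dict[str, float] = {}
    for a in cfg.analyte_names():
        b_age = cfg.covariate_effects.get((a, "age"), 0.0)
        b_sex = cfg.covariate_effects.get((a, "sex_male"), 0.0)
        b_black = cfg.covariate_effects.get((a, "race_black"), 0.0)
        b_other = cfg.covariate_effects.get((a, "race_other"), 0.0)
        e1 = e2 = 0.0
        for d, w_d in weights.items():
            delta = diag_fx.get((a, d), 0.0)
            age_m = (cfg.age_by_diagnosis[d][0] - mu_age) / sd_age
            age_v = (cfg.age_by_diagnosis[d][1] / sd_age) ** 2
            for male, p_s in ((1, cfg.sex_male_freq[d]), (0, 1 - cfg.sex_male_freq[d])):
                zs = (male - moments["sex_male"][0]) / moments["sex_male"][1]
                for race, p_r in cfg.race_freq[d].items():
                    zb = ((race == "Black") - moments["race_black"][0]) / moments["race_black"][1]
                    zo = ((race == "Other") - moments["race_other"][0]) / moments["race_other"][1]
                    w = w_d * p_s * p_r
                    m = delta + b_sex * zs + b_black * zb + b_other * zo + b_age * age_m
                    v = b_age ** 2 * age_v
                    e1 += w * m
                    e2 += w * (v + m * m)
        out[a] = max(e2 - e1 * e1, 0.0)
    return out


def generate_cohort(config: SyntheticConfig | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format visit table plus its ground truth.

    Deterministic given ``config`` and ``seed`` (``config.seed`` when the
    argument is omitted).
    """
    cfg = config if config is not None else SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    active = [(d, n) for d in DIAGNOSES for n in [cfg.group_sizes.get(d, 0)] if n > 0]
    n_sub = sum(n for _, n in active)
    diagnosis = np.concatenate([[d] * n for d, n in active])
    subjects = np.array([f"S{i:04d}" for i in range(1, n_sub + 1)])
    weights = {d: n / n_sub for d, n in active}
    moments = _pooled_covariate_moments(cfg, weights)
    analytes = cfg.analyte_names()
    pm = panel_map(cfg.panel)
    partition = cfg.partition()
    diag_fx = cfg.resolved_diagnosis_effects()

    # --- covariates -----------------------------------------------------
    age0 = np.empty(n_sub)
    male = np.empty(n_sub, dtype=int)
    race = np.empty(n_sub, dtype=object)
    for d, _ in active:
        m = diagnosis == d
        mu, sd = cfg.age_by_diagnosis[d]
        age0[m] = np.clip(rng.normal(mu, sd, m.sum()), 18.0, 90.0)
        male[m] = rng.random(m.sum()) < cfg.sex_male_freq[d]
        levels = sorted(cfg.race_freq[d])  # stable order regardless of dict order
        probs = np.array([cfg.race_freq[d][l] for l in levels], float)
        race[m] = rng.choice(levels, size=m.sum(), p=probs / probs.sum())
    cov_z = {
        "age": (age0 - moments["age"][0]) / moments["age"][1],
        "sex_male": (male - moments["sex_male"][0]) / moments["sex_male"][1],
        "race_black": ((race == "Black").astype(float) - moments["race_black"][0])
        / moments["race_black"][1],
        "race_other": ((race == "Other").astype(float) - moments["race_other"][0])
        / moments["race_other"][1],
    }

    # --- latent structure ----------------------------------------------
    n_visits = rng.integers(cfg.visits_min, cfg.visits_max + 1, n_sub)
    factor_names = sorted(set(partition.values()))
    F = pd.DataFrame(rng.standard_normal((n_sub, len(factor_names))),
                     index=subjects, columns=factor_names)
    loadings = {}
    for cl in cfg.latent_clusters:
        loadings.update(cl.loadings)
    vfix = _fixed_effect_variance(cfg, weights, moments, diag_fx)
    t = cfg.icc_target
    sig_e = {a: math.sqrt((1.0 + vfix[a]) * (1.0 - t) / t) if t < 1.0 else 0.0
             for a in analytes}

    u = rng.standard_normal((n_sub, len(analytes)))
    stable = np.empty((n_sub, len(analytes)))
    fixed = np.zeros((n_sub, len(analytes)))
    for j, a in enumerate(analytes):
        load = loadings.get(a, 0.8)  # unlisted singleton: own factor
        sign = -1.0 if pm[a].polarity == "negative" else 1.0
        stable[:, j] = sign * load * F[partition[a]].to_numpy() \
            + math.sqrt(max(1.0 - load * load, 0.0)) * u[:, j]
        for cov in COVARIATE_KEYS:
            b = cfg.covariate_effects.get((a, cov), 0.0)
            if b:
                fixed[:, j] += b * cov_z[cov]
        for d, _ in active:
            delta = diag_fx.get((a, d), 0.0)
            if delta:
                fixed[diagnosis == d, j] += delta

    # --- severity (subject level) --------------------------------------
    coup_p = {f: spearman_to_pearson(r) for f, r in cfg.severity_coupling.items()}
    lin = np.zeros(n_sub)
    for f in sorted(coup_p):  # stable summation order
        lin = lin + coup_p[f] * F[f].to_numpy()
    resid_sd = math.sqrt(max(1.0 - sum(r * r for r in coup_p.values()), 0.0))
    sev_subject = {s: lin + resid_sd * rng.standard_normal(n_sub) for s in SEVERITY_COLS}

    # --- expand to visits ----------------------------------------------
    row_subject = np.repeat(np.arange(n_sub), n_visits)
    visit_index = np.concatenate([np.arange(1, k + 1) for k in n_visits])
    n_rows = row_subject.size
    e = rng.standard_normal((n_rows, len(analytes)))
    values = fixed[row_subject] + stable[row_subject] \
        + e * np.array([sig_e[a] for a in analytes])

    # induce right skew per analyte; pipeline re-standardizes, so scale is free
    obs = np.empty_like(values)
    for j, a in enumerate(analytes):
        sd_tot = math.sqrt(1.0 + vfix[a] + sig_e[a] ** 2)
        arg = values[:, j] / sd_tot + cfg.skew_offset
        lam = 1.0 if cfg.skew_lambdas is None else cfg.skew_lambdas.get(a, 1.0)
        if lam > 0:
            arg = np.maximum(arg, 1e-3)  # keep inside the inverse-transform domain
        obs[:, j] = inv_boxcox(arg, lam)

    sev_noise = rng.standard_normal((n_rows, len(SEVERITY_COLS))) * cfg.severity_visit_sd
    sev_visit = {}
    for k, s in enumerate(SEVERITY_COLS):
        g = sev_subject[s][row_subject] + sev_noise[:, k]
        if s == "msdss":
            sev_visit[s] = np.clip(1.9 + 0.85 * g, 0.1, 5.9)
        else:
            sev_visit[s] = np.clip(4.8 + 1.9 * g, 0.05, 9.95)

    table = pd.DataFrame({
        "subject_id": subjects[row_subject],
        "diagnosis": diagnosis[row_subject],
        "visit_index": visit_index,
        "age": np.round(age0[row_subject] + 0.5 * (visit_index - 1), 2),
        "sex": np.where(male[row_subject] == 1, "M", "F"),
        "race": race[row_subject],
    })
    for j, a in enumerate(analytes):
        table[a] = obs[:, j]
    for s in SEVERITY_COLS:
        table[s] = sev_visit[s]

    if cfg.missing_rate > 0:
        table = inject_missingness(table, cfg.missing_rate,
                                   int(rng.integers(2 ** 31)), columns=analytes)
    if cfg.severity_missing_rate > 0:
        table = inject_missingness(table, cfg.severity_missing_rate,
                                   int(rng.integers(2 ** 31)),
                                   columns=list(SEVERITY_COLS))

    truth = GroundTruth(
        factors=F,
        partition=partition,
        diagnosis_effects=diag_fx,
        covariate_effects=dict(cfg.covariate_effects),
        severity_coupling_spearman=dict(cfg.severity_coupling),
        severity_coupling_pearson=coup_p,
        icc_target=cfg.icc_target,
        fixed_effect_variance=vfix,
        visit_noise_sd=sig_e,
    )
    return table, truth


def inject_missingness(table: pd.DataFrame, missing_rate: float, seed: int,
                       columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Blank biomarker cells independently at ``missing_rate``.

    Identifier, diagnosis and covariate columns are never touched.
    Deterministic given ``seed``; a rate of 0 returns an identical copy.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise SyntheticConfigError("missing_rate", "must be in [0, 1)")
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if c in panel_map()]
    forbidden = set(ID_COLS) & set(columns)
    if forbidden:
        raise SyntheticConfigError("columns",
                                   f"cannot blank identifier columns {sorted(forbidden)}")
    if missing_rate == 0.0 or not len(columns):
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(table), len(columns))) < missing_rate
    for j, c in enumerate(columns):
        col = out[c].to_numpy(dtype=float, copy=True)
        col[mask[:, j]] = np.nan
        out[c] = col
    return out
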