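import logging

import numpy as np
import pytest

from msinflam.synthetic import SyntheticConfig, generate_cohort

logging.disable(logging.WARNING)


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """A light single-visit cohort with no fixed effects or skew tricks."""
    base = dict(
        group_sizes={"HD": 50, "RRMS": 100, "PPMS": 75, "SPMS": 75},
        visits_min=1, visits_max=1, icc_target=0.9,
        diagnosis_effects={}, covariate_effects={},
        missing_rate=0.0, severity_missing_rate=0.0, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def icc_oracle(values, subjects):
    """Brute-force one-way ANOVA mean-squares ICC, written independently.

    Explicit per-group loops over the classical sums of squares; kept free
    of any vectorised shortcut shared with the implementation.
    """
    groups = {}
    for v, s in zip(values, subjects):
        if v is not None and np.isfinite(v):
            groups.setdefault(s, []).append(float(v))
    a = len(groups)
    N = sum(len(g) for g in groups.values())
    grand = sum(sum(g) for g in groups.values()) / N
    ssb = ssw = 0.0
    for g in groups.values():
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for v in g:
            ssw += (v - m) ** 2
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    k0 = (N - sum(len(g) ** 2 for g in groups.values()) / N) / (a - 1)
    denom = msb + (k0 - 1) * msw
    return (msb - msw) / denom if denom != 0 else float("nan")


def bh_oracle(pvals):
    """Literal Benjamini-Hochberg step-up: adj(i) = min_{j>=i} p(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj
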