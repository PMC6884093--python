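"""Polarity handling, correlation-driven cluster derivation and scoring.

Clusters are connected components of the graph whose edges join two
same-compartment analytes when their residuals' pairwise-complete Pearson
correlation reaches ``r_threshold`` with raw p < 0.05 (post polarity flip,
so expected within-cluster correlations are positive).  Blood clusters are
derived on all patients; CSF clusters on MS patients only.  A frozen mode
returns the published composite layout instead of deriving one — the CSF
split into innate vs humoral arms is a biological choice, not a purely
statistical one, so frozen is the reproduction default for CSF.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .adjust import ResidualMatrix
from .panel import (BiomarkerSpec, FROZEN_CLUSTER_LAYOUT, compartment_names,
                    panel_map)


class ClusterError(ValueError):
    pass


class ClusterDerivationError(ClusterError):
    pass


@dataclass(frozen=True)
class ClusterDefinition:
    name: str
    compartment: str
    members: tuple[str, ...]
    derivation: str = "frozen"       # "frozen" | "data-driven"
    population: str = "all"          # "all" | "MS-only"


@dataclass
class ClusterScoreTable:
    scores: pd.DataFrame             # subjects x clusters
    counts: pd.DataFrame             # contributing member count per cell


def frozen_clusters(panel: list[BiomarkerSpec] | None = None) -> list[ClusterDefinition]:
    """The published partition: Blood 1-3, CSF innate/humoral, two singletons."""
    pm = panel_map(panel)
    out = []
    for name, compartment, members in FROZEN_CLUSTER_LAYOUT:
        missing = [m for m in members if m not in pm]
        if missing:
            raise ClusterError(f"frozen cluster {name!r} references {missing}")
        pop = "MS-only" if compartment == "csf" else "all"
        out.append(ClusterDefinition(name, compartment, tuple(members), "frozen", pop))
    return out


def _frame(residuals) -> pd.DataFrame:
    return residuals.data if isinstance(residuals, ResidualMatrix) else residuals


def apply_polarity(residuals, panel: list[BiomarkerSpec] | None = None):
    """Multiply negative-APR columns by -1; an involution, missing preserved."""
    pm = panel_map(panel)
    df = _frame(residuals).copy()
    for c in df.columns:
        if c not in pm:
            raise ClusterError(f"analyte {c!r} absent from panel")
        if pm[c].polarity == "negative":
            df[c] = -df[c]
    if isinstance(residuals, ResidualMatrix):
        prov = dict(residuals.provenance)
        prov["polarity_applied"] = not prov.get("polarity_applied", False)
        return ResidualMatrix(df, prov)
    return df


def derive_clusters(residuals, compartment: str,
                    panel: list[BiomarkerSpec] | None = None,
                    subjects: pd.Index | None = None,
                    r_threshold: float = 0.3, alpha: float = 0.05,
                    min_pairwise_n: int = 10,
                    population_label: str = "all") -> list[ClusterDefinition]:
    """Connected-component clusters from the residual correlation graph.

    Deterministic: components are ordered by size (descending) then by
    first member name; multi-member components are named
    ``"<Compartment> cluster <k>"`` and singletons after their analyte.
    """
    df = _frame(residuals)
    names = [c for c in compartment_names(compartment, panel) if c in df.columns]
    if len(names) < 2:
        raise ClusterDerivationError(
            f"need >= 2 analytes in compartment {compartment!r}")
    if subjects is not None:
        df = df.loc[subjects]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = df[[a, b]].dropna()
            n = len(pair)
            if n < min_pairwise_n:
                raise ClusterDerivationError(
                    f"pair ({a}, {b}) has only {n} complete observations "
                    f"(< {min_pairwise_n}); use a frozen partition instead")
            r, p = stats.pearsonr(pair[a], pair[b])
            if r >= r_threshold and p < alpha:
                g.add_edge(a, b)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    pm = panel_map(panel)
    label = compartment.upper() if compartment == "csf" else compartment.capitalize()
    out, k = [], 0
    for comp in comps:
        if len(comp) > 1:
            k += 1
            name = f"{label} cluster {k}"
        else:
            name = pm[comp[0]].display
        out.append(ClusterDefinition(name, compartment, comp, "data-driven",
                                     population_label))
    return out


def score_clusters(residuals, definitions: list[ClusterDefinition]) -> ClusterScoreTable:
    """Per-subject mean of non-missing member residuals, with member counts.

    A score is missing iff every member residual is missing for that
    subject; invariant to member order and to all-missing subject rows.
    """
    df = _frame(residuals)
    scores, counts = {}, {}
    for d in definitions:
        if not d.members:
            raise ClusterError(f"cluster {d.name!r} has no members")
        missing = [m for m in d.members if m not in df.columns]
        if missing:
            raise ClusterError(f"cluster {d.name!r} members absent from residuals: {missing}")
        block = df[list(d.members)]
        scores[d.name] = block.mean(axis=1, skipna=True)
        counts[d.name] = block.notna().sum(axis=1)
    return ClusterScoreTable(pd.DataFrame(scores, index=df.index),
                             pd.DataFrame(counts, index=df.index))


def pairwise_correlations(residuals, members: list[str]) -> pd.DataFrame:
    """Pairwise-complete Pearson r/p/N table for a set of analytes."""
    df = _frame(residuals)
    rows = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            pair = df[[a, b]].dropna()
            if len(pair) >= 3:
                r, p = stats.pearsonr(pair[a], pair[b])
            else:
                r, p = np.nan, np.nan
            rows.append((a, b, r, p, len(pair)))
    return pd.DataFrame(rows, columns=["analyte_1", "analyte_2", "r", "p", "n"])
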