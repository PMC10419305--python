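"""Topography reports, parameter tables and scenario-delta rendering.

The topography report summarises the per-snapshot network metrics
(median/mean/sd across snapshots) and adds the two per-agent diagnostics
of interest for this model: whether the BMI assortativity of an agent's
own network neighbourhood grows with age, and whether BMI and
neighbourhood size are inversely related.  Both are reported as Spearman
rank correlations — only the direction is claimed, not linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .groups import AGE_GROUP_LABELS
from .network import build_graph
from .simulate import SimulationResult

__all__ = ["MetricsReport", "neighbourhood_bmi_assortativity", "render_tables", "topography_report"]

METRIC_NAMES = ("clustering", "transitivity", "degree_assortativity",
                "bmi_assortativity", "average_degree")


@dataclass
class MetricsReport:
    """Summary of network topography across snapshots.

    ``snapshots`` holds one row per snapshot month; ``summary`` the
    median/mean/sd per metric; the correlation attributes are Spearman
    (rho, p-value) pairs, NaN where undefined (zero variance).
    """

    snapshots: pd.DataFrame
    summary: pd.DataFrame
    age_vs_neighbourhood_assortativity: tuple[float, float]
    bmi_vs_neighbourhood_size: tuple[float, float]


def neighbourhood_bmi_assortativity(pop, state, weight_min: float = 0.0) -> np.ndarray:
    """Per-agent BMI assortativity of the agent's network neighbourhood.

    For each agent, the Pearson correlation of BMI across the endpoints of
    every edge incident to its neighbourhood (the agent's local social
    context), NaN when fewer than two such edges exist or variance is
    zero.  The precise notion of a *neighbourhood's* assortativity is a
    modelling choice; this incident-edge definition is documented in the
    methods note.
    """
    graph = build_graph(pop, state, weight_min)
    bmi = pop.bmi
    adj = {node: set(graph.neighbors(node)) for node in graph.nodes()}
    out = np.full(len(pop), np.nan)
    for node in graph.nodes():
        nbhd = adj[node]
        if not nbhd:
            continue
        pairs = set()
        for member in nbhd | {node}:
            for other in adj[member]:
                pairs.add((member, other) if member < other else (other, member))
        if len(pairs) < 2:
            continue
        u = np.array([bmi[a] for a, _ in pairs])
        v = np.array([bmi[b] for _, b in pairs])
        x = np.concatenate([u, v])
        y = np.concatenate([v, u])
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[node] = np.corrcoef(x, y)[0, 1]
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x[ok], y[ok])
    return (float(rho), float(p))


def topography_report(result: SimulationResult) -> MetricsReport:
    """Cross-snapshot topography summary plus per-agent diagnostics.

    Requires at least two network snapshots in the result.  The per-agent
    diagnostics are computed on the final network state.
    """
    if len(result.metrics) < 2:
        raise ConfigurationError("topography report needs >= 2 network snapshots")
    snapshots = pd.DataFrame(
        [{"month": month, **metrics.as_dict()} for month, metrics in result.metrics]
    )
    summary = pd.DataFrame(
        {
            "median": snapshots[list(METRIC_NAMES)].median(),
            "mean": snapshots[list(METRIC_NAMES)].mean(),
            "sd": snapshots[list(METRIC_NAMES)].std(ddof=1),
        }
    )
    pop, state = result.population, result.state
    weight_min = result.config.params.network.neighbour_weight_min
    nb_assort = neighbourhood_bmi_assortativity(pop, state, weight_min)
    graph = build_graph(pop, state, weight_min)
    degree = np.zeros(len(pop))
    for node, d in graph.degree():
        degree[node] = d
    alive = pop.alive
    return MetricsReport(
        snapshots=snapshots,
        summary=summary,
        age_vs_neighbourhood_assortativity=_spearman(pop.age[alive], nb_assort[alive]),
        bmi_vs_neighbourhood_size=_spearman(pop.bmi[alive], degree[alive]),
    )


def render_tables(data, style: str = "csv") -> str:
    """Render a gender x age-group parameter grid (or a metrics summary).

    ``data`` may be a 2 x 6 array-like (rows male, female), or a
    DataFrame which is rendered as-is.  ``style`` is ``csv`` or
    ``markdown``; numeric values round-trip losslessly (repr precision).
    """
    if isinstance(data, pd.DataFrame):
        frame = data.copy()
    else:
        arr = np.asarray(data, dtype=float)
        if arr.shape != (2, len(AGE_GROUP_LABELS)):
            raise ConfigurationError(
                f"expected a 2 x {len(AGE_GROUP_LABELS)} grid, got shape {arr.shape}"
            )
        frame = pd.DataFrame(arr, index=["male", "female"], columns=AGE_GROUP_LABELS)
        frame.index.name = "gender"
    if style == "csv":
        return frame.to_csv(float_format=None)
    if style == "markdown":
        return frame.to_markdown()
    raise ConfigurationError(f"unknown table style {style!r} (csv, markdown)")
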