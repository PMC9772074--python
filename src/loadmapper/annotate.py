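"""Condition annotation and participation coefficients for shape graphs.

Nodes of a Mapper graph are sets of time frames; colouring a graph by a task
factor (load or anxiety) assigns each node the proportions of its member
frames in each level and a community label (the dominant level).  The
participation coefficient

    P_i = 1 - sum_s (kappa_is / k_i)^2

(kappa_is = links of node i into community s, k_i = its degree) quantifies
how much a node's links cross community boundaries: 0 when all links stay
within its own community, approaching 1 - 1/N_M when links are spread
uniformly over the N_M communities.  A graph whose load communities barely
touch (low mean PC) displays segregated load dynamics; heavily interlinked
communities (high mean PC) display integrated dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper import MapperGraph
from .synthetic import ANXIETY_LEVELS, LOAD_LEVELS

#: annotation axes and their canonical level order (also the tie-break order)
AXIS_LEVELS: dict[str, tuple[str, str]] = {
    "load": LOAD_LEVELS,
    "anxiety": ANXIETY_LEVELS,
}

#: phases whose frames count towards annotation proportions
DEFAULT_PHASES = ("letters",)


@dataclass
class AnnotationResult:
    """Node-level annotation, communities and PC for one graph and axis."""

    axis: str
    node_table: pd.DataFrame  # node, size, n_annotated, prop_*, community, degree, pc
    communities: dict[int, str]
    excluded_nodes: list[int]  # no annotated members
    isolated_nodes: list[int]  # degree 0 (PC undefined)
    mean_pc: float
    pc_aggregate: str = "mean"

    @property
    def n_included(self) -> int:
        return int(self.node_table["pc"].notna().sum())


def annotate_nodes(
    graph: MapperGraph,
    labels: pd.DataFrame,
    axis: str = "load",
    include_phases: Sequence[str] = DEFAULT_PHASES,
) -> tuple[pd.DataFrame, dict[int, str], list[int]]:
    """Per-node level proportions and dominant-level communities.

    ``labels`` must have one row per frame referenced by node members (the
    retained-frame label table), with columns ``load``, ``anxiety`` and
    ``phase``.  Frames labelled ``"none"`` on the chosen axis or outside
    ``include_phases`` are excluded from the proportions.  A node whose
    members are all excluded gets no community and is reported separately.
    Ties are broken by canonical level order.
    """
    if axis not in AXIS_LEVELS:
        raise ValueError(f"unknown annotation axis {axis!r}")
    levels = AXIS_LEVELS[axis]
    values = labels[axis].to_numpy()
    phases = labels["phase"].to_numpy()
    annotatable = np.isin(phases, list(include_phases)) & (values != "none")

    rows = []
    communities: dict[int, str] = {}
    excluded: list[int] = []
    for node in graph.nodes:
        members = node.members
        keep = members[annotatable[members]]
        counts = {lvl: int((values[keep] == lvl).sum()) for lvl in levels}
        total = sum(counts.values())
        row: dict = {"node": node.node_id, "size": len(members), "n_annotated": total}
        if total == 0:
            excluded.append(node.node_id)
            for lvl in levels:
                row[f"prop_{lvl}"] = np.nan
            row["community"] = None
        else:
            props = {lvl: counts[lvl] / total for lvl in levels}
            for lvl in levels:
                row[f"prop_{lvl}"] = props[lvl]
            best = max(props.values())
            community = next(lvl for lvl in levels if props[lvl] == best)
            communities[node.node_id] = community
            row["community"] = community
        rows.append(row)
    return pd.DataFrame(rows), communities, excluded


def participation_coefficient(
    graph: MapperGraph,
    communities: Mapping[int, str],
) -> dict[int, float]:
    """Unweighted participation coefficient per community-labelled node.

    Nodes without a community label are skipped; neighbours without a label
    do not contribute links.  Isolated nodes (no labelled-neighbour links)
    get ``nan`` — the formula divides by the degree.
    """
    neighbours: dict[int, list[int]] = {n.node_id: [] for n in graph.nodes}
    for u, v in graph.edges:
        neighbours[u].append(v)
        neighbours[v].append(u)
    pc: dict[int, float] = {}
    for node_id in communities:
        links = [v for v in neighbours[node_id] if v in communities]
        k_i = len(links)
        if k_i == 0:
            pc[node_id] = np.nan
            continue
        counts: dict[str, int] = {}
        for v in links:
            s = communities[v]
            counts[s] = counts.get(s, 0) + 1
        pc[node_id] = 1.0 - sum((c / k_i) ** 2 for c in counts.values())
    return pc


def graph_pc_summary(pc: Mapping[int, float], aggregate: str = "mean") -> tuple[float, int, int]:
    """Aggregate node PC values -> (summary, n_included, n_isolated)."""
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    vals = np.array(list(pc.values()), dtype=float)
    finite = vals[np.isfinite(vals)]
    n_isolated = int(np.isnan(vals).sum())
    if finite.size == 0:
        raise ValueError("no nodes with defined participation coefficient")
    agg = float(np.mean(finite) if aggregate == "mean" else np.median(finite))
    return agg, int(finite.size), n_isolated


def annotate_and_score(
    graph: MapperGraph,
    labels: pd.DataFrame,
    axis: str = "load",
    include_phases: Sequence[str] = DEFAULT_PHASES,
    aggregate: str = "mean",
) -> AnnotationResult:
    """Full annotation pass: proportions, communities, PC and summary."""
    table, communities, excluded = annotate_nodes(graph, labels, axis, include_phases)
    pc = participation_coefficient(graph, communities)
    mean_pc, _, _ = graph_pc_summary(pc, aggregate)
    degrees = {n.node_id: 0 for n in graph.nodes}
    for u, v in graph.edges:
        degrees[u] += 1
        degrees[v] += 1
    table["degree"] = table["node"].map(degrees)
    table["pc"] = table["node"].map(pc)
    isolated = sorted(nid for nid, val in pc.items() if np.isnan(val))
    return AnnotationResult(
        axis=axis,
        node_table=table,
        communities=communities,
        excluded_nodes=excluded,
        isolated_nodes=isolated,
        mean_pc=mean_pc,
        pc_aggregate=aggregate,
    )


def check_community_balance(
    graph: MapperGraph,
    communities: Mapping[int, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Community sizes, intramodular degree, and a permutation imbalance test.

    PC implicitly assumes comparably sized communities; this check reports
    the node count and within-community degree sum per community and, for
    two-community graphs, permutation p-values (community labels shuffled
    across nodes) for the absolute size and intramodular-degree differences.
    """
    levels = sorted(set(communities.values()))
    node_ids = sorted(communities)
    labels = np.array([communities[n] for n in node_ids])
    edges = [
        (u, v) for u, v in graph.edges if u in communities and v in communities
    ]

    def stats(lab: np.ndarray) -> tuple[dict, dict]:
        lab_of = dict(zip(node_ids, lab))
        sizes = {lvl: int((lab == lvl).sum()) for lvl in levels}
        intra = {lvl: 0 for lvl in levels}
        for u, v in edges:
            if lab_of[u] == lab_of[v]:
                intra[lab_of[u]] += 2  # both endpoints' within-community degree
        return sizes, intra

    sizes, intra = stats(labels)
    result: dict = {"sizes": sizes, "intramodular_degree": intra, "levels": levels}
    if len(levels) < 2:
        result["comparison"] = "skipped: single community"
        return result
    if len(levels) > 2:
        result["comparison"] = "skipped: more than two communities"
        return result
    a, b = levels
    obs_size = abs(sizes[a] - sizes[b])
    obs_intra = abs(intra[a] - intra[b])
    rng = np.random.default_rng(seed)
    ge_size = ge_intra = 0
    for _ in range(n_perm):
        # size imbalance: null = each node equally likely in either community
        # (label permutation would keep the sizes fixed)
        rand = rng.choice(levels, size=labels.size)
        s, _ = stats(rand)
        if abs(s[a] - s[b]) >= obs_size:
            ge_size += 1
        # intramodular imbalance: labels permuted across nodes (sizes held)
        perm = rng.permutation(labels)
        _, it = stats(perm)
        if abs(it[a] - it[b]) >= obs_intra:
            ge_intra += 1
    result["size_difference"] = obs_size
    result["intramodular_difference"] = obs_intra
    result["p_size"] = (1 + ge_size) / (n_perm + 1)
    result["p_intramodular"] = (1 + ge_intra) / (n_perm + 1)
    return result
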