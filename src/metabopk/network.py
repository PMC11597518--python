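"""Signed distance-correlation association networks.

Associations between individual metabolites and each pharmacokinetic
parameter or participant characteristic are scored with the distance
correlation (the biased V-statistic, which lives on [0, 1] and is zero
in the population exactly under independence), signed by the Pearson
correlation, and tested against a permutation null.  Retained edges
(dCor >= 0.5 and BH-FDR q <= 0.05 within a phase) form a weighted
tripartite graph whose community structure is found with the Leiden
algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "distance_correlation",
    "permutation_pvalue",
    "signed_association_table",
    "build_tripartite_graph",
    "detect_communities",
    "CommunityPartition",
    "network_summary",
]

_NODE_TYPES = {"metabolite", "pk_parameter", "characteristic"}

#: association target classes collapsed to tripartite node types
_CLASS_TO_NODE_TYPE = {
    "pk_parameter": "pk_parameter",
    "clinical": "characteristic",
    "laboratory_serum": "characteristic",
    "laboratory_urine": "characteristic",
}


def _check_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"{name} needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Doubly centered pairwise-distance matrix (V-statistic centering)."""
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation (Szekely's biased V-statistic).

    dCov^2 = mean(A * B) of the doubly centered distance matrices;
    dCor = sqrt(dCov^2 / sqrt(dVar_x * dVar_y)), clipped into [0, 1].
    A constant vector has zero distance variance; the statistic is then
    defined as 0 (with a warning) since no dependence is measurable.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        warnings.warn("constant input vector: distance correlation defined as 0")
        return 0.0
    dcov2 = (a * b).mean()
    r2 = dcov2 / np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def _permuted_dcors(
    a_centered: np.ndarray, d_y: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Distance correlations of x against row/column-permuted y, batched."""
    bp = d_y[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    bp = (
        bp
        - bp.mean(axis=1, keepdims=True)
        - bp.mean(axis=2, keepdims=True)
        + bp.mean(axis=(1, 2), keepdims=True)
    )
    dvar_x = (a_centered * a_centered).mean()
    dvar_y = (bp * bp).mean(axis=(1, 2))
    dcov2 = (a_centered[None] * bp).mean(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = dcov2 / np.sqrt(dvar_x * dvar_y)
    return np.sqrt(np.clip(r2, 0.0, 1.0))


def permutation_pvalue(
    x, y, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for dCor with the add-one estimator.

    p = (1 + #{permuted dCor >= observed}) / (1 + n_perm); permutations
    shuffle y against x under a seeded generator, so identical seeds
    give identical p-values.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    observed = distance_correlation(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    a = _centered_distances(x)
    d_y = np.abs(y[:, None] - y[None, :])
    permuted = _permuted_dcors(a, d_y, perms)
    return float((1 + np.sum(permuted >= observed - 1e-15)) / (1 + n_perm))


def signed_association_table(
    abundance: pd.DataFrame,
    targets: pd.DataFrame,
    phase: str,
    target_classes: dict[str, str] | None = None,
    d_threshold: float = 0.5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every metabolite x target pair within one phase.

    ``abundance`` (subjects x metabolites) and ``targets`` (subjects x
    parameters/characteristics) must be indexed by the same subjects.
    Each pair gets a distance correlation, a Pearson-derived sign, a
    permutation p-value, and a BH q-value adjusted across all pairs of
    the phase; ``retained`` marks edges with dCor >= ``d_threshold`` and
    q <= ``alpha``.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    if abundance.columns.duplicated().any():
        raise ValueError("duplicate metabolite columns")
    if not abundance.index.sort_values().equals(targets.index.sort_values()):
        raise ValueError("subject mismatch between abundance matrix and targets")
    targets = targets.loc[abundance.index]
    classes = dict(target_classes or {})
    n = abundance.shape[0]
    rng = np.random.default_rng(seed)

    # center each metabolite's distance matrix once
    a_centered = {
        met: _centered_distances(abundance[met].to_numpy(dtype=float))
        for met in abundance.columns
    }
    rows = []
    for target in targets.columns:
        y = targets[target].to_numpy(dtype=float)
        d_y = np.abs(y[:, None] - y[None, :])
        # one shared permutation null per target, reused across metabolites
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        bp = d_y[perms[:, :, None], perms[:, None, :]]
        bp -= bp.mean(axis=1, keepdims=True)
        bp -= bp.mean(axis=2, keepdims=True) - bp.mean(axis=(1, 2), keepdims=True)
        dvar_y_perm = (bp * bp).mean(axis=(1, 2))
        for met in abundance.columns:
            x = abundance[met].to_numpy(dtype=float)
            a = a_centered[met]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = distance_correlation(x, y)
                pearson = (
                    stats.pearsonr(x, y).statistic
                    if np.std(x) > 0 and np.std(y) > 0
                    else 0.0
                )
            dvar_x = (a * a).mean()
            if dvar_x <= 0 or np.all(dvar_y_perm <= 0):
                p = 1.0
            else:
                dcov2 = np.einsum("ij,pij->p", a, bp) / (n * n)
                with np.errstate(invalid="ignore", divide="ignore"):
                    null = np.sqrt(np.clip(dcov2 / np.sqrt(dvar_x * dvar_y_perm), 0, 1))
                p = float((1 + np.sum(null >= d - 1e-15)) / (1 + n_perm))
            rows.append(
                {
                    "metabolite_id": met,
                    "target_name": target,
                    "target_class": classes.get(target, "laboratory_serum"),
                    "dcor": d,
                    "sign": "+" if pearson >= 0 else "-",
                    "p_perm": p,
                    "phase": phase,
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(["metabolite_id", "target_name"], kind="stable").reset_index(drop=True)
    if len(table):
        table["q_bh"] = multipletests(table["p_perm"].to_numpy(), method="fdr_bh")[1]
        table["retained"] = (table["dcor"] >= d_threshold) & (table["q_bh"] <= alpha)
    else:
        table["q_bh"] = []
        table["retained"] = []
    return table


def build_tripartite_graph(edges: pd.DataFrame) -> nx.Graph:
    """Weighted undirected graph from retained association edges.

    Metabolites connect PK parameters and characteristics; no edge of
    any other type pair can exist by construction.  Targets that lost
    every edge upstream simply never enter the graph.
    """
    graph = nx.Graph()
    retained = edges[edges["retained"]] if "retained" in edges.columns else edges
    for row in retained.itertuples():
        node_type = _CLASS_TO_NODE_TYPE.get(row.target_class)
        if node_type is None:
            raise ValueError(f"unknown target class {row.target_class!r}")
        graph.add_node(row.metabolite_id, type="metabolite")
        graph.add_node(row.target_name, type=node_type)
        graph.add_edge(
            row.metabolite_id,
            row.target_name,
            weight=float(row.dcor),
            sign=row.sign,
        )
    for u, v in graph.edges:
        types = {graph.nodes[u]["type"], graph.nodes[v]["type"]}
        if "metabolite" not in types or len(types) != 2:
            raise ValueError(f"non-tripartite edge {u!r}-{v!r}")
    return graph


@dataclass
class CommunityPartition:
    """Leiden module assignment with per-module summaries."""

    membership: dict[str, int]
    modules: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modules:
            n = max(self.membership.values(), default=-1) + 1
            self.modules = [set() for _ in range(n)]
            for node, m in self.membership.items():
                self.modules[m].add(node)

    def __len__(self) -> int:
        return len(self.modules)

    def summaries(self, graph: nx.Graph) -> pd.DataFrame:
        rows = []
        for m, members in enumerate(self.modules):
            sub = graph.subgraph(members)
            by_type: dict[str, int] = {}
            for node in members:
                t = graph.nodes[node]["type"]
                by_type[t] = by_type.get(t, 0) + 1
            rows.append(
                {
                    "module": m,
                    "n_nodes": len(members),
                    "n_metabolites": by_type.get("metabolite", 0),
                    "n_pk_parameters": by_type.get("pk_parameter", 0),
                    "n_characteristics": by_type.get("characteristic", 0),
                    "n_edges": sub.number_of_edges(),
                    "members": ";".join(sorted(members)),
                }
            )
        return pd.DataFrame(rows)


def detect_communities(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Leiden community detection on edge weights (dCor magnitudes).

    Uses the RB-configuration objective, which at resolution 1.0 is
    standard modularity.  Module ids are relabeled by decreasing size
    (ties broken by the lexicographically smallest member) so repeated
    seeded runs are stable.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [float(graph.edges[u, v].get("weight", 1.0)) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,  # iterate until no further improvement
    )
    raw_modules = [set(nodes[i] for i in community) for community in partition]
    raw_modules.sort(key=lambda members: (-len(members), min(members)))
    membership = {node: m for m, members in enumerate(raw_modules) for node in members}
    return CommunityPartition(membership=membership, modules=raw_modules)


def network_summary(graph: nx.Graph, partition: CommunityPartition) -> dict[str, int]:
    """Counts mirroring the study-report phrasing: N metabolites related
    to PK parameters and characteristics by E edges forming M modules."""
    by_type: dict[str, int] = {"metabolite": 0, "pk_parameter": 0, "characteristic": 0}
    by_class: dict[str, int] = {}
    for node, data in graph.nodes(data=True):
        by_type[data["type"]] += 1
    return {
        "n_metabolites": by_type["metabolite"],
        "n_pk_parameters": by_type["pk_parameter"],
        "n_characteristics": by_type["characteristic"],
        "n_edges": graph.number_of_edges(),
        "n_modules": len(partition),
    }
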