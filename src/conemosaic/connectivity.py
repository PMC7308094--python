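"""Convergence/divergence statistics of true-S-cone → SCBC wiring.

Contact tables list individual dendritic-branch contacts between S-cone
bipolar cells (SCBCs) and true-S-cone pedicles.  Counting rules:

* blind endings (a dendrite ending on no pedicle) are not counted;
* multiple branch records from the same SCBC branch onto the same pedicle
  collapse to a single contact;
* distinct secondary bifurcations of one SCBC reaching a pedicle count as
  multiple contact sites, but divergence/convergence are computed on
  distinct partners (a pedicle's divergence is the number of different
  SCBCs it touches, and vice versa), so multiplicities are retained only
  as edge annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mosaic_stats import DEFAULT_KNN_RADIUS_UM
from .synthetic_retina import TRUE_S, ConeMosaic

logger = logging.getLogger(__name__)


def collapse_contacts(raw: pd.DataFrame, retina: str | None = None) -> nx.Graph:
    """Collapse raw contact records into a bipartite wiring graph.

    Blind records are dropped.  Per (SCBC, pedicle) pair the edge weight is
    the number of distinct branches reaching that pedicle (minimum 1);
    repeated records from one branch collapse to one.  Missing branch ids
    are treated as a single branch per pair (warning logged).  Idempotent:
    collapsing an already-collapsed edge list changes nothing.
    """
    df = raw.copy()
    required = {"scbc_id", "pedicle_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"contact table needs columns {sorted(required)}")
    if "is_blind" in df.columns:
        df = df[~df["is_blind"].astype(bool)]
    df = df[df["pedicle_id"].notna()]

    if "branch_id" not in df.columns or df["branch_id"].isna().any():
        logger.warning("missing branch ids treated as a single branch per pair")
        if "branch_id" not in df.columns:
            df["branch_id"] = "b?"
        df["branch_id"] = df["branch_id"].fillna("b?")

    g = nx.Graph()
    g.graph["retina"] = retina
    if len(df) == 0:
        return g
    grouped = df.groupby(["scbc_id", "pedicle_id"])["branch_id"].nunique()
    for (scbc, ped), n_branches in grouped.items():
        s = ("scbc", scbc)
        p = ("pedicle", ped)
        g.add_node(s, bipartite="scbc")
        g.add_node(p, bipartite="pedicle")
        g.add_edge(s, p, n_contact_sites=int(max(n_branches, 1)))
    return g


def graph_to_contacts(g: nx.Graph) -> pd.DataFrame:
    """Serialize a collapsed graph back to a contact table (one record per
    distinct contact site).  collapse_contacts(graph_to_contacts(g))
    reproduces g exactly — i.e. collapsing is idempotent."""
    rows = []
    for (a, b), data in g.edges.items():
        scbc = a[1] if a[0] == "scbc" else b[1]
        ped = a[1] if a[0] == "pedicle" else b[1]
        for j in range(data.get("n_contact_sites", 1)):
            rows.append((scbc, ped, f"s{scbc}_p{ped}_b{j}", False))
    return pd.DataFrame(rows, columns=["scbc_id", "pedicle_id", "branch_id", "is_blind"])


@dataclass
class ConnectivityStats:
    """Distinct-partner contact means, averaged per retina then across
    retinas (SD across retinas)."""

    divergence_mean: float  # SCBCs per true-S pedicle
    divergence_sd: float
    convergence_mean: float  # pedicles per SCBC
    convergence_sd: float
    per_retina: pd.DataFrame
    n_pedicles: int
    n_scbcs: int


def _graph_means(g: nx.Graph) -> tuple[float, float, int, int]:
    ped_deg = [d for n, d in g.degree() if n[0] == "pedicle"]
    scbc_deg = [d for n, d in g.degree() if n[0] == "scbc"]
    return (
        float(np.mean(scbc_deg)) if scbc_deg else float("nan"),
        float(np.mean(ped_deg)) if ped_deg else float("nan"),
        len(ped_deg),
        len(scbc_deg),
    )


def connectivity_stats(graphs: nx.Graph | list[nx.Graph]) -> ConnectivityStats:
    """Divergence (mean distinct SCBCs per pedicle) and convergence (mean
    distinct pedicles per SCBC), per retina, then averaged across retinas.

    With a single graph the across-retina SD is NaN.
    """
    if isinstance(graphs, nx.Graph):
        graphs = [graphs]
    if not graphs or all(g.number_of_edges() == 0 for g in graphs):
        raise ValueError("empty wiring graph(s)")
    rows = []
    for i, g in enumerate(graphs):
        conv, div, n_ped, n_scbc = _graph_means(g)
        rows.append(
            {
                "retina": g.graph.get("retina") or f"retina_{i}",
                "divergence": div,
                "convergence": conv,
                "n_pedicles": n_ped,
                "n_scbcs": n_scbc,
            }
        )
    per = pd.DataFrame(rows).set_index("retina")
    return ConnectivityStats(
        divergence_mean=float(per["divergence"].mean()),
        divergence_sd=float(per["divergence"].std(ddof=1)),
        convergence_mean=float(per["convergence"].mean()),
        convergence_sd=float(per["convergence"].std(ddof=1)),
        per_retina=per,
        n_pedicles=int(per["n_pedicles"].sum()),
        n_scbcs=int(per["n_scbcs"].sum()),
    )


def density_ratio(true_s_density: float, scbc_density: float) -> tuple[float, str]:
    """True-S : SCBC density ratio, formatted with the smaller side
    normalized to 1 (e.g. 100 vs 360 cells/mm² → "1:3.6")."""
    if true_s_density <= 0 or scbc_density <= 0:
        raise ValueError("densities must be positive")
    ratio = true_s_density / scbc_density

    def fmt(v: float) -> str:
        s = f"{v:.1f}"
        return s[:-2] if s.endswith(".0") else s

    if ratio >= 1:
        return ratio, f"{fmt(ratio)}:1"
    return ratio, f"1:{fmt(1 / ratio)}"


def true_s_clusters(
    mosaic: ConeMosaic,
    radius_um: float = DEFAULT_KNN_RADIUS_UM,
    min_size: int = 3,
) -> pd.Series:
    """Cluster labels for true S-cones: connected components of the
    within-radius neighbour graph, keeping components of at least
    ``min_size`` cones.  Returns a Series mapping cone id → cluster id."""
    ts = mosaic.of_type(TRUE_S)
    if len(ts) == 0:
        return pd.Series(dtype=int)
    pts = ts[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_um)
    g = nx.Graph()
    g.add_nodes_from(range(len(ts)))
    g.add_edges_from(pairs)
    ids = ts["id"].to_numpy()
    labels = {}
    cluster = 0
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        for i in comp:
            labels[int(ids[i])] = cluster
        cluster += 1
    return pd.Series(labels, dtype=int, name="cluster")


def cluster_convergence(
    mosaic: ConeMosaic, graph: nx.Graph, cluster_labels: pd.Series
) -> pd.DataFrame:
    """Per true-S cluster, the SCBCs contacting at least two of its
    pedicles, and whether a majority of the cluster shares one SCBC.

    Returns a table: cluster, n_pedicles, scbc, n_shared, majority.
    Clusters with no SCBC shared by ≥ 2 pedicles yield no rows.
    """
    rows = []
    for cluster in sorted(set(cluster_labels.values)):
        ped_ids = [pid for pid, c in cluster_labels.items() if c == cluster]
        counts: dict = {}
        for pid in ped_ids:
            node = ("pedicle", pid)
            if node not in graph:
                continue
            for scbc_node in graph.neighbors(node):
                counts[scbc_node[1]] = counts.get(scbc_node[1], 0) + 1
        for scbc, n_shared in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0]))):
            if n_shared < 2:
                continue
            rows.append(
                {
                    "cluster": cluster,
                    "n_pedicles": len(ped_ids),
                    "scbc": scbc,
                    "n_shared": n_shared,
                    "majority": n_shared > len(ped_ids) / 2,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "n_pedicles", "scbc", "n_shared", "majority"])
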