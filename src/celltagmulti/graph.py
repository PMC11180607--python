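"""Clone-cell graphs and subclone-level spatial statistics.

For joint 2-D embedding of cells and clones, a cell-cell kNN similarity
graph is augmented with one abstract node per clone (or subclone) connected
to each of its member cells; layout engines (UMAP graph layout, ForceAtlas)
then place clone nodes amid their members. The cell-cell edges are never
modified, so the embedding of cells is anchored by the original graph.

Subclones split each clone by (time point, assay) — up to four pieces in a
two-time-point, two-assay design. Two statistics operate on subclone-node
coordinates in an embedding:

* Wasserstein overlap between RNA and ATAC subclone clouds, within and
  across fate groups (agreement of the two modalities' clonal geometry);
* a closeness-vs-fate-bias percentile curve: subclones far from every
  alternative fate group's centroid (high "closeness" metric) should show
  higher fate bias if position in state space encodes fate commitment.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .clones import CloneTable
from .ot import wasserstein_distance

CLONE_PREFIX = "clone:"
SUBCLONE_PREFIX = "subclone:"


def read_knn_edges(path: str | Path) -> nx.Graph:
    """Read a weighted edge-list TSV ``node_a  node_b  weight`` into a Graph."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, weight=float(row.weight))
    return g


def write_knn_edges(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as an edge-list TSV (inverse of :func:`read_knn_edges`)."""
    rows = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def build_clone_cell_graph(
    knn: nx.Graph,
    memberships: Mapping[str, Iterable[str]],
    weight_rule: str = "mean_incident",
    fixed_weight: float = 1.0,
    node_prefix: str = CLONE_PREFIX,
) -> nx.Graph:
    """Add abstract clone/subclone nodes and clone-cell edges to a kNN graph.

    ``memberships`` maps a clone/subclone identifier to its member cells
    (all of which must be nodes of ``knn``). Each abstract node gets one
    edge per member; the weight is the mean of that cell's incident kNN
    edge weights (``mean_incident``, keeps clone edges on the same scale as
    the similarities around the cell) or a constant (``fixed``). Cell-cell
    edges are copied untouched.
    """
    if weight_rule not in ("mean_incident", "fixed"):
        raise ValueError(f"unknown weight_rule {weight_rule!r}")
    g = nx.Graph()
    g.add_nodes_from((n, {"node_type": "cell"}) for n in knn.nodes)
    g.add_edges_from((u, v, dict(d)) for u, v, d in knn.edges(data=True))
    for clone, members in memberships.items():
        node = f"{node_prefix}{clone}"
        g.add_node(node, node_type="clone")
        for cell in members:
            if cell not in knn:
                raise ValueError(f"member cell {cell!r} absent from kNN graph")
            if weight_rule == "fixed":
                w = fixed_weight
            else:
                incident = [d.get("weight", 1.0) for _, _, d in knn.edges(cell, data=True)]
                w = float(np.mean(incident)) if incident else fixed_weight
            g.add_edge(node, cell, weight=w)
    return g


def cell_subgraph(g: nx.Graph) -> nx.Graph:
    """The induced subgraph on cell nodes (drops clone/subclone nodes).

    Node annotations added during augmentation are stripped, so the result
    compares equal to the original kNN graph.
    """
    cells = [n for n, d in g.nodes(data=True) if d.get("node_type", "cell") == "cell"]
    out = nx.Graph()
    out.add_nodes_from(cells)
    out.add_edges_from(
        (u, v, dict(d)) for u, v, d in g.subgraph(cells).edges(data=True)
    )
    return out


def split_subclones(clones: CloneTable, keys: tuple[str, ...] = ("time_point", "modality")) -> pd.DataFrame:
    """Partition each clone into subclones by metadata keys.

    Returns a tidy frame ``subclone_id, clone_id, <keys...>, cell``; empty
    key combinations produce no subclone, so a 2x2 design yields at most
    four subclones per clone.
    """
    df = clones.cells
    for key in keys:
        if df[key].isna().any():
            missing = df.loc[df[key].isna(), "cell"].tolist()
            raise ValueError(f"cells missing {key!r}: {missing[:5]}")
    rows = []
    for (cid, *vals), grp in df.groupby(["clone_id", *keys], sort=True):
        sub_id = ".".join([str(cid), *map(str, vals)])
        for cell in grp["cell"]:
            rows.append((sub_id, cid, *vals, cell))
    return pd.DataFrame(rows, columns=["subclone_id", "clone_id", *keys, "cell"])


def subclone_overlap(
    coords: pd.DataFrame,
    groups: pd.DataFrame,
    order: int = 1,
) -> pd.DataFrame:
    """Wasserstein distances between per-(modality, fate group) subclone clouds.

    ``coords``: subclone embedding, one row per subclone (any
    dimensionality; 30-D in the reference workflow). ``groups``: frame
    indexed like ``coords`` with columns ``modality`` and ``fate_group``.
    Returns one row per (RNA fate group, ATAC fate group) pair with the
    exact Wasserstein distance between the two clouds and a
    ``comparison`` column: ``intra`` when the fate groups match (same
    lineage seen by the two assays) else ``inter``. Five fate groups yield
    5 intra- and 20 inter-lineage values.
    """
    for col in ("modality", "fate_group"):
        if col not in groups.columns:
            raise ValueError(f"groups frame needs column {col!r}")
    clouds: dict[tuple[str, str], np.ndarray] = {}
    for (mod, fg), idx in groups.groupby(["modality", "fate_group"]).groups.items():
        pts = coords.loc[idx].to_numpy(dtype=float)
        if len(pts) == 0:
            raise ValueError(f"empty subclone group ({mod}, {fg})")
        clouds[(str(mod), str(fg))] = pts
    rna_groups = sorted(fg for m, fg in clouds if m == "RNA")
    atac_groups = sorted(fg for m, fg in clouds if m == "ATAC")
    rows = []
    for fg_r in rna_groups:
        for fg_a in atac_groups:
            d = wasserstein_distance(clouds[("RNA", fg_r)], clouds[("ATAC", fg_a)], order)
            rows.append(
                (fg_r, fg_a, "intra" if fg_r == fg_a else "inter", d)
            )
    return pd.DataFrame(
        rows, columns=["rna_fate_group", "atac_fate_group", "comparison", "distance"]
    )


def closeness_fatebias_curve(
    coords: pd.DataFrame,
    fate_group: pd.Series,
    fate_bias: pd.Series,
    centroids: pd.DataFrame | None = None,
    percentiles: np.ndarray | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Closeness metric per state subclone and its fate-bias percentile curve.

    closeness(s) = min over fate groups g != group(s) of the Euclidean
    distance from s to centroid_g. A *larger* value means the subclone sits
    farther from every alternative fate territory. The curve reports, for
    each percentile rank p of the closeness metric, the mean fate bias over
    subclones at or above that rank; at p = 0 this is the overall mean.

    ``centroids`` (per-fate-group mean coordinates) defaults to the
    centroids of the provided subclones themselves.
    """
    groups = fate_group.astype(str)
    unique_groups = sorted(groups.unique())
    if len(unique_groups) < 2:
        raise ValueError("need >= 2 fate groups for a closeness metric")
    X = coords.to_numpy(dtype=float)
    if centroids is None:
        centroids = coords.groupby(groups).mean()
    cent = centroids.loc[unique_groups].to_numpy(dtype=float)
    closeness = pd.Series(index=coords.index, dtype=float, name="closeness")
    for i, idx in enumerate(coords.index):
        others = [j for j, g in enumerate(unique_groups) if g != groups.loc[idx]]
        d = np.linalg.norm(cent[others] - X[i], axis=1)
        closeness.loc[idx] = float(d.min())
    if percentiles is None:
        percentiles = np.arange(0, 100, 5)
    rows = []
    bias = fate_bias.astype(float)
    for p in percentiles:
        thresh = float(np.percentile(closeness, p))
        mask = closeness >= thresh
        rows.append((float(p), thresh, float(bias[mask].mean()), int(mask.sum())))
    curve = pd.DataFrame(
        rows, columns=["percentile", "closeness_threshold", "mean_fate_bias", "n_subclones"]
    )
    return closeness, curve
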