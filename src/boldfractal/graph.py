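"""Node centrality measures, synthetic-lesioning robustness (delta
efficiency), z-scoring and contralateral homologue ratios for weighted
functional networks.

Path-based measures map edge weight w to length 1/w (stronger connections
are shorter), the standard convention for weighted efficiency and
betweenness.  Delta efficiency removes a node and all of its connections
and reports the percentage change in global efficiency — by default on the
reduced (n-1)-node graph; the alternative convention (keep the node as an
isolate) is exposed via ``lesion_convention="isolate"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .parcellate import Parcellation

BASE_METRICS = (
    "strength",
    "nodal_efficiency",
    "betweenness",
    "within_module_z",
    "participation",
    "eigenvector",
    "delta_efficiency",
)


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(W < 0):
        raise ValueError("negative weights not supported")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weights must be symmetric")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def _length_matrix(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_path_lengths(W: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths with length = 1/weight;
    unreachable pairs are +inf."""
    return dijkstra(_length_matrix(W), directed=False)


def global_efficiency(W: np.ndarray) -> float:
    """Mean over ordered node pairs of 1 / shortest-path length
    (unreachable pairs contribute 0)."""
    W = _check_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    D = shortest_path_lengths(W)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(W: np.ndarray) -> np.ndarray:
    """Per-node mean of 1/d(i, j) over the other nodes — the node's
    contribution to global efficiency."""
    W = _check_weights(W)
    D = shortest_path_lengths(W)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return inv.sum(axis=1) / (W.shape[0] - 1)


def delta_efficiency(
    W: np.ndarray, node: int, lesion_convention: str = "reduced"
) -> float:
    """Percentage change in global efficiency after synthetically lesioning
    ``node`` (removing it and all its connections).

    ``reduced`` recomputes efficiency on the (n-1)-node graph; ``isolate``
    keeps the node in place with all edges zeroed.  Returns NaN when the
    intact efficiency is 0 (flagged, not raised).
    """
    W = _check_weights(W)
    if W.shape[0] < 3:
        raise ValueError("delta efficiency needs >= 3 nodes")
    e_intact = global_efficiency(W)
    if e_intact == 0:
        warnings.warn("intact efficiency is 0; delta undefined", stacklevel=2)
        return np.nan
    if lesion_convention == "reduced":
        keep = np.ones(W.shape[0], dtype=bool)
        keep[node] = False
        lesioned = W[np.ix_(keep, keep)]
    elif lesion_convention == "isolate":
        lesioned = W.copy()
        lesioned[node, :] = 0.0
        lesioned[:, node] = 0.0
    else:
        raise ValueError("lesion_convention must be 'reduced' or 'isolate'")
    e_les = global_efficiency(lesioned)
    return 100.0 * (e_les - e_intact) / e_intact


def betweenness(W: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness centrality (Brandes, length = 1/w);
    pairs are counted once (undirected)."""
    W = _check_weights(W)
    G = nx.from_numpy_array(np.where(W > 0, W, 0.0))
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


def eigenvector_centrality(W: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the weight matrix, non-negative, unit L2
    norm (Perron vector)."""
    W = _check_weights(W)
    vals, vecs = np.linalg.eigh(W)
    v = vecs[:, np.argmax(vals)]
    if v.sum() < 0:
        v = -v
    return np.abs(v) / np.linalg.norm(v)


def strength(W: np.ndarray) -> np.ndarray:
    return _check_weights(W).sum(axis=1)


def within_module_z(W: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Within-module degree z-score: each node's within-module strength,
    standardized within its module (population SD; degenerate modules give 0)."""
    W = _check_weights(W)
    partition = np.asarray(partition)
    z = np.zeros(W.shape[0])
    for m in np.unique(partition):
        members = partition == m
        kappa = W[np.ix_(members, members)].sum(axis=1)
        sd = kappa.std()
        z[members] = (kappa - kappa.mean()) / sd if sd > 0 else 0.0
    return z


def participation_coefficient(W: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient ``1 - sum_m (k_im / k_i)^2``; zero-strength
    nodes get 0."""
    W = _check_weights(W)
    partition = np.asarray(partition)
    k = W.sum(axis=1)
    frac_sq = np.zeros(W.shape[0])
    for m in np.unique(partition):
        k_im = W[:, partition == m].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_sq += np.where(k > 0, (k_im / k) ** 2, 0.0)
    return np.where(k > 0, 1.0 - frac_sq, 0.0)


def detect_modules(W: np.ndarray, seed: int = 0) -> np.ndarray:
    """Modularity-maximizing partition (Louvain) with a fixed seed, used when
    no partition is supplied for the module-based measures."""
    W = _check_weights(W)
    G = nx.from_numpy_array(np.where(W > 0, W, 0.0))
    communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
    labels = np.empty(W.shape[0], dtype=int)
    for m, nodes in enumerate(communities):
        labels[list(nodes)] = m
    return labels


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    out = np.full_like(x, np.nan)
    sd = x[ok].std(ddof=0)
    if sd > 0:
        out[ok] = (x[ok] - x[ok].mean()) / sd
    else:
        out[ok] = 0.0
    return out


def node_centralities(
    W: np.ndarray,
    partition: np.ndarray | None = None,
    parcel_ids: np.ndarray | None = None,
    lesion_convention: str = "reduced",
    partition_seed: int = 0,
) -> pd.DataFrame:
    """All pre-hoc centrality measures plus delta efficiency per node, with
    z-scored variants (``*_z`` columns, standardized across nodes).

    When no module partition is supplied one is derived by seeded modularity
    maximization (and recorded in ``DataFrame.attrs['partition']``).
    """
    W = _check_weights(W)
    n = W.shape[0]
    if partition is None:
        partition = detect_modules(W, seed=partition_seed)
    partition = np.asarray(partition)
    if partition.shape != (n,):
        raise ValueError("partition length must equal node count")

    table = pd.DataFrame(
        {
            "id": np.arange(n) if parcel_ids is None else np.asarray(parcel_ids),
            "strength": strength(W),
            "nodal_efficiency": nodal_efficiency(W),
            "betweenness": betweenness(W),
            "within_module_z": within_module_z(W, partition),
            "participation": participation_coefficient(W, partition),
            "eigenvector": eigenvector_centrality(W),
            "delta_efficiency": np.array(
                [delta_efficiency(W, i, lesion_convention) for i in range(n)]
            ),
        }
    )
    for col in BASE_METRICS:
        table[col + "_z"] = _zscore(table[col].to_numpy())
    table.attrs["partition"] = partition
    table.attrs["lesion_convention"] = lesion_convention
    return table


def homologue_ratio(
    metrics: pd.DataFrame, parc: Parcellation, columns: tuple[str, ...] = BASE_METRICS
) -> pd.DataFrame:
    """Express each metric as a ratio over its value in the homologous
    contralateral node (``*_ratio`` columns); unpaired nodes, nodes whose
    homologue is absent from the table (e.g. removed for tumor overlap), and
    zero denominators yield NaN."""
    table = metrics.copy()
    pairing = parc.table.set_index("id")["homologue_id"]
    idx = pd.Index(table["id"])
    for col in columns:
        vals = table.set_index("id")[col]
        ratios = np.full(len(table), np.nan)
        for row, pid in enumerate(table["id"]):
            hid = pairing.get(pid, -1)
            if hid != -1 and hid in idx:
                denom = vals.loc[hid]
                if np.isfinite(denom) and denom != 0:
                    ratios[row] = vals.loc[pid] / denom
        table[col + "_ratio"] = ratios
    return table
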