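"""Node-level and whole-graph quantification of directed weighted networks.

Edge weights are the (nonnegative) Granger-causality values F_{i->j}.  Node
strength splits into in-strength (column sums) and out-strength (row sums);
the weighted clustering coefficient is evaluated on the symmetrized matrix;
path-based metrics use per-edge distances 1/w with shortest directed paths,
treating absent edges (w = 0) as unreachable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMetrics",
    "node_strength",
    "clustering_w",
    "weight_to_distance",
    "global_efficiency",
    "char_path_length",
    "retain_top_fraction",
    "aggregate_by_network",
    "metrics_table",
]


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero")
    return w


def node_strength(weights: np.ndarray) -> tuple:
    """(S_in, S_out, S_total): column sums, row sums, and their sum."""
    w = _check_weights(weights)
    s_in = w.sum(axis=0)
    s_out = w.sum(axis=1)
    return s_in, s_out, s_in + s_out


def clustering_w(weights: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient per node on the symmetrized matrix.

    C_i = sum_{j,k} w_ij w_ik w_jk / sum_{j != k} w_ij w_ik, with w the
    symmetrized weights (w_ij + w_ji)/2; zero where the denominator is zero.
    With a zero diagonal the numerator is the i-th diagonal of w^3 and the
    denominator is (sum_j w_ij)^2 - sum_j w_ij^2.
    """
    w = _check_weights(weights)
    s = (w + w.T) / 2.0
    num = np.diagonal(s @ s @ s).copy()
    row = s.sum(axis=1)
    denom = row**2 - (s**2).sum(axis=1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def weight_to_distance(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest directed path lengths under per-edge distances 1/w.

    An edge of weight w contributes distance 1/w; absent edges (w = 0) are
    unreachable directly.  Entry (i, j) is the minimal summed distance of any
    directed path i -> j (inf when unreachable, 0 on the diagonal).
    """
    w = _check_weights(weights)
    n = w.shape[0]
    src, tgt = np.nonzero(w)
    graph = csr_array((1.0 / w[src, tgt], (src, tgt)), shape=(n, n))
    return dijkstra(graph, directed=True)


def global_efficiency(weights: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    Unreachable pairs contribute 1/inf = 0, so the metric stays finite on
    disconnected (e.g. heavily thresholded) networks.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    d = weight_to_distance(w)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    reach = np.isfinite(d) & off
    inv[reach] = 1.0 / d[reach]
    return float(inv[off].sum() / (n * (n - 1)))


def char_path_length(weights: np.ndarray) -> tuple:
    """(L, connected): mean shortest-path distance over reachable pairs.

    On disconnected graphs the average runs over reachable ordered pairs only
    and ``connected`` is False; with no reachable pair at all L is NaN.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    d = weight_to_distance(w)
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(d) & off
    n_reach = int(reach.sum())
    connected = n_reach == n * (n - 1)
    if n_reach == 0:
        return float("nan"), False
    return float(d[reach].mean()), connected


def retain_top_fraction(weights: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Keep the ceil(fraction * nnz) largest off-diagonal weights, zero the rest.

    Ties at the cutoff are all retained, so the result does not depend on
    any internal ordering of equal weights.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    w = _check_weights(weights).copy()
    vals = w[w > 0]
    if vals.size == 0:
        return w
    k = math.ceil(fraction * vals.size)
    cutoff = np.sort(vals)[::-1][k - 1]
    w[w < cutoff] = 0.0
    return w


def aggregate_by_network(values: np.ndarray, networks) -> dict:
    """Unweighted mean of a per-node quantity within each intrinsic network.

    ``networks`` maps node index order to network labels (sequence aligned
    with ``values``).  Networks with zero members are omitted with a warning.
    """
    values = np.asarray(values, dtype=float)
    networks = np.asarray(networks)
    if values.shape[0] != networks.shape[0]:
        raise ValueError("values and network labels must align")
    out = {}
    for net in dict.fromkeys(networks):
        member = networks == net
        if not member.any():  # pragma: no cover - dict.fromkeys guards this
            logger.warning("network %s has no member nodes; omitted", net)
            continue
        out[str(net)] = float(values[member].mean())
    return out


@dataclass
class NodeMetrics:
    """Per-node strengths/clustering plus whole-graph efficiency and path length."""

    s_in: np.ndarray
    s_out: np.ndarray
    s_total: np.ndarray
    clustering: np.ndarray
    e_global: float
    path_length: float
    connected: bool
    network_strength: dict

    @classmethod
    def from_weights(cls, weights: np.ndarray, networks=None) -> "NodeMetrics":
        s_in, s_out, s_total = node_strength(weights)
        length, connected = char_path_length(weights)
        return cls(
            s_in=s_in,
            s_out=s_out,
            s_total=s_total,
            clustering=clustering_w(weights),
            e_global=global_efficiency(weights),
            path_length=length,
            connected=connected,
            network_strength=(
                aggregate_by_network(s_total, networks) if networks is not None else {}
            ),
        )


def metrics_table(gc_long: pd.DataFrame, atlas: pd.DataFrame) -> pd.DataFrame:
    """Long metric table from the GC long-format edge list.

    One row per (subject, band, condition, window, unit, metric): node-level
    strengths and clustering, network-level mean total strength, and the two
    graph-level metrics.  ``atlas`` maps channel index order to intrinsic
    networks via its row order.
    """
    networks = atlas["network"].to_numpy()
    n_ch = len(atlas)
    rows = []
    keys = ["subject", "group", "band", "condition", "window"]
    for cell, df in gc_long.groupby(keys, sort=False):
        w = np.zeros((n_ch, n_ch))
        w[df["source"].to_numpy(), df["target"].to_numpy()] = df["F"].to_numpy()
        m = NodeMetrics.from_weights(w, networks)
        base = dict(zip(keys, cell))
        for i in range(n_ch):
            for metric, vec in (
                ("s_in", m.s_in),
                ("s_out", m.s_out),
                ("s_total", m.s_total),
                ("clustering", m.clustering),
            ):
                rows.append(
                    {**base, "unit": "node", "unit_id": atlas["channel_name"].iloc[i],
                     "network": networks[i], "metric": metric, "value": vec[i]}
                )
        for net, val in m.network_strength.items():
            rows.append(
                {**base, "unit": "network", "unit_id": net, "network": net,
                 "metric": "network_strength", "value": val}
            )
        for metric, val in (
            ("global_efficiency", m.e_global),
            ("char_path_length", m.path_length),
        ):
            rows.append(
                {**base, "unit": "graph", "unit_id": "graph", "network": None,
                 "metric": metric, "value": val}
            )
    return pd.DataFrame(rows)
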