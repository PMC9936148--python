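"""Relative wavelet-packet energy entropy and per-trial brain networks.

Each channel's signal is decomposed three levels deep; the component
energies (three detail levels plus the deepest approximation) are
normalized into a distribution P whose Shannon entropy S is the channel's
energy-entropy feature. Channels become graph nodes; edge weights are the
similarity exp(-D) of the two channels' energy distributions under
symmetrized Kullback-Leibler divergence D, the graph is sparsified to a
fixed edge density (default 30%), and degree, clustering, nodal efficiency
and matrix norms of the result are the topology features.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._wavelets import wavedec
from .epochs import EpochSet
from .features import FeatureMatrix, MinMaxScaler

__all__ = [
    "EnergyProfile",
    "BrainNetwork",
    "TopologyFeatures",
    "wavelet_energy",
    "relative_energy",
    "channel_energy_profiles",
    "edge_weight",
    "build_network",
    "topology_features",
    "fuse_features",
    "network_feature_block",
]

_COMPONENTS = ("A3", "D3", "D2", "D1")


@dataclass
class EnergyProfile:
    """Per-channel component energies E, relative energies P, entropy S."""

    E: np.ndarray  # (n_channels, 4)
    P: np.ndarray  # (n_channels, 4), rows on the simplex
    S: np.ndarray  # (n_channels,)
    components: tuple[str, ...] = _COMPONENTS


@dataclass
class BrainNetwork:
    similarity: np.ndarray  # symmetric, zero diagonal
    adjacency: np.ndarray  # binary symmetric
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.similarity.shape[0]


@dataclass
class TopologyFeatures:
    degree: np.ndarray  # k_i, counts both edge directions
    clustering: np.ndarray
    efficiency: np.ndarray
    norm1: float
    norm_spectral: float


def wavelet_energy(signal: np.ndarray, wavelet_name: str = "db10", levels: int = 3) -> np.ndarray:
    """Component energies of one channel's signal.

    Detail levels contribute their L2 norm; the deepest approximation
    contributes the mean of its absolute coefficients (the approximation
    carries the dominant low-frequency mass of EEG, so averaging keeps it
    on a comparable scale). Order: [A_levels, D_levels, ..., D1].
    """
    coeffs = wavedec(np.asarray(signal, dtype=float), wavelet_name, levels)
    e = np.empty(levels + 1)
    e[0] = np.mean(np.abs(coeffs[0]))
    for i, d in enumerate(coeffs[1:], start=1):
        e[i] = np.linalg.norm(d)
    return e


def relative_energy(E: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize component energies to a distribution P and return its
    Shannon entropy S = -sum P ln P (0 ln 0 := 0)."""
    E = np.asarray(E, dtype=float)
    total = E.sum()
    if total <= 0:
        raise ValueError("degenerate channel: all component energies are zero")
    P = E / total
    nz = P > 0
    S = float(-np.sum(P[nz] * np.log(P[nz])))
    return P, S


def channel_energy_profiles(trial: np.ndarray, wavelet_name: str = "db10", levels: int = 3) -> EnergyProfile:
    """EnergyProfile for one trial's (n_channels, n_samples) block."""
    E = np.stack([wavelet_energy(ch, wavelet_name, levels) for ch in trial])
    P = np.empty_like(E)
    S = np.empty(E.shape[0])
    for i in range(E.shape[0]):
        P[i], S[i] = relative_energy(E[i])
    comps = tuple([f"A{levels}"] + [f"D{j}" for j in range(levels, 0, -1)])
    return EnergyProfile(E, P, S, comps)


def edge_weight(P_m: np.ndarray, P_n: np.ndarray, floor: float = 1e-12) -> float:
    """Similarity of two energy distributions: exp(-D) in (0, 1] with D the
    symmetrized KL divergence, components floored before the logs."""
    P_m, P_n = np.asarray(P_m, float), np.asarray(P_n, float)
    if P_m.shape != P_n.shape:
        raise ValueError("distributions must have equal length")
    p = np.maximum(P_m, floor)
    q = np.maximum(P_n, floor)
    d = 0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
    return float(np.exp(-d))


def build_network(profile: EnergyProfile, sparsity: float = 0.30) -> BrainNetwork:
    """Sparsify the pairwise-similarity graph to a fixed edge density.

    The top ceil(sparsity * n(n-1)/2) node pairs by similarity are kept
    (ties resolved by lexicographic pair order); any node left isolated then
    gets back its single strongest incident edge.
    """
    n = profile.P.shape[0]
    if n < 3:
        raise ValueError("build_network needs at least 3 channels")
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = edge_weight(profile.P[i], profile.P[j])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_keep = int(np.ceil(sparsity * len(pairs)))
    ranked = sorted(pairs, key=lambda ij: (-sim[ij], ij))
    adj = np.zeros((n, n), dtype=int)
    for i, j in ranked[:n_keep]:
        adj[i, j] = adj[j, i] = 1
    for i in np.flatnonzero(adj.sum(axis=1) == 0):  # repair isolated nodes
        j = int(np.argmax(sim[i]))
        adj[i, j] = adj[j, i] = 1
    return BrainNetwork(sim, adj, sparsity)


def topology_features(net: BrainNetwork) -> TopologyFeatures:
    """Degree, clustering, nodal efficiency, and norms of the weighted graph.

    Degree counts both edge directions (k_i = 2 x neighbor count on the
    symmetric adjacency). Clustering is t_i / (k_i (k_i - 1)) with t_i the
    triangles through node i, zero when k_i <= 1. Distances are unweighted
    shortest-path hops (BFS); unreachable pairs count n_nodes hops; nodal
    efficiency is (n-1) / sum_j d_ij. The 1-norm (max absolute column sum)
    and spectral norm are taken on the thresholded weighted matrix
    similarity * adjacency.
    """
    A = net.adjacency
    n = net.n_nodes
    deg = A.sum(axis=1)
    k = 2 * deg  # both directions
    G = nx.from_numpy_array(A)
    tri = np.array([nx.triangles(G, i) for i in range(n)], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        clustering = np.where(k > 1, tri / (k * (k - 1.0)), 0.0)
    dist = np.full((n, n), float(n))
    for i, dmap in nx.all_pairs_shortest_path_length(G):
        for j, d in dmap.items():
            dist[i, j] = d
    np.fill_diagonal(dist, 0.0)
    sums = dist.sum(axis=1)
    efficiency = np.where(sums > 0, (n - 1.0) / sums, 0.0)
    W = net.similarity * A
    norm1 = float(np.abs(W).sum(axis=0).max()) if n else 0.0
    norm_spec = float(np.linalg.norm(W, 2)) if A.any() else 0.0
    return TopologyFeatures(k.astype(float), clustering, efficiency, norm1, norm_spec)


def network_feature_block(
    epochs: EpochSet,
    wavelet_name: str = "db10",
    levels: int = 3,
    sparsity: float = 0.30,
) -> FeatureMatrix:
    """Per-trial entropy + topology features for all channels of ``epochs``.

    Columns: S per channel, degree/clustering/efficiency per node, then the
    two matrix norms. Channel names flow into the feature names so planted
    structure stays traceable after selection.
    """
    rows = []
    ch = epochs.channel_names
    for t in range(epochs.n_trials):
        prof = channel_energy_profiles(epochs.data[t], wavelet_name, levels)
        net = build_network(prof, sparsity)
        topo = topology_features(net)
        rows.append(np.concatenate([
            prof.S, topo.degree, topo.clustering, topo.efficiency,
            [topo.norm1, topo.norm_spectral],
        ]))
    names = (
        [f"S_{c}" for c in ch]
        + [f"deg_{c}" for c in ch]
        + [f"clust_{c}" for c in ch]
        + [f"eff_{c}" for c in ch]
        + ["norm1", "norm_spectral"]
    )
    return FeatureMatrix(np.vstack(rows), names)


def fuse_features(
    blocks: list[FeatureMatrix],
    scaler: MinMaxScaler | None = None,
) -> tuple[FeatureMatrix, MinMaxScaler]:
    """Concatenate feature blocks and min-max scale columns to [0, 1].

    Pass a fitted ``scaler`` to apply training-set scaling to test trials;
    otherwise a new scaler is fitted on the given (training) trials.
    Constant columns map to 0; out-of-range test values scale past [0, 1]
    without clipping.
    """
    fused = FeatureMatrix.hstack(blocks)
    if scaler is None:
        scaler = MinMaxScaler().fit(fused)
    return scaler.transform(fused), scaler
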