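"""Pearson-correlation functional networks and binary graph metrics.

A band-filtered multichannel recording yields a channels x channels Pearson
correlation matrix; thresholding it (edge present iff r >= threshold, i != j)
gives a binary undirected graph whose node degree k_i and clustering
coefficient C_i = 2*E_i / (k_i*(k_i-1)) are the reported features (E_i =
edges among node i's neighbours; C_i defined as 0 for k_i < 2).

Thresholds are study-level settings (the working-memory analysis used
0.32/0.56 for delta/gamma, the stimulation contrast 0.43/0.67);
``select_threshold`` offers the stated data-driven criteria — no isolated
nodes and a density inside a configured range — on a 0.01 grid for new data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import Band, FEATURE_COLUMNS, Recording

__all__ = [
    "CorrelationMatrix",
    "BinaryNetwork",
    "correlation_matrix",
    "binarize",
    "select_threshold",
    "network_features",
    "edges_dataframe",
]

#: pseudo-channel label used for whole-network mean rows in feature tables
NETWORK_MEAN_CHANNEL = "_network_"


@dataclass
class CorrelationMatrix:
    r: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]
    channels: list[str]
    band: Band | None = None


@dataclass
class BinaryNetwork:
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    threshold: float
    channels: list[str]
    degree: np.ndarray = field(init=False)
    clustering: np.ndarray = field(init=False)
    density: float = field(init=False)

    def __post_init__(self) -> None:
        a = self.adjacency
        n = a.shape[0]
        if a.shape != (n, n) or not np.array_equal(a, a.T) or a.diagonal().any():
            raise ValueError("adjacency must be square, symmetric and hollow")
        self.degree = a.sum(axis=1).astype(int)
        g = nx.from_numpy_array(a)
        clust = nx.clustering(g)
        self.clustering = np.array([clust[i] for i in range(n)])
        self.density = float(a.sum() / (n * (n - 1))) if n > 1 else 0.0


def correlation_matrix(rec: Recording, band: Band | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation over the full time course."""
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sd = rec.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [rec.channels[i] for i in dead]
        raise ValueError(f"zero-variance channel(s): {names}")
    r = np.corrcoef(rec.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, channels=list(rec.channels), band=band)


def binarize(
    cm: CorrelationMatrix, threshold: float, absolute: bool = False
) -> BinaryNetwork:
    """Edge (i, j) present iff r_ij >= threshold (|r_ij| if ``absolute``)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    r = np.abs(cm.r) if absolute else cm.r
    adj = (r >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adjacency=adj, threshold=threshold, channels=list(cm.channels))


def select_threshold(
    cm: CorrelationMatrix,
    density_range: tuple[float, float] = (0.05, 0.45),
    absolute: bool = False,
) -> float:
    """Largest 0.01-grid threshold with no isolated node and in-range density.

    If no grid value satisfies both criteria, falls back (with a warning) to
    the largest threshold leaving no isolated node; raises if even that is
    impossible (fully uncorrelated input).
    """
    lo, hi = density_range
    if not (0 < lo < hi <= 1):
        raise ValueError("density_range must satisfy 0 < lo < hi <= 1")
    grid = np.round(np.arange(0.99, 0.0, -0.01), 2)
    fallback = None
    for thr in grid:
        net = binarize(cm, float(thr), absolute)
        if net.degree.min() == 0:
            continue
        if fallback is None:
            fallback = float(thr)
        if lo <= net.density <= hi:
            return float(thr)
    if fallback is not None:
        warnings.warn(
            f"no threshold gives density in {density_range}; using {fallback} "
            "(no-isolated-node criterion only)",
            stacklevel=2,
        )
        return fallback
    raise ValueError("no threshold on the 0.01 grid leaves every node connected")


def network_features(
    net: BinaryNetwork,
    subject_id: str,
    group: str,
    state: str,
    band_name: str,
) -> pd.DataFrame:
    """Per-channel degree/clustering rows plus whole-network mean rows.

    Mean rows carry the pseudo-channel label `_network_` so that per-channel
    statistics can exclude them by prefix.
    """
    rows = []
    for ch, k, c in zip(net.channels, net.degree, net.clustering):
        rows.append((subject_id, group, state, ch, "degree", band_name, float(k)))
        rows.append((subject_id, group, state, ch, "clustering", band_name, float(c)))
    rows.append(
        (subject_id, group, state, NETWORK_MEAN_CHANNEL, "degree", band_name,
         float(net.degree.mean()))
    )
    rows.append(
        (subject_id, group, state, NETWORK_MEAN_CHANNEL, "clustering", band_name,
         float(net.clustering.mean()))
    )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def edges_dataframe(net: BinaryNetwork) -> pd.DataFrame:
    """Edge list (channel_a, channel_b), upper triangle, label order."""
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    return pd.DataFrame(
        {
            "channel_a": [net.channels[i] for i in ii],
            "channel_b": [net.channels[j] for j in jj],
        }
    )
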