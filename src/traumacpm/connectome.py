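"""Functional connectomes from node time series.

A connectome is the matrix of pairwise Pearson correlations between node
BOLD time series, Fisher z-transformed (z = arctanh r).  Each subject
contributes one connectome per valid scan; scans are averaged elementwise
into a single subject connectome.  Models downstream never see the matrix
itself, only its vectorized upper triangle ("edges").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Correlations are clipped to +/-(1 - CLIP_MARGIN) before arctanh so that
#: numerically perfect correlations stay finite.
CLIP_MARGIN = 1e-7

SCAN_LABELS = ("rest", "face_matching", "srdc")


@dataclass
class NodeTimeSeries:
    """T x N matrix of BOLD values for one subject-scan."""

    subject_id: str
    scan_label: str
    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 nodes, got {n}")
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match number of columns")
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")


@dataclass
class Connectome:
    """Symmetric N x N Fisher-z connectivity matrix, zero diagonal."""

    subject_id: str
    z: np.ndarray
    n_scans_averaged: int = 1
    node_ids: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, E = N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def compute_connectome(ts: NodeTimeSeries, clip: float = CLIP_MARGIN) -> Connectome:
    """Correlate all node pairs and Fisher-transform each edge.

    Raises if any node has zero temporal variance: a flat BOLD trace means
    corrupt input, and its correlations are undefined.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.node_ids[i] for i in dead)
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -(1.0 - clip), 1.0 - clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return Connectome(ts.subject_id, z, n_scans_averaged=1,
                      node_ids=list(ts.node_ids))


def average_connectomes(connectomes: list[Connectome]) -> Connectome:
    """Elementwise mean over a subject's valid-scan connectomes (unweighted)."""
    if not connectomes:
        raise ValueError("cannot average an empty list of connectomes")
    first = connectomes[0]
    for c in connectomes[1:]:
        if c.z.shape != first.z.shape:
            raise ValueError("connectome dimensions differ across scans")
        if c.subject_id != first.subject_id:
            raise ValueError("connectomes belong to different subjects")
        if c.node_ids is not None and first.node_ids is not None \
                and c.node_ids != first.node_ids:
            raise ValueError("node order differs across scans")
    z = np.mean([c.z for c in connectomes], axis=0)
    np.fill_diagonal(z, 0.0)
    return Connectome(first.subject_id, z,
                      n_scans_averaged=len(connectomes),
                      node_ids=first.node_ids)


def triu_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: pairs (i, j), i < j, row-major upper triangle."""
    return np.triu_indices(n_nodes, k=1)


def vectorize(c: Connectome) -> np.ndarray:
    """Upper-triangle edge vector of length N(N-1)/2 in canonical order."""
    i, j = triu_pairs(c.n_nodes)
    return c.z[i, j].copy()


def devectorize(v: np.ndarray, n_nodes: int, subject_id: str = "") -> Connectome:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(v, dtype=float)
    expected = n_edges(n_nodes)
    if v.shape != (expected,):
        raise ValueError(
            f"edge vector length {v.size} != N(N-1)/2 = {expected} for N={n_nodes}")
    z = np.zeros((n_nodes, n_nodes))
    i, j = triu_pairs(n_nodes)
    z[i, j] = v
    z[j, i] = v
    return Connectome(subject_id, z)
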