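"""Virtual-lesion attribution and network-level summaries of predictive edges.

The atlas assigns each node to one of 10 canonical functional networks
(anterior/posterior default mode, central executive, salience, motor
sensory, two visual, visual association, subcortical, cerebellar).  A
virtual lesion keeps only the edges with at least one endpoint in the
network of interest (its within- and between-network connectivity) and
reruns the whole CPM pipeline on that restricted edge universe; networks
whose lesioned model outperforms the whole-brain model's median rho are
flagged as driving the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cpm
from .connectome import triu_pairs

CANONICAL_NETWORKS = ("aDMN", "pDMN", "CEN", "MSN", "VI", "VII",
                      "VAs", "SAL", "SC", "CBL")


@dataclass
class NetworkAtlas:
    """Node-to-network lookup over an ordered node list."""

    node_ids: list[str]
    labels: np.ndarray  # network label per node, aligned with node_ids

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.node_ids) != self.labels.size:
            raise ValueError("one network label required per node")

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def nodes_in(self, network: str) -> np.ndarray:
        if network not in self.networks:
            raise ValueError(f"unknown network label {network!r}")
        return np.flatnonzero(self.labels == network)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NetworkAtlas":
        return cls(df["node_id"].astype(str).tolist(),
                   df["network"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "network": self.labels})


@dataclass
class LesionResult:
    per_network: dict[str, dict]     # network -> {rho_per_repeat, median_rho}
    whole_brain_median: float
    driving_networks: list[str]


def lesion_mask(atlas: NetworkAtlas, network: str, n_nodes: int) -> np.ndarray:
    """Boolean edge mask: keep edges with >= 1 endpoint in ``network``."""
    if n_nodes != len(atlas.node_ids):
        raise ValueError("atlas size does not match node count")
    member = atlas.labels == network
    if not member.any():
        raise ValueError(f"unknown network label {network!r}")
    i, j = triu_pairs(n_nodes)
    return member[i] | member[j]


def run_lesion_cpm(edges: np.ndarray, y: np.ndarray, atlas: NetworkAtlas,
                   X: np.ndarray | None = None, *,
                   k: int = 10, repeats: int = 100, alpha: float = 0.05,
                   seed: int = 0, variant: str = "combined",
                   whole_brain_run: cpm.CVRun | None = None) -> LesionResult:
    """Rerun CPM once per network on its lesion-restricted edge universe.

    All runs (including whole-brain) share the same seed, hence identical
    fold assignments, so the outperformance comparison is paired.
    """
    n_nodes = len(atlas.node_ids)
    if whole_brain_run is None:
        whole_brain_run = cpm.run_cv(edges, y, X, k=k, repeats=repeats,
                                     alpha=alpha, seed=seed, variant=variant)
    wb_median = cpm.score(whole_brain_run)
    per_network: dict[str, dict] = {}
    for net in atlas.networks:
        mask = lesion_mask(atlas, net, n_nodes)
        run = cpm.run_cv(edges[:, mask], y, X, k=k, repeats=repeats,
                         alpha=alpha, seed=seed, variant=variant)
        per_network[net] = {
            "rho_per_repeat": run.rho_per_repeat,
            "median_rho": cpm.score(run),
        }
    driving = [net for net, d in per_network.items()
               if d["median_rho"] > wb_median]
    return LesionResult(per_network, wb_median, driving)


def degree_centrality(mask: np.ndarray, n_nodes: int) -> np.ndarray:
    """Count of selected edges incident to each node (handshake: sums to 2E)."""
    i, j = triu_pairs(n_nodes)
    if mask.size != i.size:
        raise ValueError("mask length does not match N(N-1)/2")
    deg = np.zeros(n_nodes, dtype=int)
    np.add.at(deg, i[mask], 1)
    np.add.at(deg, j[mask], 1)
    return deg


def network_contribution(mask: np.ndarray, atlas: NetworkAtlas
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selected-edge counts per network pair, raw and density-normalized.

    The density variant divides by the number of possible node pairs
    spanning the network pair: n_a * n_b off-diagonal, n_a (n_a - 1) / 2 on
    the diagonal.
    """
    nets = atlas.networks
    n_nodes = len(atlas.node_ids)
    i, j = triu_pairs(n_nodes)
    if mask.size != i.size:
        raise ValueError("mask length does not match N(N-1)/2")
    idx = {net: q for q, net in enumerate(nets)}
    lab_i = np.array([idx[atlas.labels[a]] for a in i])
    lab_j = np.array([idx[atlas.labels[b]] for b in j])
    m = len(nets)
    counts = np.zeros((m, m), dtype=int)
    np.add.at(counts, (lab_i[mask], lab_j[mask]), 1)
    counts = counts + counts.T - np.diag(np.diag(counts))
    sizes = np.array([(atlas.labels == net).sum() for net in nets])
    possible = np.outer(sizes, sizes).astype(float)
    np.fill_diagonal(possible, sizes * (sizes - 1) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(possible > 0, counts / possible, 0.0)
    raw = pd.DataFrame(counts, index=nets, columns=nets)
    norm = pd.DataFrame(density, index=nets, columns=nets)
    return raw, norm
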