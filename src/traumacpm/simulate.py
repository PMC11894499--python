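"""Synthetic trauma-survivor cohorts with known ground truth.

The generator emulates the statistical structure the CPM pipeline assumes,
so that every stage — edge screening, cross-validated prediction,
permutation significance, cluster models, virtual lesions — is testable
without any neuroimaging download:

* a five-class longitudinal symptom-trajectory mixture (low, remitting,
  moderate, high, delayed) with population prevalences 64.5 / 16.9 / 6.7 /
  6.5 / 5.5 %, driving a latent severity per subject per timepoint
  (1, 6, 14 months);
* CAPS-5 item scores (20 ordinal items, 0-4; clusters B=5, C=2, D=7, E=6
  items) thresholded from latent-plus-noise, so totals live in 0-80 and
  cluster scores sum to the total;
* per-subject functional connectomes for 3 scan modalities: a shared
  subject connectome plus independent scan noise, with a configured set of
  "planted" edges whose Fisher-z strength shifts by -beta per SD of
  1-month latent severity (decreased connectivity <-> worse symptoms),
  concentrated in configurable target networks;
* confounds (age, sex, head motion) and nested follow-up dropout at the
  study's retention rates (84.0% at 6 months, 82.1% at 14 months),
  missing-completely-at-random by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectome import n_edges, triu_pairs
from .networks import CANONICAL_NETWORKS, NetworkAtlas

TIMEPOINTS = ("1m", "6m", "14m")

#: CAPS-5 items per DSM-5 cluster (external instrument convention; the
#: four clusters partition the 20 items).
DEFAULT_CLUSTER_ITEMS = {"B": 5, "C": 2, "D": 7, "E": 6}

#: Ordinal thresholds on the item latent (latent severity + N(0,1) noise);
#: item score = number of thresholds exceeded, in {0..4}.
DEFAULT_ITEM_THRESHOLDS = (-0.5, 0.5, 1.5, 2.5)


#: Published trajectory prevalences (64.5/16.9/6.7/6.5/5.5 %) sum to 100.1%
#: because each is rounded to one decimal; the default mixture renormalizes
#: them to an exact probability vector.
_PREVALENCES = (0.645, 0.169, 0.067, 0.065, 0.055)
DEFAULT_WEIGHTS = tuple(w / sum(_PREVALENCES) for w in _PREVALENCES)


@dataclass
class TrajectoryModel:
    """Five-class mixture of latent-severity profiles over 1/6/14 months."""

    classes: tuple[str, ...] = ("low", "remitting", "moderate", "high", "delayed")
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    profiles: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "low": (-0.9, -1.0, -1.1),
        "remitting": (0.9, 0.0, -0.5),
        "moderate": (0.3, 0.25, 0.2),
        "high": (1.5, 1.55, 1.6),
        "delayed": (-0.1, 0.5, 1.2),
    })
    subject_sd: float = 0.4  # subject-level deviation shared across timepoints

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.classes):
            raise ValueError("one weight per class required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {sum(self.weights)}, not 1")
        prof = self.profiles
        if "remitting" in prof and not np.all(np.diff(prof["remitting"]) < 0):
            raise ValueError("remitting profile must decrease over time")
        if "delayed" in prof and not np.all(np.diff(prof["delayed"]) > 0):
            raise ValueError("delayed profile must increase over time")


@dataclass
class GroundTruth:
    planted_edges: np.ndarray         # edge indices into the canonical ordering
    effects: np.ndarray               # signed z-shift per SD of latent severity
    target_networks: tuple[str, ...]
    latent: np.ndarray | None = None  # (n, 3) latent severity per timepoint
    classes: np.ndarray | None = None  # (n,) trajectory class labels


@dataclass
class CohortConfig:
    """Generation parameters; defaults are the package's study conditions."""

    n_subjects: int = 160
    n_nodes: int = 60                 # 268 for full-fidelity runs
    n_scans: int = 3
    target_networks: tuple[str, ...] = ("aDMN",)
    n_planted: int = 40
    concentration: float = 0.9        # fraction of planted edges touching targets
    beta: float = 0.15                # z-units per SD of 1-month latent severity
    positive_fraction: float = 0.02   # planted edges with a positive sign
    edge_mean: float = 0.25           # population Fisher-z mean
    edge_mean_sd: float = 0.15        # spread of the population edge means
    subject_noise: float = 0.10       # per-edge subject deviation (z units)
    scan_noise: float = 0.20          # per-edge independent scan noise (z units)
    retention_6m: float = 0.84
    retention_14m: float = 0.821
    trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)


@dataclass
class SyntheticCohort:
    subject_ids: list[str]
    edges: np.ndarray                 # (n, E) averaged Fisher-z edge matrix
    scan_edges: np.ndarray            # (n, n_scans, E)
    phenotype: pd.DataFrame
    atlas: NetworkAtlas
    truth: GroundTruth
    config: CohortConfig
    seed: int


def default_atlas(n_nodes: int = 60) -> NetworkAtlas:
    """Ten canonical networks of near-equal size over ``n_nodes`` nodes."""
    if n_nodes < 10:
        raise ValueError("need at least one node per network")
    labels = [CANONICAL_NETWORKS[(i * 10) // n_nodes] for i in range(n_nodes)]
    node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    return NetworkAtlas(node_ids, np.array(labels, dtype=object))


def sample_trajectories(n: int, model: TrajectoryModel | None = None,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw trajectory classes and latent severities for ``n`` subjects.

    Returns (classes, latent) where latent is (n, 3): the class profile at
    1/6/14 months plus a subject-level Gaussian deviation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or TrajectoryModel()
    rng = np.random.default_rng(seed)
    classes = rng.choice(model.classes, size=n, p=model.weights)
    profiles = np.array([model.profiles[c] for c in classes])
    latent = profiles + rng.normal(0.0, model.subject_sd, size=(n, 1))
    return classes, latent


def simulate_caps(latent: np.ndarray,
                  cluster_items: dict[str, int] | None = None,
                  thresholds: tuple[float, ...] = DEFAULT_ITEM_THRESHOLDS,
                  seed: int = 0) -> pd.DataFrame:
    """Ordinal CAPS-5 scores from latent severity.

    Each of the 20 items adds unit-variance noise to the latent and counts
    the thresholds exceeded (score 0-4); the total is the item sum (0-80)
    and cluster scores are within-cluster sums.
    """
    cluster_items = cluster_items or DEFAULT_CLUSTER_ITEMS
    n_items = sum(cluster_items.values())
    if n_items != 20:
        raise ValueError(f"cluster item counts sum to {n_items}, expected 20")
    latent = np.atleast_2d(np.asarray(latent, float))
    n, n_tp = latent.shape
    rng = np.random.default_rng(seed)
    u = latent[:, :, None] + rng.standard_normal((n, n_tp, n_items))
    items = (u[..., None] > np.asarray(thresholds)).sum(axis=-1)
    cols = {}
    start = 0
    tp_names = TIMEPOINTS[:n_tp]
    for cl, count in cluster_items.items():
        block = items[:, :, start:start + count].sum(axis=2)
        for t, tp in enumerate(tp_names):
            cols[f"caps_{cl}_{tp}"] = block[:, t]
        start += count
    totals = items.sum(axis=2)
    for t, tp in enumerate(tp_names):
        cols[f"caps_total_{tp}"] = totals[:, t]
    return pd.DataFrame(cols)


def simulate_connectomes(n: int, n_nodes: int, atlas: NetworkAtlas,
                         latent_1m: np.ndarray,
                         config: CohortConfig | None = None,
                         seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Per-subject scan connectomes with planted severity effects.

    Planted edges shift by ``effect * standardized latent severity``; the
    effect is -beta for most planted edges (decreased connectivity with
    worse symptoms) and +beta for a small positive fraction.  Returns
    (scan_edges (n, n_scans, E), averaged_edges (n, E), GroundTruth).
    """
    cfg = config or CohortConfig(n_subjects=n, n_nodes=n_nodes)
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    for net in cfg.target_networks:
        if net not in atlas.networks:
            raise ValueError(f"target network {net!r} not in atlas")
    rng = np.random.default_rng(seed)
    E = n_edges(n_nodes)
    i, j = triu_pairs(n_nodes)
    in_target = np.zeros(n_nodes, bool)
    for net in cfg.target_networks:
        in_target[atlas.nodes_in(net)] = True
    target_edges = np.flatnonzero(in_target[i] | in_target[j])
    other_edges = np.flatnonzero(~(in_target[i] | in_target[j]))
    n_in = int(round(cfg.concentration * cfg.n_planted))
    n_out = cfg.n_planted - n_in
    if n_in > target_edges.size or n_out > other_edges.size:
        raise ValueError(
            f"cannot place {n_in}+{n_out} planted edges: only "
            f"{target_edges.size} target and {other_edges.size} other edges")
    planted = np.concatenate([
        rng.choice(target_edges, size=n_in, replace=False),
        rng.choice(other_edges, size=n_out, replace=False),
    ])
    signs = np.where(rng.random(cfg.n_planted) < cfg.positive_fraction, 1.0, -1.0)
    effects = signs * cfg.beta

    s = np.asarray(latent_1m, float)
    s = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
    mu = rng.normal(cfg.edge_mean, cfg.edge_mean_sd, size=E)
    subject_edges = mu + rng.normal(0.0, cfg.subject_noise, size=(n, E))
    subject_edges[:, planted] += np.outer(s, effects)
    scan_edges = subject_edges[:, None, :] + rng.normal(
        0.0, cfg.scan_noise, size=(n, cfg.n_scans, E))
    averaged = scan_edges.mean(axis=1)
    truth = GroundTruth(planted, effects, tuple(cfg.target_networks),
                        latent=None, classes=None)
    return scan_edges, averaged, truth


def apply_dropout(phenotype: pd.DataFrame, retention_6m: float = 0.84,
                  retention_14m: float = 0.821, seed: int = 0,
                  nested: bool = True,
                  informative_strength: float = 0.0,
                  latent: np.ndarray | None = None) -> pd.DataFrame:
    """Mask follow-up scores for non-retained subjects.

    By default retention is missing-completely-at-random and 14-month
    completers are a subset of 6-month completers.  A positive
    ``informative_strength`` tilts dropout toward higher latent severity
    (for robustness studies only).
    """
    for r in (retention_6m, retention_14m):
        if not 0 < r <= 1:
            raise ValueError("retention rates must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(phenotype)
    p6 = np.full(n, retention_6m)
    p14_given_6 = min(retention_14m / retention_6m, 1.0)
    if informative_strength and latent is not None:
        tilt = informative_strength * (latent[:, 0] - latent[:, 0].mean())
        p6 = np.clip(p6 - tilt, 0.0, 1.0)
    keep6 = rng.random(n) < p6
    if nested:
        keep14 = keep6 & (rng.random(n) < p14_given_6)
    else:
        keep14 = rng.random(n) < retention_14m
    out = phenotype.copy()
    cols6 = [c for c in out.columns if c.endswith("_6m")]
    cols14 = [c for c in out.columns if c.endswith("_14m")]
    out[cols6] = out[cols6].astype(float)
    out[cols14] = out[cols14].astype(float)
    out.loc[~keep6, cols6] = np.nan
    out.loc[~keep14, cols14] = np.nan
    out["completed_6m"] = keep6
    out["completed_14m"] = keep14
    return out


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Compose a full cohort: trajectories, CAPS-5, connectomes, confounds,
    dropout.  Bit-reproducible from ``seed``."""
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    s_traj, s_caps, s_conn, s_cov, s_drop = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    n = cfg.n_subjects
    classes, latent = sample_trajectories(n, cfg.trajectory, seed=s_traj)
    caps = simulate_caps(latent, seed=s_caps)
    atlas = default_atlas(cfg.n_nodes)
    scan_edges, averaged, truth = simulate_connectomes(
        n, cfg.n_nodes, atlas, latent[:, 0], cfg, seed=s_conn)
    truth.latent = latent
    truth.classes = classes

    rng = np.random.default_rng(s_cov)
    phen = caps.copy()
    phen.insert(0, "subject_id", [f"sub{idx:04d}" for idx in range(n)])
    phen["age"] = np.clip(rng.normal(33.9, 11.5, n), 18, 65).round(1)
    phen["sex"] = (rng.random(n) < 0.494).astype(int)  # 1 = female
    phen["motion"] = rng.gamma(4.0, 0.03, n).round(4)  # mean FD, mm
    phen = apply_dropout(phen, cfg.retention_6m, cfg.retention_14m,
                         seed=s_drop)
    return SyntheticCohort(phen["subject_id"].tolist(), averaged, scan_edges,
                           phen, atlas, truth, cfg, seed)
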